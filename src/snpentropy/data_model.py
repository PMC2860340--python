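"""Per-SNP case-control count tables and tabulation from raw genotype vectors.

Genotypes of a biallelic marker are coded as the number of copies of the
designated minor allele ``A``: ``2`` = AA (minor homozygote), ``1`` = Aa,
``0`` = aa.  Which allele is "minor" is fixed per SNP from the pooled
sample before any testing; every test statistic in this package is
invariant to that labelling, so the choice only affects reporting.

Missing genotypes are excluded per SNP (listwise within the SNP), so the
effective sample size may differ between SNPs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "MISSING",
    "Phenotype",
    "GenotypeCountTable",
    "AlleleCountTable",
    "DegenerateTableError",
    "tabulate_genotypes",
    "genotype_to_allele_table",
]

#: Sentinel integer for a missing genotype code in integer matrices.
MISSING: int = -1


class DegenerateTableError(ValueError):
    """Raised when a count table is empty and no test can be formed."""


class Phenotype(enum.Enum):
    """Binary disease status of one individual."""

    CASE = "case"
    CONTROL = "control"

    @classmethod
    def coerce(cls, value: Union["Phenotype", str, int]) -> "Phenotype":
        """Accept ``Phenotype``, ``"case"``/``"control"``, or PLINK 2/1."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            v = value.strip().lower()
            if v in ("case", "2"):
                return cls.CASE
            if v in ("control", "1"):
                return cls.CONTROL
        if isinstance(value, (int, np.integer)):
            if value == 2:
                return cls.CASE
            if value == 1:
                return cls.CONTROL
        raise ValueError(f"unrecognised phenotype label: {value!r}")


def _check_counts(name: str, counts: Sequence[int], k: int) -> tuple[int, ...]:
    counts = tuple(int(c) for c in counts)
    if len(counts) != k:
        raise ValueError(f"{name} must have {k} entries, got {len(counts)}")
    if any(c < 0 for c in counts):
        raise ValueError(f"{name} must be non-negative, got {counts}")
    return counts


@dataclass(frozen=True)
class GenotypeCountTable:
    """2x3 contingency table of genotype counts by case/control status.

    Counts are ordered ``(AA, Aa, aa)`` where ``A`` is the minor allele,
    i.e. by descending genotype code ``(2, 1, 0)``.
    """

    counts_cases: tuple[int, int, int]
    counts_controls: tuple[int, int, int]
    snp_id: str = "snp"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts_cases", _check_counts("counts_cases", self.counts_cases, 3)
        )
        object.__setattr__(
            self,
            "counts_controls",
            _check_counts("counts_controls", self.counts_controls, 3),
        )

    @property
    def n_cases(self) -> int:
        return sum(self.counts_cases)

    @property
    def n_controls(self) -> int:
        return sum(self.counts_controls)

    @property
    def n(self) -> int:
        """Total individuals tabulated at this SNP."""
        return self.n_cases + self.n_controls

    def to_array(self) -> np.ndarray:
        """Counts as a (2, 3) array, rows = (cases, controls)."""
        return np.array([self.counts_cases, self.counts_controls], dtype=np.int64)

    @property
    def column_totals(self) -> tuple[int, int, int]:
        return tuple(a + b for a, b in zip(self.counts_cases, self.counts_controls))

    @property
    def maf_pooled(self) -> float:
        """Pooled frequency of the designated minor allele."""
        if self.n == 0:
            raise DegenerateTableError(f"{self.snp_id}: empty table")
        aa, ab, _ = self.column_totals
        return (2 * aa + ab) / (2 * self.n)


@dataclass(frozen=True)
class AlleleCountTable:
    """2x2 table of allele counts (A, a) by case/control status."""

    alleles_cases: tuple[int, int]
    alleles_controls: tuple[int, int]
    snp_id: str = "snp"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "alleles_cases", _check_counts("alleles_cases", self.alleles_cases, 2)
        )
        object.__setattr__(
            self,
            "alleles_controls",
            _check_counts("alleles_controls", self.alleles_controls, 2),
        )

    @property
    def m(self) -> int:
        """Total allele count (2N when no genotype was missing)."""
        return sum(self.alleles_cases) + sum(self.alleles_controls)

    def to_array(self) -> np.ndarray:
        return np.array([self.alleles_cases, self.alleles_controls], dtype=np.int64)

    @property
    def column_totals(self) -> tuple[int, int]:
        return tuple(a + b for a, b in zip(self.alleles_cases, self.alleles_controls))


def tabulate_genotypes(
    genotype_codes: Iterable,
    labels: Iterable,
    snp_id: str = "snp",
) -> GenotypeCountTable:
    """Count genotypes by status into a :class:`GenotypeCountTable`.

    Parameters
    ----------
    genotype_codes
        Per-individual codes in ``{0, 1, 2}``; missing genotypes may be
        given as ``None``, ``NaN``, ``"NA"`` or :data:`MISSING`.
    labels
        Per-individual phenotype, anything :meth:`Phenotype.coerce` accepts.
    snp_id
        Marker identifier carried through to results.

    Individuals missing at this SNP are dropped from this SNP's table only.

    Raises
    ------
    ValueError
        If lengths differ or a code is outside the alphabet.
    DegenerateTableError
        If every genotype is missing.
    """
    codes = list(genotype_codes)
    labs = [Phenotype.coerce(l) for l in labels]
    if len(codes) != len(labs):
        raise ValueError(
            f"{snp_id}: {len(codes)} genotype codes but {len(labs)} labels"
        )
    counts = {Phenotype.CASE: [0, 0, 0], Phenotype.CONTROL: [0, 0, 0]}
    n_used = 0
    for code, lab in zip(codes, labs):
        if code is None or code == "NA":
            continue
        if isinstance(code, float) and np.isnan(code):
            continue
        c = int(code)
        if c == MISSING:
            continue
        if c not in (0, 1, 2):
            raise ValueError(f"{snp_id}: invalid genotype code {code!r}")
        # column order is (AA, Aa, aa) = codes (2, 1, 0)
        counts[lab][2 - c] += 1
        n_used += 1
    if n_used == 0:
        raise DegenerateTableError(f"{snp_id}: all genotypes missing")
    return GenotypeCountTable(
        counts_cases=tuple(counts[Phenotype.CASE]),
        counts_controls=tuple(counts[Phenotype.CONTROL]),
        snp_id=snp_id,
    )


def genotype_to_allele_table(table: GenotypeCountTable) -> AlleleCountTable:
    """Collapse a genotype table to allele counts.

    Each AA individual contributes two ``A`` alleles, each Aa one of each,
    each aa two ``a`` alleles, separately per status group, so the total
    allele count is exactly twice the individual count.
    """

    def collapse(counts: Sequence[int]) -> tuple[int, int]:
        aa, ab, bb = counts
        return (2 * aa + ab, ab + 2 * bb)

    return AlleleCountTable(
        alleles_cases=collapse(table.counts_cases),
        alleles_controls=collapse(table.counts_controls),
        snp_id=table.snp_id,
    )
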