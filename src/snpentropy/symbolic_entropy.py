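"""Symbolic-entropy likelihood-ratio tests of case-control association.

Each individual at a marker is labelled with the *symbol* (genotype,
status): six symbols for a genotypic analysis (three genotypes x two
statuses), four for an allelic one.  Writing ``h(C, C^c)`` for the
entropy of the case/control split, ``h(S)`` for the entropy of the
pooled genotype (or allele) distribution, and ``h(S, ca)``, ``h(S, co)``
for the partial entropies of the within-status symbols taken at their
*joint* frequencies ``n(X, t) / N``, the statistic for one SNP is

    GE = 2 N * [ h(C, C^c) + h(S) - h(S, ca) - h(S, co) ]

which is 2N times the mutual information between genotype and status
and, algebraically, exactly the likelihood-ratio G-statistic
``2 * sum O ln(O / E)`` of the 2x3 (or 2x2) contingency table.  Under
the null of identical genotype distributions in cases and controls it is
asymptotically chi-square with 2 degrees of freedom (genotypic) or 1
(allelic, multiplier = total allele count M = 2N).

All entropies are in nats: the chi-square asymptotics of the LRT require
the natural logarithm.  The convention ``0 * ln 0 = 0`` is applied
throughout, so empty symbol classes never poison the statistic; degrees
of freedom are *not* adapted when a genotype or allele class is absent,
which makes the tests conservative for very rare alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2

from .data_model import AlleleCountTable, DegenerateTableError, GenotypeCountTable

__all__ = [
    "EntropyDecomposition",
    "TestResult",
    "shannon_entropy",
    "entropy_decomposition",
    "entropy_genotypic_test",
    "entropy_allelic_test",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class EntropyDecomposition:
    """The four symbolic entropies of one SNP, in nats."""

    h_case_control: float
    h_symbols: float
    h_symbols_cases: float
    h_symbols_controls: float

    @property
    def mutual_information(self) -> float:
        """``h(C,C^c) + h(S) - h(S,ca) - h(S,co)`` >= 0, in nats.

        Zero exactly when the genotype distribution is identical in
        cases and controls; tiny negative rounding residue is clipped.
        """
        mi = (
            self.h_case_control
            + self.h_symbols
            - self.h_symbols_cases
            - self.h_symbols_controls
        )
        return max(mi, 0.0)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one association test on one SNP."""

    __test__ = False  # not a pytest test class despite the name

    statistic: float
    df: int
    p_value: float
    test_name: str
    n_used: int
    snp_id: str = "snp"
    degenerate: bool = field(default=False)


def shannon_entropy(relative_frequencies: Sequence[float]) -> float:
    """Shannon entropy ``-sum q ln q`` in nats, with ``0 ln 0 = 0``.

    Frequencies must be non-negative and sum to 1 within 1e-9.
    """
    q = np.asarray(relative_frequencies, dtype=float)
    if q.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(q < 0):
        raise ValueError(f"negative relative frequency in {q!r}")
    total = q.sum()
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"relative frequencies sum to {total!r}, not 1")
    return float(-xlogy(q, q).sum())


def _joint_entropies(counts: np.ndarray) -> EntropyDecomposition:
    """Entropies from a (2, k) count array, rows = (cases, controls)."""
    n = counts.sum()
    if n == 0:
        raise DegenerateTableError("empty count table")
    joint = counts / n
    row = joint.sum(axis=1)  # (N_ca/N, N_co/N)
    col = joint.sum(axis=0)  # pooled symbol frequencies

    def h(q: np.ndarray) -> float:
        return float(-xlogy(q, q).sum())

    return EntropyDecomposition(
        h_case_control=h(row),
        h_symbols=h(col),
        h_symbols_cases=h(joint[0]),
        h_symbols_controls=h(joint[1]),
    )


def entropy_decomposition(
    table: Union[GenotypeCountTable, AlleleCountTable],
) -> EntropyDecomposition:
    """The four entropies of one SNP's count table.

    The partial-group entropies use joint frequencies ``n(X, t) / N``,
    not within-group frequencies; this is the reading under which the
    statistic equals the multinomial likelihood-ratio test and the
    decomposition is a mutual information.
    """
    return _joint_entropies(table.to_array())


def _is_degenerate(counts: np.ndarray) -> bool:
    """A single pooled symbol class carries all mass (e.g. monomorphic)."""
    return int((counts.sum(axis=0) > 0).sum()) <= 1


def _entropy_test(
    counts: np.ndarray, multiplier: int, df: int, name: str, n_used: int, snp_id: str
) -> TestResult:
    dec = _joint_entropies(counts)
    stat = 2.0 * multiplier * dec.mutual_information
    return TestResult(
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
        test_name=name,
        n_used=n_used,
        snp_id=snp_id,
        degenerate=_is_degenerate(counts),
    )


def entropy_genotypic_test(table: GenotypeCountTable) -> TestResult:
    """Genotypic entropy test: ``GE = 2N * MI``, chi-square with 2 df.

    A monomorphic SNP yields statistic 0, p = 1 and the degenerate flag;
    df stays at 2 even when genotype classes are empty.
    """
    return _entropy_test(
        table.to_array(), table.n, 2, "entropy_genotypic", table.n, table.snp_id
    )


def entropy_allelic_test(table: AlleleCountTable) -> TestResult:
    """Allelic entropy test: ``AL = 2M * MI``, chi-square with 1 df.

    ``M`` is the total allele count — 2N when no genotype was missing —
    making the statistic the exact LRT of the allele-level multinomial.
    """
    return _entropy_test(
        table.to_array(), table.m, 1, "entropy_allelic", table.m // 2, table.snp_id
    )
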