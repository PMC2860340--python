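"""Case-control genotype simulator under HWE with a fixed allelic odds ratio.

For each SNP a control minor-allele frequency ``p_co`` is either fixed
or drawn uniformly, the case frequency ``p_ca`` is solved from the
allelic odds ratio

    OR = [p_ca / (1 - p_ca)] / [p_co / (1 - p_co)],

and genotypes are drawn per status group from the Hardy-Weinberg
probabilities ``(q^2, 2pq, p^2)`` for codes ``(0, 1, 2)`` with
``q = 1 - p``.  The OR is defined on allele frequencies; genotype odds
ratios follow from HWE.

Each group's genotype counts are drawn as a single multinomial
(equivalent in distribution to i.i.d. individual draws, and faster);
individual-level codes are then laid out in a fixed order.  Every SNP
uses its own deterministic substream of the seeded generator, so
changing ``n_snps`` never perturbs the data of earlier SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .data_model import GenotypeCountTable, Phenotype

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "case_maf_from_or",
    "simulate_genotypes",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation scenario.

    ``maf_controls`` is either a fixed control-group minor allele
    frequency in (0, 0.5] or the string ``"random"``, in which case each
    SNP draws its own frequency uniformly from ``random_maf_bounds``
    (the same frequency feeds both groups when ``odds_ratio`` is 1).
    """

    n_cases: int
    n_controls: int
    n_snps: int
    odds_ratio: float = 1.0
    maf_controls: Union[float, str] = "random"
    random_maf_bounds: tuple[float, float] = (1e-6, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_snps) < 1:
            raise ValueError("n_cases, n_controls and n_snps must be >= 1")
        if not self.odds_ratio > 0:
            raise ValueError(f"odds_ratio must be > 0, got {self.odds_ratio}")
        if isinstance(self.maf_controls, str):
            if self.maf_controls != "random":
                raise ValueError(f"maf_controls: {self.maf_controls!r}")
            lo, hi = self.random_maf_bounds
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"bad random_maf_bounds {self.random_maf_bounds}")
        elif not (0 <= self.maf_controls <= 0.5):
            # p = 0 is allowed and yields an all-reference-homozygote SNP
            raise ValueError(f"maf_controls must be in [0, 0.5], got {self.maf_controls}")


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated genotypes with their generating parameters.

    ``genotypes`` is (individuals x SNPs) with codes 0/1/2; cases occupy
    the first ``n_cases`` rows.  ``snp_params`` records the true
    per-SNP ``(maf_controls, maf_cases, odds_ratio)``.
    """

    genotypes: np.ndarray
    phenotypes: tuple[Phenotype, ...]
    snp_ids: tuple[str, ...]
    snp_params: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def count_table(self, snp_index: int) -> GenotypeCountTable:
        """2x3 genotype count table for one SNP (no missing data here)."""
        n_ca = sum(1 for p in self.phenotypes if p is Phenotype.CASE)
        col = self.genotypes[:, snp_index]
        cases = np.bincount(col[:n_ca], minlength=3)
        controls = np.bincount(col[n_ca:], minlength=3)
        # column order (AA, Aa, aa) = codes (2, 1, 0)
        return GenotypeCountTable(
            counts_cases=tuple(int(c) for c in cases[::-1]),
            counts_controls=tuple(int(c) for c in controls[::-1]),
            snp_id=self.snp_ids[snp_index],
        )


def case_maf_from_or(maf_controls: float, odds_ratio: float) -> float:
    """Case minor-allele frequency giving the target allelic odds ratio.

    Solves ``[p_ca/(1-p_ca)] / [p_co/(1-p_co)] = OR`` in closed form:
    ``p_ca = OR * p_co / (1 - p_co + OR * p_co)``.
    """
    if not (0 < maf_controls < 1):
        raise ValueError(f"maf_controls must be in (0, 1), got {maf_controls}")
    if not odds_ratio > 0:
        raise ValueError(f"odds_ratio must be > 0, got {odds_ratio}")
    return odds_ratio * maf_controls / (1 - maf_controls + odds_ratio * maf_controls)


def hwe_probabilities(p: float) -> np.ndarray:
    """HWE genotype probabilities for codes (0, 1, 2) at allele freq p."""
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def _snp_rng(seed: int, snp_index: int) -> np.random.Generator:
    # deterministic per-SNP substream; independent of n_snps
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(snp_index,)))


def _group_codes(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    counts = rng.multinomial(n, hwe_probabilities(p))
    return np.repeat(np.array([0, 1, 2], dtype=np.int8), counts)


def simulate_genotypes(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full case-control dataset from a :class:`SimulationConfig`.

    Fully reproducible: the same config (including seed) yields a
    bit-identical dataset.
    """
    n_ca, n_co = config.n_cases, config.n_controls
    genotypes = np.empty((n_ca + n_co, config.n_snps), dtype=np.int8)
    params = []
    for j in range(config.n_snps):
        rng = _snp_rng(config.seed, j)
        if config.maf_controls == "random":
            lo, hi = config.random_maf_bounds
            p_co = float(rng.uniform(lo, hi))
        else:
            p_co = float(config.maf_controls)
        p_ca = p_co if config.odds_ratio == 1 else case_maf_from_or(p_co, config.odds_ratio)
        genotypes[:n_ca, j] = _group_codes(rng, n_ca, p_ca)
        genotypes[n_ca:, j] = _group_codes(rng, n_co, p_co)
        params.append((f"snp{j}", p_co, p_ca, config.odds_ratio))
    snp_params = pd.DataFrame(
        params, columns=["snp_id", "maf_controls", "maf_cases", "odds_ratio"]
    )
    return SimulatedDataset(
        genotypes=genotypes,
        phenotypes=tuple([Phenotype.CASE] * n_ca + [Phenotype.CONTROL] * n_co),
        snp_ids=tuple(snp_params["snp_id"]),
        snp_params=snp_params,
        config=config,
    )
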