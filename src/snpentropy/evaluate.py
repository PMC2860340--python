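"""Monte-Carlo harness for empirical size, power and statistic gains.

For each scenario in an :class:`ExperimentGrid` the harness simulates a
dataset, runs the requested association tests on every SNP, and reports
the empirical rejection rate (fraction of SNPs with p < alpha) at each
significance level, together with the mean difference and mean
proportional gain between the entropy statistics and their conventional
chi-square counterparts.  Rejection rates over n SNPs are binomial
proportions; their standard error ``sqrt(r (1-r) / n)`` is included in
the report.

Degenerate SNPs (e.g. monomorphic draws at very low MAF) are kept in
the denominator with p = 1, preserving the unconditional interpretation
of the type-I-error estimates.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import genotype_to_allele_table
from .reference_tests import (
    fisher_exact_2x2,
    fisher_exact_2x3,
    pearson_chisq_allelic,
    pearson_chisq_genotypic,
)
from .simulate import SimulatedDataset, SimulationConfig, simulate_genotypes
from .symbolic_entropy import TestResult, entropy_allelic_test, entropy_genotypic_test

__all__ = [
    "DEFAULT_ALPHAS",
    "TEST_REGISTRY",
    "GAIN_PAIRS",
    "ExperimentGrid",
    "GainSummary",
    "PowerReport",
    "empirical_rejection_rate",
    "run_snp_tests",
    "chisq_gain",
    "run_experiment",
    "derive_config_seed",
    "preset_grid",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS: tuple[float, ...] = (0.05, 0.01, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7)

#: test name -> callable on a GenotypeCountTable
TEST_REGISTRY: Mapping[str, Callable] = {
    "entropy_genotypic": entropy_genotypic_test,
    "entropy_allelic": lambda t: entropy_allelic_test(genotype_to_allele_table(t)),
    "chisq_genotypic": pearson_chisq_genotypic,
    "chisq_allelic": lambda t: pearson_chisq_allelic(genotype_to_allele_table(t)),
    "fisher_2x2": lambda t: fisher_exact_2x2(genotype_to_allele_table(t)),
    "fisher_2x3": fisher_exact_2x3,
}

#: (entropy test, conventional counterpart) pairs for the gain summary
GAIN_PAIRS: tuple[tuple[str, str], ...] = (
    ("entropy_genotypic", "chisq_genotypic"),
    ("entropy_allelic", "chisq_allelic"),
)


@dataclass(frozen=True)
class ExperimentGrid:
    """A batch of simulation scenarios, significance levels and tests."""

    configs: tuple[SimulationConfig, ...]
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    tests: tuple[str, ...] = ("entropy_genotypic", "entropy_allelic",
                              "chisq_genotypic", "chisq_allelic")

    def __post_init__(self) -> None:
        if not all(0 < a < 1 for a in self.alphas):
            raise ValueError(f"alphas must lie strictly in (0, 1): {self.alphas}")
        unknown = set(self.tests) - set(TEST_REGISTRY)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")


@dataclass(frozen=True)
class GainSummary:
    """Mean statistic difference and mean proportional gain of a over b."""

    mean_difference: float
    mean_proportional_gain: float
    n_snps: int
    n_excluded_zero: int  # SNPs with a zero comparator statistic


@dataclass
class PowerReport:
    """Rejection rates and gain summaries for every grid cell.

    ``rates`` has one row per (config, test, alpha) with the empirical
    rejection rate, rejection count, total SNP count and binomial SE.
    ``gains`` has one row per (config, entropy test vs comparator).
    ``p_values``/``statistics`` hold the raw per-SNP results per config.
    """

    rates: pd.DataFrame
    gains: pd.DataFrame
    p_values: dict = field(repr=False, default_factory=dict)
    statistics: dict = field(repr=False, default_factory=dict)

    def to_tsv(self, path) -> None:
        self.rates.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def format_table(self, config_index: int = 0) -> str:
        """Human-readable rates table for one config: tests x alphas."""
        sub = self.rates[self.rates["config"] == config_index]
        wide = sub.pivot(index="alpha", columns="test", values="rate")
        wide = wide.sort_index(ascending=False)
        return wide.to_string(float_format=lambda x: f"{x:.4f}")


def empirical_rejection_rate(
    p_values: Sequence[float], alphas: Sequence[float]
) -> dict[float, float]:
    """Fraction of p-values strictly below each alpha.

    Degenerate-SNP p-values (= 1) stay in the denominator.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return {float(a): float(np.mean(p < a)) for a in alphas}


def run_snp_tests(
    dataset: SimulatedDataset, tests: Sequence[str]
) -> dict[str, list[TestResult]]:
    """Run each requested test on every SNP of a simulated dataset."""
    results: dict[str, list[TestResult]] = {name: [] for name in tests}
    for j in range(dataset.n_snps):
        table = dataset.count_table(j)
        for name in tests:
            results[name].append(TEST_REGISTRY[name](table))
    return results


def chisq_gain(
    results_a: Sequence[TestResult], results_b: Sequence[TestResult]
) -> GainSummary:
    """Mean (stat_a - stat_b) and mean (stat_a - stat_b) / stat_b.

    SNPs where the comparator statistic is zero are excluded from the
    proportional mean (their count is reported) but kept in the plain
    difference.
    """
    if len(results_a) != len(results_b):
        raise ValueError("mismatched result lists")
    for ra, rb in zip(results_a, results_b):
        if ra.snp_id != rb.snp_id:
            raise ValueError(f"mismatched SNPs: {ra.snp_id} vs {rb.snp_id}")
    a = np.array([r.statistic for r in results_a])
    b = np.array([r.statistic for r in results_b])
    nonzero = b > 0
    prop = float(np.mean((a[nonzero] - b[nonzero]) / b[nonzero])) if nonzero.any() else 0.0
    return GainSummary(
        mean_difference=float(np.mean(a - b)),
        mean_proportional_gain=prop,
        n_snps=len(results_a),
        n_excluded_zero=int((~nonzero).sum()),
    )


def derive_config_seed(master_seed: int, config: SimulationConfig) -> int:
    """Deterministic sub-seed (< 2^31) from a master seed and a config."""
    key = (
        f"{master_seed}|{config.n_cases}|{config.n_controls}|{config.n_snps}|"
        f"{config.odds_ratio}|{config.maf_controls}|{config.random_maf_bounds}"
    )
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_experiment(grid: ExperimentGrid) -> PowerReport:
    """Simulate and test every grid cell; deterministic given the seeds."""
    rate_rows, gain_rows = [], []
    p_store, s_store = {}, {}
    for i, config in enumerate(grid.configs):
        t0 = time.perf_counter()
        dataset = simulate_genotypes(config)
        results = run_snp_tests(dataset, grid.tests)
        n_degenerate = sum(r.degenerate for r in next(iter(results.values())))
        p_store[i] = {k: [r.p_value for r in v] for k, v in results.items()}
        s_store[i] = {k: [r.statistic for r in v] for k, v in results.items()}
        for name in grid.tests:
            rates = empirical_rejection_rate(p_store[i][name], grid.alphas)
            for alpha, rate in rates.items():
                n = len(p_store[i][name])
                rate_rows.append(
                    dict(
                        config=i, test=name, alpha=alpha, rate=rate,
                        n_rejected=int(round(rate * n)), n_total=n,
                        se=float(np.sqrt(rate * (1 - rate) / n)),
                    )
                )
        for ent, conv in GAIN_PAIRS:
            if ent in results and conv in results:
                g = chisq_gain(results[ent], results[conv])
                gain_rows.append(
                    dict(
                        config=i, test_pair=f"{ent}-vs-{conv}",
                        mean_difference=g.mean_difference,
                        mean_proportional_gain=g.mean_proportional_gain,
                        n_snps=g.n_snps, n_excluded_zero=g.n_excluded_zero,
                    )
                )
        logger.info(
            "config %d (OR=%s, maf=%s, %d/%d, %d SNPs): %.2fs, %d degenerate SNPs",
            i, config.odds_ratio, config.maf_controls, config.n_cases,
            config.n_controls, config.n_snps, time.perf_counter() - t0, n_degenerate,
        )
    return PowerReport(
        rates=pd.DataFrame(rate_rows),
        gains=pd.DataFrame(gain_rows),
        p_values=p_store,
        statistics=s_store,
    )


def preset_grid(name: str, master_seed: int = 0, n_snps: int | None = None) -> ExperimentGrid:
    """Named experiment presets.

    ``null-calibration``
        10,000 null SNPs (OR = 1, MAF uniform in (0, 0.5)), 500/500;
        empirical size at alpha 0.05 / 0.01 / 0.001 and statistic gains.
    ``power-common``
        100-SNP cells, 500/500, OR in {1.25, 1.5, 2} x MAF in
        {0.05, 0.2, 0.4}.
    ``power-low-maf``
        1,000-SNP cells, 5000/5000, OR in {1.5, 1.8} x MAF in
        {0.01, 0.03, 0.06}, plus the matching null cells.
    """
    if name == "null-calibration":
        cfgs = [SimulationConfig(500, 500, n_snps or 10_000, 1.0, "random")]
        alphas: tuple[float, ...] = (0.05, 0.01, 1e-3)
    elif name == "power-common":
        cfgs = [
            SimulationConfig(500, 500, n_snps or 100, orr, maf)
            for orr in (1.25, 1.5, 2.0)
            for maf in (0.05, 0.2, 0.4)
        ]
        alphas = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7)
    elif name == "power-low-maf":
        cfgs = [
            SimulationConfig(5000, 5000, n_snps or 1000, orr, maf)
            for orr in (1.0, 1.5, 1.8)
            for maf in (0.01, 0.03, 0.06)
        ]
        alphas = DEFAULT_ALPHAS
    else:
        raise ValueError(f"unknown preset {name!r}")
    cfgs = [
        SimulationConfig(
            c.n_cases, c.n_controls, c.n_snps, c.odds_ratio, c.maf_controls,
            c.random_maf_bounds, seed=derive_config_seed(master_seed, c),
        )
        for c in cfgs
    ]
    return ExperimentGrid(configs=tuple(cfgs), alphas=alphas)
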