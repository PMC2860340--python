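"""Conventional comparator tests: Pearson chi-square and Fisher exact.

The Pearson tests mirror the genetics convention of 1 df for the 2x2
allele table and 2 df for the 2x3 genotype table.  Cells whose expected
count is zero (an empty pooled class) contribute nothing and the degrees
of freedom are *not* reduced, mirroring the entropy tests so that any
power difference is attributable to the statistic, not df bookkeeping.

The Fisher exact tests condition on all margins and sum multivariate
hypergeometric point probabilities.  Two-sided p-values use the
minimum-likelihood criterion (sum over tables no more probable than the
observed one), the dominant convention in genetics software.  The 2x3
test (the Freeman-Halton extension) enumerates over the two smallest
column margins with precomputed log-factorials; it is exact, never a
network-algorithm approximation, and refuses rather than approximates
when the enumeration would exceed the capacity cap.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .data_model import AlleleCountTable, DegenerateTableError, GenotypeCountTable
from .symbolic_entropy import TestResult, _is_degenerate

__all__ = [
    "CapacityError",
    "pearson_chisq_genotypic",
    "pearson_chisq_allelic",
    "fisher_exact_2x2",
    "fisher_exact_2x3",
]

#: Relative tie tolerance when comparing point probabilities (log scale).
_TIE_TOL = 1e-12

#: Default cap on the number of enumerated tables in the exact tests.
MAX_TABLES = 10**8


class CapacityError(RuntimeError):
    """Exact-test enumeration would exceed the table cap."""


def _pearson(counts: np.ndarray, df: int, name: str, n_used: int, snp_id: str) -> TestResult:
    n = counts.sum()
    if n == 0:
        raise DegenerateTableError(f"{snp_id}: empty count table")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    mask = expected > 0
    stat = float((((counts - expected) ** 2)[mask] / expected[mask]).sum())
    return TestResult(
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
        test_name=name,
        n_used=n_used,
        snp_id=snp_id,
        degenerate=_is_degenerate(counts),
    )


def pearson_chisq_genotypic(table: GenotypeCountTable) -> TestResult:
    """Pearson X^2 on the 2x3 genotype table, fixed 2 df."""
    return _pearson(table.to_array(), 2, "chisq_genotypic", table.n, table.snp_id)


def pearson_chisq_allelic(table: AlleleCountTable) -> TestResult:
    """Pearson X^2 on the 2x2 allele table, fixed 1 df."""
    return _pearson(table.to_array(), 1, "chisq_allelic", table.m // 2, table.snp_id)


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _exact_2xk(counts: np.ndarray, max_tables: int, name: str, n_used: int, snp_id: str) -> TestResult:
    """Exact conditional test of a 2 x k table by full enumeration.

    Enumerates the top-row entries of the k-1 smallest columns; the
    remaining column and the bottom row follow from the margins.  The
    point probability of a table with top row ``(a_1..a_k)``, column
    margins ``c_j`` and row margin ``r`` is
    ``prod_j C(c_j, a_j) / C(N, r)``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if n == 0:
        raise DegenerateTableError(f"{snp_id}: empty count table")
    r1 = int(counts[0].sum())
    cols = counts.sum(axis=0)
    order = np.argsort(cols)  # enumerate the smallest margins, last is implied
    free, implied = order[:-1], order[-1]
    ranges = [np.arange(min(int(cols[j]), r1) + 1) for j in free]
    size = int(np.prod([len(r) for r in ranges]))
    if size > max_tables:
        raise CapacityError(
            f"{snp_id}: exact enumeration of {size} tables exceeds cap {max_tables}"
        )
    grids = np.meshgrid(*ranges, indexing="ij")
    a_free = np.stack([g.ravel() for g in grids], axis=0)  # (k-1, size)
    a_last = r1 - a_free.sum(axis=0)
    valid = (a_last >= 0) & (a_last <= int(cols[implied]))
    a_free, a_last = a_free[:, valid], a_last[valid]
    logp = _log_comb(int(cols[implied]), a_last) - _log_comb(n, r1)
    for row, j in zip(a_free, free):
        logp = logp + _log_comb(int(cols[j]), row)
    logp_obs = float(
        sum(_log_comb(int(cols[j]), int(counts[0, j])) for j in range(counts.shape[1]))
        - _log_comb(n, r1)
    )
    p = float(np.exp(logp[logp <= logp_obs + _TIE_TOL]).sum())
    return TestResult(
        statistic=float(np.exp(logp_obs)),  # observed-table point probability
        df=0,
        p_value=min(p, 1.0),
        test_name=name,
        n_used=n_used,
        snp_id=snp_id,
        degenerate=_is_degenerate(counts),
    )


def fisher_exact_2x2(table: AlleleCountTable, max_tables: int = MAX_TABLES) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 allele table.

    The p-value sums hypergeometric point probabilities of every table
    with the observed margins that is no more probable than the observed
    one (relative tie tolerance 1e-12).  The ``statistic`` field carries
    the observed table's point probability; ``df`` is reported as 0.
    """
    return _exact_2xk(table.to_array(), max_tables, "fisher_2x2", table.m // 2, table.snp_id)


def fisher_exact_2x3(table: GenotypeCountTable, max_tables: int = MAX_TABLES) -> TestResult:
    """Two-sided Freeman-Halton exact test on the 2x3 genotype table."""
    return _exact_2xk(table.to_array(), max_tables, "fisher_2x3", table.n, table.snp_id)
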