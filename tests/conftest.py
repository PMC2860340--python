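"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive — direct formula evaluation and
exhaustive enumeration — and never call into the package's own
statistics code paths.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest


def g_statistic(counts) -> float:
    """Brute-force likelihood-ratio G = 2 sum O ln(O/E) over a 2xk table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    g = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            o = counts[i, j]
            if o > 0:
                g += o * math.log(o * n / (rows[i] * cols[j]))
    return 2.0 * g


def pearson_statistic(counts) -> float:
    """Brute-force Pearson X^2 over cells with positive expectation."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    x2 = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = rows[i] * cols[j] / n
            if e > 0:
                x2 += (counts[i, j] - e) ** 2 / e
    return x2


def fisher_enumeration_p(counts) -> float:
    """Exhaustive two-sided exact p for a 2xk table (min-likelihood rule).

    Enumerates every top row compatible with the margins and sums the
    multivariate hypergeometric probabilities of tables no more probable
    than the observed one (relative tie tolerance 1e-12).
    """
    counts = np.asarray(counts, dtype=int)
    r1 = counts[0].sum()
    cols = counts.sum(axis=0)
    n = counts.sum()

    def prob(top) -> float:
        return math.prod(math.comb(c, a) for c, a in zip(cols, top)) / math.comb(n, r1)

    p_obs = prob(counts[0])
    total = 0.0
    for top in product(*(range(c + 1) for c in cols)):
        if sum(top) == r1:
            p = prob(top)
            if p <= p_obs * (1 + 1e-12):
                total += p
    return min(total, 1.0)


def random_tables(rng: np.random.Generator, n_tables: int, shape=(2, 3), max_cell=200):
    """Random non-empty count tables with at least two pooled classes."""
    out = []
    while len(out) < n_tables:
        t = rng.integers(0, max_cell + 1, size=shape)
        if t.sum() > 0 and (t.sum(axis=0) > 0).sum() >= 2 and (t.sum(axis=1) > 0).all():
            out.append(t)
    return out


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
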