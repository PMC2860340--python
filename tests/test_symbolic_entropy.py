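"""Entropy decomposition and the GE/AL likelihood-ratio statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpentropy import (
    AlleleCountTable,
    DegenerateTableError,
    GenotypeCountTable,
    entropy_allelic_test,
    entropy_decomposition,
    entropy_genotypic_test,
    genotype_to_allele_table,
    shannon_entropy,
)

from conftest import g_statistic, random_tables


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((1 / 3, 1 / 3, 1 / 3), math.log(3)),
            ((1.0, 0.0, 0.0), 0.0),
            ((0.5, 0.25, 0.25), 1.039721),  # hand evaluation of -sum q ln q
            ((0.5, 0.5), math.log(2)),
        ],
    )
    def test_values(self, freqs, expected):
        assert shannon_entropy(freqs) == pytest.approx(expected, abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            shannon_entropy([0.7, -0.1, 0.4])
        with pytest.raises(ValueError):
            shannon_entropy([0.5, 0.4])
        with pytest.raises(ValueError):
            shannon_entropy([])


class TestEntropyDecomposition:
    def test_balanced_table(self):
        dec = entropy_decomposition(GenotypeCountTable((1, 1, 1), (1, 1, 1)))
        assert dec.h_case_control == pytest.approx(math.log(2))
        assert dec.h_symbols == pytest.approx(math.log(3))
        assert dec.h_symbols_cases == pytest.approx(0.5 * math.log(6))
        assert dec.h_symbols_controls == pytest.approx(0.5 * math.log(6))
        assert dec.mutual_information == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_associated_table(self):
        dec = entropy_decomposition(GenotypeCountTable((2, 0, 0), (0, 0, 2)))
        assert dec.h_symbols == pytest.approx(math.log(2))
        assert dec.h_case_control == pytest.approx(math.log(2))
        assert dec.h_symbols_cases == pytest.approx(0.5 * math.log(2))
        assert dec.h_symbols_controls == pytest.approx(0.5 * math.log(2))
        assert dec.mutual_information == pytest.approx(math.log(2))

    @given(
        st.lists(st.integers(0, 50), min_size=3, max_size=3).filter(lambda c: sum(c) > 0),
        st.integers(1, 5),
        st.integers(1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_mutual_information_zero_iff_rows_proportional(self, col, wa, wb):
        # rows proportional to each other = identical genotype distribution
        t = GenotypeCountTable(
            tuple(wa * c for c in col), tuple(wb * c for c in col)
        )
        assert entropy_decomposition(t).mutual_information == pytest.approx(0, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(DegenerateTableError):
            entropy_decomposition(GenotypeCountTable((0, 0, 0), (0, 0, 0)))


class TestEntropyTests:
    def test_genotypic_equals_g_statistic_oracle(self, rng):
        for t in random_tables(rng, 1000, shape=(2, 3)):
            table = GenotypeCountTable(tuple(t[0]), tuple(t[1]))
            ge = entropy_genotypic_test(table)
            assert ge.statistic == pytest.approx(g_statistic(t), abs=1e-9)
            assert ge.df == 2

    def test_allelic_equals_g_statistic_oracle(self, rng):
        for t in random_tables(rng, 1000, shape=(2, 2)):
            table = AlleleCountTable(tuple(t[0]), tuple(t[1]))
            al = entropy_allelic_test(table)
            assert al.statistic == pytest.approx(g_statistic(t), abs=1e-9)
            assert al.df == 1

    def test_worked_example(self):
        t = GenotypeCountTable((10, 20, 30), (30, 20, 10))
        r = entropy_genotypic_test(t)
        assert r.statistic == pytest.approx(g_statistic(t.to_array()), abs=1e-9)
        assert 0 < r.p_value < 1e-4

    def test_no_association_gives_zero(self):
        r = entropy_genotypic_test(GenotypeCountTable((5, 5, 5), (5, 5, 5)))
        assert r.statistic == 0.0
        assert r.p_value == 1.0
        assert not r.degenerate

    def test_monomorphic_is_degenerate_not_error(self):
        r = entropy_genotypic_test(GenotypeCountTable((50, 0, 0), (50, 0, 0)))
        assert (r.statistic, r.p_value, r.degenerate) == (0.0, 1.0, True)
        a = entropy_allelic_test(AlleleCountTable((100, 0), (100, 0)))
        assert (a.statistic, a.p_value, a.degenerate) == (0.0, 1.0, True)

    def test_label_invariance(self, rng):
        for t in random_tables(rng, 100, shape=(2, 3)):
            base = entropy_genotypic_test(GenotypeCountTable(tuple(t[0]), tuple(t[1])))
            for perm in ([2, 1, 0], [1, 2, 0]):
                permuted = entropy_genotypic_test(
                    GenotypeCountTable(tuple(t[0][perm]), tuple(t[1][perm]))
                )
                assert permuted.statistic == pytest.approx(base.statistic, abs=1e-9)
            swapped = entropy_genotypic_test(GenotypeCountTable(tuple(t[1]), tuple(t[0])))
            assert swapped.statistic == pytest.approx(base.statistic, abs=1e-9)

    @given(
        st.lists(st.integers(0, 100), min_size=6, max_size=6).filter(lambda c: sum(c) > 0),
        st.integers(2, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_statistic_scales_linearly_in_sample_size(self, c, k):
        # fixed cell frequencies, counts scaled by k => statistic scaled by k,
        # hence divergence (consistency) under any fixed alternative
        t1 = GenotypeCountTable(tuple(c[:3]), tuple(c[3:]))
        tk = GenotypeCountTable(
            tuple(k * x for x in c[:3]), tuple(k * x for x in c[3:])
        )
        s1 = entropy_genotypic_test(t1).statistic
        sk = entropy_genotypic_test(tk).statistic
        assert sk == pytest.approx(k * s1, rel=1e-9, abs=1e-9)

    def test_allelic_scaling_by_ten(self):
        a = AlleleCountTable((40, 80), (80, 40))
        a10 = AlleleCountTable((400, 800), (800, 400))
        assert entropy_allelic_test(a10).statistic == pytest.approx(
            10 * entropy_allelic_test(a).statistic, rel=1e-12
        )

    @given(st.lists(st.integers(0, 400), min_size=6, max_size=6).filter(lambda c: sum(c) > 0))
    @settings(max_examples=100, deadline=None)
    def test_statistic_nonnegative_p_in_unit_interval(self, c):
        r = entropy_genotypic_test(GenotypeCountTable(tuple(c[:3]), tuple(c[3:])))
        assert r.statistic >= 0
        assert 0 <= r.p_value <= 1
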