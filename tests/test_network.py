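"""Correlation, significance and binarization against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from abnet import (
    UndefinedCorrelationError,
    ValidationError,
    binarize,
    build_network,
    correlation_matrix,
    critical_r,
    edge_list,
    p_value,
    pearson_binary,
    t_statistic,
)

from conftest import correlation_from_matrix, make_band_matrix


def phi_from_counts(n11, n10, n01, n00):
    """Closed-form phi coefficient of a 2x2 contingency table (oracle)."""
    num = n11 * n00 - n10 * n01
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    return num / np.sqrt(r1 * r0 * c1 * c0)


def vectors_from_counts(n11, n10, n01, n00):
    x = np.r_[np.ones(n11), np.ones(n10), np.zeros(n01), np.zeros(n00)]
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    return x, y


class TestPearsonBinary:
    def test_identical_vectors_give_one(self):
        x = np.array([0, 1, 1, 0, 1])
        assert pearson_binary(x, x) == pytest.approx(1.0)

    def test_complement_gives_minus_one(self):
        x = np.array([0, 1, 1, 0, 1])
        assert pearson_binary(x, 1 - x) == pytest.approx(-1.0)

    def test_matches_phi_oracle_on_the_balanced_table(self):
        # 20/5/5/20 at n = 50: (20*20 - 5*5) / sqrt(25^4) = 0.6
        x, y = vectors_from_counts(20, 5, 5, 20)
        assert pearson_binary(x, y) == pytest.approx(0.6, abs=1e-12)
        assert phi_from_counts(20, 5, 5, 20) == pytest.approx(0.6, abs=1e-12)

    def test_zero_variance_raises_not_nan(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_binary(np.ones(5), np.array([0, 1, 0, 1, 0]))

    def test_too_short_is_rejected(self):
        with pytest.raises(ValidationError):
            pearson_binary(np.array([0, 1]), np.array([1, 0]))

    def test_matches_phi_oracle_on_random_tables(self, rng):
        for _ in range(50):
            counts = rng.integers(1, 15, 4)
            x, y = vectors_from_counts(*counts)
            assert pearson_binary(x, y) == pytest.approx(
                phi_from_counts(*counts), abs=1e-12
            )


class TestCorrelationMatrix:
    def test_matches_pairwise_oracle_entrywise(self, rng):
        m = make_band_matrix(rng.integers(0, 2, (50, 10)))
        c = correlation_matrix(m)
        for i in range(10):
            for j in range(i + 1, 10):
                expected = pearson_binary(m.values[:, i], m.values[:, j])
                assert c.r[i, j] == pytest.approx(expected, abs=1e-12)
                assert c.r[i, j] == c.r[j, i]

    def test_identical_columns_correlate_at_one(self):
        col = np.array([0, 1, 1, 0, 1, 0])
        m = make_band_matrix(np.c_[col, col, 1 - col])
        c = correlation_matrix(m)
        assert c.r[0, 1] == pytest.approx(1.0)

    def test_constant_column_is_flagged_undefined(self):
        m = make_band_matrix(
            np.c_[np.ones(6, dtype=int), np.array([0, 1, 1, 0, 1, 0]), np.array([1, 0, 0, 1, 0, 1])]
        )
        c = correlation_matrix(m)
        assert not c.defined[0].any()
        assert np.isnan(c.r[0, 1])
        assert c.n_undefined_bands == 1


class TestTStatistic:
    def test_zero_correlation_gives_zero(self):
        assert t_statistic(0.0, 50) == 0.0

    def test_printed_formula_value(self):
        # 0.6 * sqrt(48) / sqrt(0.64) = 5.196 to 3 d.p.
        assert t_statistic(0.6, 50) == pytest.approx(5.196, abs=5e-4)

    def test_unit_correlation_maps_to_infinity_with_zero_p(self):
        assert t_statistic(1.0, 50) == np.inf
        assert t_statistic(-1.0, 50) == -np.inf
        assert p_value(1.0, 50) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            t_statistic(0.5, 2)

    def test_p_monotone_decreasing_in_magnitude(self):
        rs = np.linspace(0, 0.99, 25)
        ps = p_value(rs, 30)
        assert np.all(np.diff(ps) < 0)
        assert p_value(0.0, 30) == pytest.approx(1.0)


class TestBinarize:
    def test_strong_pair_links_weak_pair_does_not(self):
        c = correlation_from_matrix(
            [[1.0, 0.6, 0.1], [0.6, 1.0, 0.0], [0.1, 0.0, 1.0]], n=50
        )
        b = binarize(c, alpha=0.05)
        assert b.b[0, 1] == 1    # p ~ 1e-6
        assert b.b[0, 2] == 0    # two-tailed p ~ 0.49
        assert b.b[1, 2] == 0

    def test_flips_exactly_at_the_critical_boundary(self):
        rc = critical_r(50, 0.05)
        assert rc == pytest.approx(0.2787, abs=5e-5)
        c = correlation_from_matrix(
            [[1.0, rc + 1e-6, 0], [rc + 1e-6, 1.0, rc - 1e-6], [0, rc - 1e-6, 1.0]],
            n=50,
        )
        b = binarize(c, alpha=0.05)
        assert b.b[0, 1] == 1 and b.b[1, 2] == 0

    def test_two_tailed_alpha_equals_one_tailed_half_alpha(self, rng):
        # decision rule p_two < alpha is the same as p_one < alpha/2
        rs = rng.uniform(-0.9, 0.9, 200)
        n, alpha = 50, 0.05
        p_two = p_value(rs, n)
        p_one = stats.t.sf(np.abs(t_statistic(rs, n)), n - 2)
        assert np.array_equal(p_two < alpha, p_one < alpha / 2)

    def test_negative_significant_correlations_produce_links(self):
        c = correlation_from_matrix([[1.0, -0.6], [-0.6, 1.0]], n=50)
        assert binarize(c, 0.05).b[0, 1] == 1

    def test_zero_variance_band_gets_no_links(self):
        r = np.array([[1.0, np.nan, np.nan], [np.nan, 1.0, 0.9], [np.nan, 0.9, 1.0]])
        c = correlation_from_matrix(r, n=50)
        b = binarize(c, 0.05)
        assert b.b[0].sum() == 0 and b.b[:, 0].sum() == 0
        assert b.b[1, 2] == 1

    def test_alpha_out_of_range_rejected(self):
        c = correlation_from_matrix([[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValidationError):
            binarize(c, alpha=1.5)

    def test_corrections_only_remove_links(self, rng):
        m = make_band_matrix(rng.integers(0, 2, (50, 15)))
        c = correlation_matrix(m)
        raw = binarize(c, 0.05, correction="none").b
        for corr in ("bonferroni", "bh"):
            strict = binarize(c, 0.05, correction=corr).b
            assert np.all(strict <= raw)


class TestPermutationOracle:
    @staticmethod
    def exact_permutation_p(x, y):
        """Exact two-sided permutation p of the correlation between binary
        vectors: under permutation of y, the 2x2 count n11 is hypergeometric
        given the margins, and |r| is a function of n11."""
        n, k, m_ = len(x), int(x.sum()), int(y.sum())
        rv = stats.hypergeom(n, k, m_)

        def phi(n11):
            n10, n01 = k - n11, m_ - n11
            n00 = n - k - n01
            return (n11 * n00 - n10 * n01) / np.sqrt(
                k * (n - k) * m_ * (n - m_)
            )

        obs = abs(phi(int((x * y).sum())))
        ks = np.arange(max(0, k + m_ - n), min(k, m_) + 1)
        keep = np.abs([phi(v) for v in ks]) >= obs - 1e-12
        return float(rv.pmf(ks)[keep].sum())

    def test_t_decision_concords_with_exact_test_on_small_samples(self, rng):
        agree = total = 0
        while total < 200:
            n = int(rng.integers(6, 13))
            x = rng.integers(0, 2, n).astype(float)
            y = rng.integers(0, 2, n).astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            p_t = p_value(pearson_binary(x, y), n)
            p_exact = self.exact_permutation_p(x, y)
            total += 1
            agree += (p_t < 0.05) == (p_exact < 0.05)
        assert agree / total >= 0.95


class TestExports:
    def test_edge_list_has_one_row_per_unique_link(self, rng):
        m = make_band_matrix(rng.integers(0, 2, (50, 12)))
        c, b = build_network(m)
        edges = edge_list(c, b)
        assert len(edges) == b.b.sum() // 2
        assert (edges["node_a"] < edges["node_b"]).all()
        assert (edges["p"] < b.alpha).all()

    def test_graphml_round_trips_edges(self, rng, tmp_path):
        import networkx as nx
        from abnet import write_graphml

        m = make_band_matrix(rng.integers(0, 2, (50, 12)))
        c, b = build_network(m)
        path = tmp_path / "g.graphml"
        write_graphml(c, b, path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == b.b.sum() // 2
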