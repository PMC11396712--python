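"""Distance, ordination and permutation statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance as ssd
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from plexcompo import compstats as cs


def _random_comp(rng, n, m, alpha=3.0):
    return pd.DataFrame(
        rng.dirichlet(np.ones(m) * alpha, n) * 100,
        index=[f"s{i}" for i in range(n)],
    )


def naive_pseudo_f(d, labels):
    """Loop-based PERMANOVA pseudo-F, independent of the vectorized path."""
    labels = np.asarray(labels)
    n = len(labels)
    d2 = d**2
    ss_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for u in np.unique(labels):
        idx = np.where(labels == u)[0]
        ss_w += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    g = len(np.unique(labels))
    return ((ss_t - ss_w) / (g - 1)) / (ss_w / (n - g))


class TestBrayCurtis:
    def test_identity_is_zero(self):
        assert cs.bray_curtis([10, 20, 70], [10, 20, 70]) == 0.0

    def test_disjoint_supports_are_one(self):
        assert cs.bray_curtis([10, 0, 0], [0, 5, 5]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert cs.bray_curtis([10, 90], [30, 70]) == pytest.approx(0.2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cs.bray_curtis([0, 0], [0, 0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cs.bray_curtis([-1, 2], [1, 2])

    def test_matrix_matches_scipy_pdist(self, rng):
        comp = _random_comp(rng, 15, 6)
        D = cs.bc_distance_matrix(comp)
        expected = ssd.squareform(ssd.pdist(comp.to_numpy(), metric="braycurtis"))
        np.testing.assert_allclose(D.data, expected, atol=1e-12)

    def test_matrix_consistent_under_sample_permutation(self, rng):
        comp = _random_comp(rng, 8, 5)
        D = cs.bc_distance_matrix(comp)
        perm = rng.permutation(8)
        Dp = cs.bc_distance_matrix(comp.iloc[perm])
        np.testing.assert_allclose(Dp.data, D.data[np.ix_(perm, perm)], atol=1e-12)


class TestPermanova:
    def test_statistic_matches_skbio(self, rng):
        import skbio

        comp = _random_comp(rng, 14, 6)
        groups = ["a"] * 7 + ["b"] * 7
        D = cs.bc_distance_matrix(comp)
        res = cs.permanova(D, groups, n_perm=999, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D.data, ids=list(D.ids)),
            grouping=groups,
            permutations=999,
        )
        assert res.statistic == pytest.approx(sk["test statistic"], rel=1e-10)
        assert res.p_value == pytest.approx(sk["p-value"], abs=0.06)

    def test_monte_carlo_agrees_with_enumeration_on_tiny_instance(self, rng):
        for _ in range(3):
            comp = _random_comp(rng, 6, 4)
            groups = np.array(["a", "a", "a", "b", "b", "b"])
            D = cs.bc_distance_matrix(comp)
            f_obs = naive_pseudo_f(D.data, groups)
            perms = [
                naive_pseudo_f(D.data, np.array(p))
                for p in itertools.permutations(groups)
            ]
            p_exact = np.mean([f >= f_obs - 1e-9 for f in perms])
            res = cs.permanova(D, groups, n_perm=9999, seed=7)
            se = np.sqrt(p_exact * (1 - p_exact) / 9999)
            assert abs(res.p_value - p_exact) <= 3 * se + 2e-4

    def test_maximal_separation_attains_p_floor(self):
        a = np.array([100.0, 0.0, 0.0])
        b = np.array([0.0, 100.0, 0.0])
        comp = pd.DataFrame([a, a, a, b, b, b])
        D = cs.bc_distance_matrix(comp)
        res = cs.permanova(D, ["g1"] * 3 + ["g2"] * 3, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_group_of_one_rejected(self, rng):
        comp = _random_comp(rng, 5, 4)
        D = cs.bc_distance_matrix(comp)
        with pytest.raises(ValueError, match="fewer than 2"):
            cs.permanova(D, ["a", "a", "a", "a", "b"])

    def test_single_group_rejected(self, rng):
        comp = _random_comp(rng, 4, 4)
        D = cs.bc_distance_matrix(comp)
        with pytest.raises(ValueError, match="2 groups"):
            cs.permanova(D, ["a"] * 4)


class TestPermanovaPairwise:
    def test_three_groups_give_three_pairs(self, rng):
        comp = _random_comp(rng, 9, 5)
        D = cs.bc_distance_matrix(comp)
        table = cs.permanova_pairwise(D, ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                                      n_perm=99, seed=0)
        assert len(table) == 3
        assert set(map(tuple, table[["group_a", "group_b"]].to_numpy())) == {
            ("a", "b"), ("a", "c"), ("b", "c")
        }

    def test_pair_equals_permanova_on_subset(self, rng):
        comp = _random_comp(rng, 9, 5)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        D = cs.bc_distance_matrix(comp)
        table = cs.permanova_pairwise(D, groups, n_perm=199, seed=3)
        row = table[(table.group_a == "a") & (table.group_b == "c")].iloc[0]
        keep = [s for s, g in zip(D.ids, groups) if g in ("a", "c")]
        direct = cs.permanova(
            D.subset(keep), ["a"] * 3 + ["c"] * 3, n_perm=199, seed=int(row["seed"])
        )
        assert row["statistic"] == pytest.approx(direct.statistic, rel=1e-12)
        assert row["p_value"] == pytest.approx(direct.p_value, abs=1e-12)

    def test_divergent_group_has_smallest_pairwise_p(self, rng):
        base = rng.dirichlet([5, 5, 5, 5], 8) * 100
        shifted = rng.dirichlet([20, 1, 1, 1], 4) * 100
        comp = pd.DataFrame(np.vstack([base, shifted]))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        D = cs.bc_distance_matrix(comp)
        table = cs.permanova_pairwise(D, groups, n_perm=999, seed=5)
        with_c = table[(table.group_a == "c") | (table.group_b == "c")]
        without_c = table[(table.group_a != "c") & (table.group_b != "c")]
        assert with_c["p_value"].max() <= without_c["p_value"].min()


class TestSimper:
    def test_single_differing_category_carries_all_dissimilarity(self):
        comp = pd.DataFrame(
            [[60, 20, 20], [60, 20, 20], [40, 20, 20], [40, 20, 20]],
            columns=["x", "y", "z"], dtype=float,
        )
        # note: unequal totals make |a_i - b_i| nonzero only for x
        out = cs.simper(comp, ["a", "a", "b", "b"], "a", "b", n_perm=49, seed=0)
        top = out.iloc[0]
        assert top["cell_type"] == "x"
        assert top["percent"] == pytest.approx(100.0)

    def test_contributions_match_bruteforce_on_toy(self):
        comp = pd.DataFrame(
            [[10, 30, 60], [20, 20, 60], [50, 25, 25], [40, 35, 25]],
            columns=list("xyz"), dtype=float,
        )
        groups = ["a", "a", "b", "b"]
        out = cs.simper(comp, groups, "a", "b", n_perm=49, seed=0)
        x = comp.to_numpy()
        expected = np.zeros(3)
        for i in (0, 1):
            for j in (2, 3):
                expected += np.abs(x[i] - x[j]) / (x[i] + x[j]).sum()
        expected /= 4
        got = out.set_index("cell_type").loc[list("xyz"), "contribution"].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_decomposition_identity(self, rng):
        comp = _random_comp(rng, 8, 6)
        groups = ["a"] * 4 + ["b"] * 4
        out = cs.simper(comp, groups, "a", "b", n_perm=9, seed=0)
        x = comp.to_numpy()
        mean_bc = np.mean(
            [cs.bray_curtis(x[i], x[j]) for i in range(4) for j in range(4, 8)]
        )
        assert abs(out["contribution"].sum() - mean_bc) < 1e-10

    def test_small_group_rejected(self, rng):
        comp = _random_comp(rng, 4, 3)
        with pytest.raises(ValueError):
            cs.simper(comp, ["a", "b", "b", "b"], "a", "b")


class TestNMDS:
    def _euclidean_dm(self, pts):
        d = ssd.squareform(ssd.pdist(pts))
        return cs.DistanceMatrix(d, tuple(f"p{i}" for i in range(len(pts))),
                                 "euclidean")

    def test_recovers_exact_2d_configuration(self, rng):
        D = self._euclidean_dm(rng.normal(size=(10, 2)))
        res = cs.nmds(D, k=2, n_restarts=20, seed=0)
        assert res.stress <= 0.01

    def test_minimal_size_runs(self, rng):
        D = self._euclidean_dm(rng.normal(size=(4, 2)))
        res = cs.nmds(D, k=2, n_restarts=3, seed=0)
        assert res.coords.shape == (4, 2)

    def test_too_small_rejected(self, rng):
        D = self._euclidean_dm(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            cs.nmds(D, k=2)

    def test_same_seed_identical_coordinates(self, rng):
        comp = _random_comp(rng, 9, 5)
        D = cs.bc_distance_matrix(comp)
        r1 = cs.nmds(D, seed=3, n_restarts=5)
        r2 = cs.nmds(D, seed=3, n_restarts=5)
        np.testing.assert_array_equal(r1.coords, r2.coords)

    def test_stress_nonincreasing_within_run(self, rng):
        comp = _random_comp(rng, 12, 5)
        D = cs.bc_distance_matrix(comp)
        res = cs.nmds(D, seed=1, n_restarts=5)
        h = np.array(res.stress_history)
        assert (np.diff(h) <= 1e-8).all()
        assert res.stress == pytest.approx(h[-1])


class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        np.testing.assert_allclose(cs.clr([25, 25, 25, 25]), 0.0, atol=1e-12)

    def test_closed_form(self):
        np.testing.assert_allclose(
            cs.clr([1, 2, 4]), [-np.log(2), 0.0, np.log(2)], atol=1e-12
        )

    @settings(derandomize=True, max_examples=200)
    @given(
        hnp.arrays(
            float, st.integers(2, 10),
            elements=st.floats(0, 100, allow_nan=False),
        ).filter(lambda a: a.sum() > 0)
    )
    def test_output_sums_to_zero(self, x):
        assert abs(cs.clr(x).sum()) < 1e-10

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cs.clr([0.0, 0.0])

    def test_matches_skbio_on_positive_compositions(self, rng):
        from skbio.stats.composition import clr as skbio_clr

        x = rng.dirichlet([2, 3, 4])
        np.testing.assert_allclose(cs.clr(x), skbio_clr(x), atol=1e-12)


class TestCLRAnova:
    def test_two_groups_reduce_to_squared_t(self, rng):
        comp = _random_comp(rng, 10, 4)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        out = cs.clr_anova(comp, groups)
        z = cs.clr_matrix(comp)
        for _, row in out.iterrows():
            col = z[row["cell_type"]]
            t, p = scipy.stats.ttest_ind(col[groups == "a"], col[groups == "b"])
            assert row["F"] == pytest.approx(t**2, rel=1e-10)
            assert row["p_value"] == pytest.approx(p, rel=1e-10)

    def test_null_p_values_roughly_uniform(self, rng):
        ps = []
        for _ in range(150):
            comp = _random_comp(rng, 10, 4, alpha=8.0)
            out = cs.clr_anova(comp, ["a"] * 5 + ["b"] * 5)
            ps.extend(out["p_value"])
        stat, p = scipy.stats.kstest(ps, "uniform")
        assert p > 1e-3

    def test_zero_within_group_variance_flagged(self):
        comp = pd.DataFrame(
            [[60, 40], [60, 40], [30, 70], [30, 70]], columns=["x", "y"],
            dtype=float,
        )
        out = cs.clr_anova(comp, ["a", "a", "b", "b"])
        assert out["flagged"].all()
        assert (out["F"] == np.inf).all()
        assert (out["p_value"] == 0.0).all()


class TestFisherExact:
    def test_hand_enumerated_2x2(self):
        assert cs.fisher_exact([[3, 1], [1, 3]]) == pytest.approx(
            0.4857142857142857, abs=1e-12
        )

    def test_matches_scipy_on_random_2x2(self, rng):
        for _ in range(20):
            t = rng.integers(0, 25, (2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            expected = scipy.stats.fisher_exact(t)[1]
            assert cs.fisher_exact(t) == pytest.approx(expected, abs=1e-12)

    def test_independent_table_near_one(self):
        t = np.outer([40, 60], [30, 70]) // 10
        assert cs.fisher_exact(t) > 0.5

    def test_monte_carlo_agrees_with_enumeration_on_2x3(self):
        """The r x c Monte-Carlo path against full enumeration of all
        tables with the observed margins (exhaustive oracle)."""
        from scipy.special import gammaln

        obs = np.array([[6, 3, 11], [4, 12, 4]])
        rows = obs.sum(axis=1)
        cols = obs.sum(axis=0)

        def logprob(t):
            return float(
                gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                - gammaln(t.sum() + 1) - gammaln(t + 1).sum()
            )

        lp_obs = logprob(obs)
        p_exact = 0.0
        for a in range(min(rows[0], cols[0]) + 1):
            for b in range(min(rows[0] - a, cols[1]) + 1):
                c = rows[0] - a - b
                if c > cols[2]:
                    continue
                t = np.array([[a, b, c], [cols[0] - a, cols[1] - b, cols[2] - c]])
                lp = logprob(t)
                if lp <= lp_obs + 1e-7:
                    p_exact += np.exp(lp)
        n_mc = 40000
        p_mc = cs.fisher_exact(obs, n_mc=n_mc, seed=0)
        se = np.sqrt(p_exact * (1 - p_exact) / n_mc)
        assert abs(p_mc - p_exact) <= 4 * se + 1e-4

    def test_three_row_monte_carlo_matches_transposed_two_row(self):
        """The generic >2-row sampler agrees with the vectorized 2-row path
        on a transposed table (the p-value is transpose-invariant)."""
        t = np.array([[5, 9], [11, 2], [4, 7]])
        p3 = cs.fisher_exact(t, n_mc=4000, seed=1)
        p2 = cs.fisher_exact(t.T, n_mc=4000, seed=2)
        assert p3 == pytest.approx(p2, abs=0.05)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            cs.fisher_exact([[0, 0], [1, 2]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            cs.fisher_exact([[1.5, 2], [3, 4]])
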