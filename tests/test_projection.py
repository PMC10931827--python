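import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from brsgkit.projection import (ahc_cluster, binomial_side_test, pca_biplot,
                                side_counts)


def _random_matrix(rng, n_genes=12, n_samples=9):
    return pd.DataFrame(rng.lognormal(2, 1, size=(n_genes, n_samples)),
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


class TestPcaBiplot:
    def test_rank_one_case(self, rng):
        base = rng.normal(size=6)
        m = pd.DataFrame([base * 2 + 1, base * -3 + 5], index=["a", "b"],
                         columns=[f"s{i}" for i in range(6)])
        res = pca_biplot(m)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_orientation_rule_holds(self, rng):
        for seed in range(5):
            m = _random_matrix(np.random.default_rng(seed))
            res = pca_biplot(m)
            raw_means = m.loc[res.gene_coords.index].mean(axis=1)
            c = np.corrcoef(res.gene_coords["PC1"], raw_means)[0, 1]
            assert c >= 0

    def test_scores_match_correlation_eigendecomposition(self, rng):
        """Sample scores equal (up to per-component sign) the projection on
        eigenvectors of the gene-gene correlation matrix."""
        m = _random_matrix(rng)
        res = pca_biplot(m)
        X = m.T.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        order = np.argsort(evals)[::-1]
        ref = Z @ evecs[:, order[:2]]
        got = res.sample_scores.to_numpy()
        for j in range(2):
            assert (np.allclose(got[:, j], ref[:, j], atol=1e-8)
                    or np.allclose(got[:, j], -ref[:, j], atol=1e-8))

    def test_explained_variance_sums_to_one(self, rng):
        res = pca_biplot(_random_matrix(rng), n_components=2)
        ev = res.explained_variance_ratio
        assert ev.sum() == pytest.approx(1.0)
        assert (np.diff(ev) <= 1e-12).all()

    def test_zero_variance_genes_dropped(self, rng):
        m = _random_matrix(rng)
        m.loc["flat"] = 3.0
        res = pca_biplot(m)
        assert res.dropped_genes == ("flat",)
        with pytest.raises(ValueError, match="non-zero variance"):
            pca_biplot(m.loc[["flat", "g0"]].iloc[[0, 0]]
                       .set_axis(["flat", "flat2"]))

    def test_elevated_genes_fall_on_high_expression_side(self):
        """Genes elevated in half the samples separate to the right of PC1."""
        rng = np.random.default_rng(5)
        n_up, n_bg = 20, 20
        base = rng.lognormal(2, 0.5, size=(n_up + n_bg, 1))
        noise = rng.lognormal(0, 0.2, size=(n_up + n_bg, 10))
        x = np.tile(base, (1, 10)) * noise
        x[:n_up, 5:] *= 6.0  # elevated group
        m = pd.DataFrame(x, index=[f"up{i}" for i in range(n_up)]
                         + [f"bg{i}" for i in range(n_bg)],
                         columns=[f"s{j}" for j in range(10)])
        res = pca_biplot(m)
        up_coords = res.gene_coords.loc[[f"up{i}" for i in range(n_up)], "PC1"]
        assert (up_coords > 0).mean() >= 0.9


class TestSideCounts:
    def test_all_positive(self):
        c = side_counts(pd.Series([0.5, 1.2, 3.0]))
        assert (c.n_left, c.n_right) == (0, 3)

    def test_symmetric_pairs(self):
        c = side_counts(pd.Series([-1.0, 1.0, -2.0, 2.0]))
        assert c.n_left == c.n_right == 2

    def test_zero_counted_right_and_flagged(self):
        c = side_counts(pd.Series([0.0, -1.0]))
        assert (c.n_left, c.n_right, c.n_zero) == (1, 1, 1)

    def test_empty_subset_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            side_counts(pd.Series([1.0]), items=[])


class TestBinomialSideTest:
    def test_unanimous_upper_tail(self):
        p = binomial_side_test(18, 18, "one-sided-ge").p_value
        assert p == pytest.approx(0.5 ** 18)
        assert float(f"{p:.2g}") == 3.8e-06

    def test_central_two_sided_is_one(self):
        assert binomial_side_test(2, 1, "two-sided").p_value == 1.0

    def test_hypothalamus_split_below_printed_bound(self):
        p = binomial_side_test(46, 9, "two-sided").p_value
        assert p == pytest.approx(4.06e-5, rel=1e-2)
        assert p <= 0.00045

    def test_equals_brute_force_enumeration(self):
        """For n ≤ 15, the pmf summation equals exhaustive enumeration of all
        2^n equally likely outcome sequences."""
        for n, k, side in [(7, 6, "two-sided"), (10, 2, "one-sided-le"),
                           (12, 9, "one-sided-ge"), (15, 8, "two-sided")]:
            pmf = np.zeros(n + 1)
            for outcome in itertools.product([0, 1], repeat=n):
                pmf[sum(outcome)] += 0.5 ** n
            if side == "one-sided-ge":
                ref = pmf[k:].sum()
            elif side == "one-sided-le":
                ref = pmf[: k + 1].sum()
            else:
                ref = pmf[pmf <= pmf[k] + 1e-15].sum()
            assert binomial_side_test(n, k, side).p_value == pytest.approx(ref)

    def test_two_sided_symmetry(self):
        for n, k in [(10, 3), (17, 5), (46, 9)]:
            assert binomial_side_test(n, k, "two-sided").p_value == \
                pytest.approx(binomial_side_test(n, n - k, "two-sided").p_value)

    def test_matches_scipy_binomtest(self):
        for n, k, side, alt in [(20, 15, "two-sided", "two-sided"),
                                (20, 15, "one-sided-ge", "greater"),
                                (9, 2, "one-sided-le", "less")]:
            ref = binomtest(k, n, 0.5, alternative=alt).pvalue
            assert binomial_side_test(n, k, side).p_value == pytest.approx(ref)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            binomial_side_test(5, 6, "two-sided")


class TestAhcCluster:
    def test_identical_profiles_cocluster(self, rng):
        m = _random_matrix(rng, n_genes=5)
        m.loc["g1"] = m.loc["g0"]
        cl = ahc_cluster(m, n_clusters=4, standardize=False)
        assert cl.labels["g0"] == cl.labels["g1"]

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.1, size=(10, 6))
        b = rng.normal(5, 0.1, size=(10, 6))
        m = pd.DataFrame(np.vstack([a, b]),
                         index=[f"a{i}" for i in range(10)]
                         + [f"b{i}" for i in range(10)])
        cl = ahc_cluster(m, n_clusters=2, standardize=False)
        assert cl.labels[[f"a{i}" for i in range(10)]].nunique() == 1
        assert cl.labels[[f"b{i}" for i in range(10)]].nunique() == 1
        assert cl.labels["a0"] != cl.labels["b0"]
        assert sorted(cl.cluster_sizes) == [10, 10]

    def test_input_order_invariance_up_to_relabel(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(12, 6)),
                         index=[f"g{i}" for i in range(12)])
        c1 = ahc_cluster(m, n_clusters=3, standardize=False)
        perm = m.sample(frac=1, random_state=1)
        c2 = ahc_cluster(perm, n_clusters=3, standardize=False)
        # same partition: co-membership must agree pairwise
        for gi in m.index:
            for gj in m.index:
                assert (c1.labels[gi] == c1.labels[gj]) == \
                    (c2.labels[gi] == c2.labels[gj])

    def test_invalid_linkage(self, rng):
        with pytest.raises(ValueError, match="unknown linkage"):
            ahc_cluster(_random_matrix(rng), n_clusters=2, method="banana")
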