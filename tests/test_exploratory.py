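import numpy as np
import pytest

from ltsp_sig import (
    DataError,
    ExpressionSimConfig,
    gene_loadings,
    hierarchical_cluster,
    pca,
    preprocess,
    simulate_expression,
)
from ltsp_sig.synthetic import random_collection

from conftest import make_matrix


class TestHierarchicalCluster:
    def test_identical_pair_merges_first_at_zero(self):
        m = make_matrix(np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]]))
        d = hierarchical_cluster(m, axis="samples")
        a, b, h = d.merges[0]
        assert {a, b} == {0, 1} and h == 0.0

    def test_four_point_average_linkage_heights(self):
        # samples at 2-D coordinates (0,0),(0,1),(5,0),(5,1): the two tight
        # pairs merge at height 1; the cross-cluster average distance is
        # (5 + sqrt(26) + sqrt(26) + 5)/4 = 2.5 + sqrt(26)/2
        m = make_matrix(np.array([[0.0, 0.0, 5.0, 5.0], [0.0, 1.0, 0.0, 1.0]]))
        d = hierarchical_cluster(m, axis="samples")
        heights = sorted(h for _, _, h in d.merges)
        np.testing.assert_allclose(heights,
                                   [1.0, 1.0, 2.5 + np.sqrt(26) / 2], rtol=1e-12)

    def test_merge_heights_invariant_to_item_order(self, rng):
        vals = rng.normal(0, 1, size=(6, 10))
        m = make_matrix(vals)
        perm = rng.permutation(10)
        m2 = make_matrix(vals[:, perm],
                         sample_ids=[f"s{j}" for j in perm])
        h1 = sorted(h for _, _, h in hierarchical_cluster(m, "samples").merges)
        h2 = sorted(h for _, _, h in hierarchical_cluster(m2, "samples").merges)
        np.testing.assert_allclose(h1, h2, rtol=1e-10)

    def test_single_item_axis_rejected(self):
        with pytest.raises(DataError, match=">= 2"):
            hierarchical_cluster(make_matrix([[1.0, 2.0]]), axis="genes")

    def test_newick_has_all_leaves(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4))
        nwk = hierarchical_cluster(m, "samples").to_newick()
        assert nwk.endswith(";")
        for s in ("s0", "s1", "s2", "s3"):
            assert s in nwk


class TestPca:
    def test_rank_one_data_concentrates_variance(self, rng):
        pattern = rng.normal(0, 1, size=8)
        scale = rng.uniform(0.5, 2.0, size=20)
        m = make_matrix(np.outer(scale, pattern), scale="log10")
        res = pca(m)
        np.testing.assert_allclose(res.variance_fraction[0], 1.0, atol=1e-10)
        np.testing.assert_allclose(res.variance_fraction[1:], 0.0, atol=1e-10)

    def test_matches_independent_eigendecomposition(self, rng):
        m = make_matrix(rng.normal(0, 1, size=(40, 8)), scale="log10")
        res = pca(m)
        # oracle: eigendecomposition of the samples x samples Gram matrix of
        # gene-standardized data
        X = m.values.to_numpy()
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1,
                                                        keepdims=True)
        G = X.T @ X
        w, v = np.linalg.eigh(G)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(res.variance_fraction,
                                   w[:7] / w[:7].sum(), atol=1e-8)
        for k in range(7):
            expected = v[:, k] * np.sqrt(w[k])
            got = res.scores.iloc[:, k].to_numpy()
            assert (np.allclose(got, expected, atol=1e-8)
                    or np.allclose(got, -expected, atol=1e-8))
        assert abs(res.variance_fraction.sum() - 1) < 1e-8

    def test_sklearn_cross_check(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        m = make_matrix(rng.normal(0, 1, size=(30, 6)), scale="log10")
        X = m.values.to_numpy()
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1,
                                                        keepdims=True)
        ref = sklearn_pca(n_components=5).fit(X.T)
        res = pca(m)
        np.testing.assert_allclose(res.variance_fraction,
                                   ref.explained_variance_ratio_, atol=1e-8)

    def test_invariant_to_gene_order_up_to_sign(self, rng):
        vals = rng.normal(0, 1, size=(25, 6))
        m1 = make_matrix(vals, scale="log10")
        perm = rng.permutation(25)
        m2 = make_matrix(vals[perm], gene_ids=[f"g{i:03d}" for i in perm],
                         scale="log10")
        r1, r2 = pca(m1), pca(m2)
        np.testing.assert_allclose(r1.variance_fraction, r2.variance_fraction,
                                   atol=1e-10)
        np.testing.assert_allclose(np.abs(r1.scores.to_numpy()),
                                   np.abs(r2.scores.to_numpy()), atol=1e-8)

    def test_sign_convention_first_sample_nonnegative(self, rng):
        m = make_matrix(rng.normal(0, 1, size=(30, 7)), scale="log10")
        res = pca(m)
        first = sorted(m.sample_ids)[0]
        assert (res.scores.loc[first] >= -1e-12).all()

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(DataError, match="3 samples"):
            pca(make_matrix([[1.0, 2.0], [0.5, 3.0]], scale="log10"))

    def test_zero_variance_genes_dropped_with_warning(self, rng, caplog):
        vals = rng.normal(0, 1, size=(10, 5))
        vals[3] = 2.0
        with caplog.at_level("WARNING", logger="ltsp_sig"):
            res = pca(make_matrix(vals, scale="log10"))
        assert "g003" not in res.loadings.index

    def test_condition_shift_separates_on_pc1(self):
        """With a planted condition shift on many genes, condition labels
        separate cleanly along PC1 (silhouette > 0.5) in >= 18/20 seeds."""
        from sklearn.metrics import silhouette_score

        hits = 0
        for seed in range(20):
            genes = [f"g{i:05d}" for i in range(300)]
            coll = random_collection(1, genes, size_range=(100, 100), seed=0)
            cfg = ExpressionSimConfig(
                n_genes=300, noise_log10_sd=0.2, seed=seed, collection=coll,
                planted_effects=[("SET0", "LL", 0.8)])
            m, _ = simulate_expression(cfg)
            norm = preprocess(m)
            res = pca(norm)
            labels = [0 if m.condition_of[s] == "LL" else 1
                      for s in res.scores.index]
            pc1 = res.scores.iloc[:, [0]].to_numpy()
            if silhouette_score(pc1, labels) > 0.5:
                hits += 1
        assert hits >= 18


class TestGeneLoadings:
    def test_perfect_and_anti_correlation(self):
        score = np.array([1.0, 2.0, 3.0, 4.0])
        m = make_matrix(np.vstack([score, -score]), scale="log10")
        lo = gene_loadings(m, score)
        np.testing.assert_allclose(lo.to_numpy(), [1.0, -1.0], atol=1e-12)

    def test_matches_textbook_pearson(self, rng):
        vals = rng.normal(0, 1, size=(100, 8))
        score = rng.normal(0, 1, size=8)
        lo = gene_loadings(make_matrix(vals, scale="log10"), score)
        for i in range(100):
            x, y = vals[i], score
            expected = (np.cov(x, y, ddof=1)[0, 1]
                        / (x.std(ddof=1) * y.std(ddof=1)))
            assert abs(lo.iloc[i] - expected) < 1e-12

    def test_length_mismatch_rejected(self):
        m = make_matrix(np.ones((3, 4)))
        with pytest.raises(DataError, match="length"):
            gene_loadings(m, np.array([1.0, 2.0]))

    def test_zero_variance_gene_is_nan(self):
        m = make_matrix(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]),
                        scale="log10")
        lo = gene_loadings(m, np.array([0.0, 1.0, 2.0]))
        assert np.isnan(lo.iloc[0]) and abs(lo.iloc[1] - 1.0) < 1e-12
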