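import numpy as np
import pytest
from scipy import stats

from ltsp_sig import (
    DataError,
    RankedList,
    enrichment_score,
    rank_by_mean_difference,
    run_gsea,
)
from ltsp_sig.synthetic import random_collection

from conftest import make_collection, make_matrix


def walk_es(gene_ids, metric, members, p):
    """Independent step-by-step running-sum oracle (pure python)."""
    hits = [g in set(members) for g in gene_ids]
    K = sum(hits)
    N = len(gene_ids)
    denom = sum(abs(m) ** p for m, h in zip(metric, hits) if h)
    run, hi, lo = 0.0, 0.0, 0.0
    for g, m, h in zip(gene_ids, metric, hits):
        if h:
            run += (abs(m) ** p / denom) if denom > 0 else 1.0 / K
        else:
            run -= 1.0 / (N - K)
        hi, lo = max(hi, run), min(lo, run)
    # sign ties at machine precision resolve positive, as in the package
    return hi if hi >= -lo - 1e-12 else lo


def random_ranked(rng, n=20):
    metric = np.sort(rng.normal(0, 1, n))[::-1]
    return RankedList(gene_ids=[f"g{i:02d}" for i in range(n)],
                      metric=metric, condition_pair=("A", "B"))


class TestRankByMeanDifference:
    def test_metric_is_difference_of_condition_means(self):
        m = make_matrix([[2.0, 2.0, 1.0], [1.5, 1.5, 1.0]],
                        sample_ids=["a1", "a2", "b1"],
                        conditions={"a1": "A", "a2": "A", "b1": "B"},
                        scale="log10")
        r = rank_by_mean_difference(m, "A", "B")
        assert r.gene_ids == ["g000", "g001"]
        np.testing.assert_allclose(r.metric, [1.0, 0.5])

    def test_same_condition_gives_zero_metric_lexicographic_order(self):
        m = make_matrix([[1.0, 2.0], [0.5, 1.0]],
                        conditions={"s0": "A", "s1": "A"}, scale="log10")
        r = rank_by_mean_difference(m, "A", "A")
        np.testing.assert_array_equal(r.metric, [0.0, 0.0])
        assert r.gene_ids == sorted(r.gene_ids)

    def test_swapping_conditions_negates_and_reverses(self, rng):
        vals = rng.normal(0, 1, size=(30, 6))
        cond = {f"s{j}": ("A" if j < 3 else "B") for j in range(6)}
        m = make_matrix(vals, conditions=cond, scale="log10")
        fwd = rank_by_mean_difference(m, "A", "B")
        rev = rank_by_mean_difference(m, "B", "A")
        by_gene_fwd = dict(zip(fwd.gene_ids, fwd.metric))
        by_gene_rev = dict(zip(rev.gene_ids, rev.metric))
        for g in fwd.gene_ids:
            assert abs(by_gene_fwd[g] + by_gene_rev[g]) < 1e-12

    def test_unknown_condition_rejected(self):
        m = make_matrix([[1.0, 2.0]], conditions={"s0": "A", "s1": "B"},
                        scale="log10")
        with pytest.raises(DataError, match="nope"):
            rank_by_mean_difference(m, "A", "nope")


class TestEnrichmentScore:
    def test_single_member_ranked_first(self):
        r = random_ranked(np.random.default_rng(0))
        es, running, peak = enrichment_score(r, [r.gene_ids[0]], weight_p=0)
        assert abs(es - 1.0) < 1e-12
        assert peak == 0

    def test_single_member_ranked_last_matches_walk_and_is_negative(self):
        r = random_ranked(np.random.default_rng(1))
        members = [r.gene_ids[-1]]
        es, _, _ = enrichment_score(r, members, weight_p=0)
        assert es < 0
        assert abs(es - walk_es(r.gene_ids, r.metric, members, 0)) < 1e-12

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 2.0])
    def test_matches_independent_walk(self, rng, weight_p):
        for _ in range(50):
            r = random_ranked(rng)
            members = list(rng.choice(r.gene_ids, size=4, replace=False))
            es, _, _ = enrichment_score(r, members, weight_p=weight_p)
            assert abs(es - walk_es(r.gene_ids, r.metric, members,
                                    weight_p)) < 1e-12

    def test_weight_zero_equals_ks_statistic(self, rng):
        for _ in range(30):
            r = random_ranked(rng, n=25)
            members = set(rng.choice(r.gene_ids, size=6, replace=False))
            es, _, _ = enrichment_score(r, members, weight_p=0)
            positions = np.arange(len(r))
            hit_pos = positions[[g in members for g in r.gene_ids]]
            miss_pos = positions[[g not in members for g in r.gene_ids]]
            ks = stats.ks_2samp(hit_pos, miss_pos).statistic
            assert abs(abs(es) - ks) < 1e-12

    def test_es_bounded_by_one(self, rng):
        for _ in range(50):
            r = random_ranked(rng, n=30)
            members = rng.choice(r.gene_ids, size=int(rng.integers(1, 29)),
                                 replace=False)
            es, _, _ = enrichment_score(r, list(members), weight_p=1)
            assert -1 - 1e-12 <= es <= 1 + 1e-12

    def test_reversed_ranking_negates_es(self, rng):
        r = random_ranked(rng)
        members = list(rng.choice(r.gene_ids, size=5, replace=False))
        es_fwd, _, _ = enrichment_score(r, members, weight_p=1)
        rev = RankedList(gene_ids=r.gene_ids[::-1], metric=-r.metric[::-1],
                         condition_pair=("B", "A"))
        es_rev, _, _ = enrichment_score(rev, members, weight_p=1)
        assert abs(es_fwd + es_rev) < 1e-12

    def test_empty_and_full_sets_rejected(self):
        r = random_ranked(np.random.default_rng(2))
        with pytest.raises(DataError, match="no member"):
            enrichment_score(r, ["absent"], weight_p=1)
        with pytest.raises(DataError, match="universe"):
            enrichment_score(r, r.gene_ids, weight_p=1)

    def test_zero_metric_hits_fall_back_to_uniform(self, caplog):
        r = RankedList(gene_ids=list("abcdef"),
                       metric=np.array([3.0, 2.0, 0.0, 0.0, 0.0, 0.0]),
                       condition_pair=("A", "B"))
        with caplog.at_level("WARNING", logger="ltsp_sig"):
            es, _, _ = enrichment_score(r, ["e", "f"], weight_p=1)
        assert any("uniform" in rec.message for rec in caplog.records)
        assert abs(es - walk_es(r.gene_ids, [0] * 6, ["e", "f"], 1)) < 1e-12


class TestRunGsea:
    @staticmethod
    def _noise_matrix(seed, n_genes=400):
        rng = np.random.default_rng(seed)
        cond = {}
        samples = []
        for lab, n in (("A", 5), ("B", 3)):
            for i in range(n):
                s = f"{lab}{i}"
                samples.append(s)
                cond[s] = lab
        return make_matrix(rng.normal(1, 0.3, size=(n_genes, len(samples))),
                           sample_ids=samples, conditions=cond, scale="log10")

    def test_identical_seed_identical_tables(self):
        m = self._noise_matrix(5)
        coll = random_collection(10, m.gene_ids, size_range=(8, 30), seed=1)
        r1 = run_gsea(m, "A", "B", coll, n_permutations=100, seed=42)
        r2 = run_gsea(m, "A", "B", coll, n_permutations=100, seed=42)
        assert [(a.set_id, a.es, a.nes, a.p_nominal, a.q_fdr)
                for a in r1] == [(b.set_id, b.es, b.nes, b.p_nominal, b.q_fdr)
                                 for b in r2]

    def test_too_few_permutations_rejected(self):
        m = self._noise_matrix(0)
        coll = random_collection(3, m.gene_ids, size_range=(8, 20), seed=0)
        with pytest.raises(ValueError, match="permutations"):
            run_gsea(m, "A", "B", coll, n_permutations=5)

    def test_empty_collection_after_filter_rejected(self):
        m = self._noise_matrix(1)
        coll = make_collection({"tiny": m.gene_ids[:2]})
        with pytest.raises(DataError, match="size filter"):
            run_gsea(m, "A", "B", coll, n_permutations=50)

    def test_null_p_values_near_uniform(self):
        """Exchangeable genes: fraction of sets with p<0.05 stays within 3
        binomial standard errors of 0.05."""
        m = self._noise_matrix(7, n_genes=1000)
        coll = random_collection(300, m.gene_ids, size_range=(10, 40), seed=2)
        res = run_gsea(m, "A", "B", coll, n_permutations=200, seed=3)
        frac = np.mean([r.p_nominal < 0.05 for r in res])
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert abs(frac - 0.05) < 3 * se + 1e-9

    def test_q_monotone_in_abs_nes_within_sign(self):
        m = self._noise_matrix(9)
        coll = random_collection(40, m.gene_ids, size_range=(8, 30), seed=4)
        res = run_gsea(m, "A", "B", coll, n_permutations=200, seed=5)
        for sign in (1, -1):
            sub = sorted([r for r in res if (r.nes >= 0) == (sign > 0)],
                         key=lambda r: -abs(r.nes))
            qs = [r.q_fdr for r in sub]
            assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_direction_labels_follow_es_sign(self):
        m = self._noise_matrix(11)
        coll = random_collection(10, m.gene_ids, size_range=(8, 30), seed=6)
        for r in run_gsea(m, "A", "B", coll, n_permutations=100, seed=7):
            assert r.direction == ("higher in A" if r.es >= 0 else "higher in B")

    def test_phenotype_scheme_runs_and_is_deterministic(self):
        m = self._noise_matrix(13, n_genes=150)
        coll = random_collection(5, m.gene_ids, size_range=(8, 20), seed=8)
        r1 = run_gsea(m, "A", "B", coll, n_permutations=30, seed=9,
                      scheme="phenotype")
        r2 = run_gsea(m, "A", "B", coll, n_permutations=30, seed=9,
                      scheme="phenotype")
        assert [(a.set_id, a.es, a.q_fdr) for a in r1] == \
            [(b.set_id, b.es, b.q_fdr) for b in r2]
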