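"""Gene-set enrichment analysis between two conditions.

Self-contained GSEA in the weighted Kolmogorov-Smirnov running-sum form:
genes are ranked by the difference of condition-mean (log10) expression,
the running sum gains |metric|^p / sum_hits |metric|^p at each member gene
("hit") and loses 1/(N-K) at each non-member ("miss"), and the enrichment
score ES is the signed maximal deviation from zero.  A positive ES means
the set concentrates where expression is higher in condition A; negative,
in condition B.

The null is a gene-sampling permutation: for each set size, random
same-size gene sets are drawn from the ranked universe.  (With only three
replicates in one condition, sample-label permutation offers too few
distinct splits for a stable FDR; phenotype permutation remains available
via ``scheme="phenotype"`` for larger designs.)  NES divides ES by the
mean magnitude of same-sign null ES; nominal p uses add-one smoothing;
the FDR q-value is the classical ratio of pooled-null to observed tail
fractions of sign-matched NES, capped at 1 and monotonized so that a more
extreme |NES| never receives a larger q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    filter_sets_by_size,
)

logger = logging.getLogger("ltsp_sig")

_ES_CHUNK = 256  # rows per vectorized running-sum batch (memory control)


@dataclass
class RankedList:
    """Genes ordered by ranking metric, descending; ties by gene ID."""

    gene_ids: list[str]
    metric: np.ndarray
    condition_pair: tuple[str, str]

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.gene_ids) != len(self.metric):
            raise DataError("gene_ids and metric lengths differ")
        if np.any(np.diff(self.metric) > 1e-12):
            raise DataError("metric must be non-increasing along the ranking")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GseaSetResult:
    set_id: str
    size: int
    es: float
    nes: float
    p_nominal: float
    q_fdr: float
    direction: str  # "higher in A" / "higher in B"


def rank_by_mean_difference(matrix: ExpressionMatrix, cond_a: str,
                            cond_b: str) -> RankedList:
    """Rank all genes by mean(cond_a) - mean(cond_b), descending."""
    for c in (cond_a, cond_b):
        if not matrix.samples_of(c):
            raise DataError(f"condition {c!r} not present in matrix")
    mean_a = matrix.values[matrix.samples_of(cond_a)].mean(axis=1)
    mean_b = matrix.values[matrix.samples_of(cond_b)].mean(axis=1)
    metric = (mean_a - mean_b).to_numpy()
    genes = np.asarray(matrix.gene_ids, dtype=object)
    order = np.lexsort((genes, -metric))
    return RankedList(gene_ids=list(genes[order]), metric=metric[order],
                      condition_pair=(cond_a, cond_b))


def _es_from_hits(weights: np.ndarray, hits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ES for a batch of hit-indicator rows.

    weights : (N,) |metric|^p along the ranking.
    hits : (B, N) boolean membership indicators.
    Returns (es, peak_index) per row.  Rows whose hit weights sum to zero
    fall back to uniform hit increments.
    """
    B, N = hits.shape
    K = hits.sum(axis=1)
    if np.any(K == 0) or np.any(K == N):
        raise DataError("each set must be a proper non-empty subset of the "
                        "ranked universe")
    es = np.empty(B)
    peak = np.empty(B, dtype=int)
    for start in range(0, B, _ES_CHUNK):
        h = hits[start:start + _ES_CHUNK]
        k = K[start:start + _ES_CHUNK].astype(float)
        w_hit = np.where(h, weights[None, :], 0.0)
        sums = w_hit.sum(axis=1)
        zero = sums == 0
        if np.any(zero):
            logger.warning("%d set(s) with all-zero hit metrics: uniform "
                           "hit increments used", int(zero.sum()))
            w_hit[zero] = h[zero].astype(float)
            sums[zero] = k[zero]
        miss_dec = 1.0 / (N - k)
        step = w_hit / sums[:, None] - (~h) * miss_dec[:, None]
        cs = np.cumsum(step, axis=1)
        e, p = _signed_extremum(cs)
        es[start:start + _ES_CHUNK] = e
        peak[start:start + _ES_CHUNK] = p
    return es, peak


def _signed_extremum(cs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed maximal deviation per row; sign ties within 1e-12 go positive."""
    imax = np.argmax(cs, axis=1)
    imin = np.argmin(cs, axis=1)
    rows = np.arange(cs.shape[0])
    pos, neg = cs[rows, imax], cs[rows, imin]
    take_pos = pos >= -neg - 1e-12
    return np.where(take_pos, pos, neg), np.where(take_pos, imax, imin)


def enrichment_score(ranked: RankedList, set_members, weight_p: float = 1.0
                     ) -> tuple[float, np.ndarray, int]:
    """ES of one gene set: (es, running_sum, peak_index).

    The set must intersect the ranked universe in a proper non-empty
    subset.  With ``weight_p=0`` |ES| reduces to the two-sample KS
    statistic between hit and miss positions.
    """
    members = set(set_members)
    hit = np.fromiter((g in members for g in ranked.gene_ids), dtype=bool,
                      count=len(ranked))
    k = int(hit.sum())
    if k == 0:
        raise DataError("gene set has no member in the ranked universe")
    if k == len(ranked):
        raise DataError("gene set equals the ranked universe; miss decrement "
                        "undefined")
    weights = np.abs(ranked.metric) ** weight_p
    w_hit = np.where(hit, weights, 0.0)
    total = w_hit.sum()
    if total == 0:
        logger.warning("all hit metrics are zero; uniform hit increments used")
        w_hit = hit.astype(float)
        total = float(k)
    step = w_hit / total - (~hit) / (len(ranked) - k)
    running = np.cumsum(step)
    es, peak = _signed_extremum(running[None, :])
    return float(es[0]), running, int(peak[0])


def _random_hits(rng: np.random.Generator, m: int, N: int, K: int) -> np.ndarray:
    """m random size-K subsets of range(N) as a boolean (m, N) matrix."""
    keys = rng.random((m, N))
    idx = np.argpartition(keys, K - 1, axis=1)[:, :K]
    hits = np.zeros((m, N), dtype=bool)
    hits[np.arange(m)[:, None], idx] = True
    return hits


def run_gsea(
    matrix: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
    min_size: int = 6,
    max_size: int = 200,
    scheme: str = "gene",
) -> list[GseaSetResult]:
    """Full GSEA between two conditions with permutation NES/p/q.

    The collection is size-filtered (default 6-200) against the matrix
    genes.  ``scheme="gene"`` (default) draws random same-size gene sets as
    the null; ``scheme="phenotype"`` permutes sample condition labels.
    Deterministic given ``seed``.  Results sorted by q, then |NES|
    descending, then set_id.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    if scheme not in ("gene", "phenotype"):
        raise ValueError("scheme must be 'gene' or 'phenotype'")
    ranked = rank_by_mean_difference(matrix, cond_a, cond_b)
    filtered = filter_sets_by_size(collection, ranked.gene_ids, min_size, max_size)
    if len(filtered) == 0:
        raise DataError("no gene set survives the size filter")

    N = len(ranked)
    weights = np.abs(ranked.metric) ** weight_p
    pos = {g: i for i, g in enumerate(ranked.gene_ids)}
    set_ids = filtered.set_ids()
    hit_obs = np.zeros((len(set_ids), N), dtype=bool)
    for i, sid in enumerate(set_ids):
        hit_obs[i, [pos[g] for g in filtered[sid].members]] = True
    es_obs, _ = _es_from_hits(weights, hit_obs)
    sizes = hit_obs.sum(axis=1)

    rng = np.random.default_rng(seed)
    if scheme == "gene":
        # one null per distinct set size, shared across same-size sets
        null_by_size: dict[int, np.ndarray] = {}
        for K in sorted(set(int(s) for s in sizes)):
            null_by_size[K], _ = _es_from_hits(
                weights, _random_hits(rng, n_permutations, N, K))
        null_es = np.stack([null_by_size[int(K)] for K in sizes])
    else:
        null_es = _phenotype_null(matrix, cond_a, cond_b, hit_obs, weight_p,
                                  n_permutations, rng)

    results = _score_against_null(set_ids, sizes, es_obs, null_es,
                                  ranked.condition_pair)
    results.sort(key=lambda r: (r.q_fdr, -abs(r.nes), r.set_id))
    return results


def _phenotype_null(matrix, cond_a, cond_b, hit_obs, weight_p, m, rng):
    """Null ES by shuffling condition labels across the A+B samples."""
    samples = matrix.samples_of(cond_a) + matrix.samples_of(cond_b)
    n_a = len(matrix.samples_of(cond_a))
    sub = matrix.values[samples].to_numpy()
    genes = np.asarray(matrix.gene_ids, dtype=object)
    null = np.empty((hit_obs.shape[0], m))
    for j in range(m):
        perm = rng.permutation(len(samples))
        metric = sub[:, perm[:n_a]].mean(axis=1) - sub[:, perm[n_a:]].mean(axis=1)
        order = np.lexsort((genes, -metric))
        w = np.abs(metric[order]) ** weight_p
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        null[:, j], _ = _es_from_hits(w, hit_obs[:, inv])
    return null


def _score_against_null(set_ids, sizes, es_obs, null_es, condition_pair):
    """NES, nominal p (add-one smoothed) and pooled-null FDR q per set."""
    n_sets = len(set_ids)
    nes_obs = np.empty(n_sets)
    p_nom = np.empty(n_sets)
    null_nes_rows = []
    for i in range(n_sets):
        null = null_es[i]
        pos_mean = null[null > 0].mean() if np.any(null > 0) else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if np.any(null < 0) else np.nan
        es = es_obs[i]
        if es >= 0:
            denom = pos_mean if np.isfinite(pos_mean) else np.abs(null).mean()
            same = null[null >= 0]
            b = int((same >= es).sum())
        else:
            denom = neg_mean if np.isfinite(neg_mean) else np.abs(null).mean()
            same = null[null < 0]
            b = int((same <= es).sum())
        if not np.isfinite(denom) or denom == 0:
            raise DataError(f"degenerate null for set {set_ids[i]}")
        nes_obs[i] = es / denom
        p_nom[i] = (b + 1) / (len(same) + 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = np.where(null >= 0,
                          null / (pos_mean if np.isfinite(pos_mean) else denom),
                          null / (neg_mean if np.isfinite(neg_mean) else denom))
        null_nes_rows.append(nn)

    pooled = np.concatenate(null_nes_rows)
    q = np.empty(n_sets)
    n_pos_obs = max(int((nes_obs >= 0).sum()), 1)
    n_neg_obs = max(int((nes_obs < 0).sum()), 1)
    n_pos_null = max(int((pooled >= 0).sum()), 1)
    n_neg_null = max(int((pooled < 0).sum()), 1)
    for i in range(n_sets):
        v = nes_obs[i]
        if v >= 0:
            num = (pooled >= v).sum() / n_pos_null
            den = (nes_obs >= v).sum() / n_pos_obs
        else:
            num = (pooled <= v).sum() / n_neg_null
            den = (nes_obs <= v).sum() / n_neg_obs
        q[i] = min(1.0, num / den) if den > 0 else 1.0

    # monotonize within each sign: a more extreme |NES| never has larger q
    for sign_mask in (nes_obs >= 0, nes_obs < 0):
        idx = np.flatnonzero(sign_mask)
        if idx.size == 0:
            continue
        order = idx[np.argsort(-np.abs(nes_obs[idx]), kind="mergesort")]
        best = q[order].copy()  # most extreme first
        # enforce non-decreasing along decreasing |NES|: cummin from the tail
        for j in range(order.size - 2, -1, -1):
            best[j] = min(best[j], best[j + 1])
        for j, i in enumerate(order):
            q[i] = best[j]

    a, b_lab = condition_pair
    return [
        GseaSetResult(set_id=set_ids[i], size=int(sizes[i]), es=float(es_obs[i]),
                      nes=float(nes_obs[i]), p_nominal=float(p_nom[i]),
                      q_fdr=float(q[i]),
                      direction=f"higher in {a}" if es_obs[i] >= 0
                      else f"higher in {b_lab}")
        for i in range(n_sets)
    ]


def gsea_table(results: list[GseaSetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_id, r.size, r.es, r.nes, r.p_nominal, r.q_fdr, r.direction)
         for r in results],
        columns=["set_id", "size", "ES", "NES", "p_nominal", "q_fdr", "direction"])
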