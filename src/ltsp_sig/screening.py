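"""PC-loading gene screening and hypergeometric over-representation.

Genes "highly contributing" to a component are those whose factor loading
(gene-score Pearson correlation) lies in the top or bottom 3% of all
analyzed genes AND exceeds +0.8 (top) or falls below -0.8 (bottom).  Gene
sets over-represented among the screened genes are then found with a
one-sided (upper-tail) hypergeometric test against the analyzed-gene
universe, significant at raw p < 0.01 by default; a Benjamini-Hochberg
option exists behind a flag but is off by default, matching the raw-p
screening convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DataError, ExpressionMatrix, GeneSetCollection, filter_sets_by_size
from .exploratory import PcaResult

logger = logging.getLogger("ltsp_sig")


@dataclass
class LoadingScreen:
    component: int
    direction: str  # "top" | "bottom"
    percent: float
    loading_cutoff: float
    genes: list[str]


@dataclass
class OverrepResult:
    set_id: str
    k: int        # overlap with the screened list
    K: int        # set size in the universe
    n: int        # screened-list size
    N: int        # universe size
    p_value: float
    significant: bool


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in n draws without replacement from a population of
    N containing K successes.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric margins k={k} N={N} K={K} n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def select_loading_genes(
    loadings: pd.Series,
    percent: float = 3.0,
    cutoff: float = 0.8,
    direction: str = "top",
) -> LoadingScreen:
    """Screen genes satisfying both the quantile rule and the cutoff.

    top: loading rank within the highest ceil(percent% of genes) AND
    loading >= +cutoff; bottom symmetric with <= -cutoff.  Genes with
    undefined (NaN) loading are excluded from numerator and universe with a
    warning.  Rank-boundary ties break by gene ID lexicographic order.
    """
    if not 0 < percent <= 50:
        raise ValueError("percent must be in (0, 50]")
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    n_missing = int(loadings.isna().sum())
    if n_missing:
        logger.warning("select_loading_genes: %d gene(s) with undefined loading "
                       "excluded", n_missing)
    defined = loadings.dropna()
    n_take = math.ceil(percent / 100.0 * len(defined))
    # deterministic order: metric, then gene ID at rank-boundary ties
    if direction == "top":
        ordered = defined.iloc[np.lexsort((defined.index.to_numpy(dtype=object),
                                           -defined.to_numpy()))]
        eligible = ordered.iloc[:n_take]
        genes = [g for g, v in eligible.items() if v >= cutoff]
    else:
        ordered = defined.iloc[np.lexsort((defined.index.to_numpy(dtype=object),
                                           defined.to_numpy()))]
        eligible = ordered.iloc[:n_take]
        genes = [g for g, v in eligible.items() if v <= -cutoff]
    return LoadingScreen(component=0, direction=direction, percent=percent,
                         loading_cutoff=cutoff, genes=genes)


def hypergeom_overrep(
    genes: list[str],
    collection: GeneSetCollection,
    universe: list[str],
    alpha: float = 0.01,
    bh_correct: bool = False,
) -> list[OverrepResult]:
    """Upper-tail hypergeometric over-representation of each set in the
    screened gene list.

    The collection is expected to be size-filtered against the universe.
    Results are sorted by p ascending, ties by set_id.  With
    ``bh_correct=True`` significance is called on Benjamini-Hochberg
    adjusted p-values instead of raw p (off by default).
    """
    uni = set(universe)
    if len(uni) != len(universe):
        raise DataError("universe contains duplicate gene IDs")
    offenders = [g for g in genes if g not in uni]
    if offenders:
        raise DataError(f"screened genes not in universe: {offenders}")
    gene_set = set(genes)
    N, n = len(uni), len(gene_set)
    results = []
    for gs in collection:
        members = [g for g in gs.members if g in uni]
        K = len(members)
        if K == 0:
            continue
        k = sum(1 for g in members if g in gene_set)
        p = hypergeom_pvalue(k, N, K, n)
        results.append(OverrepResult(set_id=gs.set_id, k=k, K=K, n=n, N=N,
                                     p_value=p, significant=p < alpha))
    if bh_correct and results:
        ps = np.array([r.p_value for r in results])
        m = len(ps)
        order = np.argsort(ps, kind="mergesort")
        adj = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, ps[idx] * m / rank)
            adj[idx] = running
        for r, q in zip(results, adj):
            r.significant = bool(q < alpha)
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


@dataclass
class ScreenOutcome:
    screens: dict[str, LoadingScreen]
    tables: dict[str, list[OverrepResult]] = field(default_factory=dict)


def screen_component(
    pca_result: PcaResult,
    component: int,
    collection: GeneSetCollection,
    matrix: ExpressionMatrix,
    percent: float = 3.0,
    cutoff: float = 0.8,
    alpha: float = 0.01,
    min_size: int = 6,
    max_size: int = 200,
) -> ScreenOutcome:
    """Screen one component both ways and test gene-set over-representation.

    Composes :func:`select_loading_genes` (top and bottom) with
    :func:`hypergeom_overrep` on the analyzed-gene universe.  An empty
    screened list yields an empty table without running any test.
    """
    if not 1 <= component <= pca_result.n_components:
        raise ValueError(f"component {component} out of range "
                         f"1..{pca_result.n_components}")
    loadings = pca_result.loadings[f"PC{component}"]
    universe = [g for g in matrix.gene_ids if g in loadings.index
                and not np.isnan(loadings[g])]
    filtered = filter_sets_by_size(collection, universe, min_size, max_size)
    outcome = ScreenOutcome(screens={})
    for direction in ("top", "bottom"):
        screen = select_loading_genes(loadings.loc[universe], percent, cutoff, direction)
        screen.component = component
        outcome.screens[direction] = screen
        if not screen.genes:
            outcome.tables[direction] = []
            continue
        outcome.tables[direction] = hypergeom_overrep(
            screen.genes, filtered, universe, alpha)
    return outcome


def overrep_table(results: list[OverrepResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_id, r.k, r.K, r.n, r.N, r.p_value, r.significant) for r in results],
        columns=["set_id", "overlap", "set_size", "list_size", "universe_size",
                 "p_value", "significant"])
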