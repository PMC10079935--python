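"""Gene filtering, log transformation and normalization of signal matrices.

The preprocessing chain mirrors standard microarray practice for
model-extracted signal estimates: genes whose mean linear signal falls
below a noise threshold (default -1.5 pM-like units) are eliminated, the
surviving signals are log10-transformed (flooring non-positive values at a
small epsilon), and each array is affinely standardized so all arrays share
common statistics (mean/sd) on the log scale.  Per-gene centering and
per-gene-set replicate z-scores support the visual/GO-level summaries.

Sample standard deviations use the n-1 denominator throughout (replicate
counts are small).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import LINEAR, LOG10, DataError, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("ltsp_sig")


@dataclass
class NormalizationParams:
    """Thresholds of the preprocessing chain.

    low_signal_threshold : linear signal units; genes with across-sample
        mean below it are eliminated (default -1.5).
    epsilon_floor : linear units; values below it are floored before log10
        (default 0.01), keeping the log map total and monotone.
    target_mean / target_sd : log10 units; per-array standardization
        targets.  ``None`` means "use the pooled mean/sd of all arrays".
    method : "affine" (default) or "quantile".
    """

    low_signal_threshold: float = -1.5
    epsilon_floor: float = 0.01
    target_mean: float | None = None
    target_sd: float | None = None
    method: str = "affine"

    def __post_init__(self) -> None:
        if self.epsilon_floor <= 0:
            raise ValueError("epsilon_floor must be > 0")
        if self.target_sd is not None and self.target_sd <= 0:
            raise ValueError("target_sd must be > 0")
        if self.method not in ("affine", "quantile"):
            raise ValueError("method must be 'affine' or 'quantile'")


def filter_low_signal(matrix: ExpressionMatrix, threshold: float = -1.5) -> ExpressionMatrix:
    """Drop genes whose mean linear signal across all samples is < threshold.

    Defined on the linear scale only; log-scale input is rejected.
    """
    if matrix.scale != LINEAR:
        raise DataError("low-signal filter is defined on linear-scale signal")
    means = matrix.values.mean(axis=1)
    keep = means >= threshold
    removed = int((~keep).sum())
    logger.info("low-signal filter (< %g): removed %d of %d genes, %d kept",
                threshold, removed, matrix.n_genes, int(keep.sum()))
    return matrix.with_values(matrix.values.loc[keep])


def to_log10(matrix: ExpressionMatrix, epsilon_floor: float = 0.01) -> ExpressionMatrix:
    """log10-transform a linear matrix, flooring values at epsilon_floor."""
    if matrix.scale != LINEAR:
        raise DataError("to_log10 expects a linear-scale matrix")
    if epsilon_floor <= 0:
        raise ValueError("epsilon_floor must be > 0")
    vals = matrix.values.to_numpy()
    n_floored = int((vals < epsilon_floor).sum())
    if n_floored:
        logger.info("to_log10: floored %d entries at %g", n_floored, epsilon_floor)
    out = pd.DataFrame(np.log10(np.maximum(vals, epsilon_floor)),
                       index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(out, scale=LOG10)


def to_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Back-transform a log10 matrix to the linear signal scale (10**x)."""
    if matrix.scale != LOG10:
        raise DataError("to_linear expects a log10-scale matrix")
    out = pd.DataFrame(np.power(10.0, matrix.values.to_numpy()),
                       index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(out, scale=LINEAR)


def normalize_arrays(matrix: ExpressionMatrix,
                     params: NormalizationParams | None = None) -> ExpressionMatrix:
    """Standardize each array so all share common statistics on the log scale.

    Default (affine): each sample column is rescaled to the target mean and
    sample sd, which default to the pooled mean and pooled sd of all columns
    before normalization.  ``method="quantile"`` substitutes classical
    quantile normalization (columns mapped onto the mean order-statistic
    profile) for users who want distribution-identical arrays.
    """
    if matrix.scale != LOG10:
        raise DataError("normalize_arrays expects a log10-scale matrix")
    params = params or NormalizationParams()
    vals = matrix.values.to_numpy(dtype=float, copy=True)

    sds = vals.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise DataError("zero standard deviation in sample(s): "
                        f"{[matrix.sample_ids[j] for j in zero]}")

    if params.method == "quantile":
        order = np.argsort(vals, axis=0)
        ranks = np.empty_like(order)
        n = vals.shape[0]
        ranked = np.take_along_axis(vals, order, axis=0)
        profile = ranked.mean(axis=1)
        for j in range(vals.shape[1]):
            ranks[order[:, j], j] = np.arange(n)
        out = profile[ranks]
    else:
        target_mean = params.target_mean
        target_sd = params.target_sd
        if target_mean is None:
            target_mean = float(vals.mean())
        if target_sd is None:
            # pooled sd: all values around their own column means
            target_sd = float(np.sqrt(((vals - vals.mean(axis=0)) ** 2).sum()
                                      / (vals.size - vals.shape[1])))
        out = (vals - vals.mean(axis=0)) / sds * target_sd + target_mean

    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(df)


def center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's across-sample mean (per-gene centering for the
    clustered-heatmap view)."""
    if matrix.scale != LOG10:
        raise DataError("center_genes expects a log10-scale matrix")
    out = matrix.values.sub(matrix.values.mean(axis=1), axis=0)
    return matrix.with_values(out)


def geneset_replicate_zscores(matrix: ExpressionMatrix,
                              collection: GeneSetCollection) -> pd.DataFrame:
    """Per-set, per-sample z-values of set-average expression.

    For each gene set, average the member genes' (log10) values per sample,
    then z-score that per-set vector across all samples (mean 0, sample sd 1
    over the replicates).  Sets with no member gene in the matrix are
    excluded with a warning.  Requires >= 2 samples.
    """
    if matrix.scale != LOG10:
        raise DataError("geneset_replicate_zscores expects a log10-scale matrix")
    if matrix.n_samples < 2:
        raise DataError("z-scores across samples need >= 2 samples")
    present = set(matrix.gene_ids)
    rows, ids = [], []
    for gs in collection:
        members = [g for g in gs.members if g in present]
        if not members:
            logger.warning("set %s: no member gene in matrix; excluded", gs.set_id)
            continue
        avg = matrix.values.loc[members].mean(axis=0).to_numpy()
        sd = avg.std(ddof=1)
        if sd == 0:
            raise DataError(f"set {gs.set_id}: zero variance across samples")
        rows.append((avg - avg.mean()) / sd)
        ids.append(gs.set_id)
    return pd.DataFrame(rows, index=ids, columns=matrix.sample_ids)


def preprocess(matrix: ExpressionMatrix,
               params: NormalizationParams | None = None) -> ExpressionMatrix:
    """Composed chain: low-signal filter -> log10 -> per-array normalization."""
    params = params or NormalizationParams()
    filtered = filter_low_signal(matrix, params.low_signal_threshold)
    logged = to_log10(filtered, params.epsilon_floor)
    return normalize_arrays(logged, params)
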