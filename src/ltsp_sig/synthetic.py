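"""Synthetic expression matrices and CFU time courses with known ground truth.

The expression generator emulates the statistical structure of the study
design the pipeline targets: ~3,700 genes measured on 13 arrays in three
condition groups (late-log LL n=5, short-term stationary STS n=3, long-term
stationary-phase supernatant LTSsn n=5), log-normal replicate noise on the
log10 signal scale, an optional fraction of low-signal genes whose linear
signal hovers near zero (including small negatives, as model-extracted
signal estimates do), and planted condition-specific log10 shifts on chosen
gene sets.  The CFU generator produces piecewise-exponential growth/decay
with multiplicative log-normal count noise.

All randomness derives from a single seed through fixed
``numpy.random.SeedSequence`` stream splitting, so any stage is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    LINEAR,
    CfuTimecourse,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)

DEFAULT_CONDITIONS: tuple[tuple[str, int], ...] = (("LL", 5), ("STS", 3), ("LTSsn", 5))

# fixed stream-split keys: one child per consumer of randomness
_STREAM_BASELINE = 0
_STREAM_NOISE = 1
_STREAM_LOWSIG = 2
_STREAM_COLLECTION = 3
_STREAM_CFU = 4


@dataclass
class ExpressionSimConfig:
    """Parameters of the expression-matrix simulator.

    ``planted_effects`` entries are ``(set_id, condition, shift)`` with the
    shift in log10 units added to every member gene in every sample of that
    condition.  ``low_signal_fraction`` genes are drawn on the *linear*
    scale from Normal(low_signal_mean, low_signal_sd) so that the low-signal
    elimination step has something to remove.
    """

    n_genes: int = 2000
    conditions: Sequence[tuple[str, int]] = DEFAULT_CONDITIONS
    baseline_log10_mean: float = 1.0
    baseline_log10_sd: float = 0.6
    noise_log10_sd: float = 0.2
    planted_effects: Sequence[tuple[str, str, float]] = ()
    collection: GeneSetCollection | None = None
    low_signal_fraction: float = 0.0
    low_signal_mean: float = -3.0
    low_signal_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if any(n < 1 for _, n in self.conditions):
            raise ValueError("every condition needs n_replicates >= 1")
        if self.noise_log10_sd <= 0:
            raise ValueError("noise_log10_sd must be > 0")
        if not 0.0 <= self.low_signal_fraction < 1.0:
            raise ValueError("low_signal_fraction must be in [0, 1)")


@dataclass
class CfuSimConfig:
    """Piecewise-exponential CFU kinetics.

    ``phases`` is a list of ``(duration_h, rate_per_h, sign)`` with sign in
    {"growth", "death"}.  ``count_noise_cv`` is the coefficient of variation
    of mean-one multiplicative log-normal noise applied at each sampling
    time.
    """

    n0: float = 1e8
    phases: Sequence[tuple[float, float, str]] = ((150.0, 0.05, "death"),)
    sampling_times: Sequence[float] = (0.0, 16.0, 22.0, 28.5, 70.0, 138.5)
    count_noise_cv: float = 0.0
    seed: int = 0
    strain: str = "sim"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be > 0")
        for dur, rate, sign in self.phases:
            if dur <= 0:
                raise ValueError("phase durations must be > 0")
            if sign not in ("growth", "death"):
                raise ValueError(f"phase sign must be growth/death, got {sign!r}")
        span = sum(d for d, _, _ in self.phases)
        ts = np.asarray(self.sampling_times, dtype=float)
        if np.any(ts < 0) or np.any(ts > span + 1e-9):
            raise ValueError("sampling_times must lie within the phase span")
        if self.count_noise_cv < 0:
            raise ValueError("count_noise_cv must be >= 0")


def random_collection(
    n_sets: int,
    gene_ids: Sequence[str],
    size_range: tuple[int, int] = (10, 50),
    seed: int | np.random.Generator = 0,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Random gene sets drawn (without replacement within a set) from
    ``gene_ids``; sizes uniform over ``size_range``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(gene_ids):
        raise ValueError("invalid size_range for the given universe")
    coll = GeneSetCollection(provenance="synthetic")
    genes = np.asarray(gene_ids, dtype=object)
    width = len(str(n_sets))
    for i in range(n_sets):
        k = int(rng.integers(lo, hi + 1))
        members = tuple(rng.choice(genes, size=k, replace=False))
        coll.add(GeneSet(set_id=f"{prefix}{i:0{width}d}", name=f"synthetic set {i}",
                         members=members))
    return coll


def simulate_expression(config: ExpressionSimConfig) -> tuple[ExpressionMatrix, dict]:
    """Simulate a linear-scale expression matrix plus a ground-truth record.

    Per gene g, condition c: log10 signal = b_g + delta_{g,c} + eps with
    b_g ~ N(baseline_log10_mean, baseline_log10_sd), delta the planted shift
    (0 unless g belongs to a planted set for c), eps ~ N(0, noise_log10_sd).
    The returned matrix holds 10**x.  Low-signal genes (the configured
    fraction, taken from the end of the gene list) instead get linear values
    drawn from Normal(low_signal_mean, low_signal_sd).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(5)
    rng_base = np.random.default_rng(children[_STREAM_BASELINE])
    rng_noise = np.random.default_rng(children[_STREAM_NOISE])
    rng_low = np.random.default_rng(children[_STREAM_LOWSIG])

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    sample_ids: list[str] = []
    cond_of: dict[str, str] = {}
    for label, n_rep in cfg.conditions:
        for r in range(1, n_rep + 1):
            sid = f"{label}_{r}"
            sample_ids.append(sid)
            cond_of[sid] = label
    n_samples = len(sample_ids)

    collection = cfg.collection
    for set_id, cond_label, _ in cfg.planted_effects:
        if collection is None or set_id not in collection:
            raise ValueError(f"planted set {set_id!r} absent from collection")
        if cond_label not in {c for c, _ in cfg.conditions}:
            raise ValueError(f"planted condition {cond_label!r} not simulated")

    baseline = rng_base.normal(cfg.baseline_log10_mean, cfg.baseline_log10_sd,
                               size=cfg.n_genes)
    log10_x = baseline[:, None] + rng_noise.normal(0.0, cfg.noise_log10_sd,
                                                   size=(cfg.n_genes, n_samples))

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    shifts = np.zeros((cfg.n_genes, n_samples))
    for set_id, cond_label, shift in cfg.planted_effects:
        rows = [gene_pos[g] for g in collection[set_id].members if g in gene_pos]
        cols = [j for j, s in enumerate(sample_ids) if cond_of[s] == cond_label]
        shifts[np.ix_(rows, cols)] += shift
    log10_x += shifts

    values = np.power(10.0, log10_x)

    n_low = int(round(cfg.low_signal_fraction * cfg.n_genes))
    low_genes: list[str] = []
    if n_low:
        low_genes = gene_ids[cfg.n_genes - n_low:]
        values[cfg.n_genes - n_low:, :] = rng_low.normal(
            cfg.low_signal_mean, cfg.low_signal_sd, size=(n_low, n_samples))

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        condition_of=cond_of, scale=LINEAR)
    truth = {
        "seed": cfg.seed,
        "planted_effects": [
            {"set_id": sid, "condition": c, "shift_log10": sh,
             "members": list(collection[sid].members)}
            for sid, c, sh in cfg.planted_effects
        ],
        "low_signal_genes": low_genes,
        "baseline_log10": {g: float(b) for g, b in zip(gene_ids, baseline)},
    }
    return matrix, truth


def simulate_cfu(config: CfuSimConfig) -> CfuTimecourse:
    """Simulate a CFU time course: piecewise N(t) = N(t_k) exp(+-r (t - t_k))
    per phase, times sampled at ``sampling_times``, each count multiplied by
    mean-one log-normal noise with the configured CV."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(5)[_STREAM_CFU])

    # phase boundaries and log-count at each boundary
    bounds = [0.0]
    log_n = [np.log(cfg.n0)]
    for dur, rate, sign in cfg.phases:
        s = 1.0 if sign == "growth" else -1.0
        bounds.append(bounds[-1] + dur)
        log_n.append(log_n[-1] + s * rate * dur)

    ts = np.asarray(cfg.sampling_times, dtype=float)
    true_counts = np.empty_like(ts)
    for i, t in enumerate(ts):
        k = int(np.searchsorted(bounds, t, side="right") - 1)
        k = min(k, len(cfg.phases) - 1)
        dur, rate, sign = cfg.phases[k]
        s = 1.0 if sign == "growth" else -1.0
        true_counts[i] = np.exp(log_n[k] + s * rate * (t - bounds[k]))

    if cfg.count_noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.count_noise_cv ** 2))
        noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=ts.shape))
        counts = true_counts * noise
    else:
        counts = true_counts
    return CfuTimecourse(strain=cfg.strain, replicate=cfg.replicate,
                         times=ts, counts=counts)
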