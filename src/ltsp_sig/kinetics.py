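"""Growth and death rates from CFU time courses.

Between consecutive timepoints the per-interval rate is
``mu_i = |ln(N_{i+1}/N_i) / (t_{i+1} - t_i)|`` (natural log by default;
the base only rescales mu and is configurable).  A strain's growth or
death rate is the arithmetic mean of mu_i over a window of timepoints —
windows are inputs, defaulting to timepoints 0-3 (growth, early intervals)
and 3-5 (death, late intervals).  Mutant strains are compared to a control
with Dunnett's many-to-one test on replicate-level rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CfuTimecourse, DataError

logger = logging.getLogger("ltsp_sig")

GROWTH_WINDOW_DEFAULT = (0, 3)  # timepoint indices, inclusive
DEATH_WINDOW_DEFAULT = (3, 5)


@dataclass
class RateEstimate:
    strain: str
    replicate: int
    mu_growth: float  # per hour, >= 0
    mu_death: float   # per hour, >= 0
    windows_used: dict


def stepwise_rates(tc: CfuTimecourse, log_base: float = math.e) -> pd.DataFrame:
    """Per-interval rates mu_i = |log(N_{i+1}/N_i)/(t_{i+1}-t_i)|.

    Returns a frame with columns ``interval, t_start, t_end, mu, signed_mu``
    (signed_mu keeps the growth/decay sign for window classification).
    Intervals touching a zero (or negative) count get NaN with a warning.
    """
    if tc.n_timepoints < 2:
        raise DataError(f"{tc.strain}/{tc.replicate}: need >= 2 timepoints")
    n, t = tc.counts, tc.times
    rows = []
    for i in range(len(t) - 1):
        if n[i] <= 0 or n[i + 1] <= 0:
            logger.warning("%s/%d interval %d: non-positive count, mu missing",
                           tc.strain, tc.replicate, i)
            signed = np.nan
        else:
            signed = math.log(n[i + 1] / n[i], log_base) / (t[i + 1] - t[i])
        rows.append((i, t[i], t[i + 1], abs(signed), signed))
    return pd.DataFrame(rows, columns=["interval", "t_start", "t_end", "mu",
                                       "signed_mu"])


def windowed_rate(tc: CfuTimecourse, window: tuple[int, int],
                  log_base: float = math.e) -> float:
    """Mean of mu_i over the window ``(first, last)`` of timepoint indices
    (inclusive), i.e. intervals first..last-1.  Missing intervals are
    excluded from the mean with a warning; all-missing is an error."""
    first, last = window
    if not (0 <= first < last <= tc.n_timepoints - 1):
        raise DataError(f"window {window} invalid for {tc.n_timepoints} timepoints")
    mus = stepwise_rates(tc, log_base)["mu"].to_numpy()[first:last]
    ok = ~np.isnan(mus)
    if not ok.any():
        raise DataError(f"{tc.strain}/{tc.replicate}: every interval in window "
                        f"{window} is missing")
    if not ok.all():
        logger.warning("%s/%d: %d missing interval(s) excluded from window %s",
                       tc.strain, tc.replicate, int((~ok).sum()), window)
    return float(mus[ok].mean())


def estimate_rates(
    timecourses: list[CfuTimecourse],
    growth_window: tuple[int, int] = GROWTH_WINDOW_DEFAULT,
    death_window: tuple[int, int] = DEATH_WINDOW_DEFAULT,
    log_base: float = math.e,
) -> list[RateEstimate]:
    """Windowed growth and death rates per strain/replicate."""
    out = []
    for tc in timecourses:
        out.append(RateEstimate(
            strain=tc.strain, replicate=tc.replicate,
            mu_growth=windowed_rate(tc, growth_window, log_base),
            mu_death=windowed_rate(tc, death_window, log_base),
            windows_used={"growth": growth_window, "death": death_window}))
    return out


@dataclass
class DunnettComparison:
    strain: str
    mean_difference: float  # strain mean - control mean
    p_adjusted: float
    significant: bool


def compare_to_control_dunnett(rates: pd.DataFrame | dict, control: str,
                               alpha: float = 0.05) -> list[DunnettComparison]:
    """Dunnett's many-to-one comparison of per-replicate rates vs a control.

    ``rates``: mapping strain -> replicate rate values (or a DataFrame with
    ``strain`` and ``mu`` columns).  Every strain needs >= 2 replicates and
    the pooled within-strain variance must be nonzero.
    """
    if isinstance(rates, pd.DataFrame):
        groups = {s: g["mu"].to_numpy(dtype=float)
                  for s, g in rates.groupby("strain", sort=False)}
    else:
        groups = {s: np.asarray(v, dtype=float) for s, v in rates.items()}
    if control not in groups:
        raise DataError(f"control strain {control!r} missing")
    small = [s for s, v in groups.items() if len(v) < 2]
    if small:
        raise DataError(f"strain(s) with < 2 replicates: {small}")
    if all(np.allclose(v, v[0]) for v in groups.values()):
        raise DataError("zero pooled variance; Dunnett test undefined")
    treatments = [s for s in groups if s != control]
    if not treatments:
        raise DataError("no treatment strain besides the control")
    # fixed rng: the multivariate-t tail integration is randomized quadrature
    res = stats.dunnett(*(groups[s] for s in treatments), control=groups[control],
                        rng=np.random.default_rng(0))
    out = []
    for s, p in zip(treatments, res.pvalue):
        out.append(DunnettComparison(
            strain=s,
            mean_difference=float(groups[s].mean() - groups[control].mean()),
            p_adjusted=float(p), significant=bool(p < alpha)))
    return out
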