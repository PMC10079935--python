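"""Stress/growth balance statistic and all-pairs condition comparison.

The balance statistic contrasts two functional programs per array: the
average linear mRNA signal over "response to stress" (RS, GO:0006950)
members versus over "macromolecule biosynthetic process" (MBS, GO:0009059)
members, reported as log10(AVR_RS / AVR_MBS).  A higher ratio means the
array's transcriptome weights stress survival over growth.  Condition
means of the per-array ratios are compared all-pairs with Tukey's HSD
(studentized-range family-wise adjustment).

Averages are taken on the linear signal scale and the ratio logged
afterwards; averaging already-logged values would compute a geometric
rather than arithmetic mean signal.  Set ``on_log_scale=True`` to get the
geometric-mean variant.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import LINEAR, DataError, ExpressionMatrix

logger = logging.getLogger("ltsp_sig")


@dataclass
class PairwiseComparison:
    cond_a: str
    cond_b: str
    mean_difference: float  # mean(a) - mean(b)
    p_adjusted: float
    stars: str  # "**" p<0.01, "*" p<0.05, "" otherwise


@dataclass
class BalanceResult:
    per_sample_log10_ratio: pd.Series
    per_condition: pd.DataFrame  # index condition, columns mean/sd/n
    pairwise: list[PairwiseComparison]


def balance_ratio(matrix: ExpressionMatrix, rs_set, mbs_set,
                  on_log_scale: bool = False) -> pd.Series:
    """Per-sample log10(AVR_RS / AVR_MBS) on the linear signal scale.

    AVR_RS(s) is the arithmetic mean of the linear signal of RS members
    present in the matrix (likewise AVR_MBS).  Hard errors: empty
    intersection, or a non-positive average in any sample.
    """
    if not on_log_scale and matrix.scale != LINEAR:
        raise DataError("balance_ratio averages linear signal; pass a linear "
                        "matrix (e.g. preprocess.to_linear) or set on_log_scale")
    present = set(matrix.gene_ids)
    rs = [g for g in rs_set if g in present]
    mbs = [g for g in mbs_set if g in present]
    if not rs or not mbs:
        raise DataError("RS or MBS set has empty intersection with matrix genes")
    avr_rs = matrix.values.loc[rs].mean(axis=0)
    avr_mbs = matrix.values.loc[mbs].mean(axis=0)
    if on_log_scale:
        # geometric-mean variant: difference of mean log10 values
        return avr_rs - avr_mbs
    bad = avr_rs[(avr_rs <= 0)].index.tolist() + avr_mbs[(avr_mbs <= 0)].index.tolist()
    if bad:
        raise DataError(f"non-positive set-average signal in sample(s) {bad}; "
                        "log ratio undefined")
    return np.log10(avr_rs / avr_mbs)


def compare_conditions_tukey(per_sample_values: pd.Series | dict,
                             condition_of: dict, alpha: float = 0.05
                             ) -> list[PairwiseComparison]:
    """All-pairs comparison of condition means with Tukey's HSD.

    Requires >= 2 conditions with >= 2 samples each and nonzero pooled
    variance.  Stars: ** adjusted p < 0.01, * < 0.05.
    """
    values = pd.Series(per_sample_values, dtype=float)
    groups: dict[str, np.ndarray] = {}
    for s, v in values.items():
        if s not in condition_of:
            raise DataError(f"sample {s!r} missing from condition map")
        groups.setdefault(condition_of[s], []).append(v)
    groups = {c: np.asarray(v) for c, v in groups.items()}
    if len(groups) < 2:
        raise DataError("Tukey HSD needs >= 2 conditions")
    small = [c for c, v in groups.items() if len(v) < 2]
    if small:
        raise DataError(f"condition(s) with < 2 samples: {small}")
    if all(np.allclose(v, v[0]) for v in groups.values()):
        raise DataError("zero pooled variance; Tukey HSD undefined")
    labels = list(groups)
    res = stats.tukey_hsd(*(groups[c] for c in labels))
    out = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        p = float(res.pvalue[i, j])
        out.append(PairwiseComparison(
            cond_a=labels[i], cond_b=labels[j],
            mean_difference=float(groups[labels[i]].mean() - groups[labels[j]].mean()),
            p_adjusted=p,
            stars="**" if p < 0.01 else "*" if p < alpha else ""))
    return out


def stress_growth_balance(matrix: ExpressionMatrix, rs_set, mbs_set,
                          alpha: float = 0.05,
                          on_log_scale: bool = False) -> BalanceResult:
    """Balance ratios plus per-condition summary and Tukey HSD table."""
    ratios = balance_ratio(matrix, rs_set, mbs_set, on_log_scale=on_log_scale)
    rows = []
    for c in matrix.conditions:
        v = ratios[matrix.samples_of(c)]
        rows.append((c, v.mean(), v.std(ddof=1) if len(v) > 1 else np.nan, len(v)))
    per_cond = pd.DataFrame(rows, columns=["condition", "mean", "sd", "n"]) \
        .set_index("condition")
    pairwise = compare_conditions_tukey(ratios, matrix.condition_of, alpha)
    return BalanceResult(per_sample_log10_ratio=ratios, per_condition=per_cond,
                         pairwise=pairwise)
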