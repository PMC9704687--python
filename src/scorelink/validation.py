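"""Agreement and validation statistics for linked scores.

The battery used to judge whether a crosswalk built in one population can be
applied in another: Pearson correlation, mean/SD/RMSD of paired score
differences, two-way absolute-agreement ICC, Bland-Altman bias and limits of
agreement, disattenuated correlations with coefficient-alpha reliabilities,
item-parameter confidence-interval comparison, and descriptive summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grm import GRMItem, ResponseMatrix

__all__ = [
    "AgreementReport",
    "ParamComparison",
    "score_agreement",
    "icc_agreement",
    "disattenuated_correlation",
    "coefficient_alpha",
    "compare_item_parameters",
    "summary_stats",
]


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between observed and derived paired scores.

    Differences follow the derived - observed convention.  ``sd_diff`` uses
    the n-1 denominator; ``rmsd`` uses n, so the decomposition
    rmsd^2 = mean_diff^2 + sd_diff^2 * (n-1)/n holds exactly.
    """

    pearson_r: float
    mean_diff: float
    sd_diff: float
    rmsd: float
    icc: float
    bland_altman: dict
    n: int
    convention: str = "derived - observed"
    icc_variant: str = "ICC(A,1): two-way, absolute agreement, single rater"


@dataclass(frozen=True)
class ParamComparison:
    """Parameter-by-parameter comparison of two item-parameter sets."""

    table: pd.DataFrame  # item_id, param, est_a, se_a, est_b, se_b, ci_overlap
    n_overlap_slopes: int
    n_slopes: int
    n_overlap_thresholds: int
    n_thresholds: int
    max_abs_diff: float
    mode: str  # "ci" or "estimate"


def score_agreement(observed_t, derived_t) -> AgreementReport:
    """Full agreement report for paired observed vs crosswalk-derived T scores."""
    x = np.asarray(observed_t, dtype=float)
    y = np.asarray(derived_t, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observed and derived vectors must pair up")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance score vector: correlation undefined")
    d = y - x
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    rmsd = float(np.sqrt(np.mean(d**2)))
    r = float(stats.pearsonr(x, y).statistic)
    icc = icc_agreement(x, y)
    ba = {
        "bias": mean_diff,
        "loa_low": mean_diff - 1.96 * sd_diff,
        "loa_high": mean_diff + 1.96 * sd_diff,
    }
    return AgreementReport(
        pearson_r=r,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        rmsd=rmsd,
        icc=icc,
        bland_altman=ba,
        n=n,
    )


def icc_agreement(x, y) -> float:
    """Two-way, absolute-agreement, single-rater ICC — ICC(A,1).

    From the two-way ANOVA mean squares with n subjects and k=2 measurements:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / 1  # k - 1
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def disattenuated_correlation(x_raw, y_raw, rel_x: float, rel_y: float) -> float:
    """Observed Pearson r divided by sqrt(rel_x * rel_y).

    Corrects the raw-score correlation for unreliability in both measures.
    Values above 1 are reported unclamped with a warning.
    """
    if not (0 < rel_x <= 1 and 0 < rel_y <= 1):
        raise ValueError("reliabilities must be in (0, 1]")
    r = float(stats.pearsonr(np.asarray(x_raw, float), np.asarray(y_raw, float)).statistic)
    out = r / np.sqrt(rel_x * rel_y)
    if abs(out) > 1:
        warnings.warn(f"disattenuated correlation {out:.3f} exceeds 1 in magnitude", stacklevel=2)
    return float(out)


def coefficient_alpha(responses: ResponseMatrix) -> float:
    """Cronbach's alpha for one scale: (k/(k-1)) (1 - sum item var / total var).

    Complete rows only; sample variances use the n-1 denominator.
    """
    if responses.n_items < 2:
        raise ValueError("alpha needs at least 2 items")
    complete = responses.observed_mask().all(axis=1)
    vals = responses.values[complete].astype(float)
    if vals.shape[0] < 2:
        raise ValueError("fewer than 2 complete response rows")
    total_var = np.var(vals.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance: alpha undefined")
    item_var = np.var(vals, axis=0, ddof=1).sum()
    k = responses.n_items
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def _param_frame(items: Sequence[GRMItem], ses: dict | None) -> pd.DataFrame:
    rows = []
    for it in items:
        se = None if ses is None else np.asarray(ses[it.item_id], dtype=float)
        for p, (name, est) in enumerate(
            [("a", it.slope)] + [(f"b{i + 1}", b) for i, b in enumerate(it.thresholds)]
        ):
            rows.append(
                {
                    "item_id": it.item_id,
                    "param": name,
                    "estimate": est,
                    "se": np.nan if se is None else float(se[p]),
                }
            )
    return pd.DataFrame(rows)


def compare_item_parameters(
    set_a: Sequence[GRMItem],
    set_b: Sequence[GRMItem],
    se_a: dict | None = None,
    se_b: dict | None = None,
    z: float = 1.96,
) -> ParamComparison:
    """Compare two parameter sets for the same items.

    With standard errors on both sides, flags per-parameter overlap of the
    ``estimate +/- z*SE`` intervals and counts overlapping slopes and
    thresholds.  Without SEs, falls back to estimate-difference mode (CI
    flags all True vacuously is avoided: overlap column is NaN).
    """
    ids_a = [it.item_id for it in set_a]
    ids_b = [it.item_id for it in set_b]
    if ids_a != ids_b or any(
        a.n_categories != b.n_categories for a, b in zip(set_a, set_b)
    ):
        raise ValueError("item sets must share items and category structure")
    fa = _param_frame(set_a, se_a).rename(columns={"estimate": "est_a", "se": "se_a"})
    fb = _param_frame(set_b, se_b).rename(columns={"estimate": "est_b", "se": "se_b"})
    tab = fa.merge(fb, on=["item_id", "param"])
    tab["abs_diff"] = (tab["est_a"] - tab["est_b"]).abs()
    mode = "ci" if se_a is not None and se_b is not None else "estimate"
    if mode == "ci":
        lo_a, hi_a = tab.est_a - z * tab.se_a, tab.est_a + z * tab.se_a
        lo_b, hi_b = tab.est_b - z * tab.se_b, tab.est_b + z * tab.se_b
        tab["ci_overlap"] = (lo_a <= hi_b) & (lo_b <= hi_a)
        slopes = tab[tab.param == "a"]
        thr = tab[tab.param != "a"]
        n_os, n_ot = int(slopes.ci_overlap.sum()), int(thr.ci_overlap.sum())
    else:
        tab["ci_overlap"] = np.nan
        n_os = n_ot = 0
    n_slopes = int((tab.param == "a").sum())
    n_thr = int((tab.param != "a").sum())
    return ParamComparison(
        table=tab,
        n_overlap_slopes=n_os,
        n_slopes=n_slopes,
        n_overlap_thresholds=n_ot,
        n_thresholds=n_thr,
        max_abs_diff=float(tab["abs_diff"].max()),
        mode=mode,
    )


def summary_stats(scores) -> dict:
    """Mean, median, SD (n-1), min, max and [Q1, Q3] with linear interpolation."""
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("empty score vector")
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "iqr": [float(q1), float(q3)],
        "n": int(x.size),
    }
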