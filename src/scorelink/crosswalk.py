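"""Raw-score -> T-score crosswalk tables via summed-score EAP.

The summed-score distribution conditional on theta is computed with the
Lord-Wingersky recursion

    L_j(s | theta) = sum_k L_{j-1}(s - k | theta) * P_j(k | theta),

then combined with a prior on theta (standard normal by default, so T scores
are referenced to the anchor's general population) to give, for every raw
summed score s, the posterior mean EAP(theta | s), its posterior SD, the
T score 50 + 10*EAP and its SEM 10*PSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grm import GRMItem, ThetaGrid, category_prob_table

__all__ = [
    "CrosswalkTable",
    "CrosswalkComparison",
    "lw_score_distribution",
    "summed_score_eap",
    "build_crosswalk",
    "compare_crosswalks",
    "apply_crosswalk",
]


@dataclass(frozen=True)
class CrosswalkTable:
    """Per raw summed score: EAP theta, posterior SD, T score and its SEM."""

    raw_score: np.ndarray
    theta_eap: np.ndarray
    theta_psd: np.ndarray
    t_score: np.ndarray
    t_sem: np.ndarray
    prior_label: str = "normal(0,1)"

    def __post_init__(self) -> None:
        rs = np.asarray(self.raw_score)
        n = rs.size
        if not np.array_equal(rs, np.arange(n)):
            raise ValueError("raw scores must be consecutive integers from 0")
        for name in ("theta_eap", "theta_psd", "t_score", "t_sem"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must align with raw_score")
            object.__setattr__(self, name, arr)
        if np.any(np.diff(self.t_score) <= 0):
            raise ValueError("t_score must be strictly increasing in raw score")
        if np.any(self.t_sem <= 0):
            raise ValueError("t_sem must be positive everywhere")
        object.__setattr__(self, "raw_score", rs.astype(int))

    @property
    def max_score(self) -> int:
        return int(self.raw_score[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "raw_score": self.raw_score,
                "theta_eap": self.theta_eap,
                "theta_psd": self.theta_psd,
                "t_score": self.t_score,
                "t_sem": self.t_sem,
            }
        )


@dataclass(frozen=True)
class CrosswalkComparison:
    """Per-score T differences (a - b) and SEM-interval overlap flags."""

    raw_score: np.ndarray
    t_diff: np.ndarray
    max_abs_diff: float
    mean_diff: float
    sem_overlap: np.ndarray

    @property
    def all_overlap(self) -> bool:
        return bool(np.all(self.sem_overlap))


def lw_score_distribution(items: Sequence[GRMItem], grid: ThetaGrid, D: float = 1.0) -> np.ndarray:
    """P(summed score s | theta_q) table of shape (S_max + 1, Q).

    Dynamic programming over items; each theta column sums to one.
    """
    items = list(items)
    if not items:
        raise ValueError("at least one item required")
    tables = category_prob_table(items, grid, D)  # (K_j, Q) each
    dist = np.ones((1, len(grid)))
    for P in tables:
        K = P.shape[0]
        cur = dist.shape[0]
        new = np.zeros((cur + K - 1, len(grid)))
        for k in range(K):
            new[k : k + cur] += dist * P[k][None, :]
        dist = new
    return dist


def summed_score_eap(
    lw_table: np.ndarray, prior: ThetaGrid, prior_label: str = "normal(0,1)"
) -> CrosswalkTable:
    """EAP and posterior SD of theta given each raw summed score.

    ``theta_eap(s) = sum_q theta_q w_q P(s|theta_q) / sum_q w_q P(s|theta_q)``.
    A single-point (degenerate) prior yields zero posterior SD and is
    rejected, since a crosswalk SEM must be positive.
    """
    lw_table = np.asarray(lw_table, dtype=float)
    if len(prior) < 2:
        raise ValueError("degenerate single-point prior: posterior SD would be 0")
    joint = lw_table * prior.weights[None, :]
    marg = joint.sum(axis=1)
    if np.any(marg <= 0):
        bad = int(np.argmin(marg))
        raise ValueError(f"raw score {bad} has zero marginal probability under the prior")
    post = joint / marg[:, None]
    eap = post @ prior.points
    var = post @ prior.points**2 - eap**2
    psd = np.sqrt(np.clip(var, 0.0, None))
    return CrosswalkTable(
        raw_score=np.arange(lw_table.shape[0]),
        theta_eap=eap,
        theta_psd=psd,
        t_score=50.0 + 10.0 * eap,
        t_sem=10.0 * psd,
        prior_label=prior_label,
    )


def build_crosswalk(
    items: Sequence[GRMItem],
    grid: ThetaGrid | None = None,
    prior: str | ThetaGrid = "normal",
    D: float = 1.0,
) -> CrosswalkTable:
    """Crosswalk table for the summed score over ``items``.

    ``prior="normal"`` uses N(0,1) weights on the default 49-point [-4, 4]
    grid; pass a :class:`ThetaGrid` (e.g. a calibration's updated latent
    weights) for an empirical prior.
    """
    if isinstance(prior, ThetaGrid):
        prior_grid, label = prior, "empirical"
    elif prior == "normal":
        prior_grid = grid or ThetaGrid.equally_spaced()
        label = "normal(0,1)"
    else:
        raise ValueError(f"unknown prior {prior!r}")
    lw = lw_score_distribution(items, prior_grid, D)
    return summed_score_eap(lw, prior_grid, label)


def compare_crosswalks(cw_a: CrosswalkTable, cw_b: CrosswalkTable) -> CrosswalkComparison:
    """Per-score T differences (a - b) and whether the t +/- SEM intervals intersect."""
    if not np.array_equal(cw_a.raw_score, cw_b.raw_score):
        raise ValueError("crosswalks have different raw-score support")
    diff = cw_a.t_score - cw_b.t_score
    overlap = np.abs(diff) <= cw_a.t_sem + cw_b.t_sem
    return CrosswalkComparison(
        raw_score=cw_a.raw_score,
        t_diff=diff,
        max_abs_diff=float(np.max(np.abs(diff))),
        mean_diff=float(np.mean(diff)),
        sem_overlap=overlap,
    )


def apply_crosswalk(cw: CrosswalkTable, raw_scores) -> np.ndarray:
    """Map raw summed scores to T scores by table lookup.

    NaN inputs (undefined summed score from missing responses) map to NaN;
    out-of-range scores raise, naming the offending value.
    """
    arr = np.asarray(raw_scores, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    vals = arr[ok]
    if vals.size:
        if np.any(vals != np.round(vals)):
            bad = vals[vals != np.round(vals)][0]
            raise ValueError(f"raw score {bad!r} is not an integer")
        ints = vals.astype(int)
        if np.any((ints < 0) | (ints > cw.max_score)):
            bad = ints[(ints < 0) | (ints > cw.max_score)][0]
            raise ValueError(f"raw score {bad} outside table support 0..{cw.max_score}")
        out[ok] = cw.t_score[ints]
    return out
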