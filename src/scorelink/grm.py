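"""Graded response model (GRM) probabilities and likelihoods.

The GRM (Samejima) models an ordered polytomous item with ``K`` response
categories coded ``0 .. K-1`` through cumulative category probabilities that
are logistic in the latent trait ``theta``:

    P*(X >= k | theta) = 1 / (1 + exp(-D * a * (theta - b_k))),   k = 1..K-1

with discrimination (slope) ``a > 0`` and strictly increasing location
(threshold) parameters ``b_1 < ... < b_{K-1}``.  Category probabilities are
adjacent differences of the cumulative curves.  The scaling constant ``D``
defaults to 1.0 (pure logistic metric, the PROMIS convention); ``D = 1.702``
puts parameters on the normal-ogive metric.

Everything downstream — calibration, crosswalks, scoring — consumes the
three primitives defined here: :func:`cumulative_prob`,
:func:`category_prob` and :func:`pattern_loglik`, plus the containers
:class:`GRMItem`, :class:`ThetaGrid` and :class:`ResponseMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "MISSING",
    "GRMItem",
    "ThetaGrid",
    "ResponseMatrix",
    "cumulative_prob",
    "category_prob",
    "category_prob_table",
    "expected_score",
    "pattern_loglik",
    "loglik_matrix",
    "threshold_to_intercept",
]

#: Sentinel for a missing item response inside :class:`ResponseMatrix`.
MISSING: int = -1


@dataclass(frozen=True)
class GRMItem:
    """One polytomous item's parameters on the anchor metric.

    Parameters
    ----------
    item_id
        Label, e.g. ``"BSI_D4"``.
    slope
        Discrimination ``a``; must be positive.
    thresholds
        Strictly increasing locations ``b_1 < ... < b_{K-1}``.
    fixed
        True for anchor items whose parameters are never re-estimated.
    """

    item_id: str
    slope: float
    thresholds: tuple[float, ...]
    fixed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(float(b) for b in self.thresholds))
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise ValueError(f"item {self.item_id!r}: slope must be positive, got {self.slope}")
        if len(self.thresholds) < 1:
            raise ValueError(f"item {self.item_id!r}: needs at least one threshold (K >= 2)")
        b = np.asarray(self.thresholds, dtype=float)
        if not np.all(np.isfinite(b)):
            raise ValueError(f"item {self.item_id!r}: non-finite threshold")
        if np.any(np.diff(b) <= 0):
            raise ValueError(
                f"item {self.item_id!r}: thresholds must be strictly increasing, got {self.thresholds}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    def replace(self, **kwargs) -> "GRMItem":
        """Return a copy with some fields replaced."""
        data = {
            "item_id": self.item_id,
            "slope": self.slope,
            "thresholds": self.thresholds,
            "fixed": self.fixed,
        }
        data.update(kwargs)
        return GRMItem(**data)


def threshold_to_intercept(item: GRMItem) -> np.ndarray:
    """Convert location thresholds ``b_k`` to slope-intercept form ``c_k = -a * b_k``."""
    return -item.slope * np.asarray(item.thresholds, dtype=float)


@dataclass(frozen=True)
class ThetaGrid:
    """Quadrature points with weights representing a latent-trait distribution.

    Points are on the anchor theta metric where the referent population has
    mean 0 and SD 1 (T = 50 + 10*theta).  Weights must be non-negative and
    sum to one.
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        wts = np.asarray(self.weights, dtype=float)
        if pts.ndim != 1 or wts.shape != pts.shape:
            raise ValueError("points and weights must be 1-D arrays of equal length")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if np.any(wts < 0):
            raise ValueError("grid weights must be non-negative")
        if abs(wts.sum() - 1.0) > 1e-10:
            raise ValueError(f"grid weights must sum to 1, got {wts.sum()!r}")
        pts.setflags(write=False)
        wts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts)

    def __len__(self) -> int:
        return self.points.size

    @classmethod
    def equally_spaced(
        cls, n_points: int = 49, lo: float = -4.0, hi: float = 4.0, prior: str = "normal"
    ) -> "ThetaGrid":
        """Equally spaced grid on ``[lo, hi]``.

        ``prior="normal"`` sets initial weights proportional to the standard
        normal density (renormalized); ``prior="uniform"`` sets them flat.
        The default 49 points on [-4, 4] spans T scores 10-90.
        """
        pts = np.linspace(lo, hi, n_points)
        if prior == "normal":
            w = norm.pdf(pts)
        elif prior == "uniform":
            w = np.ones_like(pts)
        else:
            raise ValueError(f"unknown prior {prior!r}")
        return cls(pts, w / w.sum())

    def with_weights(self, weights: np.ndarray) -> "ThetaGrid":
        return ThetaGrid(self.points, weights)

    @property
    def mean(self) -> float:
        return float(self.weights @ self.points)

    @property
    def sd(self) -> float:
        m = self.mean
        return float(np.sqrt(self.weights @ (self.points - m) ** 2))


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items integer response table.

    ``values[i, j]`` is person ``i``'s response to item ``j`` coded
    ``0 .. K_j - 1``, or :data:`MISSING` for a skipped item.
    """

    values: np.ndarray
    item_ids: tuple[str, ...]
    person_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D persons x items array")
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("responses must be integers (use MISSING=-1 for missing cells)")
        vals = vals.astype(np.int64)
        if vals.size and vals.min() < MISSING:
            raise ValueError("response codes must be >= 0 (or MISSING)")
        item_ids = tuple(str(c) for c in self.item_ids)
        if len(item_ids) != vals.shape[1]:
            raise ValueError("item_ids must align with columns")
        if len(set(item_ids)) != len(item_ids):
            raise ValueError("duplicate item ids")
        person_ids = tuple(str(p) for p in self.person_ids) if self.person_ids else tuple(
            f"P{i:05d}" for i in range(vals.shape[0])
        )
        if len(person_ids) != vals.shape[0]:
            raise ValueError("person_ids must align with rows")
        if len(set(person_ids)) != len(person_ids):
            raise ValueError("duplicate person ids")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "item_ids", item_ids)
        object.__setattr__(self, "person_ids", person_ids)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> np.ndarray:
        return self.values != MISSING

    def validate_against(self, items: Sequence[GRMItem]) -> None:
        """Check every observed entry is inside its item's category range."""
        by_id = {it.item_id: it for it in items}
        for j, cid in enumerate(self.item_ids):
            if cid not in by_id:
                raise ValueError(f"no item parameters for response column {cid!r}")
            K = by_id[cid].n_categories
            col = self.values[:, j]
            bad = np.where((col != MISSING) & ((col < 0) | (col >= K)))[0]
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"response out of range: person {self.person_ids[i]!r}, item {cid!r}, "
                    f"code {int(col[i])} not in 0..{K - 1}"
                )

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(c) for c in item_ids]
        return ResponseMatrix(self.values[:, idx], tuple(item_ids), self.person_ids)


def _as_theta_array(theta) -> tuple[np.ndarray, bool]:
    arr = np.atleast_1d(np.asarray(theta, dtype=float))
    return arr, np.ndim(theta) == 0


def cumulative_prob(item: GRMItem, theta, k: int, D: float = 1.0):
    """P(X >= k | theta) for category index ``k`` in ``1 .. K-1``.

    Scalar theta returns a scalar; array theta returns an array.
    """
    if not 1 <= k <= item.n_categories - 1:
        raise IndexError(
            f"category index k={k} out of range 1..{item.n_categories - 1} for item {item.item_id!r}"
        )
    arr, scalar = _as_theta_array(theta)
    p = expit(D * item.slope * (arr - item.thresholds[k - 1]))
    return float(p[0]) if scalar else p


def category_prob(item: GRMItem, theta, D: float = 1.0):
    """Probability vector over the K categories at each theta.

    Returns shape ``(K,)`` for scalar theta, ``(len(theta), K)`` otherwise.
    Entries are non-negative and sum to one (telescoping differences of the
    cumulative curves).
    """
    arr, scalar = _as_theta_array(theta)
    b = np.asarray(item.thresholds, dtype=float)
    # cumulative P(X>=k) for k=0..K with boundary columns 1 and 0
    cum = np.empty((arr.size, item.n_categories + 1))
    cum[:, 0] = 1.0
    cum[:, -1] = 0.0
    cum[:, 1:-1] = expit(D * item.slope * (arr[:, None] - b[None, :]))
    p = cum[:, :-1] - cum[:, 1:]
    np.maximum(p, 0.0, out=p)  # guard tiny negative round-off
    return p[0] if scalar else p


def category_prob_table(items: Sequence[GRMItem], grid: ThetaGrid, D: float = 1.0) -> list[np.ndarray]:
    """Per-item category probabilities on a grid: list of ``(K_j, Q)`` arrays."""
    return [category_prob(it, grid.points, D).T for it in items]


def expected_score(item: GRMItem, theta, D: float = 1.0):
    """E[X | theta] = sum_k k * P(X = k | theta); non-decreasing in theta."""
    p = category_prob(item, theta, D)
    k = np.arange(item.n_categories)
    return p @ k


def pattern_loglik(responses: Sequence[int], items: Sequence[GRMItem], theta, D: float = 1.0):
    """Log-likelihood of one person's response row at theta.

    Missing entries (:data:`MISSING`) are skipped — the MAR-ignorable
    convention; an all-missing row has no likelihood and raises.
    """
    responses = np.asarray(responses)
    if responses.shape != (len(items),):
        raise ValueError("response row must align with items")
    if np.all(responses == MISSING):
        raise ValueError("all responses missing: likelihood undefined")
    arr, scalar = _as_theta_array(theta)
    total = np.zeros(arr.size)
    for x, item in zip(responses, items):
        if x == MISSING:
            continue
        if not 0 <= x < item.n_categories:
            raise ValueError(f"response {x} out of range for item {item.item_id!r}")
        total += np.log(category_prob(item, arr, D)[:, int(x)])
    return float(total[0]) if scalar else total


def loglik_matrix(responses: ResponseMatrix, items: Sequence[GRMItem], grid: ThetaGrid,
                  D: float = 1.0) -> np.ndarray:
    """Persons x grid-points log-likelihood matrix, missing entries skipped.

    Vectorized over persons: the workhorse behind the E-step and EAP scoring.
    """
    responses.validate_against(items)
    by_id = {it.item_id: it for it in items}
    ll = np.zeros((responses.n_persons, len(grid)))
    for j, cid in enumerate(responses.item_ids):
        item = by_id[cid]
        logp = np.log(category_prob(item, grid.points, D))  # (Q, K)
        col = responses.values[:, j]
        obs = col != MISSING
        ll[obs] += logp[:, col[obs]].T
    return ll
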