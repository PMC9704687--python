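"""Fixed-parameter marginal maximum-likelihood calibration.

Places free (legacy) items on the metric defined by anchor items whose
parameters are held fixed, via an EM algorithm in which the latent trait
distribution is represented by weights on a quadrature grid and is itself
freely re-estimated every cycle ("multiple weights updating, multiple EM
cycles").  The complete-data log-likelihood separates into a weights part and
per-item parts, so updating the weights (posterior column means) and
maximizing each free item's expected log-likelihood are both exact M-steps
and the marginal log-likelihood is non-decreasing across cycles.

Standard errors for the free parameters are computed at convergence from the
outer product of per-person score vectors (OPG information), with the latent
weights held at their final values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grm import (
    MISSING,
    GRMItem,
    ResponseMatrix,
    ThetaGrid,
    category_prob,
    loglik_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationConfig",
    "CalibrationResult",
    "e_step",
    "m_step_item",
    "update_latent_weights",
    "fixed_parameter_calibrate",
    "marginal_loglik",
    "collapse_empty_categories",
]


class AnchoringError(ValueError):
    """No fixed items: the latent metric is undefined."""


class LinkageError(ValueError):
    """No respondent connects the anchor and free items."""


class ConvergenceError(RuntimeError):
    """An inner optimizer failed; carries the optimizer message."""


@dataclass(frozen=True)
class CalibrationConfig:
    """EM settings.

    param_tol
        Stop when the largest absolute parameter change in a cycle falls
        below this (jointly with ``loglik_tol``).
    loglik_tol
        Relative marginal log-likelihood change threshold.
    max_cycles
        Hard cap on EM cycles.
    D
        Logistic scaling constant (1.0 logistic metric, 1.702 normal-ogive).
    update_weights
        Freely re-estimate the latent distribution each cycle.
    compute_se
        Compute OPG standard errors at convergence.
    """

    param_tol: float = 1e-4
    loglik_tol: float = 1e-7
    max_cycles: int = 500
    D: float = 1.0
    update_weights: bool = True
    compute_se: bool = True
    m_step_maxiter: int = 80


@dataclass
class CalibrationResult:
    """Output of :func:`fixed_parameter_calibrate`.

    ``items`` holds anchors untouched and legacy items at their estimates;
    ``standard_errors[item_id]`` is an array aligned with
    ``(slope, b_1, ..., b_{K-1})``; ``latent_weights`` is the final updated
    distribution; ``collapsed_categories[item_id]`` records the
    original->estimation category recode applied when a category had no
    observed responses (absent when no recode was needed).
    """

    items: list[GRMItem]
    standard_errors: dict[str, np.ndarray]
    latent_weights: ThetaGrid
    loglik_trace: np.ndarray
    n_cycles: int
    converged: bool
    n_persons_used: int
    n_persons_dropped: int
    collapsed_categories: dict[str, dict[int, int]] = field(default_factory=dict)

    @property
    def free_items(self) -> list[GRMItem]:
        return [it for it in self.items if not it.fixed]

    def item(self, item_id: str) -> GRMItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def recode_responses(self, responses: ResponseMatrix) -> ResponseMatrix:
        """Apply the collapsed-category recodes to a response matrix.

        Needed before summing raw scores for a crosswalk built from items
        whose categories were collapsed during estimation.
        """
        if not self.collapsed_categories:
            return responses
        values = np.array(responses.values)
        for item_id, mapping in self.collapsed_categories.items():
            if item_id not in responses.item_ids:
                continue
            j = responses.item_ids.index(item_id)
            col = values[:, j]
            obs = col != MISSING
            values[obs, j] = np.vectorize(mapping.get)(col[obs])
        return ResponseMatrix(values, responses.item_ids, responses.person_ids)

    def confidence_interval(self, item_id: str, z: float = 1.96) -> np.ndarray:
        """(n_params, 2) array of normal-theory CIs (estimate +/- z*SE)."""
        it = self.item(item_id)
        est = np.r_[it.slope, it.thresholds]
        se = self.standard_errors[item_id]
        return np.c_[est - z * se, est + z * se]


# ---------------------------------------------------------------------------
# E-step


def e_step(
    responses: ResponseMatrix,
    items: Sequence[GRMItem],
    grid: ThetaGrid,
    D: float = 1.0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Posterior weights and expected category counts.

    Returns ``(posterior, counts)`` where ``posterior`` is persons x Q with
    rows summing to one, and ``counts[item_id]`` is a ``(K_j, Q)`` table of
    expected response counts whose total equals the number of observed
    responses for that item.  Persons with no observed responses must be
    removed beforehand (see :func:`fixed_parameter_calibrate`).
    """
    if not np.any(responses.observed_mask().any(axis=1)):
        raise ValueError("no observed responses")
    ll = loglik_matrix(responses, items, grid, D)
    with np.errstate(divide="ignore"):
        logw = np.log(grid.weights)
    logpost = ll + logw[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    posterior = np.exp(logpost)

    counts: dict[str, np.ndarray] = {}
    by_id = {it.item_id: it for it in items}
    for j, cid in enumerate(responses.item_ids):
        K = by_id[cid].n_categories
        col = responses.values[:, j]
        tab = np.zeros((K, len(grid)))
        for k in range(K):
            sel = col == k
            if sel.any():
                tab[k] = posterior[sel].sum(axis=0)
        counts[cid] = tab
    return posterior, counts


# ---------------------------------------------------------------------------
# M-step

def _pack(item: GRMItem) -> np.ndarray:
    """(a, b) -> unconstrained (log a, b1, log gaps)."""
    b = np.asarray(item.thresholds)
    return np.r_[np.log(item.slope), b[0], np.log(np.diff(b))] if b.size > 1 else np.r_[
        np.log(item.slope), b[0]
    ]


def _unpack(eta: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(eta[0]))
    b = np.empty(eta.size - 1)
    b[0] = eta[1]
    if b.size > 1:
        b[1:] = np.exp(eta[2:])
        b = np.cumsum(b)
    return a, b


def expected_item_loglik(
    item: GRMItem, counts: np.ndarray, grid: ThetaGrid, D: float = 1.0
) -> float:
    """sum_{k,q} r_kq * log P_k(theta_q) for one item."""
    p = category_prob(item, grid.points, D).T  # (K, Q)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = counts * np.log(p)
    return float(np.sum(t[counts > 0]))


def m_step_item(
    counts: np.ndarray,
    grid: ThetaGrid,
    start: GRMItem,
    D: float = 1.0,
    maxiter: int = 80,
) -> GRMItem:
    """Maximize one free item's expected complete-data log-likelihood.

    Thresholds are re-parameterized as (b1, log-gaps) so ordering holds by
    construction; the slope as log(a).  Warm-started at ``start``; if the
    optimizer cannot improve it returns ``start`` (EM monotonicity is never
    sacrificed).
    """
    if start.fixed:
        raise ValueError(f"item {start.item_id!r} is fixed; no M-step applies")
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (start.n_categories, len(grid)):
        raise ValueError("counts table shape must be (K, Q)")
    if np.any(counts < 0):
        raise ValueError("expected counts must be non-negative")

    pts = grid.points

    def neg_q(eta: np.ndarray) -> float:
        a, b = _unpack(eta)
        if not np.all(np.isfinite(b)) or not np.isfinite(a):
            return np.inf
        cum = np.empty((b.size + 2, pts.size))
        cum[0] = 1.0
        cum[-1] = 0.0
        cum[1:-1] = 1.0 / (1.0 + np.exp(-D * a * (pts[None, :] - b[:, None])))
        p = cum[:-1] - cum[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.log(p)
        val = np.sum(counts[counts > 0] * lp[counts > 0])
        return -val if np.isfinite(val) else np.inf

    eta0 = _pack(start)
    res = minimize(neg_q, eta0, method="L-BFGS-B", options={"maxiter": maxiter})
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"M-step failed for item {start.item_id!r}: {res.message}")
    if res.fun > neg_q(eta0):
        # optimizer ended worse than the start (pathological); keep start
        return start
    a, b = _unpack(res.x)
    if np.any(np.diff(b) <= 0):  # numerically collapsed gap
        b = np.maximum.accumulate(b + np.arange(b.size) * 1e-8)
    return start.replace(slope=a, thresholds=tuple(b))


def update_latent_weights(posterior: np.ndarray, grid: ThetaGrid) -> ThetaGrid:
    """New weights = column means of the posterior table."""
    posterior = np.asarray(posterior, dtype=float)
    if posterior.ndim != 2 or posterior.shape[0] == 0:
        raise ValueError("posterior table must be a non-empty 2-D array")
    if posterior.shape[1] != len(grid):
        raise ValueError("posterior columns must match grid points")
    w = posterior.mean(axis=0)
    return grid.with_weights(w / w.sum())


# ---------------------------------------------------------------------------
# Driver


def marginal_loglik(
    responses: ResponseMatrix, items: Sequence[GRMItem], grid: ThetaGrid, D: float = 1.0
) -> float:
    """Marginal log-likelihood sum_i log sum_q w_q L_i(theta_q)."""
    ll = loglik_matrix(responses, items, grid, D)
    with np.errstate(divide="ignore"):
        logw = np.log(grid.weights)
    return float(np.sum(logsumexp(ll + logw[None, :], axis=1)))


def collapse_empty_categories(
    responses: ResponseMatrix, items: Sequence[GRMItem]
) -> tuple[ResponseMatrix, list[GRMItem], dict[str, dict[int, int]]]:
    """Merge never-endorsed categories of free items into their lower neighbour.

    A category with zero observed responses cannot anchor its threshold, so
    for estimation it is merged with the adjacent lower category (category 0
    merges upward).  Returns recoded responses, reduced items, and the
    original->recoded category maps for items that changed.
    """
    by_id = {it.item_id: it for it in items}
    values = np.array(responses.values)
    new_items: list[GRMItem] = []
    mappings: dict[str, dict[int, int]] = {}
    for it in items:
        if it.fixed or it.item_id not in responses.item_ids:
            new_items.append(it)
            continue
        j = responses.item_ids.index(it.item_id)
        col = values[:, j]
        observed = set(int(c) for c in np.unique(col[col != MISSING]))
        K = it.n_categories
        if observed == set(range(K)):
            new_items.append(it)
            continue
        mapping: dict[int, int] = {}
        nxt = 0
        for k in range(K):
            if k in observed:
                mapping[k] = nxt
                nxt += 1
            else:
                # merge downwards; if no lower observed category yet, upwards
                mapping[k] = max(nxt - 1, 0)
        new_K = nxt
        if new_K < 2:
            raise ValueError(
                f"item {it.item_id!r}: fewer than 2 observed categories; cannot estimate"
            )
        warnings.warn(
            f"item {it.item_id}: categories {sorted(set(range(K)) - observed)} never endorsed; "
            f"collapsed for estimation",
            stacklevel=2,
        )
        logger.warning("collapsing empty categories for %s: %s", it.item_id, mapping)
        obs = col != MISSING
        values[obs, j] = np.vectorize(mapping.get)(col[obs])
        # seed thresholds for the reduced item from the surviving boundaries
        keep = [k for k in range(1, K) if mapping[k] != mapping[k - 1]]
        b = tuple(it.thresholds[k - 1] for k in keep)
        new_items.append(GRMItem(it.item_id, it.slope, b, fixed=False))
        mappings[it.item_id] = mapping
    return (
        ResponseMatrix(values, responses.item_ids, responses.person_ids),
        new_items,
        mappings,
    )


def _starting_values(responses: ResponseMatrix, items: Sequence[GRMItem]) -> list[GRMItem]:
    """Crude starts for free items: a=1.5, thresholds from normal quantiles of
    the observed cumulative endorsement proportions."""
    from scipy.stats import norm

    out: list[GRMItem] = []
    for it in items:
        if it.fixed:
            out.append(it)
            continue
        j = responses.item_ids.index(it.item_id)
        col = responses.values[:, j]
        obs = col[col != MISSING]
        K = it.n_categories
        b = []
        for k in range(1, K):
            p = np.clip(np.mean(obs >= k), 1e-3, 1 - 1e-3)
            b.append(norm.ppf(1 - p))
        b = np.asarray(b)
        # enforce strict ordering on ties from equal proportions
        for i in range(1, b.size):
            if b[i] <= b[i - 1]:
                b[i] = b[i - 1] + 1e-3
        out.append(it.replace(slope=1.5, thresholds=tuple(b)))
    return out


def _free_param_vector(items: Sequence[GRMItem]) -> np.ndarray:
    return np.concatenate(
        [np.r_[it.slope, it.thresholds] for it in items if not it.fixed]
    ) if any(not it.fixed for it in items) else np.empty(0)


def _opg_standard_errors(
    responses: ResponseMatrix,
    items: list[GRMItem],
    grid: ThetaGrid,
    D: float,
    h: float = 1e-5,
) -> dict[str, np.ndarray]:
    """OPG (cross-product-of-gradients) SEs for all free item parameters.

    Per-person score vectors are obtained by central finite differences of
    the per-person marginal log-likelihood; the information matrix is the sum
    of their outer products, inverted jointly across items.
    """

    def per_person_ll(its: Sequence[GRMItem]) -> np.ndarray:
        ll = loglik_matrix(responses, its, grid, D)
        with np.errstate(divide="ignore"):
            logw = np.log(grid.weights)
        return logsumexp(ll + logw[None, :], axis=1)

    free_idx = [i for i, it in enumerate(items) if not it.fixed]
    layout: list[tuple[str, int]] = []  # (item_id, n_params)
    G_cols: list[np.ndarray] = []
    for i in free_idx:
        it = items[i]
        n_par = 1 + len(it.thresholds)
        layout.append((it.item_id, n_par))
        for p in range(n_par):
            def perturbed(delta: float) -> list[GRMItem]:
                vec = np.r_[it.slope, it.thresholds]
                vec[p] += delta
                mod = it.replace(slope=vec[0], thresholds=tuple(vec[1:]))
                return [mod if j == i else jt for j, jt in enumerate(items)]

            step = h * max(1.0, abs(np.r_[it.slope, it.thresholds][p]))
            G_cols.append((per_person_ll(perturbed(step)) - per_person_ll(perturbed(-step))) / (2 * step))
    if not G_cols:
        return {}
    G = np.column_stack(G_cols)
    info = G.T @ G
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # singular information: report pseudo-inverse SEs
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    out: dict[str, np.ndarray] = {}
    pos = 0
    for item_id, n_par in layout:
        out[item_id] = se[pos : pos + n_par]
        pos += n_par
    return out


def fixed_parameter_calibrate(
    responses: ResponseMatrix,
    items: Sequence[GRMItem],
    grid: ThetaGrid | None = None,
    config: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Calibrate free items onto the metric of the fixed anchor items.

    Parameters
    ----------
    responses
        Persons x items table covering (at least) every item in ``items``.
    items
        Anchor items flagged ``fixed=True`` plus free legacy items.  At
        least one fixed item is required unless every item is fixed (then
        only the latent weights are updated).
    grid
        Quadrature grid; defaults to 49 points on [-4, 4] with standard
        normal starting weights.
    config
        EM settings; see :class:`CalibrationConfig`.
    """
    grid = grid or ThetaGrid.equally_spaced()
    config = config or CalibrationConfig()
    items = list(items)
    ids = [it.item_id for it in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate item ids in parameter list")

    free = [it for it in items if not it.fixed]
    anchors = [it for it in items if it.fixed]
    if not anchors:
        raise AnchoringError("no fixed items: the latent metric is undefined")
    anchor_snapshot = {it.item_id: it for it in anchors}

    responses = responses.subset_items([it.item_id for it in items])
    responses.validate_against(items)

    # drop persons with no observed responses
    any_obs = responses.observed_mask().any(axis=1)
    n_dropped = int((~any_obs).sum())
    if n_dropped:
        logger.warning("dropping %d persons with no observed responses", n_dropped)
        responses = ResponseMatrix(
            responses.values[any_obs],
            responses.item_ids,
            tuple(np.asarray(responses.person_ids)[any_obs]),
        )
    if responses.n_persons == 0:
        raise ValueError("no persons with observed responses")

    if free:
        obs = responses.observed_mask()
        a_cols = [j for j, c in enumerate(responses.item_ids) if c in anchor_snapshot]
        f_cols = [j for j, c in enumerate(responses.item_ids) if c not in anchor_snapshot]
        linked = obs[:, a_cols].any(axis=1) & obs[:, f_cols].any(axis=1)
        if not linked.any():
            raise LinkageError(
                "no respondent answered both an anchor item and a free item; linking impossible"
            )

    responses, items, collapsed = collapse_empty_categories(responses, items)
    if free:
        items = _starting_values(responses, items)

    trace: list[float] = []
    converged = False
    cycle = 0
    prev_ll = marginal_loglik(responses, items, grid, config.D)
    trace.append(prev_ll)
    for cycle in range(1, config.max_cycles + 1):
        old_params = _free_param_vector(items)
        posterior, counts = e_step(responses, items, grid, config.D)
        new_items = [
            it if it.fixed else m_step_item(
                counts[it.item_id], grid, it, config.D, config.m_step_maxiter
            )
            for it in items
        ]
        if config.update_weights:
            grid = update_latent_weights(posterior, grid)
        items = new_items
        ll = marginal_loglik(responses, items, grid, config.D)
        trace.append(ll)
        new_params = _free_param_vector(items)
        dpar = float(np.max(np.abs(new_params - old_params))) if new_params.size else 0.0
        dll = abs(ll - prev_ll) / (abs(prev_ll) + 1.0)
        prev_ll = ll
        if dpar < config.param_tol and dll < config.loglik_tol:
            converged = True
            break

    for it in items:  # anchors must be byte-identical to the input
        if it.fixed:
            assert it == anchor_snapshot[it.item_id]

    se: dict[str, np.ndarray] = {}
    if config.compute_se and free:
        se = _opg_standard_errors(responses, items, grid, config.D)

    return CalibrationResult(
        items=items,
        standard_errors=se,
        latent_weights=grid,
        loglik_trace=np.asarray(trace),
        n_cycles=cycle,
        converged=converged,
        n_persons_used=responses.n_persons,
        n_persons_dropped=n_dropped,
        collapsed_categories=collapsed,
    )
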