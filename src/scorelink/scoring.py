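"""Response-pattern EAP scoring on the anchor metric.

Produces the "observed" T scores (posterior mean of theta given a person's
full response pattern) against which crosswalk-derived scores are validated.
Quadrature EAP with the same default grid and N(0,1) prior as the crosswalk
module, so observed and derived scores share one referencing convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grm import GRMItem, ResponseMatrix, ThetaGrid, loglik_matrix

__all__ = ["PersonScore", "pattern_eap", "t_transform"]


@dataclass(frozen=True)
class PersonScore:
    person_id: str
    theta_eap: float
    theta_se: float
    t_score: float
    t_se: float
    n_items_observed: int


def t_transform(theta: float) -> float:
    """T = 50 + 10*theta (mean 50, SD 10 in the referent population)."""
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    return 50.0 + 10.0 * np.asarray(theta) if np.ndim(theta) else 50.0 + 10.0 * float(theta)


def pattern_eap(
    responses: ResponseMatrix,
    items: Sequence[GRMItem],
    prior: ThetaGrid | None = None,
    D: float = 1.0,
) -> pd.DataFrame:
    """EAP theta and T score per person given their response pattern.

    Persons with no observed responses are excluded (their ids are absent
    from the output).  Returns a DataFrame with columns ``person_id,
    theta_eap, theta_se, t_score, t_se, n_items_observed``; deterministic.
    """
    prior = prior or ThetaGrid.equally_spaced()
    any_obs = responses.observed_mask().any(axis=1)
    if not any_obs.all():
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d persons with no observed responses", int((~any_obs).sum())
        )
        responses = ResponseMatrix(
            responses.values[any_obs],
            responses.item_ids,
            tuple(np.asarray(responses.person_ids)[any_obs]),
        )
    ll = loglik_matrix(responses, items, prior, D)
    with np.errstate(divide="ignore"):
        logw = np.log(prior.weights)
    logpost = ll + logw[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    eap = post @ prior.points
    var = post @ prior.points**2 - eap**2
    se = np.sqrt(np.clip(var, 0.0, None))
    return pd.DataFrame(
        {
            "person_id": list(responses.person_ids),
            "theta_eap": eap,
            "theta_se": se,
            "t_score": 50.0 + 10.0 * eap,
            "t_se": 10.0 * se,
            "n_items_observed": responses.observed_mask().sum(axis=1),
        }
    )
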