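"""Kaplan-Meier estimators: overall curves and susceptibility-weighted
conditional curves.

The overall curve is the standard product-limit estimator over all
subjects.  The conditional curve estimates survival among the latent
susceptible subpopulation only: observed events are certainly susceptible
(weight 1), while a subject censored at ``c`` is susceptible with posterior
probability

    w = pi * S(c) / (pi * S(c) + 1 - pi),

computed from a fitted mixture model, and enters the risk set with that
fractional weight.  The conditional curve therefore tends to 0 while the
overall curve plateaus at the cure fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .model import MixtureFit, SurvivalRecord, loglogistic_survival

__all__ = [
    "KMCurve",
    "km_overall",
    "susceptibility_weights",
    "km_conditional",
    "curve_table",
]


@dataclass
class KMCurve:
    """Step-function survival estimate with (possibly fractional) risk sets.

    ``times`` holds the distinct times at which (weighted) events occur;
    ``survival`` the value of the step function just after each of them.
    ``last_followup`` extends the final flat segment to the latest
    observation time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n_start: float
    last_followup: float

    def survival_at(self, t) -> np.ndarray:
        """Step-function value at arbitrary times (1 before the first event)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.r_[1.0, self.survival]
        return padded[idx]


def _weighted_product_limit(
    times: np.ndarray, events: np.ndarray, weights: np.ndarray
) -> KMCurve:
    """Weighted product-limit over a sample; ties keep censorings in the
    risk set at the tied event time (events-before-censorings convention)."""
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("total weight is zero; cannot estimate a curve")
    uniq, inv = np.unique(times, return_inverse=True)
    d = np.bincount(inv, weights=weights * events)
    mass = np.bincount(inv, weights=weights)
    at_risk = mass[::-1].cumsum()[::-1]
    surv = np.cumprod(1.0 - d / at_risk)
    mask = d > 0
    return KMCurve(
        times=uniq[mask],
        survival=surv[mask],
        at_risk=at_risk[mask],
        events=d[mask],
        n_start=total,
        last_followup=float(times.max()),
    )


def km_overall(
    records: Sequence[SurvivalRecord],
    group_labels: Optional[Sequence] = None,
):
    """Product-limit DMFS estimate, optionally per group.

    With ``group_labels`` (one label per record) a dict of label -> KMCurve
    is returned; otherwise a single curve.  Unit weights throughout:
    censored subjects simply leave the risk set at their censoring time.
    """
    if not records:
        raise ValueError("no records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=float)
    if group_labels is None:
        return _weighted_product_limit(times, events, np.ones(len(records)))
    labels = np.asarray(group_labels)
    if len(labels) != len(records):
        raise ValueError("group_labels must align with records")
    out = {}
    for label in pd.unique(labels):
        mask = labels == label
        if not mask.any():
            raise ValueError(f"empty group {label!r}")
        out[label] = _weighted_product_limit(times[mask], events[mask], np.ones(mask.sum()))
    return out


def susceptibility_weights(
    records: Sequence[SurvivalRecord], fit_result: MixtureFit
) -> np.ndarray:
    """Posterior susceptibility probability per record under a fitted model.

    Events get weight 1.  A record censored at ``c`` gets
    ``pi(Z) S(c|Z) / (pi(Z) S(c|Z) + 1 - pi(Z))``, its probability of a
    later event given event-free follow-up to ``c``.  Weights are one-pass,
    taken from the final fit (not iteratively refitted).
    """
    if not fit_result.converged:
        raise ValueError("fit did not converge; weights would be unreliable")
    design = fit_result.design
    params = fit_result.params
    n = len(records)

    def matrix(terms):
        return np.column_stack(
            [np.ones(n)] + [[float(r.covariates[t]) for r in records] for t in terms]
        )

    pi = special.expit(matrix(design.logistic_terms) @ params.beta)
    mu = matrix(design.location_terms) @ params.gamma
    sigma = np.exp(matrix(design.scale_terms) @ params.alpha)
    times = np.array([r.time for r in records], dtype=float)
    s_cond = loglogistic_survival(times, mu, sigma)
    event = np.array([r.event for r in records], dtype=bool)
    censored_w = pi * s_cond / (pi * s_cond + 1.0 - pi)
    return np.where(event, 1.0, censored_w)


def km_conditional(
    records: Sequence[SurvivalRecord], weights: Sequence[float]
) -> KMCurve:
    """Weighted product-limit estimate of susceptible-only survival."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(records):
        raise ValueError("weights must align with records")
    if np.any((weights < 0) | (weights > 1)):
        raise ValueError("weights must lie in [0, 1]")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=float)
    return _weighted_product_limit(times, events, weights)


def curve_table(curve: KMCurve, log_time: bool = False) -> pd.DataFrame:
    """Step-function breakpoints as a (time, survival) table.

    On the linear scale the table starts at (0, 1); on the log scale the
    t = 0 row is dropped (undefined abscissa) and times are ln-transformed.
    If follow-up extends past the last event, a final flat row is added.
    """
    t = list(curve.times)
    s = list(curve.survival)
    if curve.last_followup > (t[-1] if t else 0.0):
        t.append(curve.last_followup)
        s.append(s[-1] if s else 1.0)
    if log_time:
        return pd.DataFrame({"time": np.log(t), "survival": s})
    return pd.DataFrame({"time": [0.0] + t, "survival": [1.0] + s})
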