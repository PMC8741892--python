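"""Logistic-AFT mixture cure regression with log-logistic event times.

The model describes right-censored time-to-event data (e.g. years from
surgery to distant metastasis) in a population where a latent fraction is
cured.  A binary indicator ``D`` marks susceptibility: ``D = 1`` means the
subject will eventually experience the event if followed indefinitely.
Covariates ``Z`` act through three regression parts:

* logistic part:  ``logit Pr(D = 1 | Z) = beta' Z`` — who is susceptible;
* location part:  ``mu(Z) = gamma' Z`` — centre of log event time;
* scale part:     ``sigma(Z) = exp(alpha' Z)`` — spread of log event time.

For a susceptible subject ``ln T = mu(Z) + sigma(Z) * eps`` with ``eps``
standard logistic, so ``T`` is log-logistic with median ``exp(mu(Z))``.
Overall survival mixes the two latent classes:

    Pr(T > t | Z) = pi(Z) * S(t | mu, sigma) + (1 - pi(Z)),

where ``pi = Pr(D = 1 | Z)`` and ``S`` is the log-logistic survival
function.  The overall curve plateaus at the cure fraction ``1 - pi``.

All three coefficient vectors are estimated jointly by maximum likelihood
from right-censored records; an event at ``t`` contributes
``pi * f(t)`` and a censoring at ``t`` contributes ``pi * S(t) + 1 - pi``.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "SurvivalRecord",
    "ModelDesign",
    "MixtureParams",
    "MixtureFit",
    "loglogistic_survival",
    "loglogistic_density",
    "cure_probability",
    "overall_survival",
    "median_event_time",
    "neg_log_likelihood",
    "initial_values",
    "fit",
    "wald_test",
    "confidence_interval",
    "likelihood_ratio_test",
    "select_model",
    "single_covariate_designs",
]

#: z-quantile used for 95% Wald intervals, fixed for bit-stable output.
Z_975 = 1.959964

#: Parts of the regression, in reporting order.
PARTS = ("logistic", "location", "scale")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time in years, event status, covariates.

    ``event = 1`` means the event (distant metastasis) was observed at
    ``time``; ``event = 0`` means right-censoring at ``time``.
    """

    time: float
    event: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time > 0):
            raise ValueError(f"time must be positive and finite, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        for name, value in self.covariates.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"covariate {name!r} is not finite: {value}")


@dataclass(frozen=True)
class ModelDesign:
    """Which covariates enter each regression part.

    Each part always contains an (implicit, estimated) intercept; the
    term tuples list additional covariate names only.
    """

    logistic_terms: tuple[str, ...] = ()
    location_terms: tuple[str, ...] = ()
    scale_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for part, terms in zip(PARTS, self._term_sets()):
            if len(set(terms)) != len(terms):
                raise ValueError(f"duplicate terms in {part} part: {terms}")

    def _term_sets(self) -> tuple[tuple[str, ...], ...]:
        return (self.logistic_terms, self.location_terms, self.scale_terms)

    def terms(self, part: str) -> tuple[str, ...]:
        try:
            return dict(zip(PARTS, self._term_sets()))[part]
        except KeyError:
            raise ValueError(f"unknown part {part!r}; expected one of {PARTS}")

    @property
    def n_params(self) -> int:
        return 3 + sum(len(t) for t in self._term_sets())

    def all_terms(self) -> set[str]:
        return set().union(*map(set, self._term_sets()))

    def labels(self) -> list[tuple[str, str]]:
        """Flat (part, term) labels in estimation order, intercept first."""
        out = []
        for part, terms in zip(PARTS, self._term_sets()):
            out.append((part, "intercept"))
            out.extend((part, t) for t in terms)
        return out

    def is_nested_in(self, other: "ModelDesign") -> bool:
        return all(
            set(a) <= set(b)
            for a, b in zip(self._term_sets(), other._term_sets())
        )

    def describe(self) -> str:
        return "+".join(
            f"{part}[{','.join(('1',) + terms)}]"
            for part, terms in zip(PARTS, self._term_sets())
        )


@dataclass
class MixtureParams:
    """Coefficient vectors (intercept first) for the three parts."""

    beta: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        for name, vec in (("beta", self.beta), ("gamma", self.gamma), ("alpha", self.alpha)):
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"{name} contains non-finite values: {vec}")

    def check_design(self, design: ModelDesign) -> None:
        expected = (
            1 + len(design.logistic_terms),
            1 + len(design.location_terms),
            1 + len(design.scale_terms),
        )
        got = (len(self.beta), len(self.gamma), len(self.alpha))
        if expected != got:
            raise ValueError(f"parameter lengths {got} do not match design {expected}")

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma, self.alpha])

    @staticmethod
    def unpack(theta: np.ndarray, design: ModelDesign) -> "MixtureParams":
        kb = 1 + len(design.logistic_terms)
        km = 1 + len(design.location_terms)
        theta = np.asarray(theta, dtype=float)
        return MixtureParams(theta[:kb], theta[kb:kb + km], theta[kb + km:])


@dataclass
class MixtureFit:
    """Result of a maximum-likelihood fit of the mixture model."""

    params: MixtureParams
    design: ModelDesign
    loglik: float
    aic: float
    covariance: Optional[np.ndarray]
    standard_errors: Optional[np.ndarray]
    converged: bool
    n: int
    n_events: int
    data_key: str = ""

    def index_of(self, part: str, term: str) -> int:
        labels = self.design.labels()
        try:
            return labels.index((part, term))
        except ValueError:
            raise ValueError(f"term ({part!r}, {term!r}) not in fitted design")

    def estimate(self, part: str, term: str = "intercept") -> float:
        return float(self.params.pack()[self.index_of(part, term)])

    def se(self, part: str, term: str = "intercept") -> float:
        if self.standard_errors is None:
            raise ValueError("standard errors unavailable (singular information matrix)")
        return float(self.standard_errors[self.index_of(part, term)])

    @property
    def k(self) -> int:
        return self.design.n_params


# ---------------------------------------------------------------------------
# Log-logistic distribution on the time scale
# ---------------------------------------------------------------------------


def _check_t_sigma(t, sigma) -> None:
    if np.any(np.asarray(t) <= 0) or not np.all(np.isfinite(np.asarray(t, dtype=float))):
        raise ValueError(f"t must be positive and finite, got {t}")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError(f"sigma must be positive, got {sigma}")


def loglogistic_survival(t, mu, sigma):
    """Survival ``Pr(T > t)`` of the log-logistic distribution.

    ``ln T = mu + sigma * eps`` with standard-logistic ``eps`` gives
    ``S(t) = 1 / (1 + exp((ln t - mu) / sigma))``.
    """
    _check_t_sigma(t, sigma)
    w = (np.log(t) - mu) / sigma
    return special.expit(-w)


def loglogistic_density(t, mu, sigma):
    """Density of the log-logistic distribution on the time scale.

    Change of variables from the logistic density
    ``f(eps) = e^eps / (1 + e^eps)^2`` gives
    ``f(t) = s(w) (1 - s(w)) / (t sigma)`` with ``w = (ln t - mu)/sigma``
    and ``s`` the logistic sigmoid.
    """
    _check_t_sigma(t, sigma)
    w = (np.log(t) - mu) / sigma
    s = special.expit(w)
    return s * (1.0 - s) / (np.asarray(t, dtype=float) * sigma)


# ---------------------------------------------------------------------------
# Linear predictors and derived probabilities
# ---------------------------------------------------------------------------


def _design_vector(z: Mapping[str, float], terms: Sequence[str]) -> np.ndarray:
    row = [1.0]
    for name in terms:
        if name not in z:
            raise ValueError(f"covariate {name!r} missing from input mapping")
        row.append(float(z[name]))
    return np.array(row)


def cure_probability(z: Mapping[str, float], beta, design: ModelDesign) -> float:
    """``Pr(D = 0 | Z)`` — probability of belonging to the cured fraction.

    The logistic part models ``logit Pr(D = 1 | Z) = beta' Z``, so the cure
    probability is ``1 / (1 + exp(beta' Z))``.
    """
    beta = np.asarray(beta, dtype=float)
    x = _design_vector(z, design.logistic_terms)
    if len(beta) != len(x):
        raise ValueError(f"beta length {len(beta)} does not match design ({len(x)})")
    return float(special.expit(-float(beta @ x)))


def overall_survival(t, z: Mapping[str, float], params: MixtureParams, design: ModelDesign):
    """Population survival ``Pr(T > t | Z)`` mixing susceptible and cured."""
    params.check_design(design)
    cure = cure_probability(z, params.beta, design)
    pi = 1.0 - cure
    mu = float(params.gamma @ _design_vector(z, design.location_terms))
    sigma = float(np.exp(params.alpha @ _design_vector(z, design.scale_terms)))
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    s_cond = np.where(t_arr > 0, loglogistic_survival(np.maximum(t_arr, 1e-300), mu, sigma), 1.0)
    out = pi * s_cond + cure
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def median_event_time(z: Mapping[str, float], params: MixtureParams, design: ModelDesign) -> float:
    """Median event time among susceptibles: ``exp(gamma' Z)``."""
    params.check_design(design)
    return float(np.exp(params.gamma @ _design_vector(z, design.location_terms)))


# ---------------------------------------------------------------------------
# Likelihood core (vectorized over records)
# ---------------------------------------------------------------------------


class _FitData:
    """Design matrices and outcomes extracted once per (records, design)."""

    def __init__(self, records: Sequence[SurvivalRecord], design: ModelDesign):
        if not records:
            raise ValueError("no records provided")
        times = np.array([r.time for r in records], dtype=float)
        if np.any(times <= 0):
            raise ValueError("all record times must be positive")
        self.design = design
        self.logt = np.log(times)
        self.times = times
        self.event = np.array([r.event for r in records], dtype=bool)
        self.Xl = self._matrix(records, design.logistic_terms)
        self.Xm = self._matrix(records, design.location_terms)
        self.Xs = self._matrix(records, design.scale_terms)
        self.n = len(records)
        self.n_events = int(self.event.sum())
        key = hashlib.sha1(times.tobytes() + self.event.tobytes()).hexdigest()
        self.data_key = key

    @staticmethod
    def _matrix(records, terms):
        cols = [np.ones(len(records))]
        for t in terms:
            try:
                cols.append(np.array([float(r.covariates[t]) for r in records]))
            except KeyError:
                raise ValueError(f"covariate {t!r} missing from a record")
        return np.column_stack(cols)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _nll_grad(theta: np.ndarray, data: _FitData) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its analytic gradient.

    Per-record log-likelihood, with ``eta = beta'x``, ``w = (ln t - mu)/sigma``,
    ``la = ln sigma``:
      event:    log pi + w - 2*softplus(w) - ln t - la
      censored: logaddexp(log pi - softplus(w), log(1 - pi))
    where ``log pi = -softplus(-eta)``, ``log(1 - pi) = -softplus(eta)``.
    """
    kb = data.Xl.shape[1]
    km = data.Xm.shape[1]
    beta = theta[:kb]
    gamma = theta[kb:kb + km]
    alpha = theta[kb + km:]

    eta = data.Xl @ beta
    mu = data.Xm @ gamma
    la = data.Xs @ alpha
    sigma = np.exp(la)
    w = (data.logt - mu) / sigma
    sw = special.expit(w)
    pi = special.expit(eta)

    ev = data.event
    ll = np.empty(data.n)
    d_eta = np.empty(data.n)
    d_w = np.empty(data.n)

    # events: pi * f(t)
    ll[ev] = (-_softplus(-eta[ev]) + w[ev] - 2.0 * _softplus(w[ev])
              - data.logt[ev] - la[ev])
    d_eta[ev] = 1.0 - pi[ev]
    d_w[ev] = 1.0 - 2.0 * sw[ev]

    # censored: pi * S(t) + (1 - pi)
    ce = ~ev
    a = -_softplus(-eta[ce]) - _softplus(w[ce])
    b = -_softplus(eta[ce])
    llc = np.logaddexp(a, b)
    ll[ce] = llc
    pa = np.exp(a - llc)
    d_eta[ce] = pa - pi[ce]
    d_w[ce] = -pa * sw[ce]

    # chain rule: d/d mu = -d_w / sigma ; d/d la = -w*d_w (+ -1 for events)
    d_mu = -d_w / sigma
    d_la = -w * d_w
    d_la[ev] -= 1.0

    nll = -float(ll.sum())
    grad = -np.concatenate([
        data.Xl.T @ d_eta,
        data.Xm.T @ d_mu,
        data.Xs.T @ d_la,
    ])
    return nll, grad


def neg_log_likelihood(
    records: Sequence[SurvivalRecord], params: MixtureParams, design: ModelDesign
) -> float:
    """Negative log-likelihood of the mixture model for right-censored data."""
    params.check_design(design)
    data = _FitData(records, design)
    nll, _ = _nll_grad(params.pack(), data)
    return nll


# ---------------------------------------------------------------------------
# Initial values from Kaplan-Meier summaries
# ---------------------------------------------------------------------------


def _km_step(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-weight product-limit estimate; returns (event times, survival)."""
    uniq, inv = np.unique(times, return_inverse=True)
    d = np.bincount(inv, weights=events.astype(float))
    n_at = np.bincount(inv).astype(float)[::-1].cumsum()[::-1]
    factors = 1.0 - d / n_at
    surv = np.cumprod(factors)
    mask = d > 0
    return uniq[mask], surv[mask]


def initial_values(records: Sequence[SurvivalRecord], design: ModelDesign) -> MixtureParams:
    """Starting parameters derived from the Kaplan-Meier curve.

    The logistic intercept inverts the KM tail (a nonparametric proxy for
    the cure fraction); the location intercept is the log of the median of
    the KM conditional-on-susceptible curve; the scale intercept matches
    logistic quantiles to the IQR of observed log event times.  Covariate
    coefficients start at zero.
    """
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if events.sum() == 0:
        raise ValueError("cannot initialize susceptible-time distribution: no events")

    step_t, step_s = _km_step(times, events)
    tail = float(step_s[-1])
    chat = min(max(tail, 1e-3), 1.0 - 1e-3)
    beta0 = float(special.logit(1.0 - chat))

    # conditional survival (S - tail) / (1 - tail) crosses 0.5 where
    # S <= tail + 0.5 * (1 - tail)
    threshold = tail + 0.5 * (1.0 - tail)
    crossed = step_t[step_s <= threshold + 1e-12]
    median_t = float(crossed[0]) if len(crossed) else float(step_t[-1])
    gamma0 = math.log(median_t)

    log_ev = np.log(times[events == 1])
    q75, q25 = np.percentile(log_ev, [75, 25])
    sigma0 = max((q75 - q25) / (2.0 * math.log(3.0)), 0.05)
    alpha0 = math.log(sigma0)

    return MixtureParams(
        beta=np.r_[beta0, np.zeros(len(design.logistic_terms))],
        gamma=np.r_[gamma0, np.zeros(len(design.location_terms))],
        alpha=np.r_[alpha0, np.zeros(len(design.scale_terms))],
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _observed_information(theta: np.ndarray, data: _FitData) -> np.ndarray:
    """Central-difference Hessian of the negative log-likelihood.

    Differencing the analytic gradient with step ``h = 1e-5 * (1 + |theta|)``
    and symmetrizing.
    """
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        _, gp = _nll_grad(tp, data)
        _, gm = _nll_grad(tm, data)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _identifiability_warning(data: _FitData, design: ModelDesign) -> None:
    for term in sorted(design.all_terms()):
        col = None
        for X, terms in ((data.Xl, design.logistic_terms),
                         (data.Xm, design.location_terms),
                         (data.Xs, design.scale_terms)):
            if term in terms:
                col = X[:, 1 + terms.index(term)]
                break
        if col is None:
            continue
        values = np.unique(col)
        if len(values) <= 2:  # binary grouping covariate
            for v in values:
                n_ev = int(data.event[col == v].sum())
                if n_ev < 5:
                    warnings.warn(
                        f"covariate {term!r} level {v:g} has only {n_ev} events; "
                        "cure fraction and tail are weakly identified",
                        UserWarning,
                        stacklevel=3,
                    )


def fit(
    records: Sequence[SurvivalRecord],
    design: ModelDesign,
    init: Optional[MixtureParams] = None,
    tol: float = 1e-8,
    n_restarts: int = 3,
    jitter_sd: float = 0.25,
    seed: int = 0,
) -> MixtureFit:
    """Joint maximum-likelihood fit of beta, gamma and alpha.

    Quasi-Newton (BFGS) optimization on the unconstrained parameterization
    (sigma enters as exp(alpha'Z), so no bounds are needed), started from
    Kaplan-Meier-based initial values plus ``n_restarts`` Gaussian-jittered
    restarts; the best final log-likelihood wins.  Standard errors come from
    the inverse central-difference observed information.
    """
    data = _FitData(records, design)
    if data.n_events < 2:
        raise ValueError(f"need at least 2 events to fit, got {data.n_events}")
    _identifiability_warning(data, design)

    if init is None:
        init = initial_values(records, design)
    init.check_design(design)
    theta0 = init.pack()
    f0, _ = _nll_grad(theta0, data)
    if not math.isfinite(f0):
        raise ValueError(
            f"likelihood not finite at initial values (nll={f0}); "
            f"check covariate scaling (init={theta0})"
        )

    rng = np.random.default_rng(seed)
    starts = [theta0]
    starts += [theta0 + rng.normal(0.0, jitter_sd, size=len(theta0)) for _ in range(n_restarts)]

    best = None
    for start in starts:
        res = optimize.minimize(
            _nll_grad, start, args=(data,), jac=True, method="BFGS",
            options={"gtol": tol * max(1.0, abs(f0)), "maxiter": 500},
        )
        if not math.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ValueError("optimization failed from every start")

    theta_hat = best.x
    loglik = -float(best.fun)
    k = design.n_params

    covariance = None
    se = None
    try:
        H = _observed_information(theta_hat, data)
        cov = np.linalg.inv(H)
        if np.all(np.isfinite(cov)) and np.all(np.diag(cov) >= 0):
            covariance = cov
            se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        pass

    return MixtureFit(
        params=MixtureParams.unpack(theta_hat, design),
        design=design,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        covariance=covariance,
        standard_errors=se,
        converged=bool(best.success),
        n=data.n,
        n_events=data.n_events,
        data_key=data.data_key,
    )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def wald_test(fit_result: MixtureFit, part: str, term_name: str) -> tuple[float, float]:
    """Wald z statistic and two-sided normal p-value for one coefficient."""
    est = fit_result.estimate(part, term_name)
    se = fit_result.se(part, term_name)
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def confidence_interval(
    fit_result: MixtureFit, part: str, term_name: str, level: float = 0.95
) -> tuple[float, float]:
    """Wald confidence interval ``estimate +/- z * SE``."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    est = fit_result.estimate(part, term_name)
    se = fit_result.se(part, term_name)
    z = Z_975 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    return est - z * se, est + z * se


def likelihood_ratio_test(fit_full: MixtureFit, fit_null: MixtureFit) -> tuple[float, int, float]:
    """LRT of a nested null fit against the full fit on the same records.

    Returns (statistic, df, chi-square p).  ``df = 0`` (identical designs)
    yields p = 1.
    """
    if not fit_null.design.is_nested_in(fit_full.design):
        raise ValueError("null design is not nested in the full design")
    if fit_full.data_key != fit_null.data_key or fit_full.n != fit_null.n:
        raise ValueError("fits were computed on different record sets")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    if stat < -1e-6:
        warnings.warn(f"negative LRT statistic {stat:.3g} (optimizer slack)", UserWarning)
    stat = max(stat, 0.0)
    df = fit_full.k - fit_null.k
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def single_covariate_designs(name: str) -> list[ModelDesign]:
    """All 8 placements of one covariate across the three regression parts.

    Ordered by number of parts used, then logistic < location < scale, so the
    covariate-free design comes first (a deterministic tie-break order).
    """
    out = []
    subsets = [
        (), ("logistic",), ("location",), ("scale",),
        ("logistic", "location"), ("logistic", "scale"), ("location", "scale"),
        ("logistic", "location", "scale"),
    ]
    for parts in subsets:
        out.append(ModelDesign(
            logistic_terms=(name,) if "logistic" in parts else (),
            location_terms=(name,) if "location" in parts else (),
            scale_terms=(name,) if "scale" in parts else (),
        ))
    return out


def select_model(
    records: Sequence[SurvivalRecord],
    candidate_designs: Sequence[ModelDesign],
    seed: int = 0,
    prefit: Optional[Mapping[ModelDesign, MixtureFit]] = None,
    **fit_kwargs,
) -> tuple[MixtureFit, pd.DataFrame]:
    """Fit every candidate design and pick the minimum-AIC fit.

    Ties break toward fewer parameters, then earlier candidate order.
    Failed fits are recorded in the ranking table and excluded from
    selection.  ``prefit`` can supply already-fitted designs (reused as-is).
    """
    if len(candidate_designs) < 2:
        raise ValueError("need at least 2 candidate designs")
    rows = []
    fits: list[Optional[MixtureFit]] = []
    for idx, design in enumerate(candidate_designs):
        try:
            if prefit is not None and design in prefit:
                f = prefit[design]
            else:
                f = fit(records, design, seed=seed, **fit_kwargs)
            fits.append(f)
            rows.append({
                "order": idx, "design": design.describe(), "k": design.n_params,
                "loglik": f.loglik, "aic": f.aic, "status": "ok",
            })
        except (ValueError, FloatingPointError) as exc:
            fits.append(None)
            rows.append({
                "order": idx, "design": design.describe(), "k": design.n_params,
                "loglik": np.nan, "aic": np.nan, "status": f"failed: {exc}",
            })
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"]
    if ok.empty:
        raise ValueError("every candidate fit failed")
    ranked = ok.sort_values(["aic", "k", "order"], kind="stable").reset_index(drop=True)
    best_order = int(ranked.iloc[0]["order"])
    table = pd.concat(
        [ranked, table[table["status"] != "ok"]], ignore_index=True
    ).drop(columns="order")
    best = fits[best_order]
    assert best is not None
    return best, table
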