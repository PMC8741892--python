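"""Unit and property tests for the mixture cure likelihood and inference."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, optimize as sopt, stats

import cureaft as ca
from cureaft.model import MixtureFit, _FitData, _nll_grad

from conftest import random_cohort


# ---------------------------------------------------------------------------
# log-logistic distribution
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "t, mu, sigma, expected",
    [
        (1.0, 0.0, 1.0, 0.5),
        (math.e, 0.0, 1.0, 1.0 / (1.0 + math.e)),
    ],
)
def test_loglogistic_survival_closed_forms(t, mu, sigma, expected):
    assert ca.loglogistic_survival(t, mu, sigma) == pytest.approx(expected, abs=1e-12)


def test_loglogistic_survival_matches_quadrature_oracle():
    mu, sigma = 0.3, 0.7
    integral, err = integrate.quad(ca.loglogistic_density, 0, 2, args=(mu, sigma))
    assert err < 1e-10
    assert ca.loglogistic_survival(2, mu, sigma) == pytest.approx(1 - integral, abs=1e-8)


def test_loglogistic_density_closed_form_and_normalization():
    assert ca.loglogistic_density(1.0, 0.0, 1.0) == pytest.approx(0.25, abs=1e-12)
    total, _ = integrate.quad(
        ca.loglogistic_density, 0, np.inf, args=(0.4, 0.6), limit=200
    )
    assert total == pytest.approx(1.0, abs=1e-6)


def test_density_equals_minus_survival_derivative_on_grid():
    h = 1e-5
    for t in (0.5, 1.0, 3.0, 8.0):
        for mu in (-0.5, 0.0, 1.0):
            for sigma in (0.4, 1.0, 1.7):
                num = (
                    ca.loglogistic_survival(t - h, mu, sigma)
                    - ca.loglogistic_survival(t + h, mu, sigma)
                ) / (2 * h)
                assert ca.loglogistic_density(t, mu, sigma) == pytest.approx(
                    num, abs=1e-6
                )


def test_density_matches_finite_difference_at_spec_point():
    t, mu, sigma = 3.0, 1.0, 0.5
    h = 1e-6
    cdf = lambda u: 1 - ca.loglogistic_survival(u, mu, sigma)
    num = (cdf(t + h) - cdf(t - h)) / (2 * h)
    assert ca.loglogistic_density(t, mu, sigma) == pytest.approx(num, abs=1e-6)


@given(
    t=st.floats(1e-3, 1e3),
    mu=st.floats(-3, 3),
    sigma=st.floats(0.1, 3),
)
def test_loglogistic_survival_is_a_proper_survival_function(t, mu, sigma):
    s = ca.loglogistic_survival(t, mu, sigma)
    assert 0.0 <= s <= 1.0
    assert ca.loglogistic_survival(t * 1.01, mu, sigma) <= s
    if 1e-12 < s < 1 - 1e-12:  # away from float saturation: strictly monotone
        assert ca.loglogistic_survival(t * 1.01, mu, sigma) < s
    assert ca.loglogistic_survival(1e-12, mu, sigma) > 1 - 1e-3
    assert ca.loglogistic_survival(1e12, mu, sigma) < 1e-3


@pytest.mark.parametrize("bad", [(-1.0, 0.0, 1.0), (0.0, 0.0, 1.0), (1.0, 0.0, -2.0)])
def test_loglogistic_domain_errors(bad):
    t, mu, sigma = bad
    with pytest.raises(ValueError):
        ca.loglogistic_survival(t, mu, sigma)
    with pytest.raises(ValueError):
        ca.loglogistic_density(t, mu, sigma)


# ---------------------------------------------------------------------------
# cure probability and overall survival
# ---------------------------------------------------------------------------


def test_cure_probability_symmetry_and_published_inversion():
    null = ca.ModelDesign()
    assert ca.cure_probability({}, [0.0], null) == pytest.approx(0.5)
    assert round(ca.cure_probability({}, [-0.715], null), 3) == 0.672


def test_cure_probability_matches_bernoulli_simulation():
    null = ca.ModelDesign()
    beta0 = -0.5
    p_cure = ca.cure_probability({}, [beta0], null)
    rng = np.random.default_rng(7)
    n = 10**6
    frac = 1.0 - rng.binomial(1, 1 / (1 + math.exp(-beta0)), n).mean()
    se = math.sqrt(p_cure * (1 - p_cure) / n)
    assert abs(frac - p_cure) < 3 * se


def test_cure_probability_missing_covariate_errors():
    design = ca.ModelDesign(logistic_terms=("z",))
    with pytest.raises(ValueError, match="missing"):
        ca.cure_probability({}, [0.0, 1.0], design)


def test_overall_survival_composition_and_limits():
    design = ca.ModelDesign()
    params = ca.MixtureParams([0.0], [0.0], [0.0])  # pi = 0.5, mu = 0, sigma = 1
    assert ca.overall_survival(0.0, {}, params, design) == pytest.approx(1.0)
    expected = 0.5 * ca.loglogistic_survival(2, 0, 1) + 0.5
    assert ca.overall_survival(2.0, {}, params, design) == pytest.approx(expected)

    # pi = 0.328 plateau: the curve flattens at the cure fraction
    params2 = ca.MixtureParams([-0.715], [2.249], [-0.545])
    tail = ca.overall_survival(1e9, {}, params2, design)
    cure = ca.cure_probability({}, [-0.715], design)
    assert tail == pytest.approx(cure, abs=1e-6)
    assert round(tail, 3) == 0.672


@given(
    beta0=st.floats(-3, 3),
    gamma0=st.floats(-1, 3),
    alpha0=st.floats(-1.5, -0.3),  # sigma <= 0.74: tail < 1e-6 by t = 1e6
)
def test_overall_survival_monotone_and_plateaus(beta0, gamma0, alpha0):
    design = ca.ModelDesign()
    params = ca.MixtureParams([beta0], [gamma0], [alpha0])
    ts = np.linspace(0, 40, 60)
    values = np.array([ca.overall_survival(t, {}, params, design) for t in ts])
    assert values[0] == pytest.approx(1.0)
    assert np.all(np.diff(values) <= 1e-12)
    cure = ca.cure_probability({}, [beta0], design)
    assert ca.overall_survival(1e6, {}, params, design) == pytest.approx(cure, abs=1e-6)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def test_neg_log_likelihood_closed_forms():
    null = ca.ModelDesign()
    params = ca.MixtureParams([0.0], [0.0], [0.0])
    ev = [ca.SurvivalRecord(1.0, 1)]
    ce = [ca.SurvivalRecord(1.0, 0)]
    assert ca.neg_log_likelihood(ev, params, null) == pytest.approx(
        math.log(8), abs=1e-10
    )
    assert ca.neg_log_likelihood(ce, params, null) == pytest.approx(
        -math.log(0.75), abs=1e-10
    )


def test_neg_log_likelihood_is_additive_over_records():
    design = ca.ModelDesign(location_terms=("x",))
    params = ca.MixtureParams([0.3], [0.5, -0.2], [-0.1])
    cohort = random_cohort(50, seed=5)
    total = ca.neg_log_likelihood(cohort, params, design)
    parts = sum(ca.neg_log_likelihood([r], params, design) for r in cohort)
    assert total == pytest.approx(parts, abs=1e-10)


def test_neg_log_likelihood_stable_for_large_predictors():
    null = ca.ModelDesign()
    cohort = [ca.SurvivalRecord(2.0, 1), ca.SurvivalRecord(3.0, 0)]
    for b in (-50.0, 50.0):
        val = ca.neg_log_likelihood(cohort, ca.MixtureParams([b], [0.0], [0.0]), null)
        assert math.isfinite(val)


def test_analytic_gradient_matches_finite_differences():
    design = ca.ModelDesign(
        logistic_terms=("x",), location_terms=("x",), scale_terms=("x",)
    )
    cohort = random_cohort(60, seed=9)
    data = _FitData(cohort, design)
    theta = np.array([0.2, -0.3, 0.6, 0.4, -0.2, 0.1])
    _, grad = _nll_grad(theta, data)
    num = sopt.approx_fprime(theta, lambda th: _nll_grad(th, data)[0], 1e-7)
    np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-6)


def test_record_invariants_rejected():
    with pytest.raises(ValueError):
        ca.SurvivalRecord(0.0, 1)
    with pytest.raises(ValueError):
        ca.SurvivalRecord(-1.0, 0)
    with pytest.raises(ValueError):
        ca.SurvivalRecord(1.0, 2)
    with pytest.raises(ValueError):
        ca.SurvivalRecord(1.0, 1, {"x": float("nan")})


# ---------------------------------------------------------------------------
# initial values
# ---------------------------------------------------------------------------


def test_initial_values_km_tail_and_median():
    null = ca.ModelDesign()
    # KM: event at 1 of 2 at risk -> tail 0.5 -> logit(0.5) = 0
    cohort = [ca.SurvivalRecord(1.0, 1), ca.SurvivalRecord(2.0, 0)]
    init = ca.initial_values(cohort, null)
    assert init.beta[0] == pytest.approx(0.0, abs=1e-12)

    # all events at e -> conditional median e -> gamma0 = 1
    all_events = [ca.SurvivalRecord(math.e, 1) for _ in range(5)]
    init2 = ca.initial_values(all_events, null)
    assert init2.gamma[0] == pytest.approx(1.0, abs=1e-12)


def test_initial_values_require_events():
    with pytest.raises(ValueError, match="cannot initialize"):
        ca.initial_values([ca.SurvivalRecord(1.0, 0)], ca.ModelDesign())


def test_multistart_agrees_with_single_start(paper80_cohort, paper80_design):
    """Fits from the KM start and from jittered restarts reach the same
    maximized log-likelihood."""
    records = paper80_cohort.records
    single = ca.fit(records, paper80_design, n_restarts=0, seed=0)
    multi = ca.fit(records, paper80_design, n_restarts=3, seed=0)
    assert multi.loglik == pytest.approx(single.loglik, abs=1e-4)
    assert multi.loglik >= single.loglik - 1e-9


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_fit_requires_events():
    cohort = [ca.SurvivalRecord(1.0, 0) for _ in range(10)]
    with pytest.raises(ValueError):
        ca.fit(cohort, ca.ModelDesign())


def test_fit_recovers_generative_parameters(paper80_cohort, paper80_fit):
    truth = {
        ("logistic", "intercept"): -0.715,
        ("location", "intercept"): 2.249,
        ("location", "high"): -1.022,
        ("scale", "intercept"): -0.545,
    }
    for (part, term), value in truth.items():
        est = paper80_fit.estimate(part, term)
        se = paper80_fit.se(part, term)
        assert abs(est - value) < 2 * se, (part, term, est, se)
    assert paper80_fit.converged
    assert paper80_fit.loglik == pytest.approx(
        -ca.neg_log_likelihood(
            paper80_cohort.records, paper80_fit.params, paper80_fit.design
        ),
        abs=1e-8,
    )


def test_fit_beats_grid_search_oracle():
    cohort = random_cohort(80, seed=3)
    null = ca.ModelDesign()
    result = ca.fit(cohort, null, seed=3)
    theta_hat = result.params.pack()
    rng = np.random.default_rng(1)
    for _ in range(100):
        theta = theta_hat + rng.normal(0, 0.3, size=3)
        nll = ca.neg_log_likelihood(cohort, ca.MixtureParams.unpack(theta, null), null)
        assert -nll <= result.loglik + 1e-9


def test_aic_definition(paper80_fit):
    assert paper80_fit.aic == pytest.approx(
        2 * paper80_fit.k - 2 * paper80_fit.loglik, abs=1e-10
    )


def test_aft_acceleration_shifts_location_intercept(paper80_cohort, paper80_design):
    """Multiplying all times by c shifts the fitted location intercept by
    ln c and leaves the logistic and scale estimates unchanged."""
    records = paper80_cohort.records
    c = 2.5
    scaled = [
        ca.SurvivalRecord(r.time * c, r.event, dict(r.covariates)) for r in records
    ]
    base = ca.fit(records, paper80_design, seed=0)
    shifted = ca.fit(scaled, paper80_design, seed=0)
    assert shifted.estimate("location") - base.estimate("location") == pytest.approx(
        math.log(c), abs=0.02
    )
    assert shifted.estimate("logistic") == pytest.approx(
        base.estimate("logistic"), abs=0.02
    )
    assert shifted.estimate("scale") == pytest.approx(base.estimate("scale"), abs=0.02)
    assert shifted.estimate("location", "high") == pytest.approx(
        base.estimate("location", "high"), abs=0.02
    )


# ---------------------------------------------------------------------------
# Wald / CI / LRT / median
# ---------------------------------------------------------------------------


def _fit_with(estimates, ses, design=None, loglik=-100.0, n=100, key="k"):
    design = design or ca.ModelDesign(location_terms=("high",))
    k = design.n_params
    cov = np.diag(np.asarray(ses, dtype=float) ** 2)
    return MixtureFit(
        params=ca.MixtureParams.unpack(np.asarray(estimates, dtype=float), design),
        design=design,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        covariance=cov,
        standard_errors=np.asarray(ses, dtype=float),
        converged=True,
        n=n,
        n_events=n // 2,
        data_key=key,
    )


def test_wald_reproduces_published_p_value():
    se = 0.645 / 1.96  # back-computed from the printed CI half-width
    f = _fit_with([0.0, 2.249, -1.022, 0.0], [1.0, 1.0, se, 1.0])
    z, p = ca.wald_test(f, "location", "high")
    assert round(p, 3) == 0.002


def test_wald_trivial_cases():
    f = _fit_with([0.0, 0.0, 1.959964 * 2.0, 0.0], [1.0, 1.0, 2.0, 1.0])
    _, p_zero = ca.wald_test(f, "logistic", "intercept")
    assert p_zero == pytest.approx(1.0)
    _, p_crit = ca.wald_test(f, "location", "high")
    assert p_crit == pytest.approx(0.05, abs=1e-4)


def test_confidence_interval_values():
    f = _fit_with([0.0, 1.0, -1.022, 0.0], [1.0, 2.0, 0.329, 1.0])
    lo, hi = ca.confidence_interval(f, "logistic", "intercept")
    assert (lo, hi) == pytest.approx((-1.959964, 1.959964))
    lo, hi = ca.confidence_interval(f, "location", "high")
    assert (lo, hi) == pytest.approx((-1.667, -0.377), abs=1e-3)
    z75 = stats.norm.ppf(0.75)
    lo, hi = ca.confidence_interval(f, "location", "intercept", level=0.5)
    assert (lo, hi) == pytest.approx((1 - 2 * z75, 1 + 2 * z75))
    with pytest.raises(ValueError):
        ca.confidence_interval(f, "logistic", "intercept", level=1.5)


def test_lrt_self_and_chi_square_quantile():
    f = _fit_with([0.0, 0.0, 0.0, 0.0], [1.0] * 4)
    stat, df, p = ca.likelihood_ratio_test(f, f)
    assert stat == 0.0 and p == 1.0

    null = _fit_with([0.0, 0.0, 0.0], [1.0] * 3, design=ca.ModelDesign(),
                     loglik=-100.0)
    full = _fit_with([0.0, 0.0, 0.0, 0.0], [1.0] * 4, loglik=-100.0 + 3.841 / 2)
    stat, df, p = ca.likelihood_ratio_test(full, null)
    assert df == 1
    assert p == pytest.approx(0.05, abs=1e-3)


def test_lrt_rejects_non_nested_or_different_data():
    a = _fit_with([0.0] * 4, [1.0] * 4,
                  design=ca.ModelDesign(location_terms=("a",)))
    b = _fit_with([0.0] * 4, [1.0] * 4,
                  design=ca.ModelDesign(location_terms=("b",)))
    with pytest.raises(ValueError, match="nested"):
        ca.likelihood_ratio_test(a, b)
    null = _fit_with([0.0] * 3, [1.0] * 3, design=ca.ModelDesign(), key="other")
    with pytest.raises(ValueError, match="different record sets"):
        ca.likelihood_ratio_test(a, null)


def test_median_event_time_closed_form_and_root():
    design = ca.ModelDesign(location_terms=("high",))
    params = ca.MixtureParams([0.0], [2.249, -1.022], [-0.545])
    assert ca.median_event_time(
        {"high": 0}, ca.MixtureParams([0.0], [0.0], [0.0]), ca.ModelDesign()
    ) == pytest.approx(1.0)
    med_high = ca.median_event_time({"high": 1}, params, design)
    assert round(med_high, 2) == 3.41

    mu, sigma = 1.3, 0.8
    root = sopt.brentq(
        lambda t: ca.loglogistic_survival(t, mu, sigma) - 0.5, 1e-6, 1e6, xtol=1e-12
    )
    assert math.exp(mu) == pytest.approx(root, abs=1e-8)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def test_select_model_tie_break_and_aic(paper80_cohort):
    records = paper80_cohort.records
    d = ca.ModelDesign(location_terms=("high",))
    best, table = ca.select_model(records, [d, d], seed=0)
    assert best.design == d
    assert (table["status"] == "ok").all()
    # identical candidates: first wins, AIC matches definition
    for _, row in table.iterrows():
        assert row["aic"] == pytest.approx(2 * row["k"] - 2 * row["loglik"], abs=1e-8)


def test_select_model_requires_two_candidates(paper80_cohort):
    with pytest.raises(ValueError):
        ca.select_model(paper80_cohort.records, [ca.ModelDesign()])


def test_select_model_prefers_true_location_design():
    """With the effect only in the location part, the location-only design
    should win the AIC ranking in most replicates."""
    designs = ca.single_covariate_designs("high")
    target = ca.ModelDesign(location_terms=("high",))
    wins = 0
    n_rep = 20
    for s in range(n_rep):
        cfg = ca.paper80_config(
            n=2000, seed=300 + s, location={"intercept": 2.249, "high": -1.0}
        )
        out = ca.generate_cohort(cfg)
        best, _ = ca.select_model(out.records, designs, seed=s)
        wins += best.design == target
    assert wins > n_rep / 2, f"location-only design won only {wins}/{n_rep}"
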