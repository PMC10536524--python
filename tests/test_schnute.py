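"""Schnute growth model: identities, derivatives, fitting, plateaus, S:R."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoseed.schnute import (ElongationSeries, SchnuteParams, aer,
                                detect_final_length, elongation_rates,
                                fit_final_length_parabola, fit_schnute,
                                predict_length, shoot_root_ratio)
from thermoseed.simulate import simulate_rate_points  # noqa: F401 (fixtures)
from thermoseed.thermal import BetaParams, beta_value

param_strategy = st.builds(
    SchnuteParams,
    a=st.floats(0.005, 0.3),
    b=st.one_of(st.floats(-2.0, -0.05), st.floats(0.05, 2.0),
                st.just(0.0)),
    y1=st.floats(0.5, 5.0),
    y2=st.floats(8.0, 60.0),
    tau1=st.just(0.0),
    tau2=st.floats(50.0, 700.0),
)


@settings(max_examples=100, derandomize=True)
@given(param_strategy)
def test_reference_time_identities(p):
    """y(tau1) = y1 and y(tau2) = y2 for every valid parameter set."""
    assert predict_length(p, p.tau1) == pytest.approx(p.y1, rel=1e-10)
    assert predict_length(p, p.tau2) == pytest.approx(p.y2, rel=1e-10)


@settings(max_examples=100, derandomize=True)
@given(param_strategy)
def test_trajectory_monotone_for_growth(p):
    """With a > 0 and y2 > y1 the predicted length never decreases."""
    t = np.linspace(p.tau1, p.tau2, 200)
    y = predict_length(p, t)
    assert np.all(np.diff(y) >= -1e-9 * max(1.0, p.y2))


def test_predict_matches_high_precision_oracle():
    """Closed form at t = 56 agrees with a 50-digit symbolic evaluation."""
    p = SchnuteParams(a=0.05, b=0.5, y1=2.0, y2=30.0, tau1=0.0, tau2=112.0)
    a, b, y1, y2, tau2, t = [sympy.Rational(x) for x in
                             ("1/20", "1/2", 2, 30, 112, 56)]
    u = y1 ** b + (y2 ** b - y1 ** b) * (1 - sympy.exp(-a * t)) / (
        1 - sympy.exp(-a * tau2))
    expected = float((u ** (1 / b)).evalf(50))
    assert predict_length(p, 56.0) == pytest.approx(expected, rel=1e-12)


def test_gompertz_limit_matches_small_b():
    """|b| below the switch threshold reproduces the analytic b->0 limit."""
    base = dict(a=0.04, y1=1.5, y2=25.0, tau1=0.0, tau2=112.0)
    p0 = SchnuteParams(b=0.0, **base)
    p_small = SchnuteParams(b=1e-9, **base)
    t = np.linspace(0, 112, 50)
    fr = np.expm1(-0.04 * t) / np.expm1(-0.04 * 112)
    gompertz = 1.5 * np.exp(np.log(25 / 1.5) * fr)
    np.testing.assert_allclose(predict_length(p0, t), gompertz, rtol=1e-12)
    np.testing.assert_allclose(predict_length(p_small, t), gompertz,
                               rtol=1e-6)


@pytest.mark.parametrize("b", [-0.8, 0.0, 0.3, 0.5, 1.5])
def test_analytic_aer_matches_central_differences(b):
    """Analytic dy/dt agrees with central differences to 1e-6 relative."""
    p = SchnuteParams(a=0.05, b=b, y1=2.0, y2=30.0, tau1=0.0, tau2=112.0)
    t = np.linspace(1.0, 111.0, 1000)
    h = 1e-4
    numeric = (predict_length(p, t + h) - predict_length(p, t - h)) / (2 * h)
    analytic = aer(p, t)
    np.testing.assert_allclose(analytic, numeric, rtol=1e-6)


@settings(max_examples=60, derandomize=True)
@given(a=st.floats(0.01, 0.15), b=st.floats(0.05, 0.9),
       y1=st.floats(0.5, 3.0), y2=st.floats(10.0, 40.0))
def test_rer_max_closed_form_with_interior_inflection(a, b, y1, y2):
    """At an interior inflection with 0 < b < 1, RER_max = a / (1 - b)."""
    p = SchnuteParams(a=a, b=b, y1=y1, y2=y2, tau1=0.0, tau2=900.0)
    rates = elongation_rates(p)
    if rates.inflection_found:
        assert rates.rer_max == pytest.approx(a / (1.0 - b), abs=1e-9)
        assert rates.rer_max == pytest.approx(
            rates.aer_max / rates.length_at_t_star, rel=1e-12)


def test_no_inflection_when_b_at_least_one():
    """b >= 1 has no interior inflection; MER sits at the window start."""
    p = SchnuteParams(a=0.05, b=1.5, y1=2.0, y2=30.0, tau1=0.0, tau2=112.0)
    rates = elongation_rates(p)
    assert not rates.inflection_found
    assert rates.t_star == p.tau1


def test_zero_width_window_rejected():
    p = SchnuteParams(a=0.05, b=0.5, y1=2.0, y2=30.0, tau1=0.0, tau2=112.0)
    with pytest.raises(ValueError):
        elongation_rates(p, window=(10.0, 10.0))


def _series(t, y):
    return ElongationSeries("X", 1, "radicle", 25.0, 25.0, t, y)


def test_noiseless_fit_recovers_parameters():
    """A noiseless 15-point series is recovered to 1e-6 relative error."""
    t = np.linspace(0, 112, 15)
    truth = SchnuteParams(a=0.04, b=0.3, y1=1.5, y2=25.0, tau1=0.0,
                          tau2=112.0)
    fit = fit_schnute(_series(t, predict_length(truth, t)))
    assert fit.converged
    for name in ("a", "b", "y1", "y2"):
        assert getattr(fit.params, name) == pytest.approx(
            getattr(truth, name), rel=1e-6)


def test_noisy_fit_rate_constant_median_error():
    """Gaussian noise sigma = 0.3 mm: median |a_hat - a| / a below 20%."""
    t = np.linspace(0, 112, 15)
    truth = SchnuteParams(a=0.04, b=0.3, y1=1.5, y2=25.0, tau1=0.0,
                          tau2=112.0)
    y0 = predict_length(truth, t)
    rng = np.random.default_rng(5)
    errs = []
    for _ in range(200):
        y = np.maximum(y0 + rng.normal(0.0, 0.3, t.size), 0.0)
        fit = fit_schnute(_series(t, y))
        if fit.converged:
            errs.append(abs(fit.params.a - truth.a) / truth.a)
    assert len(errs) >= 190
    assert np.median(errs) < 0.20


def test_too_few_points_is_a_refusal():
    t = np.array([0.0, 8.0, 16.0, 24.0])
    with pytest.raises(ValueError, match="at least 5"):
        fit_schnute(_series(t, np.array([1.0, 2.0, 3.0, 4.0])))


def test_constant_series_returns_failure_record():
    """A no-growth trajectory yields a flagged record, not an exception."""
    t = np.linspace(0, 112, 15)
    fit = fit_schnute(_series(t, np.full(15, 3.0)))
    assert not fit.converged
    assert fit.params is None
    assert "no growth" in fit.message


def test_plateau_detection_cases():
    t = np.arange(6, dtype=float)
    confirmed = _series(t, np.array([5.0, 12.0, 18.0, 19.8, 20.0, 20.1]))
    rec = detect_final_length(confirmed, rel_tol=0.02)
    assert rec.plateau_confirmed and rec.plateau_start_index == 3
    assert rec.final_length == pytest.approx(20.1)

    growing = _series(t, 10.0 * 1.05 ** t)  # 5% per step, never settles
    assert not detect_final_length(growing, rel_tol=0.02).plateau_confirmed

    flat = _series(t, np.full(6, 7.5))
    rec = detect_final_length(flat, rel_tol=0.02)
    assert rec.plateau_confirmed and rec.plateau_start_index == 0


def test_shoot_root_ratio_values_and_undefined():
    assert shoot_root_ratio(10.0, 20.0).sr == pytest.approx(0.5)
    assert shoot_root_ratio(7.3, 7.3).sr == pytest.approx(1.0)
    und = shoot_root_ratio(5.0, 0.0)
    assert not und.defined and np.isnan(und.sr)
    with pytest.raises(ValueError):
        shoot_root_ratio(-1.0, 2.0)


def test_shoot_root_ratio_mean_tracks_truth():
    """n = 30 noisy seedlings with a true H:R final-length ratio of 0.8."""
    rng = np.random.default_rng(11)
    radicle = 20.0 + rng.normal(0.0, 0.3, 30)
    hypocotyl = 0.8 * 20.0 + rng.normal(0.0, 0.3, 30)
    srs = [shoot_root_ratio(h, r).sr for h, r in zip(hypocotyl, radicle)]
    assert np.mean(srs) == pytest.approx(0.8, abs=0.05)


def test_parabola_exact_recovery_and_collinear_flag():
    temps = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
    exact = 28.0 - 0.06 * (temps - 17.5) ** 2
    fit = fit_final_length_parabola(list(zip(temps, exact)))
    assert fit.vertex_temperature == pytest.approx(17.5, abs=1e-9)
    assert fit.concave

    line = fit_final_length_parabola(list(zip(temps, 2.0 * temps + 1.0)))
    assert not line.concave

    with pytest.raises(ValueError):
        fit_final_length_parabola([(5.0, 1.0), (5.0, 1.1), (5.0, 0.9)])


def test_parabola_vertex_from_unimodal_truth():
    """Final lengths from a hump-shaped (Beta) truth peaking at 17 degC,
    noise sigma = 1 mm: the fitted vertex lands in [15, 20] degC in >= 90%
    of 200 seeded runs."""
    temps = np.array([5.0, 9.6, 14.3, 19.2, 25.0, 30.0, 34.2])
    truth = BetaParams(mr=30.0, topt=17.0, delta=1.0, tmin=0.0, tmax=45.0)
    mean_len = beta_value(truth, temps)
    rng = np.random.default_rng(7)
    hits = 0
    for _ in range(200):
        lengths = mean_len + rng.normal(0.0, 1.0, temps.size)
        fit = fit_final_length_parabola(list(zip(temps, lengths)))
        hits += 15.0 <= fit.vertex_temperature <= 20.0
    assert hits >= 180
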