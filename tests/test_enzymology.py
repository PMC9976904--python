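"""Enzymology curve-model and fit tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agmotif import enzymology as enz
from agmotif.io_formats import ValidationError


# --- progress curves -----------------------------------------------------

def test_exponential_progress_exact_recovery():
    t = np.arange(0, 91, 3.0)
    y = 0.8 * (1 - np.exp(-0.05 * t))
    fit = enz.fit_progress_curve(t, y)
    assert fit.amplitude == pytest.approx(0.8, abs=1e-8)
    assert fit.k_obs == pytest.approx(0.05, abs=1e-8)
    assert fit.initial_rate == pytest.approx(0.04, abs=1e-8)


def test_flat_zero_signal():
    t = np.arange(0, 10.0)
    fit = enz.fit_progress_curve(t, np.zeros_like(t))
    assert fit.amplitude == 0.0 and fit.initial_rate == 0.0


def test_linear_initial_mode():
    t = np.arange(0, 20.0)
    fit = enz.fit_progress_curve(t, 0.03 * t, mode="linear_initial",
                                 linear_window=5)
    assert fit.initial_rate == pytest.approx(0.03, abs=1e-12)


def test_progress_noisy_recovery_within_5pct():
    rng = np.random.default_rng(17)
    t = np.arange(0, 91, 3.0)
    errs = []
    for _ in range(100):
        y = 0.8 * (1 - np.exp(-0.05 * t)) * (1 + 0.02 * rng.standard_normal(t.size))
        errs.append(abs(enz.fit_progress_curve(t, y).amplitude - 0.8) / 0.8)
    assert np.median(errs) < 0.05


def test_progress_requires_increasing_time():
    with pytest.raises(ValidationError):
        enz.fit_progress_curve([0, 2, 1, 3], [0, 0.1, 0.2, 0.3])


# --- Hill fits -----------------------------------------------------------

def test_hill_exact_recovery_to_1e6():
    c = 2.0 * np.logspace(-1.5, 1.5, 8)
    y = 1.0 * c ** 2 / (2.0 ** 2 + c ** 2)
    fit = enz.hill_fit(c, y)
    assert fit.y_max == pytest.approx(1.0, abs=1e-6)
    assert fit.k_half == pytest.approx(2.0, abs=1e-6)
    assert fit.h == pytest.approx(2.0, abs=1e-6)


def test_hill_prediction_at_k_half_is_half_max():
    rng = np.random.default_rng(23)
    c = np.logspace(-1, 1.5, 9)
    y = 0.9 * c ** 1.6 / (3.0 ** 1.6 + c ** 1.6) + 0.01 * rng.standard_normal(9)
    fit = enz.hill_fit(c, y)
    assert fit.predict(fit.k_half) == pytest.approx(fit.y_max / 2, rel=1e-9)


def test_hill_h1_equals_hyperbolic_binding():
    # with h = 1 the Hill form reduces to y_max*c/(K + c); compare against a
    # direct hyperbolic least-squares fit as oracle
    from scipy.optimize import curve_fit
    c = np.logspace(-1.2, 1.5, 10)
    y = 0.7 * c / (1.5 + c)
    fit = enz.hill_fit(c, y)
    popt, _ = curve_fit(lambda cc, ym, k: ym * cc / (k + cc), c, y,
                        p0=[0.7, 1.0])
    assert fit.h == pytest.approx(1.0, abs=1e-5)
    assert fit.k_half == pytest.approx(popt[1], rel=1e-4)
    assert fit.y_max == pytest.approx(popt[0], rel=1e-4)


def test_hill_input_validation():
    with pytest.raises(ValidationError):
        enz.hill_fit([-1, 1, 2, 3, 4], [0, 0.1, 0.2, 0.3, 0.4])
    with pytest.raises(ValidationError):
        enz.hill_fit([1, 2, 3, 4, 5], [0.5] * 5)
    with pytest.raises(ValidationError):
        enz.hill_fit([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])


# --- decay, ATPase, FRET -------------------------------------------------

def test_decay_half_life():
    t = np.arange(0, 61, 2.0)
    fit = enz.exp_decay_fit(t, np.exp(-0.1 * t))
    assert fit.rate == pytest.approx(0.1, abs=1e-9)
    assert fit.half_life == pytest.approx(np.log(2) / 0.1, abs=1e-8)


def test_decay_constant_signal_flagged():
    with pytest.warns(UserWarning, match="constant"):
        fit = enz.exp_decay_fit([0, 1, 2, 3], [2.0, 2.0, 2.0, 2.0])
    assert fit.rate == 0.0 and np.isinf(fit.half_life)


def test_decay_noisy_recovery_within_5pct():
    rng = np.random.default_rng(19)
    t = np.arange(0, 61, 2.0)
    errs = []
    for _ in range(50):
        y = np.exp(-0.1 * t) * (1 + 0.02 * rng.standard_normal(t.size))
        errs.append(abs(enz.exp_decay_fit(t, y).rate - 0.1) / 0.1)
    assert np.median(errs) < 0.05


def test_atpase_rate_conversion():
    t = np.arange(0, 10.5, 0.5)
    assert enz.atpase_rate(t, 0.9 - 0.062 * t) == pytest.approx(0.1, abs=1e-12)
    assert enz.atpase_rate(t, np.full_like(t, 0.9)) == pytest.approx(0.0)


def test_atpase_increasing_trace_warns_signed():
    t = np.arange(0, 5.0)
    with pytest.warns(UserWarning, match="increases"):
        rate = enz.atpase_rate(t, 0.1 + 0.062 * t)
    assert rate == pytest.approx(-0.1, abs=1e-12)


@pytest.mark.parametrize("f565,f665,expected", [(1, 1, 0.5), (1, 0, 0.0),
                                                (0, 1, 1.0)])
def test_fret_efficiency(f565, f665, expected):
    assert enz.fret_efficiency(f565, f665) == pytest.approx(expected)


def test_fret_both_zero_errors():
    with pytest.raises(ValidationError):
        enz.fret_efficiency(0, 0)


# --- mixing (subunit poisoning) ------------------------------------------

def test_noncooperative_line():
    assert enz.mixing_model(0.25) == pytest.approx(0.75)


def test_poisoned_n1_equals_noncooperative():
    f = np.linspace(0, 1, 21)
    np.testing.assert_allclose(enz.mixing_model(f, "poisoned_n", 1),
                               enz.mixing_model(f, "noncooperative"))


@pytest.mark.parametrize("n_true", [1, 2, 3, 5])
def test_mixing_fit_recovers_n(n_true):
    f = np.linspace(0, 1, 11)
    res = enz.fit_mixing(f, (1 - f) ** n_true)
    assert res["n_hat"] == n_true


def test_noncooperative_is_upper_envelope():
    f = np.linspace(0.05, 0.95, 19)
    line = enz.mixing_model(f, "noncooperative")
    for n in range(2, 7):
        assert np.all(enz.mixing_model(f, "poisoned_n", n) < line)


# --- AUC buoyancy --------------------------------------------------------

def test_vbar_limits_and_worked_value():
    assert enz.vbar_complex(0, 46000, 0.73, 10000, 0.53) == pytest.approx(0.53)
    assert enz.vbar_complex(1, 1000, 0.73, 1000, 0.53) == pytest.approx(0.63)
    assert enz.vbar_complex(10 ** 6, 46000, 0.73, 10000, 0.53) == pytest.approx(
        0.73, abs=1e-4)


@given(st.integers(0, 50), st.floats(0.4, 0.9), st.floats(0.4, 0.9))
@settings(deadline=None, derandomize=True)
def test_vbar_bounded_and_monotone(n, vp, vr):
    v_n = enz.vbar_complex(n, 46000, vp, 10000, vr)
    v_n1 = enz.vbar_complex(n + 1, 46000, vp, 10000, vr)
    lo, hi = min(vp, vr), max(vp, vr)
    assert lo - 1e-12 <= v_n <= hi + 1e-12
    # adding protein copies moves vbar toward the protein value
    assert abs(v_n1 - vp) <= abs(v_n - vp) + 1e-12


# --- reporter rates ------------------------------------------------------

def test_reporter_max_slope_piecewise():
    # slope 1 for t<10, then 5 for 10<=t<15, then flat
    t = np.arange(0, 25.0)
    y = np.piecewise(t, [t < 10, (t >= 10) & (t < 15), t >= 15],
                     [lambda x: x, lambda x: 10 + 5 * (x - 10), 35.0])
    assert enz.reporter_max_slope(t, y, window_points=5) == pytest.approx(5.0)


def test_reporter_linear_trace_any_window():
    t = np.arange(0, 20.0)
    for w in (3, 5, 8):
        assert enz.reporter_max_slope(t, 2 * t + 1, window_points=w) == \
            pytest.approx(2.0, abs=1e-12)


def test_reporter_decreasing_trace_warns():
    t = np.arange(0, 10.0)
    with pytest.warns(UserWarning, match="non-positive"):
        assert enz.reporter_max_slope(t, -t) <= 0


def test_normalize_to_reference():
    rates = enz.normalize_to_reference({"CAA": 4.0, "SL": 8.0}, "CAA")
    assert rates == {"CAA": 1.0, "SL": 2.0}
    with pytest.raises(ValidationError):
        enz.normalize_to_reference({"A": 1.0}, "B")


def test_cell_reporter_rate():
    assert enz.cell_reporter_rate([2, 4, 6], [2, 2, 2], [1, 2, 3]) == \
        pytest.approx(1.0)
    assert enz.cell_reporter_rate([5, 5, 5], [1, 1, 1], [1, 2, 3]) == \
        pytest.approx(0.0)
    rng = np.random.default_rng(29)
    t = np.array([1.0, 2.0, 3.0])
    fl = (0.7 * t + 0.2) * 2.0 + rng.normal(0, 1e-6, 3)
    k = enz.cell_reporter_rate(fl, np.full(3, 2.0), t)
    assert k == pytest.approx(0.7, abs=1e-4)
    with pytest.raises(ValidationError):
        enz.cell_reporter_rate([1, 2], [1, 0], [1, 2])


# --- cellular mRNA concentration -----------------------------------------

def test_mrna_concentration_below_1uM():
    c = enz.mrna_concentration(300000, 2425)
    assert c == pytest.approx(2.05e-7, rel=1e-2)  # N/(N_A*V) by hand
    assert c < 1e-6
    assert enz.mrna_concentration(0, 2425) == 0.0
    assert enz.mrna_concentration(600000, 2425) == pytest.approx(2 * c)
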