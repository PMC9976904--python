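"""Curve models for the in-vitro helicase assays.

Covers the fluorescence-based duplex-unwinding progress curve (single
exponential, or an early linear fit for the initial rate), the Hill
equation for cooperative titrations, single-exponential decay half-lives,
the NADH-coupled ATPase rate (1 NADH oxidised per ATP regenerated), the
relative-FRET readout, the wt/inactive-mutant subunit mixing (poisoning)
model, the partial-specific-volume equation for RNA:protein complexes in
analytical ultracentrifugation, luciferase reporter translation rates, and
the total cellular mRNA concentration estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro
from scipy.optimize import curve_fit

from .io_formats import ValidationError
from .stats_core import ols_fit

#: absorbance per mM NADH at 340 nm (machine/condition specific default)
EPSILON_NADH_MM = 0.62


@dataclass
class ProgressFit:
    """Single-exponential unwinding fit F(t) = A*(1 - exp(-k_obs*t))."""

    amplitude: float      # total fraction unwound
    k_obs: float          # per minute
    initial_rate: float   # A * k_obs, fraction per minute
    rss: float
    converged: bool = True


@dataclass
class HillFit:
    """Hill-equation fit y = y_max * c**h / (k_half**h + c**h)."""

    y_max: float
    k_half: float
    h: float
    se_y_max: float
    se_k_half: float
    se_h: float
    rss: float

    def predict(self, conc):
        c = np.asarray(conc, dtype=float)
        return self.y_max * c ** self.h / (self.k_half ** self.h + c ** self.h)


@dataclass
class DecayFit:
    """Single-exponential decay y = A*exp(-rate*t); half-life = ln2/rate."""

    amplitude: float
    rate: float
    half_life: float
    rss: float
    flagged: bool = False


def fit_progress_curve(time, signal, mode: str = "exponential",
                       linear_window: int = 5) -> ProgressFit:
    """Fit an unwinding progress curve.

    ``mode='exponential'`` fits F(t) = A*(1 - exp(-k_obs*t)) and reports the
    initial rate A*k_obs; ``mode='linear_initial'`` fits an OLS line to the
    first ``linear_window`` points and reports its slope as the initial
    rate.  Time must be strictly increasing.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape:
        raise ValidationError("time and signal must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time must be strictly increasing")
    if mode == "linear_initial":
        if t.size < 2:
            raise ValidationError("linear mode needs >= 2 points")
        w = min(linear_window, t.size)
        fit = ols_fit(t[:w], y[:w])
        return ProgressFit(amplitude=float("nan"), k_obs=float("nan"),
                           initial_rate=fit.slope, rss=fit.rss)
    if mode != "exponential":
        raise ValidationError(f"unknown mode {mode!r}")
    if t.size < 4:
        raise ValidationError("exponential mode needs >= 4 points")
    y_max = float(y.max())
    if y_max <= 0:  # flat/zero trace: no unwinding
        return ProgressFit(amplitude=0.0, k_obs=0.0, initial_rate=0.0,
                           rss=float((y ** 2).sum()))
    k0 = _halftime_rate_guess(t, y, y_max)
    model = lambda tt, a, k: a * (1.0 - np.exp(-k * tt))
    try:
        popt, _ = curve_fit(model, t, y, p0=[y_max, k0],
                            bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
        converged = True
    except RuntimeError:
        popt, converged = np.array([y_max, k0]), False
    a, k = float(popt[0]), float(popt[1])
    rss = float(((y - model(t, a, k)) ** 2).sum())
    if not converged:
        warnings.warn(f"progress-curve fit did not converge (rss={rss:.3g})",
                      stacklevel=2)
    return ProgressFit(amplitude=a, k_obs=k, initial_rate=a * k, rss=rss,
                       converged=converged)


def _halftime_rate_guess(t, y, y_max) -> float:
    above = np.nonzero(y >= 0.5 * y_max)[0]
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else (t[-1] or 1.0)
    return np.log(2.0) / t_half


def hill_fit(conc, response) -> HillFit:
    """Fit the Hill equation to a titration.

    Initialisation: y_max = max(response), k_half from the concentration at
    half-max by interpolation, h = 1; bounds h in (0, 6], k_half within the
    tested concentration range x [0.01, 100].  Requires >= 5 distinct
    non-negative concentrations and non-constant responses.
    """
    c = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.any(c < 0):
        raise ValidationError("negative concentration")
    if np.unique(c).size < 5:
        raise ValidationError("need >= 5 distinct concentrations")
    if np.ptp(y) == 0:
        raise ValidationError("all responses equal; nothing to fit")
    y_max0 = float(y.max())
    k0 = _half_max_interp(c, y, y_max0)
    pos = c[c > 0]
    lo_k, hi_k = pos.min() * 0.01, pos.max() * 100.0
    k0 = float(np.clip(k0, lo_k, hi_k))

    def model(cc, y_max, k_half, h):
        cc = np.asarray(cc, dtype=float)
        out = np.zeros_like(cc)
        nz = cc > 0
        out[nz] = y_max * cc[nz] ** h / (k_half ** h + cc[nz] ** h)
        return out

    popt, pcov = curve_fit(model, c, y, p0=[y_max0, k0, 1.0],
                           bounds=([0, lo_k, 1e-6], [np.inf, hi_k, 6.0]),
                           maxfev=20000)
    se = np.sqrt(np.diag(pcov))
    rss = float(((y - model(c, *popt)) ** 2).sum())
    return HillFit(y_max=float(popt[0]), k_half=float(popt[1]), h=float(popt[2]),
                   se_y_max=float(se[0]), se_k_half=float(se[1]),
                   se_h=float(se[2]), rss=rss)


def _half_max_interp(c, y, y_max) -> float:
    order = np.argsort(c)
    cs, ys = c[order], y[order]
    half = y_max / 2.0
    above = np.nonzero(ys >= half)[0]
    if above.size == 0 or above[0] == 0:
        return float(cs[max(len(cs) // 2 - 1, 0)])
    i = above[0]
    y0, y1 = ys[i - 1], ys[i]
    frac = (half - y0) / (y1 - y0) if y1 != y0 else 0.5
    return float(cs[i - 1] + frac * (cs[i] - cs[i - 1]))


def exp_decay_fit(time, signal) -> DecayFit:
    """Fit y = A*exp(-rate*t); half-life = ln2/rate.

    A constant trace yields rate 0 (infinite half-life) and is flagged with
    a warning rather than an error.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape or t.size < 3:
        raise ValidationError("need matched time/signal with >= 3 points")
    if np.ptp(y) == 0:
        warnings.warn("constant signal: decay rate 0", stacklevel=2)
        return DecayFit(amplitude=float(y[0]), rate=0.0,
                        half_life=float("inf"), rss=0.0, flagged=True)
    a0 = float(y.max())
    k0 = _halftime_rate_guess(t, a0 - y, float((a0 - y).max()))
    model = lambda tt, a, k: a * np.exp(-k * tt)
    popt, _ = curve_fit(model, t, y, p0=[a0, k0],
                        bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
    a, k = float(popt[0]), float(popt[1])
    rss = float(((y - model(t, a, k)) ** 2).sum())
    half_life = np.log(2.0) / k if k > 0 else float("inf")
    return DecayFit(amplitude=a, rate=k, half_life=half_life, rss=rss)


def atpase_rate(time, a340, epsilon_nadh: float = EPSILON_NADH_MM) -> float:
    """ATP hydrolysis rate from an NADH-coupled A340 trace.

    NADH oxidation (1:1 with ATP regeneration) makes the A340 trace fall;
    the rate is -slope/epsilon in mM NADH (== mM ATP) per time unit.  An
    increasing trace gives a signed (negative) rate with a warning.
    """
    fit = ols_fit(np.asarray(time, dtype=float), np.asarray(a340, dtype=float))
    if fit.slope > 0:
        warnings.warn("A340 trace increases; returning signed rate",
                      stacklevel=2)
    return -fit.slope / epsilon_nadh


def fret_efficiency(f_565, f_665) -> float:
    """Relative FRET = F_665 / (F_565 + F_665) from corrected intensities."""
    if f_565 < 0 or f_665 < 0:
        raise ValidationError("negative fluorescence intensity")
    total = f_565 + f_665
    if total == 0:
        raise ValidationError("both channels zero")
    return f_665 / total


def correct_spectrum(spectrum, cy5_only, wavelengths, donor_peak_nm: float = 565.0):
    """Spectral preprocessing for FRET: acceptor-bleed subtraction + donor norm.

    Subtracts the Cy5-only emission recorded under donor excitation, then
    normalises to the (corrected) Cy3 donor peak at ``donor_peak_nm``.
    """
    spec = np.asarray(spectrum, dtype=float) - np.asarray(cy5_only, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    peak = spec[np.argmin(np.abs(wl - donor_peak_nm))]
    if peak <= 0:
        raise ValidationError("non-positive donor peak after correction")
    return spec / peak


def mixing_model(f_inactive, model: str = "noncooperative", n: int = 1):
    """Expected relative activity of wt/inactive subunit mixtures.

    ``noncooperative``: activity = 1 - f (the x + y = 1 line expected for a
    monomer or a multimer without subunit cooperativity).  ``poisoned_n``:
    all n subunits of a complex must be active, activity = (1 - f)**n; a
    single inactive subunit poisons its complex.
    """
    f = np.asarray(f_inactive, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValidationError("f_inactive must lie in [0, 1]")
    if model == "noncooperative":
        out = 1.0 - f
    elif model == "poisoned_n":
        if n < 1:
            raise ValidationError("n must be >= 1")
        out = (1.0 - f) ** n
    else:
        raise ValidationError(f"unknown mixing model {model!r}")
    return float(out) if out.ndim == 0 else out


def fit_mixing(f_inactive, rel_activity, n_max: int = 8) -> dict:
    """Select the subunit-poisoning order n by least squares.

    Evaluates activity = (1 - f)**n for n = 1..n_max (n = 1 is the
    noncooperative line) and returns the best n with the per-model residual
    sums of squares.
    """
    f = np.asarray(f_inactive, dtype=float)
    y = np.asarray(rel_activity, dtype=float)
    if f.shape != y.shape or f.size < 3:
        raise ValidationError("need matched series with >= 3 points")
    sse = {n: float(((y - mixing_model(f, "poisoned_n", n)) ** 2).sum())
           for n in range(1, n_max + 1)}
    n_hat = min(sse, key=lambda n: (sse[n], n))
    return {"n_hat": n_hat,
            "model": "noncooperative" if n_hat == 1 else "poisoned_n",
            "sse": sse}


def vbar_complex(n: int, m_protein: float, vbar_protein: float,
                 m_rna: float, vbar_rna: float) -> float:
    """Partial specific volume of an (protein)_n : RNA complex (mL/g).

    Mass-weighted mean: (n*M_P*v_P + M_R*v_R) / (n*M_P + M_R).  n = 0
    returns the RNA value; large n tends to the protein value.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if m_protein <= 0 or m_rna <= 0:
        raise ValidationError("masses must be positive")
    for v in (vbar_protein, vbar_rna):
        if not 0 < v < 1:
            raise ValidationError("partial specific volumes must lie in (0, 1)")
    return (n * m_protein * vbar_protein + m_rna * vbar_rna) / (n * m_protein + m_rna)


def reporter_max_slope(time, luminescence, window_points: int = 5) -> float:
    """Maximum translation rate as the steepest sliding-window OLS slope.

    Windows of ``window_points`` consecutive readings are fitted by OLS and
    the maximum slope returned.  A non-positive maximum (decreasing trace)
    is reported with a warning.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(luminescence, dtype=float)
    if t.shape != y.shape or t.size < window_points:
        raise ValidationError(f"need >= {window_points} matched readings")
    slopes = [ols_fit(t[i:i + window_points], y[i:i + window_points]).slope
              for i in range(t.size - window_points + 1)]
    best = float(max(slopes))
    if best <= 0:
        warnings.warn("maximum slope is non-positive", stacklevel=2)
    return best


def normalize_to_reference(rates: dict[str, float], reference_id: str) -> dict[str, float]:
    """Scale rates so the reference reporter maps to exactly 1."""
    if reference_id not in rates:
        raise ValidationError(f"reference {reference_id!r} not in rates")
    ref = rates[reference_id]
    if ref == 0:
        raise ValidationError("reference rate is zero")
    return {k: v / ref for k, v in rates.items()}


def cell_reporter_rate(fl, rl, time) -> float:
    """Apparent translation rate in cells: OLS slope of FL/RL against time."""
    fl = np.asarray(fl, dtype=float)
    rl = np.asarray(rl, dtype=float)
    t = np.asarray(time, dtype=float)
    if not (fl.shape == rl.shape == t.shape):
        raise ValidationError("FL, RL and time must have equal length")
    if np.any(rl == 0):
        raise ValidationError("RL is zero at a time point")
    return ols_fit(t, fl / rl).slope


def mrna_concentration(copies: float, cell_volume_um3: float) -> float:
    """Total cellular mRNA concentration in mol/L.

    copies / (N_A * V) with the cell volume converted from um^3
    (1 um^3 = 1e-15 L).
    """
    if copies < 0 or cell_volume_um3 <= 0:
        raise ValidationError("copies must be >= 0 and volume > 0")
    return copies / (Avogadro * cell_volume_um3 * 1e-15)
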