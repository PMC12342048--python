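"""Enzyme kinetics: progress-curve kcat/Km and Morrison tight-binding Ki fits.

Two models are implemented:

* a single-exponential substrate-depletion progress curve,
  ``P = 1 - exp(-[E] * t * kcat/Km)``, valid when substrate concentration is
  far below Km so depletion is first-order with rate constant [E]*kcat/Km;
* the Morrison equation for tight-binding inhibitors,
  ``vi/v0 = 1 - (Et + I + Ki - sqrt((Et + I + Ki)^2 - 4*Et*I)) / (2*Et)``,
  which does not assume free inhibitor ≈ total inhibitor and therefore stays
  valid when Ki is comparable to the enzyme concentration.

All concentrations are handled in molar units internally; fits use ordinary
nonlinear least squares (scipy) with standard errors from the covariance of
the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "ProgressCurve",
    "InhibitionSeries",
    "StandardCurve",
    "progress_fraction",
    "morrison_velocity",
    "fit_progress_kcat_km",
    "fit_morrison_ki",
    "interpolate_standard_curve",
    "ProgressCurveFitter",
    "MorrisonInhibitionFitter",
]


@dataclass(frozen=True)
class ProgressCurve:
    """Fraction of substrate cleaved over time at a fixed enzyme concentration."""

    enzyme_conc: float  # molar
    times: np.ndarray  # seconds, ascending
    fraction_cleaved: np.ndarray  # P in [0, 1] (raw values up to 1.05 tolerated)
    replicate: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        fractions = np.asarray(self.fraction_cleaved, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fraction_cleaved", fractions)
        if self.enzyme_conc < 0:
            raise ValueError("enzyme_conc must be >= 0")
        if times.ndim != 1 or times.shape != fractions.shape:
            raise ValueError("times and fraction_cleaved must be 1-D and same length")
        if np.any(times < 0) or np.any(np.diff(times) < 0):
            raise ValueError("times must be non-negative and ascending")
        if np.any(fractions < -0.05) or np.any(fractions > 1.05):
            raise ValueError("fractions outside [-0.05, 1.05]")


@dataclass(frozen=True)
class InhibitionSeries:
    """Fractional velocities vi/v0 over an inhibitor titration at fixed enzyme."""

    Et: float  # total active enzyme, molar
    inhibitor_concs: np.ndarray  # molar, >= 0
    vi_over_v0: np.ndarray

    def __post_init__(self) -> None:
        concs = np.asarray(self.inhibitor_concs, dtype=float)
        v = np.asarray(self.vi_over_v0, dtype=float)
        object.__setattr__(self, "inhibitor_concs", concs)
        object.__setattr__(self, "vi_over_v0", v)
        if self.Et <= 0:
            raise ValueError("Et must be > 0")
        if concs.shape != v.shape or concs.ndim != 1:
            raise ValueError("inhibitor_concs and vi_over_v0 must be 1-D and same length")
        if np.any(concs < 0):
            raise ValueError("inhibitor concentrations must be >= 0")
        if np.any(v < 0) or np.any(v > 1.05):
            raise ValueError("vi/v0 outside [0, 1.05]")


@dataclass(frozen=True)
class StandardCurve:
    """Monotone analyte-concentration vs signal calibration (e.g. ELISA A492)."""

    concentrations: np.ndarray  # ascending
    signals: np.ndarray  # monotone (either direction)

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "signals", sig)
        if conc.size < 2 or conc.shape != sig.shape:
            raise ValueError("need >= 2 matching standard points")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("standard concentrations must be strictly ascending")
        diffs = np.diff(sig)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("standard signals must be strictly monotone")


def progress_fraction(E: float, t, k: float):
    """Fraction cleaved P = 1 - exp(-E * t * k); scalar or vectorized in t."""
    t = np.asarray(t, dtype=float)
    if E < 0 or k < 0 or np.any(t < 0):
        raise ValueError("E, t and k must be >= 0")
    out = 1.0 - np.exp(-E * t * k)
    return float(out) if out.ndim == 0 else out


def morrison_velocity(Et: float, I, Ki: float):
    """Morrison tight-binding fractional velocity vi/v0 in [0, 1].

    The discriminant is clamped at zero to guard against floating-point
    negatives when I is close to Et and Ki is very small.
    """
    I = np.asarray(I, dtype=float)
    if Et <= 0:
        raise ValueError("Et must be > 0 (use the classical 1/(1+I/Ki) limit instead)")
    if Ki < 0 or np.any(I < 0):
        raise ValueError("I and Ki must be >= 0")
    s = Et + I + Ki
    disc = np.clip(s * s - 4.0 * Et * I, 0.0, None)
    out = np.clip(1.0 - (s - np.sqrt(disc)) / (2.0 * Et), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


class ProgressCurveFitter(BaseEstimator):
    """Single-parameter least-squares fit of kcat/Km to progress curves.

    Replicates and curves at different enzyme concentrations are pooled into
    one residual vector. After :meth:`fit`: ``kcat_km_`` (M^-1 s^-1) and
    ``kcat_km_se_`` (standard error from the fit covariance).
    """

    def __init__(self, initial_guess: float | None = None):
        self.initial_guess = initial_guess

    def fit(self, curves: list[ProgressCurve]) -> "ProgressCurveFitter":
        if not curves:
            raise ValueError("need at least one progress curve")
        E = np.concatenate([np.full(c.times.size, c.enzyme_conc) for c in curves])
        t = np.concatenate([c.times for c in curves])
        P = np.clip(np.concatenate([c.fraction_cleaved for c in curves]), 0.0, 1.0)
        if t.size < 3:
            raise ValueError("need >= 3 points")
        positive = (P > 0) & (P < 1) & (E * t > 0)
        if not np.any(P > 0):
            raise ValueError("non-identifiable: no conversion observed (P all zero)")
        if self.initial_guess is not None:
            k0 = float(self.initial_guess)
        elif np.any(positive):
            k0 = float(np.median(-np.log1p(-P[positive]) / (E[positive] * t[positive])))
        else:  # all points fully converted; any large k fits
            k0 = 1.0 / float(np.min(E[E * t > 0] * t[E * t > 0]))

        popt, pcov = curve_fit(
            lambda x, k: 1.0 - np.exp(-E * t * k), t, P, p0=[k0], maxfev=10000
        )
        self.kcat_km_ = float(popt[0])
        self.kcat_km_se_ = float(np.sqrt(pcov[0, 0]))
        self.n_points_ = int(t.size)
        return self


class MorrisonInhibitionFitter(BaseEstimator):
    """Least-squares Morrison fit of the apparent Ki at known total enzyme.

    By default vi/v0 is assumed pre-normalized and only Ki is fitted; with
    ``fit_v0=True`` an uninhibited-velocity scale is floated as a nuisance
    parameter (for raw velocity inputs). After :meth:`fit`: ``ki_``,
    ``ki_se_`` and, when floated, ``v0_``.
    """

    def __init__(self, fit_v0: bool = False):
        self.fit_v0 = fit_v0

    def fit(self, series: InhibitionSeries) -> "MorrisonInhibitionFitter":
        I, v, Et = series.inhibitor_concs, series.vi_over_v0, series.Et
        if I.size < 4 or not np.any(I == 0):
            raise ValueError("need >= 4 inhibitor concentrations including 0")
        if np.all(v > 0.95):
            raise ValueError("non-identifiable: no inhibition observed (vi/v0 ~ 1)")
        # initial guess: inhibitor giving half-inhibition, corrected for titration
        half = float(np.interp(0.5, v[np.argsort(v)], I[np.argsort(v)]))
        ki0 = max(half - Et / 2.0, Et * 1e-3)
        if self.fit_v0:
            model = lambda x, ki, v0: v0 * morrison_velocity(Et, x, ki)
            p0, bounds = [ki0, 1.0], ([0.0, 0.0], [np.inf, np.inf])
        else:
            model = lambda x, ki: morrison_velocity(Et, x, ki)
            p0, bounds = [ki0], ([0.0], [np.inf])
        popt, pcov = curve_fit(
            model, I, v, p0=p0, bounds=bounds, x_scale=np.maximum(p0, 1e-15),
            maxfev=10000,
        )
        self.ki_ = float(popt[0])
        self.ki_se_ = float(np.sqrt(pcov[0, 0]))
        if self.fit_v0:
            self.v0_ = float(popt[1])
        return self


def fit_progress_kcat_km(curves: list[ProgressCurve]) -> tuple[float, float]:
    """kcat/Km estimate (M^-1 s^-1) and its standard error; replicates pooled."""
    fitter = ProgressCurveFitter().fit(curves)
    return fitter.kcat_km_, fitter.kcat_km_se_


def fit_morrison_ki(series: InhibitionSeries, fit_v0: bool = False) -> tuple[float, float]:
    """Apparent Ki estimate (molar) and its standard error."""
    fitter = MorrisonInhibitionFitter(fit_v0=fit_v0).fit(series)
    return fitter.ki_, fitter.ki_se_


def interpolate_standard_curve(
    curve: StandardCurve, signals
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate concentrations for measured signals.

    Returns (concentrations, in_range mask). Signals outside the standard
    range are flagged (mask False) and returned as NaN rather than
    extrapolated.
    """
    signals = np.atleast_1d(np.asarray(signals, dtype=float))
    sig, conc = curve.signals, curve.concentrations
    if sig[0] > sig[-1]:  # np.interp needs ascending x
        sig, conc = sig[::-1], conc[::-1]
    lo, hi = sig[0], sig[-1]
    in_range = (signals >= lo) & (signals <= hi)
    out = np.where(in_range, np.interp(signals, sig, conc), np.nan)
    return out, in_range
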