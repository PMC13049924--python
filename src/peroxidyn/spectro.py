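"""Spectroscopic curve fits: tight binding, thermal melting, biphasic kinetics.

Three nonlinear models cover the optical assays around the dynamics pipeline:

* Morrison's quadratic tight-binding equation for difference-titration data,
  valid when the enzyme concentration is comparable to K_d:

      ΔA(S) = ΔA_max · [(E + S + K_d) − √((E + S + K_d)² − 4·E·S)] / (2E)

* a Boltzmann sigmoid for thermal denaturation, with the melting temperature
  T_m at the half-transition:

      θ(T) = lower + (upper − lower) / (1 + exp((T_m − T) / slope))

* a two-summed-exponential decay for stopped-flow traces, reported fast-first:

      A(t) = offset + A₁·exp(−k₁·t) + A₂·exp(−k₂·t)

All fits use bounded least squares with a small multi-start (3 data-driven
initializations) and report Jacobian-based standard errors. The kinetic
isotope effect is the ratio of protonated to deuterated rate constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import CurveFitError


def morrison_curve(s, damax, kd, enzyme):
    """Tight-binding fractional-saturation signal at substrate concentration s."""
    s = np.asarray(s, dtype=float)
    term = enzyme + s + kd
    disc = np.clip(term**2 - 4.0 * enzyme * s, 0.0, None)
    return damax * (term - np.sqrt(disc)) / (2.0 * enzyme)


def boltzmann_curve(t, lower, upper, tm, slope):
    """Sigmoidal melting transition; signal at temperature t."""
    t = np.asarray(t, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp((tm - t) / slope))


def double_exponential_curve(t, offset, a1, k1, a2, k2):
    """Biphasic decay; amplitudes may carry either sign (rise or decay)."""
    t = np.asarray(t, dtype=float)
    return offset + a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _multi_start_fit(model, x, y, starts, bounds):
    best = None
    errors = []
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            errors.append(str(exc))
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise CurveFitError(
            "fit did not converge from any start; " + "; ".join(errors[:3])
        )
    return best


def _stderr(pcov: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.diag(pcov))


class MorrisonBinding(RegressorMixin, BaseEstimator):
    """Tight-binding titration fit (K_d, ΔA_max) at known enzyme concentration.

    Parameters
    ----------
    enzyme_concentration : float
        Total enzyme concentration E in the same units as the substrate axis
        (μM throughout this package).

    Attributes
    ----------
    kd_, damax_ : fitted dissociation constant (μM) and signal amplitude.
    stderr_kd_, stderr_damax_ : Jacobian-based standard errors.
    rss_ : residual sum of squares at the optimum.
    """

    def __init__(self, enzyme_concentration: float = 1.0):
        self.enzyme_concentration = enzyme_concentration

    def fit(self, X, y):
        s = np.asarray(X, dtype=float).ravel()
        da = np.asarray(y, dtype=float).ravel()
        if s.size < 4:
            raise ValueError("need at least 4 titration points")
        if np.any(s < 0) or self.enzyme_concentration <= 0:
            raise ValueError("concentrations must be nonnegative, enzyme positive")
        e = float(self.enzyme_concentration)

        def model(x, damax, kd):
            return morrison_curve(x, damax, kd, e)

        damax0 = float(da.max()) if da.max() > 0 else 1.0
        span = float(s.max()) if s.max() > 0 else 1.0
        starts = [
            (damax0, max(span / 10.0, 1e-6)),
            (damax0, max(span / 2.0, 1e-6)),
            (damax0 * 1.2, max(e, 1e-6)),
        ]
        bounds = ([0.0, 1e-12], [np.inf, np.inf])
        popt, pcov, rss = _multi_start_fit(model, s, da, starts, bounds)
        self.damax_, self.kd_ = float(popt[0]), float(popt[1])
        self.stderr_damax_, self.stderr_kd_ = (float(v) for v in _stderr(pcov))
        self.rss_ = rss
        return self

    def predict(self, X):
        check_is_fitted(self, "kd_")
        return morrison_curve(
            np.asarray(X, dtype=float).ravel(),
            self.damax_, self.kd_, self.enzyme_concentration,
        )


class BoltzmannMelting(RegressorMixin, BaseEstimator):
    """Boltzmann sigmoid fit of a thermal denaturation curve.

    Attributes
    ----------
    tm_ : melting temperature at the half-transition, °C.
    slope_ : transition width parameter, °C.
    lower_, upper_ : pre- and post-transition baselines (signal units).
    stderr_tm_ : standard error of T_m.
    """

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        signal = np.asarray(y, dtype=float).ravel()
        if t.size < 5:
            raise ValueError("need at least 5 temperature points")
        lo, hi = float(signal.min()), float(signal.max())
        if hi - lo <= 1e-12:
            raise CurveFitError("no transition present in the scanned range")
        mid = (lo + hi) / 2.0
        tm0 = float(t[np.argmin(np.abs(signal - mid))])
        width = float(t.max() - t.min())
        starts = [
            (lo, hi, tm0, width / 20.0),
            (lo, hi, tm0, width / 5.0),
            (lo, hi, float(np.median(t)), width / 10.0),
        ]
        bounds = (
            [-np.inf, -np.inf, float(t.min()), 1e-6],
            [np.inf, np.inf, float(t.max()), np.inf],
        )
        popt, pcov, rss = _multi_start_fit(boltzmann_curve, t, signal, starts, bounds)
        self.lower_, self.upper_, self.tm_, self.slope_ = (float(v) for v in popt)
        err = _stderr(pcov)
        self.stderr_tm_ = float(err[2])
        self.rss_ = rss
        return self

    def predict(self, X):
        check_is_fitted(self, "tm_")
        return boltzmann_curve(
            np.asarray(X, dtype=float).ravel(),
            self.lower_, self.upper_, self.tm_, self.slope_,
        )


class DoubleExponentialDecay(RegressorMixin, BaseEstimator):
    """Two-summed-exponential fit of a stopped-flow trace.

    Time zero is the first sample of the trace (no dead-time model).

    Attributes
    ----------
    rates_ : (k_fast, k_slow) in s⁻¹, fast first.
    amplitudes_ : amplitudes matching ``rates_`` order.
    offset_ : asymptotic absorbance.
    stderr_rates_ : standard errors matching ``rates_`` order.
    """

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        a = np.asarray(y, dtype=float).ravel()
        if t.size < 10:
            raise ValueError("need at least 10 trace points")
        order = np.argsort(t)
        t, a = t[order] - t[order][0], a[order]
        span = float(t.max())
        if span <= 0:
            raise ValueError("trace has zero duration")
        amp0 = float(a[0] - a[-1])
        if abs(amp0) < 1e-12:
            amp0 = float(np.ptp(a)) or 1.0
        offset0 = float(a[-1])
        k0 = 3.0 / span  # a decay mostly complete over the trace
        starts = [
            (offset0, amp0 * 0.5, 10.0 * k0, amp0 * 0.5, k0),
            (offset0, amp0 * 0.8, 30.0 * k0, amp0 * 0.2, 2.0 * k0),
            (offset0, amp0 * 0.2, 100.0 * k0, amp0 * 0.8, 5.0 * k0),
        ]
        bounds = (
            [-np.inf, -np.inf, 1e-9, -np.inf, 1e-9],
            [np.inf, np.inf, np.inf, np.inf, np.inf],
        )
        popt, pcov, rss = _multi_start_fit(
            double_exponential_curve, t, a, starts, bounds
        )
        offset, a1, k1, a2, k2 = popt
        err = _stderr(pcov)
        phases = sorted(
            [(k1, a1, err[2]), (k2, a2, err[4])], key=lambda p: -p[0]
        )
        self.offset_ = float(offset)
        self.rates_ = (float(phases[0][0]), float(phases[1][0]))
        self.amplitudes_ = (float(phases[0][1]), float(phases[1][1]))
        self.stderr_rates_ = (float(phases[0][2]), float(phases[1][2]))
        self.rss_ = rss
        if abs(self.rates_[0] - self.rates_[1]) <= 0.01 * self.rates_[0]:
            warnings.warn(
                "rate constants collapsed within 1%; consider a "
                "single-exponential model",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    def predict(self, X):
        check_is_fitted(self, "rates_")
        return double_exponential_curve(
            np.asarray(X, dtype=float).ravel(),
            self.offset_,
            self.amplitudes_[0], self.rates_[0],
            self.amplitudes_[1], self.rates_[1],
        )


@dataclass(frozen=True)
class KineticIsotopeEffect:
    """Ratio of protonated to deuterated rate constants."""

    ratio: float
    rounded: int


def kinetic_isotope_effect(
    k_protonated: float, k_deuterated: float
) -> KineticIsotopeEffect:
    """KIE = k_H / k_D, reported raw and rounded to the nearest integer."""
    if k_protonated <= 0 or k_deuterated <= 0:
        raise ValueError("rate constants must be positive")
    ratio = k_protonated / k_deuterated
    return KineticIsotopeEffect(ratio=ratio, rounded=int(round(ratio)))


# -- thin functional wrappers -------------------------------------------------

def fit_morrison_kd(
    substrate_concentrations, delta_absorbance, enzyme_concentration
) -> MorrisonBinding:
    return MorrisonBinding(enzyme_concentration).fit(
        substrate_concentrations, delta_absorbance
    )


def fit_boltzmann_tm(temperatures, signal) -> BoltzmannMelting:
    return BoltzmannMelting().fit(temperatures, signal)


def fit_double_exponential(times, absorbance) -> DoubleExponentialDecay:
    return DoubleExponentialDecay().fit(times, absorbance)
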