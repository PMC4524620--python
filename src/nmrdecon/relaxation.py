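"""Region integration, mono-exponential T2 fitting and linewidth
conversion, plus the linear signal-loss correction for long experiments.

The T2 experiment integrates a spectral window at a series of echo
delays; the integrals decay as ``A * exp(-t / T2)``.  For a Lorentzian
line the transverse relaxation time maps to the full width at half
maximum as ``FWHM (Hz) = 1 / (pi * T2)``.

When sample degradation (e.g. precipitation) bleeds signal over a long
acquisition series, identical short-delay reference experiments run
before and after the series quantify the loss; assuming a constant loss
rate, each intervening integral acquired at normalised run-time fraction
``f`` is divided by ``1 - f * (1 - end_ref / start_ref)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import RegionError, RelaxationFitError
from .spectrum_io import Spectrum, select_region


@dataclass
class DecaySeries:
    """Region integrals as a function of total delay time.

    ``runtime_fractions`` (optional) give each point's position in the
    wall-clock acquisition order on [0, 1], needed for the linear loss
    correction when experiments were run in randomised order; when absent
    the stored order is assumed chronological and evenly spaced.
    """

    delays_s: np.ndarray
    integrals: np.ndarray
    runtime_fractions: np.ndarray | None = None
    correction_applied: bool = False

    def __post_init__(self) -> None:
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        self.integrals = np.asarray(self.integrals, dtype=float)
        if self.delays_s.size != self.integrals.size:
            raise ValueError("delays and integrals must have equal length")
        if np.any(self.delays_s <= 0):
            raise ValueError("delays must be strictly positive")
        if np.unique(self.delays_s).size != self.delays_s.size:
            raise ValueError("delays must be unique within one series")
        if self.runtime_fractions is not None:
            self.runtime_fractions = np.asarray(self.runtime_fractions,
                                                dtype=float)
            if self.runtime_fractions.size != self.delays_s.size:
                raise ValueError("runtime_fractions length mismatch")
            if np.any((self.runtime_fractions < 0)
                      | (self.runtime_fractions > 1)):
                raise ValueError("runtime_fractions must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.delays_s.size)


@dataclass
class T2Fit:
    """Result of a mono-exponential decay fit."""

    t2_s: float
    amplitude: float
    t2_stderr_s: float
    ci95_s: tuple[float, float]

    @property
    def fwhm_hz(self) -> float:
        return t2_linewidth(self.t2_s)


def integrate_region(spectrum: Spectrum, left: float, right: float) -> float:
    """Trapezoidal integral (intensity * ppm) over the ppm window."""
    sub = select_region(spectrum, left, right)
    # the ppm axis decreases left to right; integrate on the ascending axis
    return float(np.trapezoid(sub.intensities[::-1], sub.ppm_axis[::-1]))


def fit_exponential_decay(series: DecaySeries) -> T2Fit:
    """Least-squares fit of A * exp(-t / T2) to a decay series."""
    if series.n < 3:
        raise ValueError("need at least 3 distinct delays to fit a decay")
    t = series.delays_s
    y = series.integrals

    # log-linear starting point from the positive integrals; the sign of
    # the slope is kept so non-decaying data converges to a negative T2
    # (rejected below) instead of drifting to the flat T2 -> inf plateau
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        t2_0 = -1.0 / slope if slope != 0 else float(t.max())
        a_0 = math.exp(intercept)
    else:
        t2_0, a_0 = float(t.max()), float(np.abs(y).max())

    def decay(tt, a, t2):
        return a * np.exp(-tt / t2)

    try:
        popt, pcov = curve_fit(decay, t, y, p0=(a_0, t2_0), maxfev=10000)
    except RuntimeError as exc:
        raise RelaxationFitError(f"decay fit failed to converge: {exc}") from exc
    a_fit, t2_fit = popt
    if t2_fit <= 0 or a_fit <= 0:
        raise RelaxationFitError(
            f"series is not a positive decay (A = {a_fit:.3g}, "
            f"T2 = {t2_fit:.3g} s)")
    t2_err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else math.nan
    ci = (t2_fit - 1.96 * t2_err, t2_fit + 1.96 * t2_err)
    return T2Fit(t2_s=float(t2_fit), amplitude=float(a_fit),
                 t2_stderr_s=t2_err, ci95_s=ci)


def t2_linewidth(t2_s: float) -> float:
    """Lorentzian FWHM (Hz) of a line relaxing with T2: 1 / (pi * T2)."""
    if not t2_s > 0:
        raise ValueError("T2 must be positive")
    return 1.0 / (math.pi * t2_s)


def linewidth_to_t2(fwhm_hz: float) -> float:
    """Inverse of :func:`t2_linewidth`."""
    if not fwhm_hz > 0:
        raise ValueError("FWHM must be positive")
    return 1.0 / (math.pi * fwhm_hz)


def linear_loss_correction(series: DecaySeries, start_ref: float,
                           end_ref: float) -> DecaySeries:
    """Divide each integral by the linearly interpolated loss factor.

    ``start_ref`` and ``end_ref`` are the reference integrals measured
    before and after the series; a point at run-time fraction ``f`` is
    divided by ``1 - f * (1 - end_ref / start_ref)``.
    """
    if not start_ref > 0:
        raise ValueError("start_ref must be positive")
    if end_ref > start_ref:
        warnings.warn("end reference exceeds start reference (signal gain); "
                      "applying the correction anyway", stacklevel=2)
    if series.runtime_fractions is not None:
        f = series.runtime_fractions
    else:
        f = np.linspace(0.0, 1.0, series.n)
    factor = 1.0 - f * (1.0 - end_ref / start_ref)
    return DecaySeries(series.delays_s.copy(), series.integrals / factor,
                       runtime_fractions=f.copy(), correction_applied=True)


def read_decay_csv(path) -> DecaySeries:
    """Read a decay series from CSV columns delay_s, integral
    [, runtime_fraction]."""
    df = pd.read_csv(path)
    for col in ("delay_s", "integral"):
        if col not in df.columns:
            raise RegionError(f"{path}: missing required column {col!r}")
    frac = df["runtime_fraction"].to_numpy() \
        if "runtime_fraction" in df.columns else None
    return DecaySeries(df["delay_s"].to_numpy(), df["integral"].to_numpy(),
                       runtime_fractions=frac)


def write_decay_csv(series: DecaySeries, path) -> None:
    data = {"delay_s": series.delays_s, "integral": series.integrals}
    if series.runtime_fractions is not None:
        data["runtime_fraction"] = series.runtime_fractions
    pd.DataFrame(data).to_csv(path, index=False)
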