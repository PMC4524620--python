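"""Bounded nonlinear least squares of a peak model to a spectrum.

Minimisation uses the lmfit Levenberg–Marquardt driver with box bounds on
every parameter.  Model comparison uses the Bayesian information
criterion in its residual-sum-of-squares profile form

    BIC = n * ln(rss / n) + k * ln(n)

appropriate for least squares with unknown Gaussian noise variance; only
BIC differences between models fit to the same data are meaningful.
exp(dBIC / 2) approximates the posterior odds between two models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

from .baseline import DEFAULT_EDGE_FRACTION, edge_window_size
from .errors import DegenerateFitError
from .lineshape import (
    PHASE_FIXED_LIMIT_RAD,
    LorentzianPeak,
    PeakModel,
    evaluate_model,
)
from .spectrum_io import Spectrum, select_region

#: Parameter order used for flattened parameter/stderr vectors.
PARAM_NAMES = ("height", "center_ppm", "fwhm_ppm", "phase_rad")


@dataclass
class FitBounds:
    """Box bounds applied to every peak parameter: (lo, hi) pairs."""

    height: tuple[float, float]
    center: tuple[float, float]
    width: tuple[float, float]
    phase: tuple[float, float]

    @classmethod
    def from_spectrum(cls, spectrum: Spectrum, phase_mode: str = "fixed",
                      phase_limit_rad: float = PHASE_FIXED_LIMIT_RAD) -> "FitBounds":
        """Default bounds: height in (0, 3*max], center inside the region,
        width in [3*resolution, region span], phase per the phase mode."""
        scale = float(np.max(np.abs(spectrum.intensities)))
        ymax = float(spectrum.intensities.max())
        hi = 3.0 * (ymax if ymax > 0 else (scale if scale > 0 else 1.0))
        lim = phase_limit_rad if phase_mode == "fixed" else math.pi
        return cls(
            height=(1e-9 * hi, hi),
            center=(spectrum.right_ppm, spectrum.left_ppm),
            width=(3.0 * spectrum.dppm, spectrum.span_ppm),
            phase=(-lim, lim),
        )

    def clip_peak(self, peak: LorentzianPeak,
                  margin: float = 0.0) -> LorentzianPeak:
        """Clip a peak into the box; a positive ``margin`` (fraction of each
        bound range) keeps values strictly inside, which matters for
        internally generated initial guesses: the bounded Levenberg-
        Marquardt parameter transform has zero gradient exactly at a
        bound, so a guess started there could never move."""

        def clip(v, lo, hi):
            pad = margin * (hi - lo)
            return float(np.clip(v, lo + pad, hi - pad))

        return LorentzianPeak(
            height=clip(peak.height, *self.height),
            center_ppm=clip(peak.center_ppm, *self.center),
            fwhm_ppm=clip(peak.fwhm_ppm, *self.width),
            phase_rad=clip(peak.phase_rad, *self.phase),
        )

    def _pairs(self) -> tuple[tuple[float, float], ...]:
        return (self.height, self.center, self.width, self.phase)

    def contains(self, model: PeakModel, rtol: float = 1e-9) -> bool:
        for pk in model.peaks:
            vals = (pk.height, pk.center_ppm, pk.fwhm_ppm, pk.phase_rad)
            for v, (lo, hi) in zip(vals, self._pairs()):
                tol = rtol * max(abs(lo), abs(hi), 1.0)
                if v < lo - tol or v > hi + tol:
                    return False
        return True


@dataclass
class FitResult:
    """An optimised peak model with its goodness-of-fit summary."""

    model: PeakModel
    rss: float
    n_data: int
    bic: float
    param_stderr: np.ndarray  # flattened, NaN where not estimable
    converged: bool
    snr: float | None = None
    stage: str = ""

    @property
    def n_peaks(self) -> int:
        return self.model.n_peaks

    def param_values(self) -> np.ndarray:
        vals = []
        for pk in self.model.peaks:
            vals.extend((pk.height, pk.center_ppm, pk.fwhm_ppm, pk.phase_rad))
        return np.array(vals)


def bic_score(rss: float, n_data: int, n_free_params: int) -> float:
    """BIC = n * ln(rss/n) + k * ln(n); raises on a perfect interpolation."""
    if n_data <= n_free_params:
        raise ValueError(
            f"n_data ({n_data}) must exceed n_free_params ({n_free_params})"
        )
    if rss < 0:
        raise ValueError(f"rss must be non-negative, got {rss}")
    if rss == 0:
        raise DegenerateFitError(
            "rss == 0: the model interpolates the data perfectly and the "
            "BIC is undefined"
        )
    return n_data * math.log(rss / n_data) + n_free_params * math.log(n_data)


def _params_from_model(model: PeakModel, bounds: FitBounds) -> lmfit.Parameters:
    params = lmfit.Parameters()
    pairs = bounds._pairs()
    for i, pk in enumerate(model.peaks):
        vals = (pk.height, pk.center_ppm, pk.fwhm_ppm, pk.phase_rad)
        for name, v, (lo, hi) in zip(PARAM_NAMES, vals, pairs):
            params.add(f"p{i}_{name}", value=float(v), min=lo, max=hi)
    return params


def _model_from_params(params: lmfit.Parameters, template: PeakModel) -> PeakModel:
    peaks = []
    for i in range(template.n_peaks):
        peaks.append(LorentzianPeak(
            height=float(params[f"p{i}_height"].value),
            center_ppm=float(params[f"p{i}_center_ppm"].value),
            fwhm_ppm=float(params[f"p{i}_fwhm_ppm"].value),
            phase_rad=float(np.clip(params[f"p{i}_phase_rad"].value,
                                    -template.phase_limit_rad
                                    if template.phase_mode == "fixed" else -math.pi,
                                    template.phase_limit_rad
                                    if template.phase_mode == "fixed" else math.pi)),
        ))
    return PeakModel(tuple(peaks), template.phase_mode, template.phase_limit_rad)


def _residual_fn(y: np.ndarray, axis: np.ndarray, n_peaks: int):
    def residual(params: lmfit.Parameters) -> np.ndarray:
        h = np.array([params[f"p{i}_height"].value for i in range(n_peaks)])
        c = np.array([params[f"p{i}_center_ppm"].value for i in range(n_peaks)])
        w = np.array([params[f"p{i}_fwhm_ppm"].value for i in range(n_peaks)])
        ph = np.array([params[f"p{i}_phase_rad"].value for i in range(n_peaks)])
        x = 2.0 * (axis[None, :] - c[:, None]) / w[:, None]
        comp = h[:, None] * (np.cos(ph)[:, None] - x * np.sin(ph)[:, None]) / (1.0 + x * x)
        return y - comp.sum(axis=0)

    return residual


def fit_model(spectrum: Spectrum, initial: PeakModel,
              bounds: FitBounds | None = None, *,
              max_nfev: int = 2000, xtol: float = 1e-8,
              ftol: float = 1e-8) -> FitResult:
    """Fit ``initial`` to ``spectrum`` by bounded Levenberg–Marquardt.

    The returned result never has a larger rss than the initial model (the
    initial parameters are kept if the optimiser somehow ends up worse).
    An empty model is legal and simply scores the data against zero.
    """
    y = spectrum.intensities
    n = spectrum.n_points
    axis = spectrum.ppm_axis

    if initial.n_peaks == 0:
        rss = float(y @ y)
        return FitResult(model=initial, rss=rss, n_data=n,
                         bic=bic_score(rss, n, 0),
                         param_stderr=np.zeros(0), converged=True)

    if bounds is None:
        bounds = FitBounds.from_spectrum(spectrum, initial.phase_mode,
                                         initial.phase_limit_rad)
    if not bounds.contains(initial):
        raise ValueError("initial model lies outside the fit bounds")

    init_resid = y - evaluate_model(initial, axis)
    rss_init = float(init_resid @ init_resid)

    params = _params_from_model(initial, bounds)
    residual = _residual_fn(y, axis, initial.n_peaks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lmfit warns on nfev exhaustion
        out = lmfit.minimize(residual, params, method="leastsq",
                             max_nfev=max_nfev, xtol=xtol, ftol=ftol)

    fitted = _model_from_params(out.params, initial)
    fit_resid = y - evaluate_model(fitted, axis)
    rss_fit = float(fit_resid @ fit_resid)

    if rss_fit <= rss_init:
        model, rss, converged = fitted, rss_fit, bool(out.success)
        stderr = np.array([
            out.params[f"p{i}_{name}"].stderr
            if out.params[f"p{i}_{name}"].stderr is not None else np.nan
            for i in range(initial.n_peaks) for name in PARAM_NAMES
        ])
    else:  # keep the initial point: descent is part of the contract
        model, rss, converged = initial, rss_init, False
        stderr = np.full(4 * initial.n_peaks, np.nan)

    return FitResult(model=model, rss=rss, n_data=n,
                     bic=bic_score(rss, n, initial.n_free_params),
                     param_stderr=stderr, converged=converged)


def signal_to_noise(spectrum: Spectrum,
                    noise_region: tuple[float, float] | None = None,
                    edge_fraction: float = DEFAULT_EDGE_FRACTION) -> float:
    """Highest signal value divided by the RMS of a signal-free region.

    By default the noise region is the union of the two baseline edge
    windows; alternatively an explicit (left, right) ppm window may be
    given.  The region mean is removed before taking the RMS so a residual
    baseline offset does not masquerade as noise.
    """
    if noise_region is not None:
        noise = select_region(spectrum, *noise_region).intensities
    else:
        m = edge_window_size(spectrum.n_points, edge_fraction)
        y = spectrum.intensities
        noise = np.concatenate([y[:m], y[-m:]])
    rms = float(noise.std())
    if rms == 0:
        warnings.warn("noise region has zero variance; SNR is infinite",
                      stacklevel=2)
        return math.inf
    return float(spectrum.intensities.max()) / rms
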