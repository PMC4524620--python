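"""The deconvolution protocol: build, select, prune, split, refine.

The pipeline fits progressively larger multi-Lorentzian models, picks a
seed model by a local BIC rule, then refines it:

1.  *Forward build* — starting from an empty model, repeatedly place a
    new peak over the longest run of consecutive positive residuals (or,
    if that fails to help, at the single highest positive residual) and
    refit all parameters jointly, up to ``max_peaks``.
2.  *Seed selection* — the largest model whose BIC is below that of the
    model with one fewer peak.
3.  *Pruning* — delete peaks one at a time (every single deletion is
    tried per round, the best kept), continuing while the reduced model's
    BIC stays within ``plimit`` of the best BIC seen.
4.  *Splitting* — randomly split one peak into two children of the same
    summed area; keep the split when the refit BIC is the same or better,
    stop once a proposal exceeds the best BIC by more than 2.
5.  *Monte-Carlo refinement* — perturb every parameter of the incumbent
    at once (scale set by the parameter standard errors and the spectrum
    signal-to-noise) and refit; refits that beat the incumbent by more
    than 2 BIC units are flagged as new bests.

All candidates from every phase are collected in a :class:`ModelEnsemble`;
those within ``plimit`` of the best BIC form the reported set.  Models
whose BIC values differ by less than 2 should be considered equally good.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .baseline import correct_baseline
from .errors import PlacementError
from .fitting import FitBounds, FitResult, fit_model, signal_to_noise
from .lineshape import (
    PHASE_FIXED_LIMIT_RAD,
    LorentzianPeak,
    PeakModel,
    evaluate_model,
)
from .spectrum_io import Spectrum, select_region

#: Positive residuals below this fraction of the data scale are treated as
#: numerically zero during peak placement (prevents chasing optimiser
#: round-off on noiseless data; real noise sits far above this level).
POSITIVE_RESIDUAL_FLOOR = 1e-6


@dataclass
class DeconvolveOptions:
    """Knobs of the deconvolution pipeline.

    ``plimit`` plays two roles, exactly as one knob: the peak-deletion
    acceptance window and the candidate-reporting window.
    """

    max_peaks: int = 12
    plimit: float = 15.0
    phase_mode: str = "fixed"
    phase_limit_rad: float = PHASE_FIXED_LIMIT_RAD
    mc_refits: int = 10
    seed: int = 0
    region: tuple[float, float] | None = None
    apply_baseline: bool = True
    max_split_attempts: int = 20
    max_nfev: int = 2000

    def __post_init__(self) -> None:
        if self.max_peaks < 1:
            raise ValueError("max_peaks must be >= 1")
        if self.plimit < 0:
            raise ValueError("plimit must be >= 0")
        if not 0 < self.phase_limit_rad <= math.pi:
            raise ValueError("phase_limit_rad must lie in (0, pi]")


@dataclass
class ModelEnsemble:
    """Ranked candidate models from one deconvolution run."""

    candidates: list[FitResult]
    best_index: int
    plimit: float
    mc_results: list[FitResult]
    seed: int
    spectrum: Spectrum
    options: DeconvolveOptions
    incumbent_bic: float  # best BIC before Monte-Carlo refinement

    @property
    def best(self) -> FitResult:
        return self.candidates[self.best_index]

    @property
    def reported(self) -> list[FitResult]:
        """All candidates within ``plimit`` BIC units of the best model."""
        cutoff = self.best.bic + self.plimit
        return [c for c in self.candidates if c.bic <= cutoff]

    @property
    def mc_new_best(self) -> list[FitResult]:
        """Monte-Carlo refits that beat the pre-MC incumbent by > 2 BIC."""
        return [r for r in self.mc_results if r.bic < self.incumbent_bic - 2.0]


def _positive_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of maximal runs of True."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def place_next_peak(residuals: np.ndarray, axis: np.ndarray,
                    bounds: FitBounds | None = None,
                    data_scale: float | None = None) -> LorentzianPeak:
    """Initial guess for the next peak from the residual trace.

    The peak is centred on the midpoint of the longest run of consecutive
    positive residuals; ties go to the run holding the higher maximum
    residual, then to the leftmost run.  Initial width is the run length
    in ppm (clipped to the bounds) and initial height the maximum residual
    within the run.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise PlacementError("empty residual trace")
    scale = data_scale if data_scale is not None else float(np.max(np.abs(r)))
    floor = POSITIVE_RESIDUAL_FLOOR * scale
    runs = _positive_runs(r > floor)
    if not runs:
        raise PlacementError("no positive residual region to host a new peak")

    def run_key(run: tuple[int, int]):
        start, stop = run
        return (stop - start, float(r[start:stop].max()), -start)

    start, stop = max(runs, key=run_key)
    dppm = abs(axis[1] - axis[0])
    center = 0.5 * (axis[start] + axis[stop - 1])
    width = max((stop - start) * dppm, dppm)
    height = float(r[start:stop].max())
    peak = LorentzianPeak(height=height, center_ppm=float(center),
                          fwhm_ppm=float(width), phase_rad=0.0)
    return bounds.clip_peak(peak, margin=1e-3) if bounds is not None else peak


def _highest_point_peak(residuals: np.ndarray, axis: np.ndarray,
                        bounds: FitBounds,
                        data_scale: float) -> LorentzianPeak | None:
    """Fallback guess at the single highest positive residual point."""
    i = int(np.argmax(residuals))
    if residuals[i] <= POSITIVE_RESIDUAL_FLOOR * data_scale:
        return None
    dppm = abs(axis[1] - axis[0])
    return bounds.clip_peak(LorentzianPeak(
        height=float(residuals[i]), center_ppm=float(axis[i]),
        fwhm_ppm=10.0 * dppm, phase_rad=0.0), margin=1e-3)


def forward_build(spectrum: Spectrum, max_peaks: int,
                  phase_mode: str = "fixed",
                  phase_limit_rad: float = PHASE_FIXED_LIMIT_RAD,
                  bounds: FitBounds | None = None,
                  max_nfev: int = 2000) -> list[FitResult]:
    """Progressively place and jointly refit 1..max_peaks peaks.

    Returns one FitResult per model size; the list is truncated early if
    no positive residual region remains to host another peak.
    """
    if bounds is None:
        bounds = FitBounds.from_spectrum(spectrum, phase_mode, phase_limit_rad)
    y = spectrum.intensities
    axis = spectrum.ppm_axis
    scale = float(np.max(np.abs(y)))
    results: list[FitResult] = []
    prev: FitResult | None = None

    for size in range(1, max_peaks + 1):
        current_peaks = prev.model.peaks if prev is not None else ()
        resid = y - evaluate_model(
            PeakModel(current_peaks, phase_mode, phase_limit_rad), axis)
        try:
            guess = place_next_peak(resid, axis, bounds, scale)
        except PlacementError:
            break
        init = PeakModel(current_peaks + (guess,), phase_mode, phase_limit_rad)
        best = fit_model(spectrum, init, bounds, max_nfev=max_nfev)
        # The run-based guess failing to improve the BIC triggers one retry
        # at the single highest positive residual point.
        if prev is not None and best.bic >= prev.bic:
            alt = _highest_point_peak(resid, axis, bounds, scale)
            if alt is not None:
                alt_init = PeakModel(current_peaks + (alt,), phase_mode,
                                     phase_limit_rad)
                alt_fit = fit_model(spectrum, alt_init, bounds, max_nfev=max_nfev)
                if alt_fit.bic < best.bic:
                    best = alt_fit
        # Nested-model safeguard: a new peak at negligible height must not
        # fit worse than the previous model.
        if prev is not None and best.rss > prev.rss:
            tiny = bounds.clip_peak(LorentzianPeak(
                height=max(bounds.height[0], 1e-9 * scale),
                center_ppm=guess.center_ppm, fwhm_ppm=guess.fwhm_ppm))
            tiny_init = PeakModel(prev.model.peaks + (tiny,), phase_mode,
                                  phase_limit_rad)
            tiny_fit = fit_model(spectrum, tiny_init, bounds, max_nfev=max_nfev)
            if tiny_fit.rss < best.rss:
                best = tiny_fit
        best.stage = f"forward_{size}"
        results.append(best)
        prev = best
    return results


def select_seed_model(results: list[FitResult]) -> FitResult:
    """Largest model whose BIC undercuts the model with one fewer peak.

    ``results`` must be ordered by increasing model size, as produced by
    :func:`forward_build`; the smallest model qualifies by default.
    """
    if not results:
        raise ValueError("select_seed_model needs at least one fit result")
    chosen = results[0]
    for prev, cur in zip(results, results[1:]):
        if cur.bic < prev.bic:
            chosen = cur
    return chosen


def prune_peaks(seed: FitResult, spectrum: Spectrum,
                bounds: FitBounds | None = None, plimit: float = 15.0,
                max_nfev: int = 2000) -> list[FitResult]:
    """Deletion refinement: the trail of accepted reduced models.

    Per round every single-peak deletion is tried and refit; the best
    reduced model is accepted while its BIC stays within ``plimit`` of the
    best BIC seen so far.  The zero-peak model is a legal endpoint.
    """
    model = seed.model
    if bounds is None:
        bounds = FitBounds.from_spectrum(spectrum, model.phase_mode,
                                         model.phase_limit_rad)
    trail: list[FitResult] = []
    current = seed
    best_bic = seed.bic
    while current.n_peaks >= 1:
        cands = []
        for i in range(current.n_peaks):
            reduced = current.model.peaks[:i] + current.model.peaks[i + 1:]
            init = PeakModel(reduced, model.phase_mode, model.phase_limit_rad)
            cands.append(fit_model(spectrum, init, bounds, max_nfev=max_nfev))
        best_del = min(cands, key=lambda r: r.bic)
        if best_del.bic <= best_bic + plimit:
            best_del.stage = f"prune_{best_del.n_peaks}"
            trail.append(best_del)
            current = best_del
            best_bic = min(best_bic, best_del.bic)
        else:
            break
    return trail


def split_peaks(current: FitResult, spectrum: Spectrum,
                rng: np.random.Generator,
                bounds: FitBounds | None = None,
                max_attempts: int = 20,
                max_nfev: int = 2000) -> list[FitResult]:
    """Splitting refinement: the trail of accepted split models.

    A randomly chosen peak is replaced by two children at the parent
    center +/- FWHM/4, each with half the parent area (same width and
    phase), and the whole model is refit.  A proposal with the same or
    better BIC is kept; the loop stops when a proposal exceeds the best
    BIC by more than 2 (or after ``max_attempts`` proposals, a safety cap).
    """
    model = current.model
    if bounds is None:
        bounds = FitBounds.from_spectrum(spectrum, model.phase_mode,
                                         model.phase_limit_rad)
    trail: list[FitResult] = []
    best_bic = current.bic
    attempts = 0
    # at machine-precision rss further BIC comparisons are meaningless:
    # splitting a numerically perfect fit only polishes round-off
    scale = float(np.max(np.abs(spectrum.intensities)))
    rss_floor = spectrum.n_points * (1e-10 * scale) ** 2
    while (current.n_peaks >= 1 and attempts < max_attempts
           and current.rss > rss_floor):
        attempts += 1
        j = int(rng.integers(current.n_peaks))
        parent = current.model.peaks[j]
        others = current.model.peaks[:j] + current.model.peaks[j + 1:]
        children = tuple(
            bounds.clip_peak(LorentzianPeak(
                height=parent.height / 2.0,
                center_ppm=parent.center_ppm + sign * parent.fwhm_ppm / 4.0,
                fwhm_ppm=parent.fwhm_ppm,
                phase_rad=parent.phase_rad), margin=1e-3)
            for sign in (-1.0, 1.0)
        )
        init = PeakModel(others + children, model.phase_mode,
                         model.phase_limit_rad)
        prop = fit_model(spectrum, init, bounds, max_nfev=max_nfev)
        if prop.bic <= current.bic:
            prop.stage = f"split_{prop.n_peaks}"
            trail.append(prop)
            current = prop
            best_bic = min(best_bic, prop.bic)
        elif prop.bic > best_bic + 2.0:
            break
    return trail


def monte_carlo_refine(best: FitResult, spectrum: Spectrum, n_refits: int,
                       rng: np.random.Generator,
                       bounds: FitBounds | None = None,
                       snr: float | None = None,
                       max_nfev: int = 2000) -> list[FitResult]:
    """Perturb-and-refit refinement of the incumbent model.

    Each parameter is redrawn from a Gaussian centred on its fitted value
    whose width is the parameter's standard error scaled by a uniform
    random number between 0 and 200 divided by the spectrum
    signal-to-noise ratio; perturbed values are clipped to the bounds
    before refitting.  Standard errors that could not be estimated fall
    back to 1% of the parameter value.  In the infinite-SNR limit every
    refit reproduces the incumbent.
    """
    model = best.model
    if model.n_peaks == 0 or n_refits <= 0:
        return []
    if bounds is None:
        bounds = FitBounds.from_spectrum(spectrum, model.phase_mode,
                                         model.phase_limit_rad)
    if snr is None:
        snr = best.snr if best.snr is not None else signal_to_noise(spectrum)

    values = best.param_values()
    stderr = np.array(best.param_stderr, dtype=float)
    fallback = 0.01 * np.abs(values)
    stderr = np.where(np.isfinite(stderr), stderr, fallback)

    lo0 = np.array([bounds.height[0], bounds.center[0], bounds.width[0],
                    bounds.phase[0]])
    hi0 = np.array([bounds.height[1], bounds.center[1], bounds.width[1],
                    bounds.phase[1]])
    pad = 1e-3 * (hi0 - lo0)
    lo = np.tile(lo0 + pad, model.n_peaks)
    hi = np.tile(hi0 - pad, model.n_peaks)

    out: list[FitResult] = []
    for r in range(n_refits):
        u = rng.uniform(0.0, 200.0, size=values.size)
        sd = stderr * u / snr if math.isfinite(snr) else np.zeros_like(values)
        perturbed = np.clip(rng.normal(values, sd), lo, hi)
        peaks = tuple(
            LorentzianPeak(*perturbed[4 * i: 4 * i + 4])
            for i in range(model.n_peaks)
        )
        init = PeakModel(peaks, model.phase_mode, model.phase_limit_rad)
        fit = fit_model(spectrum, init, bounds, max_nfev=max_nfev)
        fit.stage = f"mc_{r}"
        out.append(fit)
    return out


def deconvolve(spectrum: Spectrum,
               options: DeconvolveOptions | None = None,
               **overrides) -> ModelEnsemble:
    """Run the full deconvolution pipeline on a spectrum.

    Keyword overrides are applied on top of ``options`` (or the defaults),
    e.g. ``deconvolve(sp, max_peaks=6, phase_mode="variable", seed=3)``.
    """
    opts = options if options is not None else DeconvolveOptions()
    if overrides:
        opts = replace(opts, **overrides)

    sp = spectrum
    if opts.region is not None:
        left, right = max(opts.region), min(opts.region)
        sp = select_region(sp, left, right)
    if opts.apply_baseline:
        sp = correct_baseline(sp)

    snr = signal_to_noise(sp)
    bounds = FitBounds.from_spectrum(sp, opts.phase_mode, opts.phase_limit_rad)
    rng = np.random.default_rng(opts.seed)

    zero = fit_model(sp, PeakModel((), opts.phase_mode, opts.phase_limit_rad),
                     bounds)
    zero.stage = "forward_0"
    candidates: list[FitResult] = [zero]

    fwd = forward_build(sp, opts.max_peaks, opts.phase_mode,
                        opts.phase_limit_rad, bounds, opts.max_nfev)
    candidates.extend(fwd)
    seed_fit = select_seed_model(fwd) if fwd else zero

    candidates.extend(prune_peaks(seed_fit, sp, bounds, opts.plimit,
                                  opts.max_nfev))
    best_so_far = min(candidates, key=lambda r: r.bic)
    candidates.extend(split_peaks(best_so_far, sp, rng, bounds,
                                  opts.max_split_attempts, opts.max_nfev))
    incumbent = min(candidates, key=lambda r: r.bic)
    mc = monte_carlo_refine(incumbent, sp, opts.mc_refits, rng, bounds, snr,
                            opts.max_nfev)
    candidates.extend(mc)

    for c in candidates:
        c.snr = snr
    best_index = int(np.argmin([c.bic for c in candidates]))
    return ModelEnsemble(candidates=candidates, best_index=best_index,
                         plimit=opts.plimit, mc_results=mc, seed=opts.seed,
                         spectrum=sp, options=opts,
                         incumbent_bic=incumbent.bic)
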