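"""Synthetic 1D NMR data: FID-route Lorentzian spectra and n-site
chemical-exchange lineshapes.

Two generators are provided.

*FID route* — each peak contributes a complex free induction decay
``a * exp(i*(2*pi*nu*t - phase - phase0)) * exp(-t / T2)`` with
``T2 = 1 / (pi * FWHM_Hz)``; the per-peak FIDs are summed, complex white
Gaussian noise is added in the time domain, and the discrete Fourier
transform's real part is returned on a ppm axis.  The phase sign in the
FID is chosen so that a fitted component phase equals the imposed offset
under the lineshape convention of :mod:`nmrdecon.lineshape`.

*Exchange route* — a single nucleus hopping among 2–4 chemical-shift
environments produces the steady-precession exchange lineshape

    I(nu) = Re[ 1^T (i*2*pi*(nu*I - diag(shifts)) + diag(R2) - K)^(-1) p ]

with ``K`` the first-order exchange rate matrix (columns summing to zero,
stationary on the populations ``p``) and ``R2`` the per-site intrinsic
transverse relaxation rates.  For two sites with total exchange rate
``k_ex`` (the sum of the forward and reverse rates) the two maxima merge
at the classic critical ratio ``k_ex / delta-nu = pi * sqrt(2) ~ 4.44``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .errors import ResolutionError
from .lineshape import LorentzianPeak, fractional_areas, PeakModel
from .spectrum_io import Spectrum

DEFAULT_FREQ_MHZ = 376.5


# ---------------------------------------------------------------------------
# FID-route simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Recipe for an FID-route synthetic spectrum.

    Defaults mirror a 19F experiment: 1 ms sampling interval, 1 s
    acquisition, 376.5 MHz resonance frequency.  When
    ``auto_spectral_width`` is true (the default) the dwell time is
    shortened as needed so that every requested peak, plus a 20% margin,
    falls inside the spectral width (1/dwell Hz); otherwise peaks outside
    the window alias and a warning is issued.
    """

    peaks: tuple[LorentzianPeak, ...] = ()
    dwell_s: float = 0.001
    acq_s: float = 1.0
    freq_mhz: float = DEFAULT_FREQ_MHZ
    zero_order_phase_rad: float = 0.0
    noise_sigma: float = 0.0
    target_snr: float | None = None
    seed: int | None = None
    auto_spectral_width: bool = True
    oversample: int = 2

    def __post_init__(self) -> None:
        self.peaks = tuple(self.peaks)
        if not self.dwell_s > 0:
            raise ValueError("dwell_s must be positive")
        if self.acq_s < self.dwell_s:
            raise ValueError("acq_s must be at least one dwell time")
        if not self.freq_mhz > 0:
            raise ValueError("freq_mhz must be positive")

    def effective_dwell_s(self) -> float:
        """Dwell time actually used, after any automatic widening.

        In the automatic path the spectral width covers every peak with 10
        linewidths of padding plus 20% (so the edge windows used by the
        baseline and SNR estimates are effectively signal-free) and is then
        oversampled, which keeps the discrete-transform deviation from an
        ideal Lorentzian far below realistic noise levels.
        """
        if not self.auto_spectral_width or not self.peaks:
            return self.dwell_s
        half_needed = max(
            abs(pk.center_ppm * self.freq_mhz) + 10.0 * pk.fwhm_ppm * self.freq_mhz
            for pk in self.peaks
        ) * 1.2
        sw_needed = 2.0 * max(half_needed, 1e-12)
        sw = max(1.0 / self.dwell_s, sw_needed) * max(int(self.oversample), 1)
        return 1.0 / sw


def draw_random_peaks(rng: np.random.Generator, max_peaks: int = 12,
                      width_mu: float = 0.5, width_sigma: float = 5.0,
                      center_mu: float = 0.0, center_sigma: float = 5.0,
                      intensity_mu: float = 1.0,
                      intensity_sigma: float = 0.6) -> list[LorentzianPeak]:
    """Draw a pseudo-random peak list.

    The peak count is uniform on {0..max_peaks}; widths and centers come
    from the stated normals (widths redrawn until positive), intensities
    from a normal redrawn until positive and then normalised to sum to 1.
    """
    n = int(rng.integers(0, max_peaks + 1))

    def positive_normal(mu: float, sigma: float) -> float:
        while True:
            v = rng.normal(mu, sigma)
            if v > 0:
                return float(v)

    widths = [positive_normal(width_mu, width_sigma) for _ in range(n)]
    centers = [float(rng.normal(center_mu, center_sigma)) for _ in range(n)]
    raw = np.array([positive_normal(intensity_mu, intensity_sigma)
                    for _ in range(n)])
    if n:
        raw = raw / raw.sum()
    return [LorentzianPeak(height=float(h), center_ppm=c, fwhm_ppm=w)
            for h, c, w in zip(raw, centers, widths)]


def simulate_fid_spectrum(spec: SimulationSpec) -> Spectrum:
    """Render a SimulationSpec to a Spectrum via summed FIDs and an FFT."""
    dwell = spec.effective_dwell_s()
    n = int(round(spec.acq_s / dwell))
    if n < 2:
        raise ValueError("acquisition window holds fewer than 2 samples")
    t = np.arange(n) * dwell
    sw = 1.0 / dwell

    fid = np.zeros(n, dtype=complex)
    for pk in spec.peaks:
        nu = pk.center_ppm * spec.freq_mhz
        if abs(nu) > sw / 2.0:
            warnings.warn(
                f"peak at {pk.center_ppm} ppm ({nu:.1f} Hz) lies outside the "
                f"spectral width {sw:.1f} Hz and will alias", stacklevel=2)
        fwhm_hz = pk.fwhm_ppm * spec.freq_mhz
        t2 = 1.0 / (math.pi * fwhm_hz)
        amp = pk.height * dwell / t2
        fid += amp * np.exp(
            1j * (2.0 * math.pi * nu * t - pk.phase_rad
                  - spec.zero_order_phase_rad)
        ) * np.exp(-t / t2)
    fid[0] *= 0.5  # half-weight first point: flat baseline after the DFT

    sigma = spec.noise_sigma
    if spec.target_snr is not None:
        if not spec.peaks:
            raise ValueError("target_snr requires at least one peak")
        clean = np.fft.fft(fid).real
        sigma = float(clean.max()) / (spec.target_snr * math.sqrt(n))
    if sigma > 0:
        rng = np.random.default_rng(spec.seed)
        fid = fid + sigma * (rng.standard_normal(n)
                             + 1j * rng.standard_normal(n))

    trace = np.fft.fftshift(np.fft.fft(fid)).real
    hz = np.fft.fftshift(np.fft.fftfreq(n, dwell))
    ppm = hz / spec.freq_mhz  # ascending
    return Spectrum(float(ppm[-1]), float(ppm[0]), trace[::-1].copy(),
                    spectrometer_freq_mhz=spec.freq_mhz)


def write_truth_json(path: str | Path, spec: SimulationSpec) -> None:
    """Sidecar ground-truth file for a simulated spectrum."""
    model = PeakModel(spec.peaks, phase_mode="variable")
    payload = {
        "peaks": [
            {"height": pk.height, "center_ppm": pk.center_ppm,
             "fwhm_ppm": pk.fwhm_ppm, "phase_rad": pk.phase_rad}
            for pk in spec.peaks
        ],
        "fractional_areas": list(map(float, fractional_areas(model))),
        "zero_order_phase_rad": spec.zero_order_phase_rad,
        "dwell_s": spec.dwell_s,
        "effective_dwell_s": spec.effective_dwell_s(),
        "acq_s": spec.acq_s,
        "freq_mhz": spec.freq_mhz,
        "noise_sigma": spec.noise_sigma,
        "target_snr": spec.target_snr,
        "seed": spec.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# n-site chemical exchange
# ---------------------------------------------------------------------------

@dataclass
class ExchangeSystem:
    """A single nucleus exchanging among n chemical-shift environments.

    ``rate_matrix[j, k]`` (j != k) is the first-order rate of the k -> j
    transition (s^-1); diagonal entries make every column sum to zero, and
    the matrix must be stationary on the populations (K @ p = 0).
    """

    shifts_hz: np.ndarray
    populations: np.ndarray
    rate_matrix: np.ndarray
    r2: np.ndarray  # per-site intrinsic transverse relaxation rate, s^-1

    def __post_init__(self) -> None:
        self.shifts_hz = np.asarray(self.shifts_hz, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = self.shifts_hz.size
        if n < 2:
            raise ValueError("an exchange system needs at least 2 sites")
        if self.populations.size != n or self.r2.size != n \
                or self.rate_matrix.shape != (n, n):
            raise ValueError("shifts, populations, r2 and rate matrix sizes "
                             "disagree")
        if np.any(self.populations < 0) or abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("populations must be non-negative and sum to 1")
        scale = max(float(np.abs(self.rate_matrix).max()), 1.0)
        if np.any(np.abs(self.rate_matrix.sum(axis=0)) > 1e-9 * scale):
            raise ValueError("rate matrix columns must sum to zero")
        if np.any(np.abs(self.rate_matrix @ self.populations) > 1e-8 * scale):
            raise ValueError("rate matrix must be stationary on the "
                             "populations (K @ p = 0)")

    @property
    def n_sites(self) -> int:
        return int(self.shifts_hz.size)

    @classmethod
    def two_site(cls, delta_hz: float, k_ex: float,
                 populations: tuple[float, float] = (0.5, 0.5),
                 r2: float | tuple[float, float] = 1.0) -> "ExchangeSystem":
        """Two sites at -delta/2 and +delta/2 with total exchange rate
        ``k_ex`` (sum of the forward and reverse rates, detailed balance)."""
        p = np.asarray(populations, dtype=float)
        p = p / p.sum()
        # detailed balance: rate 1->2 = k_ex*p2, rate 2->1 = k_ex*p1,
        # so the rates sum to k_ex and K @ p = 0.  K[j,k] = rate k -> j.
        kmat = np.array([[-k_ex * p[1], k_ex * p[0]],
                         [k_ex * p[1], -k_ex * p[0]]])
        r2v = np.full(2, r2, dtype=float) if np.isscalar(r2) \
            else np.asarray(r2, dtype=float)
        return cls(np.array([-delta_hz / 2.0, delta_hz / 2.0]), p, kmat, r2v)

    @classmethod
    def chain(cls, shifts_hz, populations, k_pair: float,
              r2: float | np.ndarray = 1.0) -> "ExchangeSystem":
        """Linear-chain topology: adjacent sites i <-> i+1 exchange with a
        pairwise total rate ``k_pair`` split by detailed balance."""
        shifts = np.asarray(shifts_hz, dtype=float)
        p = np.asarray(populations, dtype=float)
        p = p / p.sum()
        n = shifts.size
        kmat = np.zeros((n, n))
        for i in range(n - 1):
            pij = p[i] + p[i + 1]
            k_fwd = k_pair * p[i + 1] / pij   # i -> i+1
            k_bwd = k_pair * p[i] / pij       # i+1 -> i
            kmat[i + 1, i] += k_fwd
            kmat[i, i] -= k_fwd
            kmat[i, i + 1] += k_bwd
            kmat[i + 1, i + 1] -= k_bwd
        r2v = np.full(n, r2, dtype=float) if np.isscalar(r2) \
            else np.asarray(r2, dtype=float)
        return cls(shifts, p, kmat, r2v)


def default_exchange_axis(system: ExchangeSystem, n_points: int = 2 ** 14,
                          pad_linewidths: float = 20.0) -> np.ndarray:
    """Hz axis spanning the shift range plus a multiple of the broadest
    expected linewidth on each side."""
    exit_rates = -np.diag(system.rate_matrix)
    lw = float(np.max((system.r2 + exit_rates) / math.pi)) + 1e-6
    lo = float(system.shifts_hz.min()) - pad_linewidths * lw
    hi = float(system.shifts_hz.max()) + pad_linewidths * lw
    return np.linspace(lo, hi, n_points)


def exchange_lineshape(system: ExchangeSystem, axis_hz: np.ndarray) -> np.ndarray:
    """Closed-form steady-precession lineshape on a Hz axis (unnormalised)."""
    axis_hz = np.asarray(axis_hz, dtype=float)
    r2 = system.r2
    if np.all(r2 <= 0) and np.all(system.rate_matrix == 0):
        warnings.warn("zero relaxation and zero exchange: perturbing R2 by "
                      "1e-6 to avoid a singular matrix", stacklevel=2)
        r2 = r2 + 1e-6
    n = system.n_sites
    base = (np.diag(r2) - system.rate_matrix
            - 2j * math.pi * np.diag(system.shifts_hz))
    a = base[None, :, :] + (2j * math.pi * axis_hz)[:, None, None] * np.eye(n)
    sol = np.linalg.solve(a, np.broadcast_to(
        system.populations.astype(complex), (axis_hz.size, n))[..., None])
    return np.real(sol[..., 0].sum(axis=1))


def simulate_exchange_spectrum(system: ExchangeSystem,
                               axis_hz: np.ndarray | None = None,
                               freq_mhz: float = DEFAULT_FREQ_MHZ,
                               noise_sigma: float = 0.0,
                               target_snr: float | None = None,
                               seed: int | None = None,
                               normalize: bool = True) -> Spectrum:
    """Render an exchange lineshape to a Spectrum (ppm axis, left first).

    With ``normalize`` the total integral over Hz is scaled to 1.  Noise,
    when requested, is white Gaussian added in the frequency domain
    (``target_snr`` sets sigma to apex / target).
    """
    if axis_hz is None:
        axis_hz = default_exchange_axis(system)
    trace = exchange_lineshape(system, axis_hz)
    if normalize:
        trace = trace / np.trapezoid(trace, axis_hz)
    sigma = noise_sigma
    if target_snr is not None:
        sigma = float(trace.max()) / target_snr
    if sigma > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, sigma, trace.size)
    ppm = axis_hz / freq_mhz  # ascending
    return Spectrum(float(ppm[-1]), float(ppm[0]), trace[::-1].copy(),
                    spectrometer_freq_mhz=freq_mhz)


def count_maxima(trace, min_prominence: float = 1e-3) -> int:
    """Number of local maxima with prominence >= min_prominence * max."""
    y = trace.intensities if isinstance(trace, Spectrum) else np.asarray(trace)
    top = float(y.max())
    if top <= 0:
        return 0
    peaks, _ = find_peaks(y, prominence=min_prominence * top)
    return int(peaks.size)


def find_coalescence_ratio(delta_hz: float = 100.0,
                           populations: tuple[float, float] = (0.5, 0.5),
                           r2_frac: float = 1e-3,
                           n_points: int = 2 ** 14,
                           ratio_bracket: tuple[float, float] = (1.0, 8.0),
                           ratio_tol: float = 5e-3) -> float:
    """Smallest k_ex / delta-nu at which the two-site lineshape shows a
    single maximum, found by bisection on k_ex.

    ``r2_frac`` sets the intrinsic relaxation as a fraction of the shift
    difference (kept negligible by default).  Raises
    :class:`ResolutionError` if the axis cannot resolve two maxima at the
    slow-exchange end of the bracket.
    """
    axis = np.linspace(-2.0 * delta_hz, 2.0 * delta_hz, n_points)

    def n_max(ratio: float) -> int:
        system = ExchangeSystem.two_site(delta_hz, ratio * delta_hz,
                                         populations,
                                         r2=r2_frac * delta_hz)
        return count_maxima(exchange_lineshape(system, axis),
                            min_prominence=1e-10)

    lo, hi = ratio_bracket
    if n_max(lo) < 2:
        raise ResolutionError(
            f"axis of {n_points} points cannot resolve two maxima at "
            f"k_ex/delta-nu = {lo}")
    if n_max(hi) != 1:
        raise ValueError(f"upper bracket {hi} still shows two maxima")
    while hi - lo > ratio_tol:
        mid = 0.5 * (lo + hi)
        if n_max(mid) == 1:
            hi = mid
        else:
            lo = mid
    return hi
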