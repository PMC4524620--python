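"""Regenerate the packaged synthetic five-peak example spectrum.

The spectrum is built from five absorption Lorentzians specified as
(relative area %, center ppm, FWHM ppm) triplets, rendered through the
FID route at a target signal-to-noise ratio of 100 with a fixed seed,
and written in the plain-text spectrum dialect (intensities rounded to
six significant digits to keep the file small).  A ground-truth sidecar
is written alongside.

Run from the repository root:  python scripts/make_example_spectrum.py
"""

import math
from pathlib import Path

import numpy as np

from nmrdecon import (
    LorentzianPeak,
    SimulationSpec,
    Spectrum,
    simulate_fid_spectrum,
    write_spectrum_text,
    write_truth_json,
)

TRIPLETS = [
    (19.24, 3.961253, 0.6362),
    (21.0776, -5.064015, 0.4249),
    (18.31387, -5.503231, 0.8113),
    (18.63312, 3.048056, 0.6403),
    (22.73541, 1.778537, 0.7756),
]


def five_peak_spec(seed: int = 7, acq_s: float = 0.12,
                   target_snr: float = 100.0) -> SimulationSpec:
    peaks = tuple(
        LorentzianPeak(height=area / 100.0 / (0.5 * math.pi * w),
                       center_ppm=c, fwhm_ppm=w)
        for area, c, w in TRIPLETS
    )
    return SimulationSpec(peaks=peaks, acq_s=acq_s, target_snr=target_snr,
                          seed=seed)


def main() -> None:
    out = Path(__file__).resolve().parent.parent / "examples"
    out.mkdir(exist_ok=True)
    spec = five_peak_spec()
    sp = simulate_fid_spectrum(spec)
    rounded = Spectrum(sp.left_ppm, sp.right_ppm,
                       np.array([float(f"{v:.6g}") for v in sp.intensities]),
                       spectrometer_freq_mhz=sp.spectrometer_freq_mhz)
    target = out / "five_peak_synthetic.txt"
    write_spectrum_text(rounded, target)
    write_truth_json(out / "five_peak_synthetic.txt.truth.json", spec)
    print(f"wrote {target} ({rounded.n_points} points, "
          f"{rounded.left_ppm:.3f}..{rounded.right_ppm:.3f} ppm)")


if __name__ == "__main__":
    main()
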