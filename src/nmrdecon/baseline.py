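"""Two-step baseline adjustment applied before fitting.

Step 1 subtracts the mean intensity of the two spectrum edges (1/30th of
the width at each end by default) — a flat-offset removal using regions
assumed free of signal.

Step 2 compensates for the fact that step 1 also subtracted the genuine
signal tail present at the edges: it models the spectrum as a single
centered absorption Lorentzian whose height is the (post-subtraction)
maximum and whose width is inferred from the area under the positive part
of the trace (left Riemann sum, area = (pi/2) h w), evaluates that peak's
tail intensity at the spectrum edge, and adds this constant back to every
point.  The re-added term is a constant, not a curved wing; see
docs/methods.md for the rationale and the alternative reading.

The whole correction is exactly invariant to adding a constant to the
input.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .errors import RegionError
from .spectrum_io import Spectrum

DEFAULT_EDGE_FRACTION = 1.0 / 30.0


def edge_window_size(n_points: int, edge_fraction: float = DEFAULT_EDGE_FRACTION) -> int:
    """Number of points in each edge window (floor(n * fraction), min 1)."""
    m = int(n_points * edge_fraction)
    if m < 1:
        raise RegionError(
            f"spectrum of {n_points} points is too short for edge windows of "
            f"fraction {edge_fraction}"
        )
    return m


def correct_baseline(spectrum: Spectrum,
                     edge_fraction: float = DEFAULT_EDGE_FRACTION) -> Spectrum:
    """Apply the two-step baseline adjustment described in the module docs."""
    y = spectrum.intensities
    m = edge_window_size(spectrum.n_points, edge_fraction)
    edge_mean = float(np.concatenate([y[:m], y[-m:]]).mean())
    y1 = y - edge_mean

    h = float(y1.max())
    if h <= 0:
        warnings.warn(
            "baseline correction: no positive maximum after edge subtraction; "
            "returning the offset-subtracted spectrum unchanged",
            stacklevel=2,
        )
        return Spectrum(spectrum.left_ppm, spectrum.right_ppm, y1,
                        spectrometer_freq_mhz=spectrum.spectrometer_freq_mhz,
                        header=spectrum.header)

    # left Riemann sum of the positive part, in intensity*ppm
    area = float(np.clip(y1[:-1], 0.0, None).sum()) * spectrum.dppm
    w = 2.0 * area / (math.pi * h)
    x_edge = spectrum.span_ppm / w  # 2 * (half span) / w
    tail = h / (1.0 + x_edge * x_edge)
    return Spectrum(spectrum.left_ppm, spectrum.right_ppm, y1 + tail,
                    spectrometer_freq_mhz=spectrum.spectrometer_freq_mhz,
                    header=spectrum.header)
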