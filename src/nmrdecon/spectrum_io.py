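"""Plain-text 1D spectrum I/O and region selection.

The on-disk dialect is the 10-row-header text export produced by common
spectrometer software ("save display region to ... a text file"):

* row 4 carries the left and right chemical-shift limits (ppm) as the 4th
  and 8th whitespace-separated tokens,
* row 6 carries the number of data points as the 4th token,
* every following non-empty line holds one intensity value, ordered from
  the left (high-ppm) edge to the right (low-ppm) edge.

Header rows are matched by token position, not byte column.  Rows other
than 4 and 6 are preserved verbatim on a read/write round trip but are
otherwise ignored; as a dialect extension, a row of the form
``# SF = <value> MHz`` (row 8 by default) stores the spectrometer
frequency so that ppm/Hz conversions survive a round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    RegionError,
    SpectrumFormatError,
    SpectrumLengthError,
    SpectrumParseError,
)

HEADER_ROWS = 10
_LIMITS_ROW = 3  # 0-based index of header row 4
_SIZE_ROW = 5    # 0-based index of header row 6
_FREQ_ROW = 7    # 0-based index of the optional "# SF = ..." row


@dataclass(eq=False)
class Spectrum:
    """A real-valued 1D trace on an arithmetic ppm axis.

    ``intensities[0]`` sits at ``left_ppm``; the axis decreases linearly to
    ``right_ppm`` (the NMR convention of ppm decreasing left to right).
    """

    left_ppm: float
    right_ppm: float
    intensities: np.ndarray
    spectrometer_freq_mhz: float | None = None
    header: tuple[str, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise ValueError("a spectrum needs a 1D intensity trace of >= 2 points")
        if not self.left_ppm > self.right_ppm:
            raise ValueError(
                f"left_ppm ({self.left_ppm}) must exceed right_ppm ({self.right_ppm})"
            )
        if self.spectrometer_freq_mhz is not None and not self.spectrometer_freq_mhz > 0:
            raise ValueError("spectrometer frequency must be positive (MHz)")

    # -- derived geometry ------------------------------------------------
    @property
    def n_points(self) -> int:
        return int(self.intensities.size)

    @property
    def ppm_axis(self) -> np.ndarray:
        return np.linspace(self.left_ppm, self.right_ppm, self.n_points)

    @property
    def dppm(self) -> float:
        """Digital resolution, ppm per point (positive)."""
        return (self.left_ppm - self.right_ppm) / (self.n_points - 1)

    @property
    def span_ppm(self) -> float:
        return self.left_ppm - self.right_ppm

    def hz_axis(self, freq_mhz: float | None = None) -> np.ndarray:
        f = freq_mhz if freq_mhz is not None else self.spectrometer_freq_mhz
        if f is None:
            raise ValueError("spectrometer frequency unknown; cannot build a Hz axis")
        return self.ppm_axis * f

    def __eq__(self, other: object) -> bool:  # header excluded on purpose
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.left_ppm == other.left_ppm
            and self.right_ppm == other.right_ppm
            and self.spectrometer_freq_mhz == other.spectrometer_freq_mhz
            and np.array_equal(self.intensities, other.intensities)
        )


def _parse_number(token: str, *, row: int, path: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise SpectrumParseError(
            f"{path}, header row {row + 1}: token {token!r} is not a number"
        ) from None


def _default_header(n: int, left: float, right: float,
                    freq_mhz: float | None) -> list[str]:
    rows = [
        "# 1D NMR spectrum (plain-text display-region export)",
        "# rows 4 and 6 carry the axis limits and the point count",
        "#",
        f"# LEFT = {left!r} ppm. RIGHT = {right!r} ppm.",
        "#",
        f"# SIZE = {n} ( = number of points)",
        "#",
        "#",
        "#",
        "#",
    ]
    if freq_mhz is not None:
        rows[_FREQ_ROW] = f"# SF = {float(freq_mhz)!r} MHz"
    return rows


def read_spectrum_text(path: str | Path) -> Spectrum:
    """Read a spectrum from the 10-row-header text dialect.

    Raises :class:`SpectrumFormatError` (or a subclass) when the header is
    short, a declared token is missing or non-numeric, or the intensity
    column length disagrees with the declared point count.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < HEADER_ROWS:
        raise SpectrumFormatError(
            f"{path}: expected a {HEADER_ROWS}-row header, file has only "
            f"{len(lines)} lines"
        )
    header = lines[:HEADER_ROWS]

    limit_tokens = header[_LIMITS_ROW].split()
    if len(limit_tokens) < 8:
        raise SpectrumFormatError(
            f"{path}: header row {_LIMITS_ROW + 1} must carry the left/right "
            f"limits as its 4th and 8th tokens (found {len(limit_tokens)} tokens)"
        )
    left = _parse_number(limit_tokens[3], row=_LIMITS_ROW, path=str(path))
    right = _parse_number(limit_tokens[7], row=_LIMITS_ROW, path=str(path))

    size_tokens = header[_SIZE_ROW].split()
    if len(size_tokens) < 4:
        raise SpectrumFormatError(
            f"{path}: header row {_SIZE_ROW + 1} must carry the point count "
            f"as its 4th token (found {len(size_tokens)} tokens)"
        )
    n_float = _parse_number(size_tokens[3], row=_SIZE_ROW, path=str(path))
    if n_float != int(n_float):
        raise SpectrumParseError(
            f"{path}: header row {_SIZE_ROW + 1}: point count {n_float!r} is "
            "not an integer"
        )
    n = int(n_float)

    freq = None
    freq_tokens = header[_FREQ_ROW].split()
    if len(freq_tokens) >= 4 and freq_tokens[1] == "SF" and freq_tokens[2] == "=":
        freq = _parse_number(freq_tokens[3], row=_FREQ_ROW, path=str(path))

    data_lines = [ln for ln in lines[HEADER_ROWS:] if ln.strip()]
    if len(data_lines) != n:
        raise SpectrumLengthError(
            f"{path}: header declares {n} points but {len(data_lines)} "
            "intensity lines follow"
        )
    intensities = np.empty(n)
    for i, ln in enumerate(data_lines):
        try:
            intensities[i] = float(ln)
        except ValueError:
            raise SpectrumParseError(
                f"{path}: intensity line {i + 1} ({ln.strip()!r}) is not a number"
            ) from None

    if not left > right:
        raise SpectrumFormatError(
            f"{path}: left limit ({left}) must exceed right limit ({right})"
        )
    return Spectrum(left, right, intensities, spectrometer_freq_mhz=freq,
                    header=tuple(header))


def write_spectrum_text(spectrum: Spectrum, path: str | Path) -> None:
    """Write ``spectrum`` in the text dialect read by :func:`read_spectrum_text`.

    Header rows 4 and 6 (and the SF row when a spectrometer frequency is
    set) are regenerated from the spectrum; any other stored header rows
    are written back verbatim.
    """
    path = Path(path)
    if spectrum.header is not None and len(spectrum.header) == HEADER_ROWS:
        rows = list(spectrum.header)
    else:
        rows = _default_header(spectrum.n_points, spectrum.left_ppm,
                               spectrum.right_ppm, spectrum.spectrometer_freq_mhz)
    rows[_LIMITS_ROW] = (
        f"# LEFT = {float(spectrum.left_ppm)!r} ppm. "
        f"RIGHT = {float(spectrum.right_ppm)!r} ppm."
    )
    rows[_SIZE_ROW] = f"# SIZE = {spectrum.n_points} ( = number of points)"
    if spectrum.spectrometer_freq_mhz is not None:
        rows[_FREQ_ROW] = f"# SF = {float(spectrum.spectrometer_freq_mhz)!r} MHz"
    body = [repr(float(v)) for v in spectrum.intensities]
    path.write_text("\n".join(rows + body) + "\n")


def select_region(spectrum: Spectrum, left: float, right: float) -> Spectrum:
    """Restrict a spectrum to the closed ppm window ``[right, left]``.

    The returned endpoints are the outermost original grid points inside
    the window, so the digital resolution is preserved exactly and the
    operation is idempotent for a fixed window.
    """
    if not left > right:
        raise RegionError(f"window left ({left}) must exceed right ({right})")
    ppm = spectrum.ppm_axis
    eps = spectrum.dppm * 1e-6
    idx = np.nonzero((ppm <= left + eps) & (ppm >= right - eps))[0]
    if idx.size < 2:
        raise RegionError(
            f"window [{right}, {left}] ppm retains fewer than 2 points of the "
            f"spectrum spanning [{spectrum.right_ppm}, {spectrum.left_ppm}] ppm"
        )
    return Spectrum(
        float(ppm[idx[0]]),
        float(ppm[idx[-1]]),
        spectrum.intensities[idx[0]: idx[-1] + 1].copy(),
        spectrometer_freq_mhz=spectrum.spectrometer_freq_mhz,
        header=spectrum.header,
    )
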