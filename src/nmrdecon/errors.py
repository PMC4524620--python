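"""Exception hierarchy for nmrdecon."""


class NmrdeconError(Exception):
    """Base class for all nmrdecon errors."""


class SpectrumFormatError(NmrdeconError):
    """The text spectrum file does not follow the expected dialect."""


class SpectrumParseError(SpectrumFormatError):
    """A header or intensity token could not be parsed as a number."""


class SpectrumLengthError(SpectrumFormatError):
    """The intensity column length disagrees with the declared point count."""


class RegionError(NmrdeconError):
    """An analysis window does not overlap the spectrum axis (or is too small)."""


class PlacementError(NmrdeconError):
    """No positive residual region is available to host a new peak."""


class DegenerateFitError(NmrdeconError):
    """A fit interpolates the data perfectly (rss == 0); BIC is undefined."""


class RelaxationFitError(NmrdeconError):
    """A decay series cannot be described by a positive transverse relaxation time."""


class ResolutionError(NmrdeconError):
    """The simulation axis is too coarse for the requested measurement."""
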