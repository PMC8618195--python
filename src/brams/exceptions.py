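"""Exception hierarchy for the brams package."""


class BramsError(Exception):
    """Base class for all package errors."""


class SpectrumFormatError(BramsError):
    """A spectrum file or array violates the Spectrum contract."""


class MapFormatError(BramsError):
    """A spectral map file or grid violates the SpectralMap contract."""


class NormalizationError(BramsError):
    """Reference-band normalization is impossible (non-positive reference)."""


class EmptyBandError(BramsError):
    """A spectral band contains no usable signal."""
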