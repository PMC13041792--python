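"""Exception hierarchy.

Every error raised by the library derives from :class:`RamanPrepError`, so
callers (and the batch engine, which must isolate per-file failures) can
catch a single base class.
"""


class RamanPrepError(Exception):
    """Base class for all ramanprep errors."""


class FormatError(RamanPrepError):
    """A file could not be parsed as the expected delimited-text format."""


class SpectrumValidationError(RamanPrepError):
    """A Spectrum (or correction factor) violates its invariants."""


class NoPeakError(RamanPrepError):
    """No peak span was found near the requested position."""


class InsufficientDataError(RamanPrepError):
    """Fewer data points than the operation mathematically requires."""


class SingularFitError(RamanPrepError):
    """Rank-deficient least-squares design (e.g. repeated pixel positions)."""


class DomainError(RamanPrepError):
    """An input falls outside the mathematical domain of a formula."""


class SpectralRangeError(RamanPrepError):
    """A requested axis range is not covered by the available data."""


class EmptyRangeError(RamanPrepError):
    """Truncation left fewer than two points."""


class BinningError(RamanPrepError):
    """An interior bin received no samples (grid coarser than bin width)."""


class ParameterError(RamanPrepError):
    """Invalid stage parameters (e.g. even smoothing window)."""


class FitError(RamanPrepError):
    """A polynomial fit inside a pipeline stage failed."""


class NormalizationError(RamanPrepError):
    """Zero denominator in the requested normalization."""


class ConfigurationError(RamanPrepError):
    """Inconsistent configuration (e.g. SRC required but no factor given)."""


class GenerationError(RamanPrepError):
    """A synthetic fixture could not be generated (e.g. line off-detector)."""
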