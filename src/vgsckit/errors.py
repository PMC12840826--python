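"""Exception hierarchy shared across the package."""


class VgscKitError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(VgscKitError):
    """A genomic/CDS/protein coordinate is outside its valid range."""


class FrameError(VgscKitError):
    """A coding sequence is not an open reading frame (length % 3 != 0)."""


class GeneModelError(VgscKitError):
    """A gene model violates one of its structural invariants."""


class ReferenceMismatchError(VgscKitError):
    """A variant's stated reference base disagrees with the gene model."""


class DegenerateVariantError(VgscKitError):
    """A variant whose alternate equals its reference base."""


class UndefinedFrequencyError(VgscKitError):
    """Frequency requested for a cell with zero total observations."""


class UndefinedRatioError(VgscKitError):
    """dN/dS requested with zero synonymous changes in the denominator."""


class ConfigError(VgscKitError):
    """An input file or simulation configuration fails validation."""
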