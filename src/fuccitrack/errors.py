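"""Exception types shared across the package."""


class FucciTrackError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FucciTrackError):
    """A file exists but its contents violate the expected format."""


class IntegrityError(FucciTrackError):
    """Structurally valid input with internally inconsistent content."""


class VocabularyError(FucciTrackError):
    """A categorical value outside the closed vocabulary."""


class UndefinedMetricError(FucciTrackError):
    """A metric was requested whose denominator is empty."""


class UnalignableTrackError(FucciTrackError):
    """A track that cannot be aligned (e.g. zero-variance / DARK signal)."""
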