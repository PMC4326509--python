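"""Exception hierarchy for the ttgedyn pipeline."""


class TTGEError(Exception):
    """Base class for all ttgedyn errors."""


class FormatError(TTGEError):
    """A file does not have the expected structure (e.g. missing column)."""


class ValidationError(TTGEError):
    """A parsed value violates a domain constraint (e.g. intensity 4)."""


class StandardizationError(TTGEError):
    """Lane standardization failed (too few shared standards, co-migration)."""


class GelInversionError(StandardizationError):
    """Observed standard order contradicts the reference order."""


class UnmappedTaxonError(TTGEError):
    """An OTU id has no entry in the taxonomy map at the requested level."""


class ScopeLookupError(TTGEError):
    """An infant / GLOTU / OTU id is unknown to the timeline."""


class ConfigError(TTGEError):
    """A simulation configuration value is out of range."""


class RenderError(TTGEError):
    """Gel rendering failed (e.g. an OTU has no ladder position)."""


class RecoveryAlignmentError(TTGEError):
    """Pipeline output and simulation truth cannot be matched by sample id."""


class FixtureIntegrityError(TTGEError):
    """A packaged data fixture fails its internal consistency checks."""
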