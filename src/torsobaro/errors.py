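"""Exception hierarchy for the torsobarography pipeline."""


class TorsobaroError(Exception):
    """Base class for all package errors."""


class FormatError(TorsobaroError):
    """A recording file is structurally malformed (header, layout, metadata)."""


class ValidationError(TorsobaroError):
    """A frame or recording violates the sensor-grid contract."""


class PreprocessError(TorsobaroError):
    """Preprocessing cannot produce an analysis frame (e.g. no torso imprint)."""


class LandmarkFailure(TorsobaroError):
    """An anatomical landmark could not be identified; carries a diagnostic."""


class UndefinedIndexError(TorsobaroError):
    """An index is mathematically undefined for this frame (e.g. zero denominator)."""


class PhantomParameterError(TorsobaroError):
    """Phantom parameters describe a torso that does not fit the sensor grid."""
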