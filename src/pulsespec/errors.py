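"""Exception hierarchy for the pulsespec pipeline.

Every error raised deliberately by this package derives from
:class:`PulsespecError`, so callers can catch pipeline failures without
masking programming errors.
"""


class PulsespecError(Exception):
    """Base class for all pulsespec errors."""


class ValidationError(PulsespecError, ValueError):
    """A configuration or input value violates its documented contract."""


class UnsegmentableRecordError(PulsespecError):
    """Fewer than three beat onsets could be located in a record."""


class NoValidBeatsError(PulsespecError):
    """Every detected beat was rejected by quality control."""


class UndersampledBeatError(PulsespecError):
    """A beat has too few samples to resolve the requested harmonics."""


class DegenerateSpectrumError(PulsespecError):
    """The reference amplitude of a spectrum is zero; proportions undefined."""


class InsufficientBeatsError(PulsespecError):
    """Fewer than three usable beats; variability indices are undefined."""


class FeatureMismatchError(PulsespecError):
    """Feature columns of a table do not match what the model was trained on."""
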