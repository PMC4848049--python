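"""Exception hierarchy for the mapgap pipeline.

Every error raised by the package derives from :class:`MapGapError`; most are
also ``ValueError`` subclasses so callers that do not care about the fine
distinctions can catch the built-in type.
"""


class MapGapError(Exception):
    """Base class for all mapgap errors."""


class DegenerateInputError(MapGapError, ValueError):
    """Input is structurally unable to support the requested fit/analysis
    (e.g. a calibration bench with fewer than two distinct wavelength shifts)."""


class CalibrationMismatchError(MapGapError, ValueError):
    """A calibration curve was applied to a sensor series from a different fiber."""


class NoBeatsError(MapGapError, ValueError):
    """The ECG channel does not contain enough QRS complexes to establish a rhythm."""


class WindowTooShortError(MapGapError, ValueError):
    """A beat window is shorter than the minimum MAP duration criterion."""


class EmptyReferenceError(MapGapError, ValueError):
    """No pre-ablation assessment with a detected MAP is available to build a
    contact-force reference."""


class UnknownFixtureError(MapGapError, KeyError):
    """Requested worked-example fixture does not exist."""
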