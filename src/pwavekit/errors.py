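"""Exception and warning hierarchy.

Exit-code mapping used by the CLI:
``ConfigError`` -> 2, ``FormatError`` -> 3, ``DataError`` (and subclasses) -> 4,
``ArgumentError`` -> 5.
"""


class PwavekitError(Exception):
    """Base class for all package errors."""


class ArgumentError(PwavekitError, ValueError):
    """An operation was called with invalid arguments (bad cutoff, n < 2, ...)."""


class ConfigError(PwavekitError):
    """Pipeline configuration is malformed (unknown key, bad type, missing path)."""


class FormatError(PwavekitError):
    """An input file does not conform to the expected on-disk format."""


class DataError(PwavekitError):
    """Input data violate a content contract (duplicate ids, bad fiducial order)."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic (e.g. < 2 valid beats)."""


class DegenerateVarianceError(DataError):
    """A continuous two-group test was requested on data with zero spread."""


class StageError(PwavekitError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


class BeatOverlapWarning(UserWarning):
    """Simulated beats overlap; waveform lobes were summed where they collide."""


class FlatSignalWarning(UserWarning):
    """QRS detection ran on a flat signal; no beats were found."""


class TemporalLeakageWarning(UserWarning):
    """A postoperative variable (mechanical ventilation time) is used as a
    predictor of a postoperative outcome; prediction from preoperative data
    alone would exclude it."""
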