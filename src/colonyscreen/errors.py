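"""Exception hierarchy shared across the pipeline stages."""


class ColonyScreenError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(ColonyScreenError, ValueError):
    """A configuration value or argument violates its contract."""


class CapacityError(InvalidParameterError):
    """More strains supplied than a plate layout can hold."""


class InvalidCalibrationError(InvalidParameterError):
    """Intensity calibration function is not monotone non-decreasing."""


class NoGrowthError(ColonyScreenError):
    """No window of a growth curve shows a positive, well-fit slope."""


class InsufficientControlsError(ColonyScreenError):
    """Fewer than the minimum number of usable control colonies on a plate."""


class MissingDataError(ColonyScreenError):
    """Too few usable replicates to compute a statistic for a strain."""


class InvalidUniverseError(InvalidParameterError):
    """Gene-set universe smaller than the union of the compared sets."""


class FormatError(ColonyScreenError, ValueError):
    """An input table violates the expected schema."""


class DuplicateRecordError(FormatError):
    """Duplicate (plate, row, col, time) rows in a curve table."""


class PipelineError(ColonyScreenError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
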