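"""Exception hierarchy shared by all analysis stages."""


class PCPhysError(Exception):
    """Base class for all package errors."""


class SpecificationError(PCPhysError, ValueError):
    """A generator or analysis spec violates its invariants.

    The message names the offending field.
    """


class ContractError(PCPhysError, ValueError):
    """Input violates a documented precondition (e.g. unsorted spike times)."""


class InsufficientDataError(PCPhysError, ValueError):
    """Not enough events/samples to compute the requested quantity."""


class DataQualityError(PCPhysError, ValueError):
    """Trial rejected on data-quality grounds (e.g. mostly saccade artifact)."""


class CalibrationError(PCPhysError, ValueError):
    """Normalization/calibration input is unusable (e.g. non-positive scale)."""


class ParseError(PCPhysError, ValueError):
    """Malformed input file; message carries the line number where known."""


class UnbalancedDesignError(PCPhysError, ValueError):
    """Repeated-measures table has missing cells."""
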