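"""Exception hierarchy for the PCG analysis pipeline."""


class PcgError(Exception):
    """Base class for all pcgkit errors."""


class ValidationError(PcgError, ValueError):
    """A configuration or input value violates its contract."""


class ParameterError(PcgError, ValueError):
    """An operation was called with invalid or infeasible parameters."""


class FormatError(PcgError, ValueError):
    """An input file is in an unsupported encoding or layout."""


class SegmentationError(PcgError, RuntimeError):
    """Heart-sound segmentation could not be completed."""


class AmbiguityError(SegmentationError):
    """Inter-peak intervals do not alternate, so systole/diastole cannot be assigned."""


class TrainingError(PcgError, RuntimeError):
    """Classifier training failed (e.g. a single class in the training data)."""
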