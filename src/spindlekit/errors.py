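"""Exception types shared across the package."""


class SpindlekitError(Exception):
    """Base class for all package errors."""


class FormatError(SpindlekitError):
    """A file could not be parsed under the named standard."""


class ParameterError(SpindlekitError, ValueError):
    """An argument violates a precondition (bands, rates, window lengths...)."""


class PlacementError(SpindlekitError):
    """Event placement failed: the requested rate is infeasible for the duration."""


class SamplingError(SpindlekitError):
    """A training-set sample could not be drawn (e.g. no events, no negatives)."""


class CalibrationError(SpindlekitError):
    """No channel admitted a threshold achieving the target detection rate."""


class TrainingError(SpindlekitError):
    """The CNN cannot be trained on the provided training set."""


class ArchitectureError(SpindlekitError):
    """An architecture spec is internally inconsistent (e.g. pooling collapse)."""
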