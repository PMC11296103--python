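"""Exception hierarchy shared across the pipeline."""


class QeegError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(QeegError, ValueError):
    """Invalid parameter value or combination."""


class FormatError(QeegError, ValueError):
    """Malformed input file (EDF header, CSV dialect, ...)."""


class ValidationError(QeegError, ValueError):
    """A domain invariant is violated (channel set, hypnogram stages, ...)."""


class GenerationError(QeegError, RuntimeError):
    """Synthetic generation failed (e.g. event placement retry budget exhausted)."""


class TrainingError(QeegError, RuntimeError):
    """Detector training preconditions not met."""


class CalibrationError(QeegError, RuntimeError):
    """No threshold attains the sensitivity floor, or annotation minimums unmet."""


class LeakageError(QeegError, RuntimeError):
    """A model was asked to score a recording from its own training fold."""


class SelectionError(QeegError, RuntimeError):
    """No common vigilance state between two hypnograms."""
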