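"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`DriftsteerError`, so callers can catch the lot with one clause.
"""


class DriftsteerError(Exception):
    """Base class for all errors raised by driftsteer."""


class ParameterError(DriftsteerError, ValueError):
    """A configuration or argument value is out of its valid range.

    The message always names the offending field.
    """


class ScheduleError(DriftsteerError, ValueError):
    """The stimulus schedule is inconsistent (unknown label, ragged reps...)."""


class DegenerateBaselineError(DriftsteerError, ValueError):
    """The pre-stimulus baseline median is non-positive, so dF/F is undefined."""


class InsufficientTrialsError(DriftsteerError, ValueError):
    """Too few repetitions for the requested statistical operation."""


class UndefinedPreferredOrientation(DriftsteerError, ArithmeticError):
    """The vector sum has (numerically) zero resultant; no PO exists."""


class DeadNeuronError(DriftsteerError, ArithmeticError):
    """A postsynaptic neuron lost all incoming weight; normalization undefined."""


class NumericalFailureError(DriftsteerError, ArithmeticError):
    """A simulation produced non-finite values; never silently repaired."""


class CalibrationError(DriftsteerError, RuntimeError):
    """The Hebbian/volatility parity calibration could not be performed."""


class ConfigValidationError(DriftsteerError, ValueError):
    """A pipeline configuration file failed validation.

    ``problems`` lists every violation found, not just the first.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))


class DependencyError(DriftsteerError, RuntimeError):
    """A pipeline stage is missing the output of an upstream stage."""
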