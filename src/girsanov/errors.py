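"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``NumericalError`` to exit code 3.
"""


class GirsanovError(Exception):
    """Base class for all package errors."""


class ConfigError(GirsanovError):
    """Invalid configuration, input value, or file format."""


class SchemeParseError(ConfigError):
    """Splitting-scheme string could not be parsed or is unsupported."""


class ReweightingUndefinedError(ConfigError):
    """Path reweighting is not available for the requested splitting scheme."""


class FileFormatError(ConfigError):
    """A trajectory or reweighting-factor file is malformed."""


class NumericalError(GirsanovError):
    """Numerical failure during simulation or analysis."""


class SimulationBlowupError(NumericalError):
    """Simulation produced non-finite coordinates/energies.

    Attributes
    ----------
    step : int
        Integrator step index at which the blow-up was detected.
    """

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"simulation blew up at step {step}")
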