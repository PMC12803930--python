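"""Exception hierarchy shared by all pipeline stages.

The CLI maps each class to a distinct process exit code so that callers can
tell configuration mistakes from malformed data and from numerical failures.
"""


class CrtsigError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(CrtsigError):
    """Invalid configuration: bad probabilities, dimensions, unknown stages."""

    exit_code = 2


class DataError(CrtsigError):
    """Structurally or semantically invalid input data."""

    exit_code = 3


class NumericalError(CrtsigError):
    """A numerical procedure failed (non-convergence, degenerate statistics)."""

    exit_code = 4
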