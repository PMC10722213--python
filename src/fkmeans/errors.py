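"""Exception hierarchy shared across the package.

Each class carries the process exit code used by the command-line
interface (0 = success, 2 = validation, 3 = I/O, 4 = degenerate input).
"""


class FKMeansError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(FKMeansError):
    """Inputs violate a documented precondition or invariant."""

    exit_code = 2


class FormatError(FKMeansError):
    """A file could not be parsed as a supported image format."""

    exit_code = 3


class IOFailure(FKMeansError):
    """Reading or writing a file failed for filesystem reasons."""

    exit_code = 3


class ConfigurationError(FKMeansError):
    """A configuration value is out of its admissible range."""

    exit_code = 2


class DegenerateInputError(FKMeansError):
    """Input is formally valid but degenerate for the requested operation
    (e.g. zero intensity variance, a closed loop with no endpoints)."""

    exit_code = 4
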