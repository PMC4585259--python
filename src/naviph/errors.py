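"""Exception hierarchy shared across the package.

Exit codes used by the CLI: 0 success, 2 configuration error, 3 data error,
4 numerical failure.
"""


class NaviphError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(NaviphError):
    """Invalid configuration or precondition violation."""

    exit_code = 2


class FormatError(NaviphError):
    """A tabular file does not have the expected layout (e.g. missing column)."""

    exit_code = 3


class DataError(NaviphError):
    """Well-formed input whose content violates an invariant."""

    exit_code = 3


class RangeError(DataError):
    """A numeric value outside its physically meaningful range."""

    exit_code = 3


class FitError(NaviphError):
    """A least-squares fit failed to converge; carries the initial guesses used."""

    exit_code = 4

    def __init__(self, message, initial_guesses=None):
        super().__init__(message)
        self.initial_guesses = initial_guesses
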