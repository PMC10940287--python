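"""Exception hierarchy shared across the package.

CLI exit-code convention: :class:`InputError` subclasses map to exit code 2,
:class:`ConvergenceError` subclasses to exit code 3.
"""


class MicroaquaError(Exception):
    """Base class for all package errors."""


class InputError(MicroaquaError):
    """Invalid user-supplied data (files, configs, compositions)."""


class ParseError(InputError):
    """Malformed record in an input file; carries the offending line number."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class RegistryError(InputError):
    """A species or residue name is not present in the registry."""


class SpecError(InputError):
    """A generator or scenario specification is internally inconsistent."""


class DomainError(MicroaquaError):
    """An operation was called outside its mathematical domain."""


class ConvergenceError(MicroaquaError):
    """An iterative solver failed to converge."""


class CalibrationError(MicroaquaError):
    """An anchor value cannot be reproduced by the model family."""


class NoBulkError(ConvergenceError):
    """A radial profile never settles to a constant value (no bulk region)."""
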