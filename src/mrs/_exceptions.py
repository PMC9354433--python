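"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 2, ``NumericalError`` to 3.
"""


class MRSError(Exception):
    """Base class for all package errors."""


class ValidationError(MRSError):
    """Malformed, inconsistent, or out-of-contract input."""


class SelectionError(MRSError):
    """P+T selection could not produce a usable sub-community."""


class NumericalError(MRSError):
    """A numerical procedure failed (non-convergence, degenerate variance, ...)."""
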