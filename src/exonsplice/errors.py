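"""Exception hierarchy shared by all pipeline stages.

``InputError`` maps to CLI exit code 2, ``NumericalError`` to exit code 3.
"""


class ExonSpliceError(Exception):
    """Base class for all package errors."""


class InputError(ExonSpliceError):
    """Malformed or inconsistent input data / configuration."""


class NumericalError(ExonSpliceError):
    """A computation could not be carried out (degenerate variance, domain error)."""
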