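"""Exception hierarchy.

The CLI maps these onto distinct exit codes (parse: 3, validation: 4,
numerical: 5) so pipeline drivers can tell a malformed input file from a
bad argument combination from an optimizer failure.
"""


class MethcompareError(Exception):
    """Base class for all package errors."""


class ParseError(MethcompareError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(MethcompareError):
    """Inputs are well-formed but violate a contract (range, shape, ...)."""


class ConvergenceError(MethcompareError):
    """A numerical routine failed to converge."""
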