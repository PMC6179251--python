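"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ``InputError`` -> 2,
``DegenerateDataError`` -> 3.
"""


class CastleError(Exception):
    """Base class for all package errors."""


class InputError(CastleError):
    """Malformed or inconsistent user input (bad files, shape mismatches...)."""


class DegenerateDataError(CastleError):
    """Structurally valid input on which the method is undefined
    (single-class labels, no shared genes, no informative features...)."""
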