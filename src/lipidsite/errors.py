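"""Exception hierarchy shared by all lipidsite stages.

Exit codes (used by the CLI): 2 input error, 3 parse error,
4 degenerate-input error.
"""


class LipidsiteError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(LipidsiteError):
    """A precondition on user-supplied data was violated."""

    exit_code = 2


class ParseError(LipidsiteError):
    """A file did not conform to its declared format.

    Messages name the offending line or frame where known.
    """

    exit_code = 3


class DegenerateInputError(LipidsiteError):
    """Input is well-formed but too small/trivial for the requested metric
    (e.g. a single-frame trajectory passed to an RMSF calculation)."""

    exit_code = 4


class MappingError(InputError):
    """Residues in a structure could not be reconciled with a score track."""
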