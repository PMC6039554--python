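"""Exception hierarchy.

Errors are split by recovery semantics: format/validation problems are the
user's data, numerical problems (disconnected network, degenerate distance
variance) are properties of the analysis and surface with their own types so
callers can map them to distinct exit codes.
"""


class CoexhierError(Exception):
    """Base class for all package errors."""


class FormatError(CoexhierError):
    """A file does not conform to its declared format (GCT/GMT/CLS/TSV)."""


class ValidationError(CoexhierError):
    """Structurally valid input violates a domain invariant."""


class DisconnectedNetworkError(CoexhierError):
    """The positive-weight gene network is not connected; commute-time and
    resistance distances are infinite between components."""


class DegenerateDistanceError(CoexhierError):
    """A cophenetic correlation is undefined because the off-diagonal
    distances (or the cophenetic heights) have zero variance."""
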