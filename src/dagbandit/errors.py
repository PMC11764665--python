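"""Exception hierarchy for dagbandit."""


class DagBanditError(Exception):
    """Base class for all package errors."""


class InvalidStructureError(DagBanditError):
    """A graph violates the DAG contract (non-square, self-loop, cycle)."""


class IncompatibleStructuresError(DagBanditError):
    """Two structures do not share the same label set/order."""


class ConstraintConflictError(DagBanditError):
    """Hard constraints are mutually inconsistent (e.g. required edge forbidden,
    or required edges cyclic)."""


class InvalidMoveError(DagBanditError):
    """An add/delete/reverse move is illegal on the given structure."""


class InsufficientDataError(DagBanditError):
    """Too few samples for the requested regression (m <= number of parents)."""


class FormatError(DagBanditError):
    """A structure or dataset file failed to parse."""
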