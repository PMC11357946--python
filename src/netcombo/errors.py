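"""Exception hierarchy.

``NetcomboError`` is the root; CLI maps validation-type errors to exit
code 2 and everything else to 1.
"""


class NetcomboError(Exception):
    """Base class for all package errors."""


class FormatError(NetcomboError):
    """A file could not be parsed in the expected tabular/graph format."""


class RowValidationError(FormatError):
    """A single input row violated the schema (empty gene cell, ...)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(f"row {row}: {message}" if row is not None else message)


class TargetsAbsentError(NetcomboError):
    """None of a drug's targets are present in the network."""

    def __init__(self, drug: str):
        self.drug = drug
        super().__init__(f"no targets of drug {drug!r} are present in the network")


class UnreachableTargetsError(NetcomboError):
    """Strict reachability mode hit a disconnected required pair."""


class EdgelessGraphError(NetcomboError):
    """Modularity is undefined on a graph with no edges (m = 0)."""


class LookupError_(NetcomboError):
    """Unknown node, community id, or method label."""
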