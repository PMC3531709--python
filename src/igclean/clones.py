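"""Clonally-related sequence sets and consensus construction.

A clone is a group of Ig sequences descending from one V(D)J
rearrangement, aligned together with a germline (or consensus) reference
row.  Grouping into clones and germline segment calling happen upstream;
this module only holds the aligned result and the small coordinate
arithmetic the indel classifier needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

GAP = "-"
_CONSENSUS_ORDER = "ACGT-"  # tie-break: nucleotides beat the gap


@dataclass
class ClonalAlignment:
    """A germline row plus member rows of equal aligned length."""

    clone_id: str
    germline_name: str
    germline_row: str
    members: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.germline_row)
        for name, row in self.members:
            if len(row) != n:
                raise ValueError(
                    f"clone {self.clone_id!r}: row {name!r} has aligned length "
                    f"{len(row)}, germline has {n}"
                )

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def width(self) -> int:
        return len(self.germline_row)

    @property
    def germline_seq(self) -> str:
        """Degapped germline sequence."""
        return self.germline_row.replace(GAP, "")

    def member_row(self, name: str) -> str:
        for n, row in self.members:
            if n == name:
                return row
        raise KeyError(name)

    def member_seq(self, name: str) -> str:
        return self.member_row(name).replace(GAP, "")


def build_consensus(rows: list[str]) -> str:
    """Per-column majority vote over aligned rows.

    The most frequent symbol among {A, C, G, T, -} wins each column; ties
    are broken in the fixed order A < C < G < T < '-' so a nucleotide
    always beats the gap on a tie.
    """
    if not rows:
        raise ValueError("no rows to build a consensus from")
    n = len(rows[0])
    for row in rows:
        if len(row) != n:
            raise ValueError("rows have unequal aligned lengths")
    out = []
    for col in range(n):
        counts = {sym: 0 for sym in _CONSENSUS_ORDER}
        for row in rows:
            counts[row[col]] += 1
        out.append(max(_CONSENSUS_ORDER, key=lambda s: (counts[s], -_CONSENSUS_ORDER.index(s))))
    return "".join(out)


def column_to_read_position(row: str, column: int) -> Optional[int]:
    """Map an alignment column to the 0-based position in the degapped row.

    Returns None when the row has a gap at that column.
    """
    if not 0 <= column < len(row):
        raise IndexError(f"column {column} outside alignment of width {len(row)}")
    if row[column] == GAP:
        return None
    return column - row.count(GAP, 0, column)


def column_position_map(row: str) -> list[Optional[int]]:
    """Vector form of :func:`column_to_read_position` for one row."""
    out: list[Optional[int]] = []
    pos = 0
    for ch in row:
        if ch == GAP:
            out.append(None)
        else:
            out.append(pos)
            pos += 1
    return out
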