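"""Degenerate-primer identification.

PCR primers flank the amplified gene and may carry IUPAC degenerate
codes.  A primer is first sought as a perfect (degeneracy-aware) match in
a window at each end of the tag-trimmed read.  When a side lacks a
perfect hit, the primer is trimmed from its outer end down to a
configured fraction of its length — sequencing tends to damage the ends
distal to the gene — and re-sought as the best *infix* (semi-global)
alignment under a unit-cost edit model, accepted only when the edit count
stays within the configured budget.

Both primers must be found on opposite ends and on opposite strands;
hits on the same strand orientation mark the read as a putative PCR
chimera.
"""

from __future__ import annotations

import functools
import math
import re
from dataclasses import dataclass
from typing import Literal, Optional, TYPE_CHECKING

from .midtags import Orientation, reverse_complement

if TYPE_CHECKING:  # pragma: no cover
    from .seqio import CleanConfig, Read

__all__ = [
    "IUPAC_EXPANSION",
    "iupac_match",
    "trim_primer",
    "min_edit_occurrence",
    "locate_primers",
    "PrimerHit",
    "PrimerPairResult",
]

#: Expansion of each IUPAC code into the read bases it matches.  An ``N``
#: called in a *read* is deliberately matched only by the primer code
#: ``N`` so that low-quality calls cannot inflate matches.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "H": frozenset("ACT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}


def iupac_match(read_base: str, primer_base: str) -> bool:
    """True iff the read base falls in the primer code's expansion."""
    try:
        return read_base in IUPAC_EXPANSION[primer_base]
    except KeyError:
        raise ValueError(f"unknown IUPAC code {primer_base!r}") from None


def trim_primer(primer: str, fraction: float) -> str:
    """Keep the gene-proximal ``ceil(fraction * len)`` bases of a primer.

    Primers are written 5'->3' on their own strand, so the gene-proximal
    side is the 3' end for both forward and reverse primers.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    keep = math.ceil(fraction * len(primer))
    return primer[-keep:]


@functools.lru_cache(maxsize=512)
def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(
        "[" + "".join(sorted(IUPAC_EXPANSION[c])) + "]" for c in pattern
    ) + "))")


def _perfect_occurrences(window: str, pattern: str) -> list[int]:
    """Start offsets of all perfect degeneracy-aware matches (overlapping)."""
    return [m.start() for m in _pattern_regex(pattern).finditer(window)]


def _prefix_distances(segment: str, pattern_sets: list[frozenset[str]]) -> list[int]:
    """d[j] = edit distance of the full pattern vs segment[:j]."""
    n = len(segment)
    prev = list(range(n + 1))
    for pset in pattern_sets:
        cur = [prev[0] + 1]
        for j in range(1, n + 1):
            cost = 0 if segment[j - 1] in pset else 1
            best = prev[j - 1] + cost
            up = prev[j] + 1
            if up < best:
                best = up
            left = cur[j - 1] + 1
            if left < best:
                best = left
            cur.append(best)
        prev = cur
    return prev


def min_edit_occurrence(
    window: str,
    pattern: str,
    outer: Literal["left", "right"] = "left",
    max_edits: Optional[int] = None,
) -> tuple[int, Optional[tuple[int, int]]]:
    """Best infix occurrence of an IUPAC pattern in a window.

    Returns ``(edits, (start, end))`` where *edits* is the minimum, over
    all substrings of the window, of the unit-cost edit distance to the
    pattern (degeneracy-compatible pairs cost 0).  Ties are broken toward
    the span closest to the window's ``outer`` edge, then the shortest
    span.  When ``max_edits`` is given and the minimum exceeds it, the
    span search is skipped and ``(edits, None)`` is returned.
    """
    if not pattern:
        raise ValueError("empty pattern")
    psets = [IUPAC_EXPANSION[c] if c in IUPAC_EXPANSION else _bad(c) for c in pattern]
    n = len(window)

    # Semi-global pass (free start and end in the window) for the minimum.
    prev = [0] * (n + 1)
    for pset in psets:
        cur = [prev[0] + 1]
        for j in range(1, n + 1):
            cost = 0 if window[j - 1] in pset else 1
            best = prev[j - 1] + cost
            up = prev[j] + 1
            if up < best:
                best = up
            left = cur[j - 1] + 1
            if left < best:
                best = left
            cur.append(best)
        prev = cur
    edits = min(prev)
    if max_edits is not None and edits > max_edits:
        return edits, None

    if outer == "left":
        for s in range(n + 1):
            d = _prefix_distances(window[s:], psets)
            for ln, val in enumerate(d):
                if val == edits:
                    return edits, (s, s + ln)
    else:
        rsets = psets[::-1]
        for e in range(n, -1, -1):
            d = _prefix_distances(window[:e][::-1], rsets)
            for ln, val in enumerate(d):
                if val == edits:
                    return edits, (e - ln, e)
    raise AssertionError("unreachable: minimum must be attained")  # pragma: no cover


def _bad(c: str):
    raise ValueError(f"unknown IUPAC code {c!r}")


@dataclass(frozen=True)
class PrimerHit:
    """One located primer occurrence on the tag-trimmed read core."""

    primer_index: int  # 1-based within its list
    which: Literal["forward", "reverse"]
    orientation: Orientation
    edits: int
    span: tuple[int, int]  # 0-based half-open, core coordinates
    matched_fraction: Literal["full", "trimmed"]


@dataclass(frozen=True)
class PrimerPairResult:
    fw_hit: PrimerHit
    rv_hit: PrimerHit
    gene_orientation: Orientation
    chimeric: bool

    @property
    def hit5(self) -> PrimerHit:
        return min((self.fw_hit, self.rv_hit), key=lambda h: h.span[0])

    @property
    def hit3(self) -> PrimerHit:
        return max((self.fw_hit, self.rv_hit), key=lambda h: h.span[1])


def _candidates(config: "CleanConfig"):
    for which, primers in (("forward", config.forward_primers),
                           ("reverse", config.reverse_primers)):
        for idx, primer in enumerate(primers, start=1):
            yield which, idx, primer


def _best_side_hit(
    window: str,
    offset: int,
    side: Literal["five_prime", "three_prime"],
    config: "CleanConfig",
) -> Optional[PrimerHit]:
    outer = "left" if side == "five_prime" else "right"

    def outer_dist(span: tuple[int, int]) -> int:
        return span[0] if side == "five_prime" else len(window) - span[1]

    def rank(which: str) -> int:
        return 0 if which == "forward" else 1

    # Stage 1: perfect scan of the full primers, both strands.
    perfect: list[tuple[tuple, PrimerHit]] = []
    for which, idx, primer in _candidates(config):
        for pattern, orient in ((primer, "sense"), (reverse_complement(primer), "antisense")):
            for s in _perfect_occurrences(window, pattern):
                span = (s, s + len(pattern))
                key = (0, rank(which), idx, 0 if orient == "sense" else 1, outer_dist(span))
                perfect.append((key, PrimerHit(
                    idx, which, orient, 0,
                    (offset + span[0], offset + span[1]), "full")))
    if perfect:
        return min(perfect, key=lambda t: t[0])[1]

    # Stage 2: bounded-edit infix match of the fraction-trimmed primers.
    partial: list[tuple[tuple, PrimerHit]] = []
    for which, idx, primer in _candidates(config):
        trimmed = trim_primer(primer, config.primer_fraction)
        for pattern, orient in ((trimmed, "sense"), (reverse_complement(trimmed), "antisense")):
            edits, span = min_edit_occurrence(
                window, pattern, outer=outer, max_edits=config.max_mismatches)
            if span is None:
                continue
            key = (edits, rank(which), idx, 0 if orient == "sense" else 1, outer_dist(span))
            partial.append((key, PrimerHit(
                idx, which, orient, edits,
                (offset + span[0], offset + span[1]), "trimmed")))
    if partial:
        return min(partial, key=lambda t: t[0])[1]
    return None


def locate_primers(core: "Read", config: "CleanConfig") -> Optional[PrimerPairResult]:
    """Find a forward/reverse primer pair on the tag-trimmed core.

    Returns None when either side has no acceptable hit, or when the two
    sides carry the same primer type on opposite strands (an anatomy no
    legitimate amplicon produces).  Hits sharing one strand orientation
    yield a result flagged ``chimeric``.
    """
    bases = core.bases
    r = config.search_range
    left = _best_side_hit(bases[:r], 0, "five_prime", config)
    right_off = max(0, len(bases) - r)
    right = _best_side_hit(bases[right_off:], right_off, "three_prime", config)
    if left is None or right is None:
        return None

    if left.orientation == right.orientation:
        fw, rv = (left, right) if left.which == "forward" else (right, left)
        orient = fw.orientation
        return PrimerPairResult(fw, rv, orient, chimeric=True)

    if {left.which, right.which} != {"forward", "reverse"}:
        return None
    fw, rv = (left, right) if left.which == "forward" else (right, left)
    return PrimerPairResult(fw, rv, fw.orientation, chimeric=False)
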