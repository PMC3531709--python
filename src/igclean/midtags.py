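"""MID (molecular identifier) tag handling.

454-style amplicon reads carry a 10-nt barcode at each end, between the
sequencing adapter and the PCR primer.  Sample-of-origin is encoded by the
*combination* of forward and reverse barcodes, so demultiplexing requires
identifying a tag at both ends of a read, in the right orientations: the
5' tag is expected in sense orientation and the 3' tag in antisense
(this holds whichever strand the sequencer happened to read).

Because base-calling errors cluster at read boundaries, a tag is first
sought as a full perfect match and, failing that, as a perfect match of
its gene-proximal (inner) end of a configurable minimal length.  The
minimal length that still distinguishes a tag set is a property of the
set itself and is computed by :func:`min_distinguishing_inner_length`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Optional, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .seqio import CleanConfig, Read

__all__ = [
    "BASIC_MID_SET",
    "MidHit",
    "reverse_complement",
    "hamming_distance",
    "min_pairwise_hamming",
    "min_distinguishing_inner_length",
    "find_mid_at_end",
    "assign_sample",
]

#: The basic nine-tag 454 barcode set (5'->3'), as supplied by the
#: sequencing vendor for multiplexed amplicon runs.  Minimum pairwise
#: Hamming distance 6; inner fragments of length 5 are unambiguous.
BASIC_MID_SET: tuple[str, ...] = (
    "ACGAGTGCGT",
    "ACGCTCGACA",
    "AGACGCACTC",
    "AGCACTGTAG",
    "ATCAGACACG",
    "ATATCGCGAG",
    "CGTGTCTCTA",
    "CTCGCGTGTC",
    "TAGTATCAGC",
)

# IUPAC-aware complement table (upper case only; reads and tags are
# plain ACGT(N), primers may carry any degenerate code).
_COMPLEMENT = str.maketrans("ACGTRYMKWSHDBVN", "TGCAYRKMWSDHVBN")
_KNOWN = set("ACGTRYMKWSHDBVN")

End = Literal["five_prime", "three_prime"]
Orientation = Literal["sense", "antisense"]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (upper case)."""
    bad = set(seq) - _KNOWN
    if bad:
        raise ValueError(f"unknown nucleotide code(s): {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_hamming(mids: list[str] | tuple[str, ...]) -> int:
    """Minimum Hamming distance over all pairs of a tag set."""
    if len(mids) < 2:
        raise ValueError("need at least two tags")
    return min(hamming_distance(a, b) for a, b in itertools.combinations(mids, 2))


def min_distinguishing_inner_length(mids: list[str] | tuple[str, ...]) -> int:
    """Smallest inner-fragment length that keeps a tag set unambiguous.

    For each candidate length ``k`` the gene-proximal length-``k`` suffix of
    every tag, together with the reverse complement of each suffix (the form
    the fragment takes at the opposite read end), must be pairwise distinct.
    Returns ``max(len) + 1`` if no length distinguishes the set.
    """
    if not mids:
        raise ValueError("empty tag set")
    longest = max(len(m) for m in mids)
    for k in range(1, min(len(m) for m in mids) + 1):
        frags = [m[-k:] for m in mids]
        frags += [reverse_complement(f) for f in frags]
        if len(set(frags)) == len(frags):
            return k
    return longest + 1


@dataclass(frozen=True)
class MidHit:
    """A located tag occurrence at one read end.

    ``span`` is a 0-based half-open interval on the read.  ``orientation``
    is *sense* when the tag string itself matched, *antisense* when its
    reverse complement did.  ``match_type`` records whether the whole tag
    or only its inner (gene-proximal) fragment was found.
    """

    mid_index: int  # 1-based, insertion order in the config
    end: End
    orientation: Orientation
    match_type: Literal["full", "partial_inner"]
    span: tuple[int, int]


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All start offsets of ``needle`` in ``haystack`` (overlapping)."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def find_mid_at_end(read: "Read", end: End, config: "CleanConfig") -> Optional[MidHit]:
    """Locate a tag in the search window at one end of a read.

    The window is the first (5') or last (3') ``search_range`` bases.  A
    full perfect match of any tag or its reverse complement is always
    preferred; only when no tag matches in full is the window re-scanned
    for the perfect inner fragment of minimal length.  When several full
    matches exist, the one closest to the read end wins, ties broken by
    sense before antisense, then lower tag index.
    """
    r = config.search_range
    bases = read.bases
    if end == "five_prime":
        window, offset = bases[:r], 0
    else:
        offset = max(0, len(bases) - r)
        window = bases[offset:]

    def pick(candidates: list[tuple[int, int, Orientation, int]]) -> Optional[tuple]:
        # candidate = (start-in-window, length, orientation, mid_index)
        if not candidates:
            return None
        if end == "five_prime":
            key = lambda c: (c[0], 0 if c[2] == "sense" else 1, c[3])
        else:
            key = lambda c: (-(c[0] + c[1]), 0 if c[2] == "sense" else 1, c[3])
        return min(candidates, key=key)

    # Pass 1: full tags, both orientations.
    full: list[tuple[int, int, Orientation, int]] = []
    for idx, mid in enumerate(config.mids, start=1):
        for pattern, orient in ((mid, "sense"), (reverse_complement(mid), "antisense")):
            for s in _occurrences(window, pattern):
                full.append((s, len(pattern), orient, idx))
    best = pick(full)
    if best is not None:
        s, ln, orient, idx = best
        return MidHit(idx, end, orient, "full", (offset + s, offset + s + ln))

    # Pass 2: gene-proximal inner fragments of length k_min.  At the 5' end
    # the inner side of an occurrence is its suffix, at the 3' end its
    # prefix, for either orientation of the tag.
    k = config.min_mid_len
    partial: list[tuple[int, int, Orientation, int]] = []
    for idx, mid in enumerate(config.mids, start=1):
        for pattern, orient in ((mid, "sense"), (reverse_complement(mid), "antisense")):
            frag = pattern[-k:] if end == "five_prime" else pattern[:k]
            for s in _occurrences(window, frag):
                partial.append((s, k, orient, idx))
    best = pick(partial)
    if best is not None:
        s, ln, orient, idx = best
        return MidHit(idx, end, orient, "partial_inner", (offset + s, offset + s + ln))
    return None


def assign_sample(
    hit5: MidHit,
    hit3: MidHit,
    orientation: Orientation,
    table: dict[tuple[int, int], str],
) -> Optional[str]:
    """Resolve a (5' tag, 3' tag) pair to a sample id.

    ``orientation`` is the gene orientation deduced from the primers: in a
    sense read the 5' tag is the forward barcode, in an antisense read the
    roles are swapped.  The lookup is strictly ordered — ``(fw, rv)`` is
    not interchangeable with ``(rv, fw)``.
    """
    if orientation == "sense":
        key = (hit5.mid_index, hit3.mid_index)
    else:
        key = (hit3.mid_index, hit5.mid_index)
    return table.get(key)
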