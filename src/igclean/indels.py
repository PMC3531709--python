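"""Homopolymer-aware classification of indels and low-quality mutations.

Pyrosequencing misreads homopolymer tracts (HPTs — maximal runs of one
nucleotide), producing artifact insertions and deletions at or next to
tracts.  Genuine indels from somatic hypermutation are rare but must not
be thrown away, so the classifier separates the two using the structure
of a clone: an indel next to a tract that no (or too few) clone siblings
share is an artifact; a shared indel, or one away from any tract, is
legitimate; and an under-shared tract-proximal indel in a sequence with
no clone siblings cannot be judged and is kept apart as *uncertain*.

Point mutations with base quality below a threshold are screened the
same way, except that mutations inside the AID hotspot motif AACA (or
its complement TGTT) are always kept: the deaminase targets those motifs,
so a low-quality call there is plausibly biological.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .clones import GAP, ClonalAlignment, column_position_map

__all__ = [
    "HPT",
    "IndelEvent",
    "MutationEvent",
    "IndelConfig",
    "SequenceVerdict",
    "find_hpts",
    "extract_events",
    "is_near_hpt",
    "count_sharing",
    "in_aid_motif",
    "classify_sequence",
    "run_indel_identifier",
]

AID_MOTIFS = ("AACA", "TGTT")

VerdictClass = Literal[
    "without_indels", "with_legitimate_indels", "uncertain",
    "artifact_indel", "low_qual_mutation",
]

#: Output file suffixes, by verdict class.
OUTPUT_FILES: dict[str, str] = {
    "without_indels": "-WithoutIndels.txt",
    "with_legitimate_indels": "-WithoutIndels.txt",
    "uncertain": "-CloneOfSize1WithIndels.txt",
    "artifact_indel": "-IllegitimateIndels.txt",
    "low_qual_mutation": "-SeqsWithLowQualPointMuts.txt",
}


@dataclass(frozen=True)
class HPT:
    """A maximal same-nucleotide run, half-open on degapped coordinates."""

    start: int
    end: int
    base: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IndelEvent:
    """A maximal gap run in the member (deletion) or germline (insertion).

    ``columns`` is the half-open alignment-column interval; ``gl_span``
    is the event's locus on the degapped germline: the deleted germline
    positions for a deletion, or the empty interval at the insertion
    point for an insertion.
    """

    kind: Literal["insertion", "deletion"]
    columns: tuple[int, int]
    gl_span: tuple[int, int]

    @property
    def length(self) -> int:
        return self.columns[1] - self.columns[0]


@dataclass(frozen=True)
class MutationEvent:
    """An aligned non-gap mismatch between member and germline."""

    column: int
    gl_base: str
    read_base: str
    read_position: int  # 0-based on the degapped member
    gl_position: int  # 0-based on the degapped germline
    qual: Optional[int] = None


@dataclass
class IndelConfig:
    """Classifier thresholds.

    ``min_share`` counts the carrier itself, so the base rule "no other
    sequence shares the indel" corresponds to the default of 2.
    ``min_qual`` of -1 disables mutation screening entirely.
    """

    min_share: int = 2
    min_hpt_len: int = 2
    min_qual: int = -1

    def __post_init__(self) -> None:
        if self.min_share < 1:
            raise ValueError("min_share must be >= 1")
        if self.min_hpt_len < 1:
            raise ValueError("min_hpt_len must be >= 1")


@dataclass(frozen=True)
class SequenceVerdict:
    read_id: str
    verdict: VerdictClass


def find_hpts(seq: str, min_len: int) -> list[HPT]:
    """All maximal same-base runs of length >= min_len, left to right."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    out: list[HPT] = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            out.append(HPT(i, j, seq[i]))
        i = j
    return out


def extract_events(
    member_row: str, germline_row: str
) -> tuple[list[IndelEvent], list[MutationEvent]]:
    """Position-by-position comparison of a member row to the germline.

    Maximal gap runs become one indel event each; a gap in the germline
    is an insertion, in the member a deletion.  Columns where both rows
    hold gaps are ignored (they belong to other members' insertions).
    Non-gap mismatches become mutation events.
    """
    if len(member_row) != len(germline_row):
        raise ValueError(
            f"aligned lengths differ: member {len(member_row)}, "
            f"germline {len(germline_row)}"
        )
    gl_map = column_position_map(germline_row)
    gl_len = len(germline_row) - germline_row.count(GAP)
    indels: list[IndelEvent] = []
    muts: list[MutationEvent] = []
    read_pos = 0
    run_kind: Optional[str] = None
    run_start = 0

    def close_run(end_col: int) -> None:
        nonlocal run_kind
        if run_kind is None:
            return
        cols = (run_start, end_col)
        if run_kind == "deletion":
            g0 = gl_map[run_start]
            g1 = gl_map[cols[1] - 1] + 1
        else:
            # insertion point: number of germline bases before the run
            nxt = next((gl_map[c] for c in range(cols[1], len(germline_row))
                        if gl_map[c] is not None), gl_len)
            g0 = g1 = nxt
        indels.append(IndelEvent(run_kind, cols, (g0, g1)))
        run_kind = None

    for col, (m, g) in enumerate(zip(member_row, germline_row)):
        if m == GAP and g == GAP:
            close_run(col)
            continue
        kind = "deletion" if m == GAP else "insertion" if g == GAP else None
        if kind != run_kind or (run_kind is not None and kind is None):
            close_run(col)
        if kind is not None and run_kind is None:
            run_kind, run_start = kind, col
        if kind is None:
            if m != g:
                muts.append(MutationEvent(col, g, m, read_pos, gl_map[col]))
        if m != GAP:
            read_pos += 1
    close_run(len(member_row))
    return indels, muts


def is_near_hpt(event: IndelEvent, germline_seq: str, min_hpt_len: int) -> bool:
    """Is an indel inside, immediately 5' of, or immediately 3' of a tract?

    The tract scan runs on the degapped germline.  A deletion qualifies
    when any deleted position lies within a tract of the minimum length
    or at either flanking position; an insertion qualifies when its
    insertion point touches such a tract (inserting just before its
    start, inside it, or just after its end).
    """
    g0, g1 = event.gl_span
    for hpt in find_hpts(germline_seq, min_hpt_len):
        if event.kind == "deletion":
            # eligible positions: tract interior plus its two flanks
            if g0 <= hpt.end and g1 > hpt.start - 1:
                return True
        else:
            if hpt.start <= g0 <= hpt.end:
                return True
    return False


def _event_key(ev) -> tuple:
    if isinstance(ev, IndelEvent):
        return ("indel", ev.kind, ev.columns)
    return ("mutation", ev.column, ev.read_base)


def count_sharing(event, clone: ClonalAlignment) -> int:
    """How many member rows (carrier included) exhibit the same event.

    Indels compare by kind and exact alignment-column interval; mutations
    by column and substituted base.
    """
    key = _event_key(event)
    count = 0
    for _, row in clone.members:
        indels, muts = extract_events(row, clone.germline_row)
        if any(_event_key(e) == key for e in indels) or \
           any(_event_key(m) == key for m in muts):
            count += 1
    return count


def in_aid_motif(mutation: MutationEvent, germline_seq: str) -> bool:
    """Does the mutated germline position fall inside AACA or TGTT?"""
    pos = mutation.gl_position
    for motif in AID_MOTIFS:
        start = germline_seq.find(motif)
        while start != -1:
            if start <= pos < start + len(motif):
                return True
            start = germline_seq.find(motif, start + 1)
    return False


def _share_counter(clone: ClonalAlignment) -> Counter:
    counter: Counter = Counter()
    for _, row in clone.members:
        indels, muts = extract_events(row, clone.germline_row)
        counter.update(_event_key(e) for e in indels)
        counter.update(_event_key(m) for m in muts)
    return counter


def classify_sequence(
    member_name: str,
    clone: ClonalAlignment,
    quals: Optional[Sequence[int]] = None,
    config: Optional[IndelConfig] = None,
    _shares: Optional[Counter] = None,
) -> SequenceVerdict:
    """Classify one clone member by walking its events in order.

    Indels away from tracts, or shared by at least ``min_share`` members,
    are legitimate.  An under-shared tract-proximal indel is an artifact
    in a multi-member clone and *uncertain* in a singleton.  Low-quality
    mutations are discarded only when outside an AID motif, under-shared,
    and the clone has siblings to judge by.  The first terminal event
    decides; otherwise uncertainty, then the presence of any indel,
    determines the class.
    """
    config = config or IndelConfig()
    row = clone.member_row(member_name)
    gl_seq = clone.germline_seq
    indels, muts = extract_events(row, clone.germline_row)
    shares = _shares if _shares is not None else _share_counter(clone)
    size = clone.size

    uncertain = False
    events: list = sorted(indels + muts, key=lambda e: e.columns[0] if isinstance(e, IndelEvent) else e.column)
    for ev in events:
        if isinstance(ev, IndelEvent):
            if not is_near_hpt(ev, gl_seq, config.min_hpt_len):
                continue  # legitimate: away from any tract
            if shares[_event_key(ev)] >= config.min_share:
                continue  # legitimate: shared within the clone
            if size == 1:
                uncertain = True
                continue
            return SequenceVerdict(member_name, "artifact_indel")
        else:
            if config.min_qual < 0 or quals is None:
                continue
            pos = ev.read_position
            qual = quals[pos] if ev.qual is None else ev.qual
            if qual >= config.min_qual:
                continue
            if in_aid_motif(ev, gl_seq):
                continue  # AID hotspot: plausibly biological, keep
            if size > 1 and shares[_event_key(ev)] < config.min_share:
                return SequenceVerdict(member_name, "low_qual_mutation")
    if uncertain:
        return SequenceVerdict(member_name, "uncertain")
    if indels:
        return SequenceVerdict(member_name, "with_legitimate_indels")
    return SequenceVerdict(member_name, "without_indels")


def run_indel_identifier(
    clones: Iterable[ClonalAlignment],
    quals: Optional[dict[str, list[int]]] = None,
    config: Optional[IndelConfig] = None,
    outdir: Optional[str] = None,
    name: str = "clones",
) -> dict[str, int]:
    """Classify every member of every clone and route it to one output.

    ``quals`` maps read ids to per-base scores of the *degapped* member
    sequences; mutation screening is skipped for reads without scores or
    when ``min_qual`` is -1.  Returns per-class counts; when ``outdir``
    is given, writes the four FASTA outputs and a run log.
    """
    config = config or IndelConfig()
    verdicts: list[tuple[SequenceVerdict, str]] = []
    for clone in clones:
        shares = _share_counter(clone)
        for mname, row in clone.members:
            q = quals.get(mname) if quals else None
            v = classify_sequence(mname, clone, q, config, _shares=shares)
            verdicts.append((v, row.replace(GAP, "")))

    counts = {cls: 0 for cls in (
        "without_indels", "with_legitimate_indels", "uncertain",
        "artifact_indel", "low_qual_mutation")}
    for v, _ in verdicts:
        counts[v.verdict] += 1

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        sinks: dict[str, list[str]] = {suffix: [] for suffix in set(OUTPUT_FILES.values())}
        for v, seq in verdicts:
            sinks[OUTPUT_FILES[v.verdict]].append(f">{v.read_id}\n{seq}\n")
        for suffix, entries in sinks.items():
            with open(os.path.join(outdir, f"{name}{suffix}"), "w") as fh:
                fh.write("".join(entries))
        with open(os.path.join(outdir, f"{name}-Ig-Indel-Identifier.log"), "w") as fh:
            fh.write(f"Sequences processed\t{len(verdicts)}\n")
            for cls, cnt in counts.items():
                fh.write(f"{cls}\t{cnt}\n")
            fh.write(
                f"min_share\t{config.min_share}\nmin_hpt_len\t{config.min_hpt_len}\n"
                f"min_qual\t{config.min_qual}\n"
            )
    return counts
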