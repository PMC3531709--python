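"""Readers and writers for the pipeline's plain-text formats.

Four dialects flow through the pipeline:

* ``.fna`` + ``.qual`` — FASTA reads with a parallel file of per-base
  quality scores (0-40, whitespace-separated, line wrapping ignored), the
  classic 454 delivery format.  Parsed with Biopython.
* the run-configuration file (``input.txt``) — titled sections holding the
  tag list, primer lists, length bounds, thresholds and the sample table,
  each list closed by a ``#`` line.
* PIR clone alignments (``.txts``) — ``>P1;name`` records terminated by
  ``*``, as emitted by classic multiple aligners; one row is the germline.
* the two-part tab-delimited run log (written by :mod:`igclean.cleaner`).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.SeqIO.QualityIO import PairedFastaQualIterator

from .clones import ClonalAlignment

__all__ = [
    "Read",
    "CleanConfig",
    "QualitySummary",
    "read_fasta_qual",
    "write_fasta_qual",
    "parse_clean_config",
    "serialize_clean_config",
    "parse_pir_alignment",
    "write_pir_alignment",
    "summarize_quality",
]

_READ_ALPHABET = set("ACGTN")


@dataclass
class Read:
    """One sequencer read: identifier, bases and per-base quality scores."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read identifier must be non-empty")
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        bad = set(self.bases) - _READ_ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r}: non-ACGTN base(s) {sorted(bad)!r}")
        for q in self.quals:
            if not 0 <= q <= 40:
                raise ValueError(f"read {self.id!r}: quality score {q} outside [0, 40]")

    def __len__(self) -> int:
        return len(self.bases)


def read_fasta_qual(fasta_text: str, qual_text: str) -> list[Read]:
    """Parse a FASTA file together with its matching quality file.

    Records must appear in the same order with identical identifiers and
    matching base/score counts; any disagreement is a hard error naming
    the offending record.
    """
    reads: list[Read] = []
    it = PairedFastaQualIterator(StringIO(fasta_text), StringIO(qual_text))
    while True:
        try:
            rec = next(it)
        except StopIteration:
            break
        except ValueError as exc:  # Biopython names the record in its message
            raise ValueError(f"FASTA/QUAL mismatch: {exc}") from exc
        reads.append(
            Read(rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
        )
    return reads


def write_fasta_qual(reads: Iterable[Read]) -> tuple[str, str]:
    """Serialize reads to (fasta_text, qual_text), one line per sequence."""
    fa, qa = [], []
    for r in reads:
        fa.append(f">{r.id}\n{r.bases}\n")
        qa.append(f">{r.id}\n{' '.join(str(q) for q in r.quals)}\n")
    return "".join(fa), "".join(qa)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_MID_ALPHABET = set("ACGT")
_PRIMER_ALPHABET = set("ACGTRYMKWSHDBVN")


@dataclass
class CleanConfig:
    """All parameters of one cleaning run.

    ``sample_table`` maps an ordered (forward tag index, reverse tag index)
    pair to a sample id; indices are 1-based insertion order, and the key
    ``(0, 0)`` denotes the tag-less single-sample mode.
    """

    organism: str
    chain: str
    quality_threshold: float
    max_mismatches: int
    primer_fraction: float
    search_range: int
    min_mid_len: int
    mids: list[str]
    forward_primers: list[str]
    reverse_primers: list[str]
    min_l1: int
    max_l1: int
    min_l2: int
    max_l2: int
    sample_table: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.min_l1 <= self.max_l1):
            raise ValueError(f"bad L1 bounds: [{self.min_l1}, {self.max_l1}]")
        if not (0 < self.min_l2 <= self.max_l2):
            raise ValueError(f"bad L2 bounds: [{self.min_l2}, {self.max_l2}]")
        if not (0 < self.primer_fraction <= 1):
            raise ValueError(f"primer fraction {self.primer_fraction} outside (0, 1]")
        if self.max_mismatches < 0:
            raise ValueError("max mismatches must be >= 0")
        if self.search_range < 1:
            raise ValueError("search range must be >= 1")
        if not self.forward_primers or not self.reverse_primers:
            raise ValueError("both primer lists must be non-empty")
        for p in self.forward_primers + self.reverse_primers:
            bad = set(p) - _PRIMER_ALPHABET
            if bad:
                raise ValueError(f"primer {p!r}: unknown code(s) {sorted(bad)!r}")
        for m in self.mids:
            bad = set(m) - _MID_ALPHABET
            if bad:
                raise ValueError(f"MID {m!r}: tags must be plain ACGT")
        if self.mids:
            if not 1 <= self.min_mid_len <= min(len(m) for m in self.mids):
                raise ValueError(
                    f"minimal MID length {self.min_mid_len} outside "
                    f"[1, {min(len(m) for m in self.mids)}]"
                )
        if not self.mids and self.sample_table and (0, 0) not in self.sample_table:
            raise ValueError("tag-less mode requires the (0, 0) sample-table entry")
        n = len(self.mids)
        for fw, rv in self.sample_table:
            if (fw, rv) == (0, 0):
                continue
            if not (1 <= fw <= n and 1 <= rv <= n):
                raise ValueError(
                    f"sample table references MID pair ({fw}, {rv}) but only "
                    f"{n} MIDs are listed"
                )

    @property
    def no_mids(self) -> bool:
        return not self.mids


_SCALAR_TITLES = {
    "organism": "organism",
    "chain": "chain",
    "quality threshold": "quality_threshold",
    "maximum mismatches allowed": "max_mismatches",
    "fraction of primer to search": "primer_fraction",
    "range to search primers in": "search_range",
    "minimal mid length": "min_mid_len",
}
_LIST_TITLES = {"mids", "forward", "reverse", "table"}
_PAIR_TITLES = {"minimum length", "maximum length"}


def parse_clean_config(text: str) -> CleanConfig:
    """Parse the titled-section run-configuration dialect.

    Section titles are matched case-insensitively and tolerate surrounding
    whitespace; a scalar value may sit on the title line or the next line;
    the Mids/Forward/Reverse/Table lists must be closed by a ``#`` line.
    """
    lines = [ln.strip() for ln in text.splitlines()]
    values: dict[str, object] = {}
    lists: dict[str, list[str]] = {}
    pairs: dict[str, tuple[int, int]] = {}

    def match_title(line: str) -> Optional[tuple[str, str]]:
        low = line.lower()
        for title in list(_SCALAR_TITLES) + sorted(_LIST_TITLES) + sorted(_PAIR_TITLES):
            if low == title or low.startswith(title):
                return title, line[len(title):].strip(" \t:") if low.startswith(title) else ""
        return None

    i = 0
    while i < len(lines):
        line = lines[i]
        i += 1
        if not line:
            continue
        hit = match_title(line)
        if hit is None:
            raise ValueError(f"unrecognized configuration line: {line!r}")
        title, inline = hit
        if title in _LIST_TITLES:
            items: list[str] = []
            closed = False
            while i < len(lines):
                ln = lines[i]
                i += 1
                if ln == "#":
                    closed = True
                    break
                if ln:
                    items.append(ln)
            if not closed:
                raise ValueError(f"section {title!r} is missing its '#' terminator")
            lists[title] = items
        else:
            value = inline
            while not value and i < len(lines):
                value = lines[i]
                i += 1
            if not value:
                raise ValueError(f"section {title!r} has no value")
            if title in _PAIR_TITLES:
                toks = value.split()
                if len(toks) != 2:
                    raise ValueError(f"section {title!r} needs two values, got {value!r}")
                pairs[title] = (int(toks[0]), int(toks[1]))
            else:
                values[_SCALAR_TITLES[title]] = value

    for required in ("mids", "forward", "reverse", "table"):
        if required not in lists:
            raise ValueError(f"missing section {required!r}")
    for required in _PAIR_TITLES:
        if required not in pairs:
            raise ValueError(f"missing section {required!r}")

    mids = [m.upper() for m in lists["mids"]]
    table: dict[tuple[int, int], str] = {}
    for row in lists["table"]:
        toks = row.split()
        if len(toks) < 3:
            raise ValueError(f"table row needs 'fw rv sample', got {row!r}")
        try:
            fw, rv = int(toks[0]), int(toks[1])
        except ValueError as exc:
            raise ValueError(f"non-integer MID index in table row {row!r}") from exc
        table[(fw, rv)] = " ".join(toks[2:])

    min_l1, min_l2 = pairs["minimum length"]
    max_l1, max_l2 = pairs["maximum length"]
    return CleanConfig(
        organism=str(values.get("organism", "")),
        chain=str(values.get("chain", "")),
        quality_threshold=float(values["quality_threshold"]),
        max_mismatches=int(values["max_mismatches"]),
        primer_fraction=float(values["primer_fraction"]),
        search_range=int(values["search_range"]),
        min_mid_len=int(values["min_mid_len"]),
        mids=mids,
        forward_primers=[p.upper() for p in lists["forward"]],
        reverse_primers=[p.upper() for p in lists["reverse"]],
        min_l1=min_l1,
        max_l1=max_l1,
        min_l2=min_l2,
        max_l2=max_l2,
        sample_table=table,
    )


def serialize_clean_config(config: CleanConfig) -> str:
    """Write a config back out in the canonical titled-section dialect."""
    out = [
        f"Organism\n{config.organism}",
        f"Chain\n{config.chain}",
        f"Quality threshold\n{config.quality_threshold:g}",
        f"Maximum mismatches allowed\n{config.max_mismatches}",
        f"Fraction of primer to search\n{config.primer_fraction:g}",
        f"Range to search primers in\n{config.search_range}",
        f"Minimal MID length\n{config.min_mid_len}",
        "Mids\n" + "".join(f"{m}\n" for m in config.mids) + "#",
        "Forward\n" + "".join(f"{p}\n" for p in config.forward_primers) + "#",
        "Reverse\n" + "".join(f"{p}\n" for p in config.reverse_primers) + "#",
        f"Minimum length\n{config.min_l1} {config.min_l2}",
        f"Maximum length\n{config.max_l1} {config.max_l2}",
        "Table\n"
        + "".join(f"{fw}\t{rv}\t{s}\n" for (fw, rv), s in config.sample_table.items())
        + "#",
    ]
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PIR clone alignments
# ---------------------------------------------------------------------------

def parse_pir_alignment(text: str, clone_id: str = "clone") -> ClonalAlignment:
    """Parse a PIR alignment into a clone.

    The germline row is the record whose name starts with ``GL`` or,
    failing that, the first record.  All aligned rows must have equal
    length and each sequence must end with the ``*`` terminator.
    """
    for block in re.split(r"(?=^>)", text, flags=re.M):
        if block.startswith(">") and "*" not in block:
            name = block.splitlines()[0]
            raise ValueError(f"PIR record {name!r} is missing its '*' terminator")
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(StringIO(text), "pir")]
    if not records:
        raise ValueError("empty PIR alignment")
    widths = {len(row) for _, row in records}
    if len(widths) != 1:
        raise ValueError(f"unequal aligned lengths in PIR alignment: {sorted(widths)}")
    gl_idx = next((i for i, (name, _) in enumerate(records) if name.startswith("GL")), 0)
    gl_name, gl_row = records[gl_idx]
    members = [rec for i, rec in enumerate(records) if i != gl_idx]
    return ClonalAlignment(clone_id, gl_name, gl_row, members)


def write_pir_alignment(aln: ClonalAlignment) -> str:
    """Serialize a clone as a PIR alignment (germline row first)."""
    out = []
    for name, row in [(aln.germline_name, aln.germline_row)] + aln.members:
        out.append(f">P1;{name}\n{name}\n{row}*\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# quality summaries
# ---------------------------------------------------------------------------

@dataclass
class QualitySummary:
    """Per-read average/minimum scores plus the sample-level average.

    The sample average is the mean of the per-read averages (not the
    pooled per-base mean).  Zero-length reads cannot contribute and are
    listed in ``skipped_ids``.
    """

    per_sequence_averages: list[float]
    per_sequence_minima: list[int]
    sample_average: float
    skipped_ids: list[str] = field(default_factory=list)


def summarize_quality(reads: Iterable[Read]) -> QualitySummary:
    averages, minima, skipped = [], [], []
    for r in reads:
        if len(r) == 0:
            skipped.append(r.id)
            continue
        averages.append(sum(r.quals) / len(r.quals))
        minima.append(min(r.quals))
    sample = sum(averages) / len(averages) if averages else math.nan
    return QualitySummary(averages, minima, sample, skipped)
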