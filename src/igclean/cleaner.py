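"""The read-cleaning pipeline.

Each raw read passes, in order: a raw-length pre-filter (L1), tag (MID)
identification at both ends, primer identification on the tag-trimmed
core, a between-primer length check (L2), and an average-quality check on
the gene region.  A read that fails a stage is routed to the failure file
for that stage; a read that survives is trimmed to the gene, normalized
to sense orientation, and written to its sample's output pair.

The run statistics mirror the classic two-part log: a per-sample table
(totals, per-stage failures with percentages, remaining, average score)
followed by global counters and a parameter echo.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import pandas as pd

from .midtags import MidHit, assign_sample, find_mid_at_end, reverse_complement
from .primers import locate_primers
from .seqio import CleanConfig, Read, write_fasta_qual

__all__ = ["CleanOutcome", "CleanStats", "average_quality", "clean_read", "clean_dataset"]

Status = Literal["pass", "fail_L1", "fail_mids", "fail_primers", "fail_L2", "fail_quality"]

#: Classic names of the per-stage failure files.
FAILURE_FILES = {
    "fail_mids": "FailedInFindMIDs.txt",
    "fail_primers": "FailedInFindPrimers.txt",
    "fail_L1": "FailedInCheckLength.txt",
    "fail_L2": "FailedInCheckLength.txt",
    "fail_quality": "FailedInQuality.txt",
}

LOG_COLUMNS = [
    "Sample", "Total", "Failed in primers", "% out of total",
    "Failed in length", "% out of total", "% of the remaining",
    "Failed in quality", "% out of total", "% of the remaining",
    "Total remaining", "Average score",
]


def average_quality(quals: list[int]) -> float:
    """Arithmetic mean of per-base quality scores."""
    if not quals:
        raise ValueError("cannot average an empty quality list")
    return sum(quals) / len(quals)


@dataclass
class CleanOutcome:
    """Per-read verdict: the stage reached and, on success, the gene."""

    read_id: str
    status: Status
    sample: Optional[str] = None  # known from the tag stage onward
    gene: Optional[Read] = None  # sense-normalized, pass only
    original_orientation: Optional[str] = None
    mid_hits: Optional[tuple[MidHit, MidHit]] = None


def clean_read(read: Read, config: CleanConfig) -> CleanOutcome:
    """Run one read through all cleaning stages; always yields an outcome."""
    # Stage 1: raw length (adapters included, as delivered).
    if not config.min_l1 <= len(read) <= config.max_l1:
        return CleanOutcome(read.id, "fail_L1")

    # Stage 2: tags at both ends (skipped when no tags were used).
    hit5 = hit3 = None
    sample: Optional[str] = None
    core_start, core_end = 0, len(read)
    if config.no_mids:
        sample = config.sample_table.get((0, 0))
    else:
        hit5 = find_mid_at_end(read, "five_prime", config)
        hit3 = find_mid_at_end(read, "three_prime", config)
        if hit5 is None or hit3 is None:
            return CleanOutcome(read.id, "fail_mids")
        # Both read orientations place the 5' tag in sense and the 3' tag
        # in antisense; anything else is not a legitimate amplicon.
        if hit5.orientation != "sense" or hit3.orientation != "antisense":
            return CleanOutcome(read.id, "fail_mids", mid_hits=(hit5, hit3))
        keys = [(hit5.mid_index, hit3.mid_index), (hit3.mid_index, hit5.mid_index)]
        sample = next((config.sample_table[k] for k in keys if k in config.sample_table), None)
        if sample is None:
            return CleanOutcome(read.id, "fail_mids", mid_hits=(hit5, hit3))
        core_start, core_end = hit5.span[1], hit3.span[0]

    core = Read(read.id, read.bases[core_start:core_end], read.quals[core_start:core_end]) \
        if core_end > core_start else Read(read.id, "", [])

    # Stage 3: primers on both ends of the core; same-strand pairs are
    # chimeras and count as primer failures.
    pair = locate_primers(core, config) if len(core) else None
    if pair is None or pair.chimeric:
        return CleanOutcome(read.id, "fail_primers", sample=sample, mid_hits=(hit5, hit3) if hit5 else None)

    orientation = pair.gene_orientation
    if hit5 is not None and hit3 is not None:
        resolved = assign_sample(hit5, hit3, orientation, config.sample_table)
        if resolved is None:
            # Only the flipped tag order is in the table; the primer
            # orientation contradicts it, so no sample can be attributed.
            return CleanOutcome(read.id, "fail_mids", mid_hits=(hit5, hit3))
        sample = resolved

    # Stage 4: between-primer length.
    gstart, gend = pair.hit5.span[1], pair.hit3.span[0]
    gene_bases = core.bases[gstart:gend] if gend > gstart else ""
    gene_quals = core.quals[gstart:gend] if gend > gstart else []
    if not config.min_l2 <= len(gene_bases) <= config.max_l2:
        return CleanOutcome(read.id, "fail_L2", sample=sample)

    # Stage 5: average gene quality, strictly above the threshold.
    if not average_quality(gene_quals) > config.quality_threshold:
        return CleanOutcome(read.id, "fail_quality", sample=sample)

    # Sense-normalize the gene for downstream alignment.
    if orientation == "antisense":
        gene_bases = reverse_complement(gene_bases)
        gene_quals = gene_quals[::-1]
    return CleanOutcome(
        read.id, "pass", sample=sample,
        gene=Read(read.id, gene_bases, gene_quals),
        original_orientation=orientation,
    )


@dataclass
class CleanStats:
    """Aggregated run statistics in the two-part log layout."""

    per_sample: pd.DataFrame  # Sample, Total, Failed in primers/length/quality, remaining, avg
    received: int = 0
    fail_l1: int = 0
    fail_mids: int = 0
    sense: int = 0
    antisense: int = 0
    config: Optional[CleanConfig] = None

    def format_log(self) -> str:
        """Render the tab-delimited two-part log."""
        def pct(a: float, b: float) -> str:
            return f"{(100.0 * a / b):.2f}" if b else "0.00"

        lines = ["\t".join(LOG_COLUMNS)]
        for _, row in self.per_sample.iterrows():
            total = row["total"]
            after_primers = total - row["failed_primers"]
            after_length = after_primers - row["failed_length"]
            avg = "" if math.isnan(row["average_score"]) else f"{row['average_score']:.2f}"
            lines.append("\t".join(str(x) for x in [
                row["sample"], total,
                row["failed_primers"], pct(row["failed_primers"], total),
                row["failed_length"], pct(row["failed_length"], total),
                pct(row["failed_length"], after_primers),
                row["failed_quality"], pct(row["failed_quality"], total),
                pct(row["failed_quality"], after_length),
                row["remaining"], avg,
            ]))
        lines += ["", "Run totals"]
        lines.append(f"Sequences received\t{self.received}")
        lines.append(f"Failed in first length check\t{self.fail_l1}")
        lines.append(f"Failed in finding MIDs\t{self.fail_mids}")
        lines.append(f"Failed in finding primers\t{int(self.per_sample['failed_primers'].sum())}")
        lines.append(f"Failed in length check\t{int(self.per_sample['failed_length'].sum())}")
        lines.append(f"Failed in quality check\t{int(self.per_sample['failed_quality'].sum())}")
        lines.append(f"Total remaining\t{int(self.per_sample['remaining'].sum())}")
        lines.append(f"Sense\t{self.sense}")
        lines.append(f"Antisense\t{self.antisense}")
        if self.config is not None:
            c = self.config
            lines += [
                "", "Run parameters",
                f"Organism\t{c.organism}",
                f"Chain\t{c.chain}",
                f"Quality threshold\t{c.quality_threshold:g}",
                f"Maximum mismatches allowed\t{c.max_mismatches}",
                f"Fraction of primer to search\t{c.primer_fraction:g}",
                f"Range to search primers in\t{c.search_range}",
                f"Minimal MID length\t{c.min_mid_len}",
                f"Minimum length\t{c.min_l1} {c.min_l2}",
                f"Maximum length\t{c.max_l1} {c.max_l2}",
            ]
        return "\n".join(lines) + "\n"


def clean_dataset(
    reads: Iterable[Read],
    config: CleanConfig,
    outdir: Optional[str] = None,
) -> tuple[CleanStats, list[CleanOutcome]]:
    """Clean a batch of reads, optionally writing all output files.

    Every read is routed to exactly one destination: a per-stage failure
    file (original, untrimmed read) or its sample's FASTA/QUAL pair
    (gene region only, sense-normalized).
    """
    reads = list(reads)
    outcomes = [clean_read(r, config) for r in reads]
    by_id = {r.id: r for r in reads}

    # Sample order follows the table; reads with unknown samples cannot
    # occur past the tag stage.
    sample_order = list(dict.fromkeys(config.sample_table.values()))
    rows = []
    for s in sample_order:
        mine = [o for o in outcomes if o.sample == s]
        passed = [o for o in mine if o.status == "pass"]
        scores = [average_quality(o.gene.quals) for o in passed]
        rows.append({
            "sample": s,
            "total": len(mine),
            "failed_primers": sum(o.status == "fail_primers" for o in mine),
            "failed_length": sum(o.status == "fail_L2" for o in mine),
            "failed_quality": sum(o.status == "fail_quality" for o in mine),
            "remaining": len(passed),
            "average_score": sum(scores) / len(scores) if scores else math.nan,
        })
    stats = CleanStats(
        per_sample=pd.DataFrame(rows, columns=[
            "sample", "total", "failed_primers", "failed_length",
            "failed_quality", "remaining", "average_score"]),
        received=len(outcomes),
        fail_l1=sum(o.status == "fail_L1" for o in outcomes),
        fail_mids=sum(o.status == "fail_mids" for o in outcomes),
        sense=sum(o.status == "pass" and o.original_orientation == "sense" for o in outcomes),
        antisense=sum(o.status == "pass" and o.original_orientation == "antisense" for o in outcomes),
        config=config,
    )

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        buckets: dict[str, list[Read]] = {name: [] for name in set(FAILURE_FILES.values())}
        for o in outcomes:
            if o.status != "pass":
                buckets[FAILURE_FILES[o.status]].append(by_id[o.read_id])
        for fname, failed in buckets.items():
            fa, _ = write_fasta_qual(failed)
            with open(os.path.join(outdir, fname), "w") as fh:
                fh.write(fa)
        for s in sample_order:
            genes = [o.gene for o in outcomes if o.status == "pass" and o.sample == s]
            fa, qa = write_fasta_qual(genes)
            with open(os.path.join(outdir, f"{s}.txt"), "w") as fh:
                fh.write(fa)
            with open(os.path.join(outdir, f"{s}.qual"), "w") as fh:
                fh.write(qa)
        with open(os.path.join(outdir, "Log.txt"), "w") as fh:
            fh.write(stats.format_log())

    return stats, outcomes
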