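"""Simulators with ground truth, for benchmarking the pipeline.

Two generators live here:

* :func:`inject_deletions` — the deletion-injection scheme used to
  benchmark the indel classifier: each clone member may receive exactly
  one deletion, placed inside or immediately next to a homopolymer tract
  of a drawn length, and is then duplicated a drawn number of times so
  that sharing within the clone can be exercised.  Every injected
  deletion is by construction a sequencing-style artifact, so the
  classifier's identification fraction against the emitted truth table
  is a direct accuracy measure.
* :func:`generate_clean_fixture` — synthetic 454-style amplicon reads
  (adapter + tag + primer + gene + primer' + tag' + adapter, either
  strand) with per-read planted defects and a truth table of intended
  cleaning outcomes.

All draws come from one seeded generator, so fixed seeds reproduce the
output byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import edlib
import numpy as np
import pandas as pd

from .clones import GAP, ClonalAlignment
from .indels import IndelConfig, classify_sequence, find_hpts, _share_counter
from .midtags import reverse_complement
from .primers import IUPAC_EXPANSION, trim_primer
from .seqio import CleanConfig, Read, write_fasta_qual

__all__ = [
    "SimParams",
    "TruthRecord",
    "inject_deletions",
    "generate_clone_set",
    "sweep_identification",
    "generate_clean_fixture",
]

_BASES = "ACGT"


@dataclass
class SimParams:
    """Deletion-injection parameters.

    ``p_del`` is the per-member probability of receiving a deletion; the
    tract length is drawn uniformly from [hpt_len_low, hpt_len_high]
    restricted to lengths actually present in the member, and the number
    of appended duplicates uniformly from [dup_low, dup_high].
    """

    p_del: float = 0.5
    hpt_len_low: int = 2
    hpt_len_high: int = 10
    dup_low: int = 0
    dup_high: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_del <= 1:
            raise ValueError("p_del must be in [0, 1]")
        if self.hpt_len_low > self.hpt_len_high or self.dup_low > self.dup_high:
            raise ValueError("empty draw range")


@dataclass
class TruthRecord:
    """What the simulator did to one original clone member."""

    read_id: str
    injected: bool
    hpt_length: Optional[int] = None
    position: Optional[int] = None  # degapped member coordinate of the '-'
    placement: Optional[Literal["five_prime", "inside", "three_prime"]] = None
    duplicates: int = 0
    carrier_ids: list[str] = field(default_factory=list)  # member + its copies


def inject_deletions(
    clone: ClonalAlignment,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ClonalAlignment, list[TruthRecord]]:
    """Inject at most one deletion per member and append duplicates.

    For each member, with probability ``p_del``: draw a tract length
    uniformly among the lengths present in the member and inside the
    configured range; pick one maximal tract of exactly that length; pick
    one position uniformly among the tract's interior positions plus its
    two flanks (never the first or last base of the sequence); replace
    that base with a gap; then append the drawn number of identical
    copies.  Members without any drawable tract are left untouched.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    new_members: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    used_columns: set[int] = set()  # one injection site per clone column
    for name, row in clone.members:
        rec = TruthRecord(read_id=name, injected=False)
        out_row = row
        if rng.random() < params.p_del:
            seq = row.replace(GAP, "")
            runs = find_hpts(seq, 1)  # all maximal runs
            present = sorted({r.length for r in runs
                              if params.hpt_len_low <= r.length <= params.hpt_len_high})
            if present:
                length = int(rng.choice(present))
                tracts = [r for r in runs if r.length == length]
                tract = tracts[int(rng.integers(len(tracts)))]
                # map degapped positions -> alignment columns once
                pos_to_col = [c for c, ch in enumerate(row) if ch != GAP]
                # Distinct members never receive the same injection site:
                # a collision would make two independent artifacts look
                # like a shared (hence legitimate) indel and corrupt the
                # truth labels.
                candidates = [p for p in range(tract.start - 1, tract.end + 1)
                              if 1 <= p <= len(seq) - 2
                              and pos_to_col[p] not in used_columns]
                if candidates:
                    pos = int(candidates[int(rng.integers(len(candidates)))])
                    placement = ("five_prime" if pos == tract.start - 1
                                 else "three_prime" if pos == tract.end else "inside")
                    col = pos_to_col[pos]
                    used_columns.add(col)
                    out_row = row[:col] + GAP + row[col + 1:]
                    dups = int(rng.integers(params.dup_low, params.dup_high + 1))
                    rec = TruthRecord(name, True, length, pos, placement, dups,
                                      [name] + [f"{name}_dup{k}" for k in range(1, dups + 1)])
        new_members.append((name, out_row))
        for dup_id in rec.carrier_ids[1:]:
            new_members.append((dup_id, out_row))
        truth.append(rec)
    sim = ClonalAlignment(clone.clone_id, clone.germline_name,
                          clone.germline_row, new_members)
    return sim, truth


def generate_clone_set(
    target_sequences: int = 500,
    seed: int = 0,
    length_range: tuple[int, int] = (150, 300),
    singleton_prob: float = 0.3,
    mutation_rate: float = 0.01,
) -> list[ClonalAlignment]:
    """Synthetic clones of indel-free members around a random germline.

    Members differ from the germline only by point substitutions placed
    at isolated positions (both neighbours differ from the site and the
    substituted base differs from both neighbours), so the homopolymer
    tract structure of every member equals the germline's.  Clone sizes
    mix singletons with geometrically distributed multi-member clones,
    echoing the long-tailed clone-size spectrum of real repertoires.
    """
    rng = np.random.default_rng(seed)
    clones: list[ClonalAlignment] = []
    total = 0
    cid = 0
    while total < target_sequences:
        cid += 1
        n = len(clones)
        if rng.random() < singleton_prob:
            size = 1
        else:
            size = min(2 + int(rng.geometric(0.25)), 40)
        size = min(size, target_sequences - total) or 1
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gl = "".join(rng.choice(list(_BASES), size=length))
        members = []
        for m in range(size):
            seq = list(gl)
            n_mut = rng.poisson(mutation_rate * length)
            eligible = [p for p in range(1, length - 1)
                        if gl[p] != gl[p - 1] and gl[p] != gl[p + 1]]
            if eligible and n_mut:
                for p in rng.choice(eligible, size=min(n_mut, len(eligible)), replace=False):
                    choices = [b for b in _BASES
                               if b not in (gl[p], gl[p - 1], gl[p + 1])]
                    seq[p] = choices[int(rng.integers(len(choices)))]
            members.append((f"c{cid}_s{m + 1}", "".join(seq)))
        clones.append(ClonalAlignment(f"c{cid}", f"GL_c{cid}", gl, members))
        total += size
    return clones


def sweep_identification(
    simulated: Iterable[tuple[ClonalAlignment, list[TruthRecord]]],
    hpt_lens: Iterable[int],
    share_thresholds: Iterable[int],
    population: Literal["all", "multi"] = "all",
) -> pd.DataFrame:
    """Identification-fraction grid over classifier parameter combinations.

    Each cell reruns the classifier and reports identified artifact
    deletions as a percentage of all injected deletions (carriers and
    their duplicates).  ``population="multi"`` restricts both numerator
    and denominator to multi-member clones, where the sharing rule can
    actually fire.
    """
    simulated = list(simulated)
    hpt_lens = list(hpt_lens)
    share_thresholds = list(share_thresholds)
    grid = pd.DataFrame(index=pd.Index(hpt_lens, name="min_hpt_len"),
                        columns=pd.Index(share_thresholds, name="min_share"),
                        dtype=float)
    for h in hpt_lens:
        for t in share_thresholds:
            config = IndelConfig(min_share=t, min_hpt_len=h, min_qual=-1)
            identified = 0
            injected = 0
            for clone, truth in simulated:
                carriers = {cid for rec in truth if rec.injected for cid in rec.carrier_ids}
                if not carriers:
                    continue
                if population == "multi" and clone.size <= 1:
                    continue
                shares = _share_counter(clone)
                for name, _ in clone.members:
                    if name not in carriers:
                        continue
                    injected += 1
                    v = classify_sequence(name, clone, None, config, _shares=shares)
                    if v.verdict == "artifact_indel":
                        identified += 1
            grid.loc[h, t] = 100.0 * identified / injected if injected else math.nan
    return grid


# ---------------------------------------------------------------------------
# synthetic amplicon reads for the cleaner
# ---------------------------------------------------------------------------

_ADAPTER_LEN = 6
_EQUALITIES = [(code, base) for code, bases in IUPAC_EXPANSION.items()
               for base in bases if base != code]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n)) if n else ""


def _realize(primer: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC codes to concrete bases, uniformly per position."""
    out = []
    for c in primer:
        opts = sorted(IUPAC_EXPANSION[c] - {"N"})
        out.append(opts[int(rng.integers(len(opts)))])
    return "".join(out)


def _mid_fragments(config: CleanConfig) -> list[str]:
    k = config.min_mid_len
    frags = []
    for m in config.mids:
        rc = reverse_complement(m)
        frags += [m, rc, m[:k], m[-k:], rc[:k], rc[-k:]]
    return frags


def _primer_patterns(config: CleanConfig) -> list[str]:
    pats = []
    for p in config.forward_primers + config.reverse_primers:
        for q in (p, trim_primer(p, config.primer_fraction)):
            pats += [q, reverse_complement(q)]
    return pats


def _unused_mid_pair(config: CleanConfig) -> Optional[tuple[int, int]]:
    """A tag index pair absent from the sample table in either order."""
    n = len(config.mids)
    for a in range(1, n + 1):
        for b in range(1, n + 1):
            if (a, b) not in config.sample_table and (b, a) not in config.sample_table:
                return a, b
    return None


def _window_has_primer(window: str, patterns: list[str], max_edits: int) -> bool:
    for pat in patterns:
        res = edlib.align(pat, window, mode="HW", task="distance",
                          additionalEqualities=_EQUALITIES)
        if res["editDistance"] <= max_edits:
            return True
    return False


def generate_clean_fixture(
    counts: dict[str, int],
    config: CleanConfig,
    seed: int = 0,
) -> tuple[str, str, pd.DataFrame]:
    """Emit synthetic reads with planted outcomes plus their truth table.

    ``counts`` maps intended outcomes (``clean``, ``fail_L1``,
    ``fail_mids``, ``fail_primers``, ``fail_L2``, ``fail_quality``) to
    read counts.  Clean reads rotate over the configured samples; about
    half of all anatomically intact reads are emitted reverse
    complemented.  Planted defects are screened (rejection sampling) so
    they cannot be rescued by a chance match.  Returns
    ``(fasta_text, qual_text, truth_table)``.
    """
    rng = np.random.default_rng(seed)
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative counts")
    unknown = set(counts) - {"clean", "fail_L1", "fail_mids",
                             "fail_primers", "fail_L2", "fail_quality"}
    if unknown:
        raise ValueError(f"unknown outcome(s): {sorted(unknown)}")

    sample_keys = [k for k in config.sample_table if k != (0, 0)]
    if not sample_keys and not config.no_mids:
        raise ValueError("config has no usable sample-table entries")
    mid_frags = _mid_fragments(config)
    primer_pats = _primer_patterns(config)
    r = config.search_range
    qlo = min(40, int(config.quality_threshold) + 10)
    bad_q = max(0, int(config.quality_threshold) - 3)

    def gene_length(overhead: int, short: bool = False, rng=rng) -> int:
        if short:
            l2 = config.min_l2 - 10
            if l2 < 1 or not config.min_l1 <= overhead + l2:
                l2 = config.max_l2 + 10
                if overhead + l2 > config.max_l1:
                    raise ValueError("cannot plant an out-of-range gene under these bounds")
            return l2
        lo = max(config.min_l2, config.min_l1 - overhead)
        hi = min(config.max_l2, config.max_l1 - overhead)
        if lo > hi:
            raise ValueError("length bounds leave no feasible gene length")
        return int(rng.integers(lo, hi + 1))

    reads: list[Read] = []
    rows = []
    serial = 0

    def emit(bases: str, quals: list[int], outcome: str, sample, gene, flipped: bool):
        nonlocal serial
        serial += 1
        rid = f"r{serial:04d}"
        if flipped:
            bases = reverse_complement(bases)
            quals = quals[::-1]
        reads.append(Read(rid, bases, quals))
        outcome = "pass" if outcome == "clean" else outcome
        rows.append({"read_id": rid, "expected_status": outcome,
                     "expected_sample": sample, "gene": gene,
                     "orientation": "antisense" if flipped else "sense"})

    full_mids = [m for mid in config.mids
                 for m in (mid, reverse_complement(mid))]

    def assemble(fw_mid: str, rv_mid: str, middle: str) -> str:
        """Adapters + tags around a middle; reject junction artifacts.

        A random adapter can, by chance, recreate a full tag spanning the
        adapter/tag junction closer to the read end than the planted tag,
        which would change the identified tag; redraw the adapters until
        no full tag outranks the planted ones.
        """
        for _ in range(100):
            bases = (_rand_seq(rng, _ADAPTER_LEN) + fw_mid + middle
                     + reverse_complement(rv_mid) + _rand_seq(rng, _ADAPTER_LEN))
            if not fw_mid:
                return bases
            # A clash is any full-tag occurrence reaching into an adapter:
            # everything else is either a planted tag or lies deeper in
            # the read than the planted tag and cannot outrank it.
            lo, hi = _ADAPTER_LEN, len(bases) - _ADAPTER_LEN
            clash = False
            for pat in full_mids:
                i = bases.find(pat)
                while i != -1 and not clash:
                    if i < lo or i + len(pat) > hi:
                        clash = True
                    i = bases.find(pat, i + 1)
                if clash:
                    break
            if not clash:
                return bases
        raise RuntimeError("could not draw clash-free adapters")  # pragma: no cover

    def build_intact(sample_key, fw_primer: str, rv_primer: str, l2: int):
        fw_mid = config.mids[sample_key[0] - 1] if sample_key != (0, 0) else ""
        rv_mid = config.mids[sample_key[1] - 1] if sample_key != (0, 0) else ""
        gene = _rand_seq(rng, l2)
        middle = fw_primer + gene + reverse_complement(rv_primer)
        return assemble(fw_mid, rv_mid, middle), gene

    order = ("clean", "fail_mids", "fail_primers", "fail_L2", "fail_quality", "fail_L1")
    for outcome in order:
        for i in range(counts.get(outcome, 0)):
            flipped = bool(rng.random() < 0.5)
            if outcome == "fail_L1":
                n = config.max_l1 + 10
                emit(_rand_seq(rng, n), list(rng.integers(qlo, 41, size=n)),
                     outcome, None, None, False)
                continue

            key = sample_keys[i % len(sample_keys)] if sample_keys else (0, 0)
            sample = config.sample_table.get(key)
            fw = _realize(config.forward_primers[
                int(rng.integers(len(config.forward_primers)))], rng)
            rv = _realize(config.reverse_primers[
                int(rng.integers(len(config.reverse_primers)))], rng)
            mid_len = 0 if config.no_mids else len(config.mids[key[0] - 1]) \
                + len(config.mids[key[1] - 1])
            overhead = 2 * _ADAPTER_LEN + mid_len + len(fw) + len(rv)

            if outcome in ("clean", "fail_quality"):
                l2 = gene_length(overhead)
                bases, gene = build_intact(key, fw, rv, l2)
                quals = list(rng.integers(qlo, 41, size=len(bases)))
                if outcome == "fail_quality":
                    gstart = _ADAPTER_LEN + (len(config.mids[key[0] - 1])
                                             if not config.no_mids else 0) + len(fw)
                    for p in range(gstart, gstart + l2):
                        quals[p] = bad_q
                    sample, gene = None, None
                emit(bases, quals, outcome, sample, gene, flipped)

            elif outcome == "fail_L2":
                l2 = gene_length(overhead, short=True)
                bases, _ = build_intact(key, fw, rv, l2)
                emit(bases, list(rng.integers(qlo, 41, size=len(bases))),
                     outcome, None, None, flipped)

            elif outcome == "fail_mids":
                if config.no_mids:
                    raise ValueError("cannot plant tag failures in tag-less mode")
                bad = _unused_mid_pair(config)
                if bad is not None:
                    # Intact tags whose combination is not in the sample
                    # table: unambiguous, no screening needed (full-tag
                    # matches always outrank chance inner fragments).
                    a, b = bad
                    mid_len = len(config.mids[a - 1]) + len(config.mids[b - 1])
                    overhead = 2 * _ADAPTER_LEN + mid_len + len(fw) + len(rv)
                    bases, _ = build_intact((a, b), fw, rv, gene_length(overhead))
                else:
                    # Every pair is legitimate: fall back to tag-free
                    # fillers screened against all tag fragments.
                    l2 = gene_length(overhead)
                    for _ in range(500):
                        gene = _rand_seq(rng, l2)
                        bases = (_rand_seq(rng, _ADAPTER_LEN) + _rand_seq(rng, 10)
                                 + fw + gene + reverse_complement(rv)
                                 + _rand_seq(rng, 10) + _rand_seq(rng, _ADAPTER_LEN))
                        w5, w3 = bases[:r], bases[-r:]
                        if not any(f in w5 or f in w3 for f in mid_frags):
                            break
                    else:  # pragma: no cover
                        raise RuntimeError("could not plant a tag-free read")
                emit(bases, list(rng.integers(qlo, 41, size=len(bases))),
                     outcome, None, None, flipped)

            elif outcome == "fail_primers":
                l2 = gene_length(overhead)
                fw_mid = config.mids[key[0] - 1] if not config.no_mids else ""
                rv_mid = config.mids[key[1] - 1] if not config.no_mids else ""
                for _ in range(200):
                    gene = _rand_seq(rng, l2)
                    filler = _rand_seq(rng, len(fw))
                    core = filler + gene + reverse_complement(rv)
                    if not _window_has_primer(core[:r], primer_pats,
                                              config.max_mismatches):
                        break
                else:  # pragma: no cover
                    raise RuntimeError("could not destroy the 5' primer")
                bases = assemble(fw_mid, rv_mid, core)
                emit(bases, list(rng.integers(qlo, 41, size=len(bases))),
                     outcome, None, None, flipped)

            else:  # clean handled above
                raise AssertionError(outcome)

    fa, qa = write_fasta_qual(reads)
    truth = pd.DataFrame(rows, columns=["read_id", "expected_status",
                                        "expected_sample", "gene", "orientation"])
    return fa, qa, truth
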