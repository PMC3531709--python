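# Methods

This note records the models and procedures `igclean` implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical and design choices made where the behaviour
was genuinely open.

## Read anatomy and the cleaning pipeline

A read is modelled as
`adapter + MID_fw + P_fw + gene + rc(P_rv) + rc(MID_rv) + adapter`,
delivered on either strand with equal probability. Two length scales are
checked: L1, the raw read length as delivered (adapters included), and
L2, the gene length strictly between the two primer spans. Both bounds
are inclusive (`minL1 ≤ L1 ≤ maxL1`, `minL2 ≤ L2 ≤ maxL2`); the quality
comparison is strict (`mean Q > threshold`), so a read at exactly the
threshold fails.

Stages run in a fixed order — L1, tags, primers, L2, quality — and a
read is routed to exactly one destination: the failure file of the first
stage it fails, or its sample's output pair. L1 failures share
`FailedInCheckLength.txt` with L2 failures (the log reports the two
counts separately); all failure files hold the original untrimmed reads
for forensics. Sample outputs hold the gene region only, with its
quality slice, reverse-complemented (and scores reversed) to sense
orientation so downstream alignment sees one strand.

### Tag (MID) identification

Tags are plain-ACGT barcodes, 10 nt in the supplied basic set. The
search window is the first/last `search_range` bases (default 50). A
full perfect match of any tag or its reverse complement always wins;
only if no full match exists is the window re-scanned for the perfect
gene-proximal inner fragment of length `min_mid_len` — the suffix of the
matched pattern at the 5′ end, its prefix at the 3′ end. This mirrors
the empirical error profile of pyrosequencing, which damages read
boundaries: the outer tag end may be truncated, the inner end is
trustworthy. When several matches coexist, the hit closest to the read
end wins, ties broken sense-before-antisense, then lower tag index
(the published tag sets never tie; the rule only pins down degenerate
configurations).

A legitimate amplicon shows the 5′ tag in sense and the 3′ tag in
antisense orientation on *both* strands, so orientation alone does not
reveal the strand; the primers do. The tag stage therefore fails a read
early only when neither ordered index pair `(i5, i3)`/`(i3, i5)` is in
the sample table, takes the first matching order as the tentative sample
for per-sample accounting, and re-resolves the ordered pair once the
primer stage fixes the gene orientation. With disjoint forward/reverse
tag roles (the usual design) the two lookups agree.

The distinguishability diagnostics treat a tag set as the 2n strings
{length-k suffix of each tag} ∪ {reverse complement of each suffix}:
the minimal distinguishing inner length is the smallest k making these
pairwise distinct, which also guards against cross-orientation
collisions. For the basic nine-tag set this gives 5, with minimum
pairwise Hamming distance 6.

### Primer identification

Primers may carry IUPAC degeneracies; a read base matches a primer code
when it lies in the code's expansion. An `N` called in a read matches
only the primer code `N`, so low-quality calls cannot inflate matches.

Stage 1 scans each end window for a perfect degeneracy-aware match of
every forward and reverse primer and their reverse complements. Stage 2,
per side lacking a perfect hit, trims each primer from the side furthest
from the gene to `ceil(fraction · len)` bases and seeks the best *infix*
occurrence under a unit-cost edit model (substitution/insertion/deletion
1, degeneracy-compatible pairs 0), accepted iff the minimum edit count
is ≤ `max_mismatches`. The acceptance criterion is an edit budget, so
the partial match is formalized as bounded semi-global (pattern-infix)
edit distance rather than a similarity score with free parameters; the
dynamic programme is exact, and ties between optimal spans resolve
toward the window's outer edge, then the shortest span. Trimming uses
the optimal span, not the nominal primer length.

A result needs one forward and one reverse primer on opposite ends.
Hits sharing a strand orientation mark the read as a putative PCR
chimera (failed at the primer stage); one primer type on both ends in
opposite orientations is likewise rejected. The forward primer's strand
fixes the gene orientation. When several primers fit one side, fewer
edits win, ties by forward-before-reverse, then lower primer index.

### Quality model

Per-base scores are integers 0–40. A read's score is the arithmetic mean
over the *gene* bases (tags and primers removed); a sample's score is
the mean of its reads' means, not the pooled per-base mean. Summaries
also report per-read minima, which drive the choice of the point-
mutation threshold in the classifier.

## Clone model and indel classification

A clone is a germline (or consensus) row plus member rows of equal
aligned length; `-` is the gap. Degapping a member row reproduces its
read. Consensus construction votes per column over {A, C, G, T, -} with
the fixed tie order A < C < G < T < -, so nucleotides beat the gap; the
gap competes because clone alignments genuinely contain gap-majority
columns.

Event extraction walks member vs germline position by position: each
maximal gap run is one indel (gap in germline ⇒ insertion, gap in member
⇒ deletion), each non-gap mismatch one mutation; columns where both rows
hold gaps belong to other members' insertions and are ignored (they also
terminate runs, keeping column intervals comparable across members).

Homopolymer tracts are maximal same-base runs detected on the degapped
germline row, which is the common coordinate system of the clone.
"Near" a tract means: any deleted germline position inside the tract or
at either immediately flanking position; for insertions, an insertion
point touching the tract (just before its start, inside, or just after
its end). Adjacency at distance one is the minimal reading consistent
with the polymerase slippage mechanism; more distant events are not
attributed to the tract.

The per-sequence ruling, walking events in alignment order:

* indel not near a tract of length ≥ `min_hpt_len` → legitimate;
* near a tract and shared by ≥ `min_share` members (carrier included;
  sharing = same kind and identical column interval, so same-column
  deletions of different lengths stay distinct) → legitimate;
* near, under-shared, clone size 1 → mark *uncertain* and continue;
* near, under-shared, clone size > 1 → *artifact*, terminal.

When `min_qual ≥ 0`, mutations with base quality < `min_qual` are kept
if inside an `AACA`/`TGTT` occurrence on the germline, kept in singleton
clones, and otherwise discarded (*low-quality mutation*, terminal) when
shared by < `min_share` members (same column and substituted base). The
first terminal event decides the class; otherwise uncertainty, then the
presence of any indel, then "without indels". `min_qual = -1` disables
mutation screening. The four outputs partition the input: clean +
legitimate sequences, uncertain singletons, artifact indels, low-quality
mutations.

Defaults `min_share = 2` (the base rule: no *other* member shares the
event) and `min_hpt_len = 2` (deliberately broad — pairs are everywhere,
but checking more indels beats keeping artifacts; 2 or 3 are the
sensible settings, since tracts longer than ~5 are rare in V-region
sequence and larger minima blind the classifier to most real errors).

## Simulators

### Deletion injection

Per clone member, with probability `p_del` (default 0.5): draw a tract
length uniformly from [2, 10] restricted to lengths actually present in
the member (equivalent to redrawing until present, but terminating);
pick one maximal tract of exactly that length uniformly; pick the
deletion position uniformly among the tract's interior plus its two
flanks, never the first or last base; replace that base with `-`; then
append 0–10 identical duplicate copies (uniform). Every injected
deletion is an artifact by construction, so the classifier's
identification fraction against the truth table is a direct accuracy
measure, and the truth records (drawn length, position, placement,
duplicate count) support stratified analysis.

Two sites in one clone are never injected twice: a collision would make
two independent artifacts look like a shared — hence legitimate — indel
and silently corrupt the truth labels. Insertions are not injected;
classification treats the two kinds symmetrically, so deletions suffice
to exercise every rule.

### Synthetic clones

Clone sets mix singletons (30%) with geometrically distributed larger
clones (sizes 2–40, mean ≈ 6), germlines are uniform random sequences of
150–300 nt, and members differ from the germline only by point
substitutions (rate 0.01/nt) placed at isolated positions — both
neighbours differ from the site, and the substituted base differs from
both neighbours. This construction makes every member's homopolymer
tract structure identical to the germline's, so a deletion injected
relative to a member tract is always tract-proximal in germline
coordinates and the truth labels are exact. Real somatic hypermutation
does create and destroy tracts; passing tests therefore certify the
classifier's rules, not its behaviour on tract-altering mutations, which
is inherently ambiguous ground truth.

### Synthetic reads

The read generator assembles anatomically correct amplicons from a run
configuration (tags, realized degenerate primers, uniform random genes
sized to satisfy both length bounds, flat high qualities), flips about
half of them to the antisense strand, and plants one defect per
requested failure mode: raw length outside bounds; a tag pair absent
from the sample table (falling back to screened tag-free fillers when
every pair is used); a 5′ primer replaced by filler verified — with an
independent alignment library — to exceed the edit budget against every
trimmed primer; a gene 10 nt below `minL2`; gene qualities pinned 3
below the threshold. Random adapters are redrawn whenever a full tag
occurrence would reach into an adapter region, since such junction
artifacts could outrank the planted tag. The generator emulates read
anatomy and the pipeline's decision boundaries, not the 454 flowgram
error process; quality profiles are flat, errors are planted rather than
drawn from an error model, and adapters are random 6-mers.

## Problem sizes and numerics

The test suite and the acceptance script run the cleaner on 1,000
generated reads (600 clean, 80 per failure mode), verify the bounded
infix edit search against substring enumeration on 500 random
window/pattern pairs (windows 25–60 nt, patterns 8–18 nt over a
degenerate alphabet), the tract scanners against naive scans on 1,000
random strings, and the classifier on ~500-sequence simulated clone
sets, sweeping the 4 × 12 grid of `min_hpt_len` ∈ [2, 5] ×
`min_share` ∈ [1, 12]. These sizes exercise every code path while
keeping a full run in tens of seconds. Monotonicity of the grid holds
exactly (not statistically): raising `min_share` can only grow, and
raising `min_hpt_len` only shrink, the artifact set on fixed inputs.

Degenerate inputs: empty quality lists cannot be averaged (zero-length
reads are excluded from summaries and reported); an empty tag list
switches the cleaner to single-sample mode keyed by `(0, 0)`; clones
with one member never lose sequences to the sharing rules. All
randomness flows from explicit seeds through one generator per run, so
every output is reproducible byte for byte.

## Known limitations

* The tentative-sample rule at the tag stage can, for pathological
  tables containing both orders of one tag pair, attribute a primer-stage
  failure to the wrong sample; the read is still counted exactly once.
* Chimera detection sees only same-orientation primer pairs and the
  length bounds; template switches between homologous V segments pass.
* The germline row of a PIR alignment is recognized by the `GL` name
  prefix (first row as fallback) — a convention, since alignment tools
  do not mark the reference row.
* The classifier flags artifacts; it does not correct them, and it
  assumes the clone grouping and alignment it is given are right.
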