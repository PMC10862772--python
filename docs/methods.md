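# Methods

## Model and assumptions

`graphsv` treats a series of long-read metagenome samples as repeated
observations of one community on a shared coassembly graph. The central
assumption is that a substantial fraction of strains is shared across
samples, so that shared sequence collapses into common graph nodes and
structural variants (SVs) appear as characteristic local topologies whose
*coverage* — not merely presence — changes between consecutive samples:

- an indel leaves a bubble: two flank nodes joined both directly and
  through a variant node (a triangle in the collapsed graph);
- a deletion-plus-insertion at one locus leaves two parallel variant paths
  between the flanks (a 4-cycle);
- a tandem duplication leaves a self-loop, or a two-node loop expressed as
  a weight-2 parallel edge.

Calling on the log fold change (lfc) between *consecutive* samples, rather
than on raw coverage or presence, is what suppresses false calls from
assembly artefacts (which persist across samples and hence have lfc ≈ 0)
and from whole-genome abundance shifts (which move a genome's flanks and
variants together, and the outlier rule is location-invariant).

A call therefore asserts an SV *increasing or decreasing in abundance*
between two specific samples — a variant present at constant frequency
throughout the series is deliberately not called.

## Graph collapse

The GFA's oriented links are canonicalised under reverse-complement twin
equivalence: the link (a, o1) → (b, o2) and its twin (b, ¬o2) → (a, ¬o1)
describe the same double-stranded junction and count as one edge
occurrence. Without this deduplication nearly every adjacency would reach
weight 2 and trigger the parallel-edge duplication rule. Remaining distinct
links between the same node pair accumulate as integer edge weight. By
default each segment is one node (modern long-read assemblers store one
record per double-stranded sequence); an explicit pairing map can merge
assembler-emitted complement records into single nodes.

## Coverage, floor, normalization

Node coverage is mean depth per bp from GAF path intervals (terminal path
segments clipped by the alignment's path offsets, interior segments full).
Coverage below 1 is floored to 1 — reads absent at one time point would
otherwise produce undefined log ratios, and depth < 1 is within noise for
long-read data anyway. Flooring happens before *and* after normalization so
the floor survives rescaling.

Normalization multiplies each sample's node coverage by m / bp_n, where
bp_n is the sample's total aligned read bases (summed GAF read lengths of
mapped records) and m their median across the series. This equalises
sequencing depth: a sample sequenced twice as deeply is scaled down by ~2.
The reciprocal multiplier bp_n / m is available as `reciprocal` mode,
and `none` disables rescaling; only the default removes depth differences,
which is the stated purpose of the step. Because any per-sample multiplier
shifts all of that step's node lfc values by the same constant, and the
outlier rule is location-invariant, the normalization mode cannot flip a
motif call — it matters for the Bandage visual overlays and coverage dumps.

Edge coverage (traversal counts) is left unnormalised and floored at 1 only
when entering the log ratio; the duplication threshold is an absolute
fold-change criterion on counts.

## Calling parameters

| parameter | default | meaning |
|---|---|---|
| `log_base` | 2 | lfc units; thresholds like "> 1" then mean "more than doubled" |
| `floor_value` | 1 | minimum node coverage (mean depth per bp) |
| `normalization_mode` | `median_ratio` | m/bp_n; `reciprocal` = bp_n/m; `none` |
| `sd_mode` | `population` | sd denominator n; `sample` uses n−1 |
| `min_mapq`, `min_read_length` | 0 | optional GAF record filters (off by default) |

Population sd is the default because with three values the sample-sd form
can never place two values beyond one sd of the median, which would make
the square rule's two-outlier branch unreachable; both conventions are
exposed.

## Numerical choices

- **Outlier rule**: strict inequalities throughout (|v − median| > sd; edge
  lfc > 1). The median of four values is the mean of the middle two.
- **Machine-noise guard**: a deviation must also exceed 1e-9 to count as an
  outlier. Mathematically identical lfc values (e.g. three flanks whose
  ratios cancel exactly) differ by ~1e-16 after floating-point
  normalization; without the guard the motif sd is ~1e-16 and round-off
  itself becomes an "outlier". 1e-9 is many orders of magnitude below any
  real coverage signal.
- **Ties** in parallel-edge duplication endpoint selection (equal node
  lfc): the lexicographically smaller node id is called, for deterministic
  output.
- **Precedence**: triangles and squares are called before duplications;
  a parallel-edge duplication is suppressed on a node already called at
  that step. Self-loop duplications are unconditional.
- **Deduplication**: a (called-node-set, type, step) combination appearing
  in several motifs is reported once, keeping the motif with the largest
  |outlier − median| and recording the agreement count; raw per-motif
  instance counts are kept in the run summary because published SV counts
  from this family of methods may be per motif instance rather than per
  node.
- Squares may share edges with called triangles and may carry chords;
  no exclusion is applied (the rule set defines none).

## Synthetic fixtures

The generator builds backbone chains (default 1000–5000 bp segments at
mean depth 10) with motifs implanted at disjoint two-flank slots, then
emits GAF reads realising the requested depths: single-node reads tiled so
mean depth lands within half a read of target, plus junction reads walking
self-loops/parallel edges to realise traversal counts exactly. Requested
depth for motif-junction nodes includes the junction-read contribution.
Implanted changes are step functions (they persist after the event step),
so each event is visible at exactly one step pair. Optional per-node
lognormal depth noise (sd of the log given by `noise_sd`) perturbs
realised depths; the default is noiseless.

Two preset designs mirror published simulation layouts at graph level:

- **hgtsim**: 10 donor + 10 recipient genomes; one gene per donor inserted
  into every recipient = 100 insertion events over one step pair; equal
  pre-transfer abundances, post-transfer relative quantities drawn from
  {1..5} per species (flanks shift with their genome; inserted genes appear
  from zero coverage). The m0/m30 mutation-rate labels differ only in
  inserted-sequence identity, which has no graph-level counterpart here, so
  both map to the same design.
- **zymo**: 10 genome backbones × (20 indels + 10 tandem duplications + 10
  complex indels) = 400 events, variant segment lengths 500–2000 bp; half
  the genomes are variant-only after the event (variant depths swing fully)
  and half are 50/50 mixtures (depth shifts halved). Genome relative
  abundances are uniform by default and config-driven.

**What the fixtures do not emulate**: read-level error, chimeras, assembler
graph errors (collapsed or fragmented variants), repeat-induced spurious
topology, off-graph alignments, and abundance drift within a genome. So
perfect recall/precision on these fixtures demonstrates the calling logic
is correct given a faithful graph and alignments — it does not bound
performance on real assemblies, where a large share of variants is known to
collapse into single nodes before calling can begin. The full-scale route
(raw reads through external `flye --keep-haplotypes` assembly plus
`minigraph` alignment) is wired into the CLI for that purpose and is
exercised only where those binaries are installed.

## Known limitations

- Inversions and translocations are out of scope: they would require
  keeping node directionality through collapse.
- Overlapping or nested SVs at one locus are not resolved; the motif rules
  assume locally isolated events.
- Samples are snapshots: oscillations between sampling points are
  invisible, and the method needs ≥ 2 samples (N ≥ 1 step pairs).
- On highly diverse communities the motif census can be enormous and most
  lfc fluctuations pass the one-sd rule; counts should then be read as a
  screening signal, not a curated call set.
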