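# Methods

This note records the models, parameter choices and numerical decisions
behind `longte`, and what the synthetic benchmarks do and do not
demonstrate.

## Problem setting

A non-reference TE insertion is a transposable element present in the
sequenced sample but absent at that locus in the reference genome. In a
polyploid sample an insertion may sit on any subset of haplotypes; the
quantity of interest beyond the locus itself is the intra-sample TE
allele frequency (TAF) — the fraction of local haplotype dosage carrying
the insertion — and its integer counterpart, the allele copy number. An
insertion on k of p haplotypes has expected TAF k/p; haplotype-specific
insertions in a tetraploid (TAF ~0.25, copy number 1) are the signature
of transposition that post-dates genome duplication.

## Detection model

Reads are aligned with minimap2 (`map-pb` preset, soft-clipped
supplementary alignments, no secondary alignments). Three per-read
insertion signals are collected: CIGAR insertion operations >= 100 bp;
split-read pairs of the same read that are adjacent on the reference
(|reference gap| <= 100 bp) but gapped on the query by >= 100 bp; and
soft clips >= 500 bp, used only for reads contributing no
sequence-level signal. Signals within 100 bp (single linkage) form a
cluster; clusters with >= 5 distinct reads and at least one recoverable
inserted sequence become candidates at the median signal position, with
the inserted sequence from the read with the longest inserted segment.

Defaults (minimum SV length 100 bp, support 5, cluster window 100 bp)
target multi-hundred-bp TE insertions at >= ~25x coverage; all are
configurable. Candidates pass to assembly only if the TE library masks
>= 10% of the inserted sequence (union of per-family local alignments,
both strands; the library is aligned one family at a time so short
nested hits are not suppressed as secondary chains of the dominant
family). A second family over the threshold sets a `nested` flag; the
dominant family is the one with the largest masked span.

A Sniffles-dialect VCF can replace the internal caller: records are
kept iff SVTYPE=INS and a sequence is recoverable from ALT or INFO/SEQ;
records without INFO/RNAMES are kept with an empty read set and
supporting reads are re-collected by signature overlap near the
breakpoint.

## Local assembly and polishing

The assembler is deliberately minimal and deterministic: the supporting
read that spans the insertion with the widest flanking anchors (>= 500
bp preferred, >= 100 bp required) becomes the contig backbone in
reference-forward orientation. Polishing (default one round) re-aligns
all supporting reads to the contig and takes a column-wise consensus:
the majority base wins (ties keep the current base), a majority of
deletions removes the column, and an insertion seen in more than half
of the covering reads is spliced in. Including indels in the vote is
what lets a single noisy backbone reach >= 99% identity under an
indel-dominant error model; a substitution-only vote cannot remove
backbone indels. Positions with no read coverage keep the backbone
base.

## Breakpoint and TSD resolution

The TE library aligned to the contig delimits the TE interval (union of
the dominant family's hits); the flanks are the residual contig ends.
Each flank's best reference placement is taken from base-level minimap2
alignments; a second placement scoring within 5% of the best flags the
flank as ambiguous (repeat-region protection). Junction coordinates are
clip-adjusted (unaligned flank tail lengths are added back), so exact
flank ends are recovered on clean data.

With both flanks placed on the same contig and strand: an overlap o
with 0 < o <= 20 bp defines a TSD of length o and the insertion
interval; o = 0 gives a zero-length interval at the junction; a gap g
with 0 < g <= 20 bp gives the interval with no TSD; larger overlaps or
gaps are retained in a diagnostics file with `overlap_exceeded` /
`gap_exceeded` status but excluded from the main call set. Flanks on
different contigs or in inconsistent orientation reject the candidate —
precision is preferred over recall in repeated regions. All internal
coordinates are 0-based half-open; VCF POS (1-based base before the
interval) is produced only at the I/O boundary.

## TAF and allele copy number

Reads overlapping the breakpoints ±1 kb are re-aligned to the polished
contig twice: forward for the 5′ junction, and against the reverse
complement for the 3′ junction, because clipped and spanning reads
beyond a 3′ junction are under-reported in forward orientation. Each
junction contributes a flank-side and a TE-side mean depth over 100 bp
windows immediately adjacent to the junction (the window shrinks, with
a flag, if a flank or the TE is shorter); spanning reads count at both
junctions. TAF is the mean of the two TE/flank depth ratios. The window
length is a measurement choice, not from the underlying method
description: long enough to damp per-base alignment jitter, short
enough to stay within the flanks.

A single zero-coverage flank falls back to the one-sided ratio
(`one_sided_taf` flag); both zero leaves TAF undefined — explicitly
distinct from TAF = 0, and such calls are excluded from TAF-dependent
analyses. The reported `taf` is clamped to [0, 1], but the unclamped
`raw_taf` is kept and used for the copy-number product, since clamping
before multiplication would bias dosage under coverage noise. Allele
copy number is round(raw_TAF x local CN) with ties rounded half away
from zero (symmetric, no bias toward even dosages). Local CN is the
length-weighted mean dosage over the two 1 kb windows flanking the
insertion interval (the interval itself excluded); profile gaps and
absent contigs use a configurable default ploidy.

## Expansion phylogenetics

Calls are filtered to high-quality full-length sequences: assembled TE
length / canonical length within per-family bounds (default 0.95–1.05,
with a relaxed 0.75–1.05 override for the internally-deleted *297*
family), both flanks mapped, TAF estimated, optional region mask and
contig exclusions. Every rejection reason is tallied.

Alignment uses MAFFT when available or a built-in centre-star
progressive aligner (edlib pairwise global alignments against the
minimum-total-distance centre, merged gap-compatibly). Trimming removes
spurious rows: a residue's overlap score is the fraction of other rows
with the same character at that column (gap matching gap), and a row is
kept iff >= 80% of its residues score >= 0.75. Same-character (rather
than residue-presence) matching is used because it is the semantics
under which an undiverged family alignment retains all rows while an
unrelated sequence is removed even when the alignment is gap-free.

Trees are neighbor joining on p-distances (pairwise mismatch fraction
over shared non-gap columns) with nonparametric column-resampling
bootstrap (default 100 replicates); support is per bipartition, so it
is invariant to rooting. All-identical alignments yield a flagged star
tree with undefined supports. External ML engines can substitute at the
same interface; the built-in tree is what the test suite and benchmarks
exercise.

Expansion classification roots the tree at the midpoint (or a supplied
outgroup) and tests every non-root internal node: >= 3
cell-line-specific insertions (designated sample, allele copy number
1), proportion of such insertions >= 20%, bootstrap >= 50%. Only
maximal qualifying clades are reported, which makes "number of source
lineages" well-defined when nested nodes qualify; the root itself is
excluded as trivially containing everything. Trivial bipartitions
(present in every possible tree) are assigned support 100.

## Synthetic data

The simulator emulates the target study conditions: a uniform-random
reference (homopolymer runs capped at 20 bp to avoid degenerate
alignment), ploidy 1–4, insertions placed >= 2 kb from the ends and
>= 2 read lengths apart, drawn without replacement; each insertion gets
a family, strand, family-specific TSD (duplicated exactly) and a random
carrier subset of the requested size. Reads follow a log-normal length
distribution (PacBio-like; mean 8 kb, sd 5 kb by default) truncated at
[500 bp, haplotype length], with i.i.d. per-base errors split 60%
insertion / 20% deletion / 20% substitution and depth divided equally
across haplotypes. Everything is deterministic per seed.

TE lineages for the phylogenetics benchmarks evolve a canonical
sequence along a rooted newick topology under Jukes–Cantor
substitution. The expansion fixture builds a two-sided topology whose
deep central split separates source clades: each side holds an
expansion clade (5 cell-line leaves, ~0.5% divergence, copy number 1)
and/or outgroup copies from other samples (~4–8% divergence) —
divergence levels chosen to resemble within-family TE variation.

What the simulator does **not** model: chimeric reads, GC or coverage
bias, reference TEs, non-TE structural variants, indel evolution in the
lineage simulator, recombination between TE copies. Passing benchmarks
therefore demonstrate the correctness of the algorithms under the
stated read model, not performance on real libraries with degenerate,
truncated or nested reference TEs.

## Benchmark scale and expectations

The headline benchmark (tests and `scripts/acceptance.py`) uses a 2 Mb
reference, tetraploid, 40 insertions from six families with carrier
counts cycling 1–4, ~125x total coverage (~31x per haplotype) and 9%
indel-dominant error — a desk-scale genome with the coverage, ploidy
and error profile of the motivating application. On it the pipeline
reaches ~100% precision and >= 90% recall with one-to-one ±10 bp
family-aware matching, class-mean TAF within ±0.10 of k/4 and >= 90%
exact integer copy number. Per-call TAF carries junction-sampling noise
of roughly ±0.1 at ~30x per haplotype; accuracy statements are about
class means. Expansion-clade recovery is exact for 1 vs 2 source
lineages in >= 95 of 100 seeded replicates.

## Known limitations

- The backbone+consensus assembler requires at least one read spanning
  the insertion with flanking anchors; very long TEs relative to read
  length reduce recall (no OLC assembly of partially spanning reads).
- Nested or composite insertions are flagged, not reconstructed.
- TSD lengths above the 20 bp overlap threshold are reported
  unresolved by design.
- TAF has no confidence interval; copy-number segmentation is consumed,
  never estimated.
- The greedy smallest-offset truth matching in `evaluate` equals
  optimal one-to-one matching when loci are separated by more than the
  match window (the simulator guarantees this), but can differ on
  adversarial overlapping configurations.
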