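# longte

Detection, local assembly, intra-sample allele-frequency estimation and
expansion phylogenetics of **non-reference transposable-element (TE)
insertions** from long-read sequencing data — without a whole-genome
assembly.

Complex genomes (polyploid cell lines, highly heterozygous samples)
resist de novo assembly, yet their TE landscapes are exactly what one
wants to study. `longte` works directly from reads: it finds insertion
signals in read-to-reference alignments, assembles a polished local
contig per insertion, resolves the breakpoint and target-site
duplication (TSD) on reference coordinates, and estimates what fraction
of the sample's haplotypes carry each insertion.

## Method

The pipeline has four stages:

1. **Detect** — long reads are aligned to the reference (minimap2);
   per-read insertion signatures (large CIGAR insertions, split-read
   pairs, long clips) are clustered into candidates, which are kept only
   if the inserted sequence has hits to a curated TE library.
2. **Assemble** — each candidate's supporting reads yield a local
   contig (best spanning read as backbone, then column-wise consensus
   polishing against all supporting reads).
3. **Annotate** — the TE library is aligned to the contig to delimit
   the TE interval, family and strand; the flanking sequences are
   re-mapped to the reference. If the flank placements overlap by
   `o <= 20` bp the overlap is the TSD and the insertion interval; a gap
   `g <= 20` bp defines the interval with no TSD; larger overlaps/gaps
   are reported unresolved.
4. **Quantify** — reads within 1 kb of the breakpoints are re-aligned
   to the contig (forward, then reverse complement for the 3′ junction)
   and the TE allele frequency is

   ```
   TAF = (5p_te_cov / 5p_flank_cov + 3p_te_cov / 3p_flank_cov) / 2
   ```

   where each term is mean read depth over a 100 bp window on the TE /
   flank side of a junction. With local copy number `CN` (from
   copy-number segments, e.g. Control-FREEC output, or a default
   ploidy), the integer **allele copy number** is `round(TAF x CN)`.

A phylogenetics module filters calls to high-quality full-length TE
sequences (per-family length-ratio bounds, both flanks mapped, TAF
estimated, optional region mask), aligns each family (MAFFT or a
built-in centre-star aligner), removes spurious rows (overlap-score
trimming), builds bootstrapped neighbor-joining trees, and classifies
family expansions as **single- or multi-source**: a source lineage is a
maximal monophyletic clade with >= 3 cell-line-specific insertions
(allele copy number 1), >= 50% bootstrap support and >= 20% such
insertions among its members.

A simulator generates polyploid genomes carrying TE insertions with
family-specific TSDs on chosen haplotype subsets, PacBio-like reads
(log-normal lengths, indel-dominant errors), diverged TE lineages, and
machine-readable truth tables, so the whole pipeline is testable without
external data.

## Worked example

Simulate a small diploid genome with two TE insertions (one
heterozygous, one homozygous), run the pipeline, and score it:

```bash
longte simulate --outdir sim --reference-length 60000 --ploidy 2 \
    --n-insertions 2 --depth 20 --error-rate 0 --read-length-mean 5000 --seed 3
longte run --reads sim/reads.fq --reference sim/reference.fa \
    --te-library sim/te_library.fa --outdir run --default-ploidy 2
longte evaluate --calls run/calls.jsonl --truth sim/truth.json
```

The run reports `2 resolved calls, 0 unresolved` and `run/calls.bed`
contains:

```
chr1  13649  13654  chr1_13649  0  +  copia  5  0.4967  1  resolved
chr1  56997  57002  chr1_57002  0  -  copia  5  1       2  resolved
```

Each line is an insertion locus (0-based half-open interval = the TSD),
strand, family, TSD length, estimated TAF, allele copy number and
breakpoint status: the first insertion is carried by one of the two
haplotypes (TAF ~0.5, copy number 1), the second by both (TAF 1, copy
number 2). `longte evaluate` prints `precision: 1.0, recall: 1.0`
against the simulator truth.

## Layout

| module | role |
| --- | --- |
| `longte.simulate` | synthetic genomes, reads, TE lineages, truth tables |
| `longte.detect` | stage 1: candidates from alignments or Sniffles VCF |
| `longte.assemble` | stages 2–3: local contig, polish, annotate, TSD |
| `longte.quantify` | stage 4: junction coverage, TAF, allele copy number |
| `longte.phylo` | full-length filter, MSA, trees, expansion clades |
| `longte.evaluate` | truth matching, precision/recall, TAF accuracy |
| `longte.io` / `longte.pipeline` / `longte.cli` | formats, orchestration, CLI |
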