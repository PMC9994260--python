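# Methods

## The measurement model

A-to-I editing converts a fraction of the RNA molecules of a transcript at a
given adenosine. In a strand-specific dUTP-type library the sequenced read
is the reverse complement of its transcript fragment, so reads align
antisense to their gene; for a plus-strand gene the editing signature is a
G call at a reference-A position, for a minus-strand gene a C call at a
reference-T position. The per-site editing fraction

    f = n_alt / (n_ref + n_alt)

(alternate and reference base calls in transcript orientation) is an
unbiased estimator of the per-molecule editing rate, because each read
descends from exactly one molecule and molecules are edited independently.
N calls enter neither numerator nor denominator.

The transcriptome-wide rate of a substitution class X→Y aggregates over all
qualifying positions as Σ n_Y / Σ (n_X + n_Y), i.e. the coverage-weighted
mean of the per-site fractions (an exact arithmetic identity, asserted in
tests). "Qualifying" means: inside an annotated non-rRNA gene, transcript
base X, coverage at or above the expressed threshold. A per-position
(unweighted) mean can be derived from the site table; the weighted form is
what the pipeline reports because it is the maximum-likelihood pooled rate
under the binomial model.

## Read filtering

Rules, applied in a fixed order (unmapped → rRNA overlap → multi-mapper →
indel → strand/assignment), each read counted once under its first failing
rule:

* **rRNA**: overlap with an annotated rRNA gene on *either* strand discards
  the read — rRNA exclusion is positional, not strand-qualified.
* **multi-mapper**: hit-count tag (NH) > 1 or MAPQ = 0; an optional MAPQ
  threshold covers aligners that encode ambiguity only in MAPQ. A read whose
  sequence occurs at several genomic positions cannot attribute its
  mismatches to a single locus.
* **indel**: any I or D CIGAR operation. Soft clips do not discard a read;
  clipped bases are simply not piled up.
* **strand/assignment**: the read must align antisense to at least one gene
  (dUTP protocol contract). No gene overlap → `unassigned`; overlap but no
  antisense gene → `wrong_strand`; two antisense candidates (a read spanning
  the gap between adjacent same-strand genes) → `ambiguous`, not kept. The
  assignment policy (`any_overlap` default, `full_overlap` optional) affects
  only which gene a boundary read is attributed to, not the pileup counts.

The rule order is an accounting convention only: the kept set is the
intersection of all rules and does not depend on the order. Mates of paired
data, if supplied, are treated as independent single-end reads.

## Site calling

The experimental readout behind the pipeline reports raw mismatch
frequencies; to make a statement like "a given fraction of adenosines is
unedited" operational, the package adds an explicit calling rule. Each
expressed adenosine position is tested with an exact binomial upper tail,
P(X ≥ n_alt | n_ref + n_alt, background), and Benjamini–Hochberg adjustment
across all tested sites; a site is called edited when q ≤ 0.05 and
f exceeds the background. The background defaults to the median of the 11
non-A→G class rates — self-calibrating against the library's error
footprint, and analytically equal to error_rate/3 under the simulator's
uniform error model. A constant override is available for libraries whose
error profile is known. Degenerate case: if all non-A→G classes are exactly
zero (error-free data), the background is 0 and any alternate call becomes
significant; with error-free data there are no spurious alternate calls, so
this is harmless, but real data should always carry a nonzero background.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: a small host
genome plus a phage contig, rRNA/tRNA/mRNA genes with expression weights, a
dUTP strand-specific single-end protocol, uniform per-base substitution
error, multi-mapping decoy regions, and Bernoulli per-molecule editing.
Defaults and their rationale:

* **read length 75 bp, constant Q30** — short-read bench-top sequencer
  profile; constant quality keeps the error model uniform.
* **error rate 0.001 per base, uniform over the three alternates** — typical
  post-filter substitution-error scale; uniformity makes the background of
  every mismatch class exactly error_rate/3, giving a closed form the tests
  check against.
* **mean depth 50×** at expression weight 1.0; a gene's depth is
  mean_depth × weight, so weights read directly as relative abundance.
  Per-gene read counts are deterministic (rounded expectation), so coverage
  differences between runs come only from fragment positions.
* **rRNA weight 5, tRNA weight 5** — residual rRNA after depletion remains a
  prominent library fraction (~20–30% here), and tRNAs are abundant; the
  tRNA weight also gives the positive-control site the high coverage a
  TadA/argQ-style signal has in real data.
* **editing is Bernoulli per molecule, before fragmentation** — reads from
  one molecule share the edit, and the per-site estimator's target is
  exactly the injected rate. One read is emitted per molecule (uniform
  start), which satisfies the shared-edit contract trivially while keeping
  the truth tally an exact Binomial(n_molecules, rate) draw.
* **decoys** — a gene's sequence is copied into intergenic space without
  annotation; reads from the source gene are truth-flagged multi-mapping
  (MAPQ 0, NH = copies + 1), exercising both aligner dialects.
* **indels** — a configurable fraction of reads carries a 1-bp insertion or
  deletion; these reads exist to be discarded by the filter.
* reads are wholly contained in transcripts (bacterial genes are
  intronless); no junctions, no UMIs, no paired ends.

What the simulator does **not** model: position- and context-dependent error
profiles, quality-score decay along the read, coverage biases (GC,
fragmentation, 3′/5′ end effects), true alignment uncertainty (truth
alignments are exact), and transcript-boundary read-through. Passing tests
therefore validate the pipeline's bookkeeping and statistics under a clean
generative model, not robustness to real-library artefacts; on real data the
background estimate absorbs a uniform error floor but not context-specific
artefacts (e.g. damage-induced G>T clusters).

## Numerical and design choices

* Coordinates are 0-based half-open internally; 1-based only in
  GFF3/SAM/locus files and TSV outputs.
* The expressed-position threshold (coverage ≥ 10) is a surfaced parameter:
  "expressed" has no canonical quantitative definition, and the choice
  trades the number of testable positions against estimator variance.
* min_base_quality defaults to 20; the constant-Q30 simulator is unaffected,
  real data gets a conventional cutoff.
* Binomial tails come from scipy (`binom.sf`), BH from statsmodels; counts
  are cast to signed integers before the k−1 tail shift (the pileup matrix
  is unsigned).
* The pileup takes a vectorised path for pure-match CIGARs and a
  pysam aligned-pairs walk otherwise; both are checked against a naive
  nested-loop counter.
* Timepoints are opaque ordered labels in minutes (0 = uninfected); no trend
  model is fitted across them.
* Host and phage contigs are processed identically; summaries can be
  stratified by contig via the site table.
* Sample-level simulation seeds are derived from the run seed through
  `numpy.random.SeedSequence`, keeping samples independent and the whole run
  reproducible from one integer.

## Problem sizes used in validation

The validation suite runs null control/treatment experiments at 200 mRNA
genes (250 bp) + 2 rRNA genes, 50× depth, 20 seeds for the null headline;
a single 4% site at ≥1000× for weak-site recovery; a 40% site at ~200× over
100 seeds for detection power; and 200 random small alignment sets (≤50
reads) for pileup-oracle equivalence. These sizes give the binomial checks
comfortable resolution while keeping a full run in the low minutes on one
core.

## Known limitations

* No alignment is performed; real data must arrive pre-aligned, and the
  multi-mapper definition must match the aligner's dialect.
* Overlapping genes on opposite strands are both reported in the site table
  for the shared interval; a read antisense to one of them is sense to the
  other and is assigned to the antisense gene only.
* The binomial test assumes independent reads; PCR duplicates or UMI-less
  high-duplication libraries will overstate significance.
* The comparison layer aligns samples by timepoint and reports deltas; it
  deliberately fits no longitudinal model.
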