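# rnaedit

Strand-aware quantification of A-to-I RNA editing from bacterial RNA-seq.

A-to-I editing deaminates adenosine to inosine in RNA; because inosine
base-pairs like guanosine, edited positions appear as A→G mismatches when
sequenced reads are aligned to the reference genome. `rnaedit` quantifies
that signature from strand-specific (dUTP-type) libraries, where reads align
*antisense* to their source gene, so gene strand decides which reference
mismatch pair — (A,G) on plus-strand genes, (T,C) on minus-strand genes —
corresponds to transcript A→G. It is aimed at groups studying editing-based
anti-phage defence systems and endogenous deaminases (e.g. TadA on the argQ
tRNA) in bacteria and their phages.

The pipeline is:

1. **filter** — discard unmapped reads, reads overlapping annotated rRNA
   genes, multi-mappers (hit-count tag > 1 or MAPQ 0; MAPQ-threshold dialect
   also supported), reads whose alignment contains insertions or deletions,
   and reads not aligned antisense to exactly one annotated gene. Every read
   is counted once, under the first failing rule, so the audit tally
   partitions the input exactly.
2. **pileup** — count base calls per reference position over the kept reads
   (base quality ≥ 20 by default), then read each gene position out in
   transcript space.
3. **statistics** — per-class substitution rates over all *expressed*
   positions (coverage ≥ 10 by default) of non-rRNA genes,
   `rate(X→Y) = Σ n_Y / Σ (n_X + n_Y)`; per-site editing fraction
   `f = n_G / (n_A + n_G)` in transcript space; an exact binomial upper-tail
   test of each expressed adenosine against the background substitution rate
   (median of the 11 non-A→G classes), Benjamini–Hochberg corrected; targeted
   locus reports; and control-vs-treatment comparisons across infection
   timepoints.
4. **simulate** — a first-class generator of miniature host+phage references
   with rRNA/tRNA/mRNA genes, expression weights, multi-mapping decoy
   regions, uniform sequencing error, and Bernoulli per-molecule A→G editing
   at configurable sites — with truth alignments and edit tallies, so every
   stage above is verifiable offline.

## Worked example

```python
from rnaedit import *
from rnaedit.simulate import adenosine_offsets

spec, genes = build_scenario(seed=3, n_host_mrna=10, n_phage_mrna=3)
genome, ann = generate_reference(spec, genes)
genome = plant_decoy(genome, ann, "hgene0", 2)   # multi-mapping decoys

def middle_a(gene_id):
    offs = adenosine_offsets(genome, ann.by_id[gene_id])
    return int(offs[len(offs) // 2])

sites = [EditSite("trna2", middle_a("trna2"), 0.40, "argQ-like"),
         EditSite("hgene1", middle_a("hgene1"), 0.04, "ssrA-like")]

res = simulate_reads(genome, ann, sites,
                     ReadSimConfig(seed=11, mean_depth=100, error_rate=0.001,
                                   indel_read_fraction=0.02))
kept, fstats = filter_alignments(res.alignments, ann)
print(fstats.counts)
# {'unmapped': 0, 'rrna': 20000, 'multimapper': 333, 'indel': 91,
#  'wrong_strand': 0, 'unassigned': 0, 'ambiguous': 0, 'kept': 4705,
#  'input': 25129}

df = site_stats_table(build_pileup(kept, genome), ann)
calls = call_sites(df)
print(calls[calls.called_edited][["gene_id", "pos", "n_ref", "n_alt", "f", "q"]])
#     gene_id   pos  n_ref  n_alt         f             q
# 66    trna2  4266    474    304  0.390746  0.000000e+00
# 490  hgene1  5490    136      5  0.035461  7.199233e-07
```

The filter tally shows the rRNA load (20000 reads), the decoy multi-mappers
(333) and the indel-carrying reads (91) being discarded before counting.
Exactly the two injected sites are called: the 40% positive-control site is
recovered at f̂ = 0.391 and the weak 4% site at f̂ = 0.035 — both within
binomial sampling error of the injected per-molecule rates (the realized
molecule tallies are in `res.truth`).

The same analysis runs from the shell on files (FASTA/GFF3/SAM in, TSVs
out), driven by a YAML config with a sample sheet:

```bash
rnaedit all --config config.yaml --out out/ --seed 1
```

producing `filter_stats.tsv`, per-sample `pileup.tsv` / `site_stats.tsv` /
`site_calls.tsv`, combined `class_rates.tsv`, `comparison.tsv`,
`loci_report.tsv` and a `manifest.json` with per-stage row counts. Re-running
with the same config and seed reproduces byte-identical outputs.

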