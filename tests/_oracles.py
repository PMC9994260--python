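"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (nested loops, explicit rule lists,
brute-force sums) and shares no code with the implementation under test.
"""
from __future__ import annotations

from math import comb

import pysam

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def naive_pileup(reads, genome, min_bq=20):
    """Per-read, per-base nested-loop counter. Returns {(contig,pos): {base: n}}."""
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for read in reads:
        if read.is_unmapped:
            continue
        contig = read.reference_name
        seq = read.query_sequence
        quals = read.query_qualities
        qpos, rpos = 0, read.reference_start
        for op, length in read.cigartuples:
            if op in (0, 7, 8):  # aligned
                for i in range(length):
                    if quals is None or quals[qpos + i] >= min_bq:
                        col = counts.setdefault((contig, rpos + i), {})
                        b = seq[qpos + i]
                        col[b] = col.get(b, 0) + 1
                qpos += length
                rpos += length
            elif op == 1:  # insertion: query only
                qpos += length
            elif op in (2, 3):  # deletion/skip: reference only
                rpos += length
            elif op == 4:  # soft clip: query only
                qpos += length
            # hard clip / pad consume nothing
    return counts


def brute_classify(read, genes, params):
    """Re-statement of the exclusion rules as one sequential checklist.

    ``genes`` is a plain list of GeneModel; no interval index is used.
    """
    if read.is_unmapped:
        return "unmapped"
    s, e = read.reference_start, read.reference_end
    contig = read.reference_name

    def overlaps(g):
        return g.contig == contig and g.start < e and g.end > s

    if params.drop_rrna and any(overlaps(g) and g.biotype == "rRNA" for g in genes):
        return "rrna"
    if params.drop_multimappers:
        nh = read.get_tag(params.hit_count_tag) if read.has_tag(params.hit_count_tag) else 1
        if nh > 1 or read.mapping_quality == 0 or (
            params.mapq_below is not None and read.mapping_quality < params.mapq_below
        ):
            return "multimapper"
    if params.drop_indels and any(op in (1, 2) for op, _ in read.cigartuples or []):
        return "indel"
    hits = [g for g in genes if overlaps(g)]
    if not hits:
        return "unassigned"
    align_strand = "-" if read.is_reverse else "+"
    good = [g for g in hits if g.strand != align_strand]
    if params.assigned_gene_policy == "full_overlap":
        good = [g for g in good if g.start <= s and e <= g.end]
    if not good:
        return "wrong_strand"
    if len(good) > 1:
        return "ambiguous"
    return "kept"


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by explicit summation."""
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def rc_dataset(genome, ann, alignments):
    """Mirror a whole dataset: reverse-complement every contig, flip gene
    strands and coordinates, and rewrite each alignment on the mirrored axis.
    Editing summaries must be invariant under this transform."""
    from rnaedit.annotation import Annotation
    from rnaedit.models import GeneModel

    genome_rc = {name: rc(seq) for name, seq in genome.items()}
    genes_rc = [
        GeneModel(
            g.gene_id, g.contig,
            len(genome[g.contig]) - g.end, len(genome[g.contig]) - g.start,
            "-" if g.strand == "+" else "+", g.biotype, g.expression_weight,
        )
        for g in ann.genes
    ]
    ann_rc = Annotation(genes_rc)
    ann_rc.multimapping_genes = set(ann.multimapping_genes)

    names = list(genome_rc)
    header = pysam.AlignmentHeader.from_references(
        names, [len(genome_rc[n]) for n in names]
    )
    tid = {n: i for i, n in enumerate(names)}
    flipped = []
    for read in alignments:
        L = len(genome[read.reference_name])
        rec = pysam.AlignedSegment(header)
        rec.query_name = read.query_name
        rec.reference_id = tid[read.reference_name]
        rec.reference_start = L - read.reference_end
        rec.flag = read.flag ^ 16
        rec.mapping_quality = read.mapping_quality
        rec.query_sequence = rc(read.query_sequence)
        rec.cigartuples = list(read.cigartuples)[::-1]
        rec.query_qualities = read.query_qualities[::-1]
        for tag, val in read.get_tags():
            rec.set_tag(tag, val)
        flipped.append(rec)
    return genome_rc, ann_rc, flipped
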