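"""Synthetic host+phage transcriptomes with known injected A-to-I editing.

The generator emulates the data a strand-specific (dUTP-type) bacterial
RNA-seq experiment produces: a small host genome plus a phage contig, genes
with biotypes and expression weights, Bernoulli per-molecule A->G editing at
configurable sites, uniform sequencing error, multi-mapping decoy regions,
and single-end reads that align antisense to their source gene. Every read
comes with a truth alignment and every edit site with realized molecule
tallies, so the downstream filter/pileup/statistics stages can be validated
exactly, offline.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import Annotation, write_gff3
from .models import (
    A,
    COMPLEMENT_CODE,
    EditSite,
    G,
    GeneModel,
    GenomeSpec,
    ReadSimConfig,
    ValidationError,
    decode_seq,
    encode_seq,
)

QUAL_CHAR = chr(30 + 33)  # constant Q30 written to FASTQ


# ---------------------------------------------------------------------------
# reference generation


def transcript_seq(genome: dict[str, str], gene: GeneModel) -> str:
    """The mature transcript sequence of a gene (5'->3')."""
    seg = genome[gene.contig][gene.start : gene.end]
    if gene.strand == "+":
        return seg
    return decode_seq(COMPLEMENT_CODE[encode_seq(seg)][::-1])


def adenosine_offsets(genome: dict[str, str], gene: GeneModel) -> np.ndarray:
    """Transcript offsets (5'->3') whose transcript base is A."""
    return np.flatnonzero(encode_seq(transcript_seq(genome, gene)) == A)


def generate_reference(
    spec: GenomeSpec, genes: list[GeneModel]
) -> tuple[dict[str, str], Annotation]:
    """Draw random contig sequences at the stated GC and validate the genes.

    Every gene's transcript is guaranteed to contain at least one adenosine
    (the middle transcript base is forced to A if the random draw missed).
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = {name: length for name, length, _ in spec.contigs}
    genome_codes: dict[str, np.ndarray] = {}
    for name, length, gc in spec.contigs:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        genome_codes[name] = rng.choice(4, size=length, p=p).astype(np.uint8)

    for gene in genes:
        if gene.contig not in lengths:
            raise ValidationError(f"gene {gene.gene_id}: unknown contig {gene.contig}")
        if gene.end > lengths[gene.contig]:
            raise ValidationError(
                f"gene {gene.gene_id}: end {gene.end} exceeds contig "
                f"{gene.contig} length {lengths[gene.contig]}"
            )
    ann = Annotation(genes)  # raises on same-strand overlap

    # transcript A at offset o corresponds to genomic A (+) or T (-)
    for gene in genes:
        seg = genome_codes[gene.contig][gene.start : gene.end]
        want = A if gene.strand == "+" else 3  # T code
        if not np.any(seg == want):
            seg[len(seg) // 2] = want

    genome = {name: decode_seq(codes) for name, codes in genome_codes.items()}
    return genome, ann


def plant_decoy(
    genome: dict[str, str],
    ann: Annotation,
    source_gene: str,
    copies: int,
) -> dict[str, str]:
    """Duplicate a gene's sequence into intergenic space to create multi-mappers.

    The duplicated copies are deliberately not annotated; reads simulated from
    the source gene are then flagged multi-mapping in the truth alignments.
    """
    if copies < 1:
        raise ValidationError("plant_decoy: copies must be >= 1")
    gene = ann.by_id.get(source_gene)
    if gene is None:
        raise ValidationError(f"plant_decoy: unknown gene {source_gene!r}")
    seg = genome[gene.contig][gene.start : gene.end]
    glen = len(seg)

    if not hasattr(ann, "decoy_regions"):
        ann.decoy_regions = []  # type: ignore[attr-defined]
        ann.decoy_counts = {}  # type: ignore[attr-defined]
    occupied: dict[str, list[tuple[int, int]]] = {}
    for g in ann.genes:
        occupied.setdefault(g.contig, []).append((g.start, g.end))
    for contig, s, e in ann.decoy_regions:  # type: ignore[attr-defined]
        occupied.setdefault(contig, []).append((s, e))

    genome = dict(genome)
    placed = 0
    for contig in genome:
        ivs = sorted(occupied.get(contig, []))
        cursor = 0
        gaps = []
        for s, e in ivs:
            if s - cursor >= glen:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if len(genome[contig]) - cursor >= glen:
            gaps.append((cursor, len(genome[contig])))
        for gap_start, gap_end in gaps:
            pos = gap_start
            while placed < copies and pos + glen <= gap_end:
                genome[contig] = (
                    genome[contig][:pos] + seg + genome[contig][pos + glen :]
                )
                ann.decoy_regions.append((contig, pos, pos + glen))  # type: ignore[attr-defined]
                placed += 1
                pos += glen
            if placed == copies:
                break
        if placed == copies:
            break
    if placed < copies:
        raise ValidationError(
            f"plant_decoy: not enough intergenic space for {copies} copies of "
            f"{source_gene} ({glen} bp each); placed {placed}"
        )
    ann.multimapping_genes.add(source_gene)
    ann.decoy_counts[source_gene] = ann.decoy_counts.get(source_gene, 0) + copies  # type: ignore[attr-defined]
    return genome


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimResult:
    """Simulated reads with their truth alignments and edit tallies."""

    header: pysam.AlignmentHeader
    alignments: list[pysam.AlignedSegment]
    fastq_records: list[tuple[str, str]]  # (name, read sequence), constant Q30
    truth: pd.DataFrame

    @property
    def n_reads(self) -> int:
        return len(self.fastq_records)

    def write(self, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
        """Write reads.fastq, truth.sam and truth_table.tsv; return the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": out_dir / f"{prefix}reads.fastq",
            "sam": out_dir / f"{prefix}truth.sam",
            "truth_table": out_dir / f"{prefix}truth_table.tsv",
        }
        with open(paths["fastq"], "w") as fq:
            for name, seq in self.fastq_records:
                fq.write(f"@{name}\n{seq}\n+\n{QUAL_CHAR * len(seq)}\n")
        with pysam.AlignmentFile(str(paths["sam"]), "wh", header=self.header) as sam:
            for rec in self.alignments:
                sam.write(rec)
        self.truth.to_csv(paths["truth_table"], sep="\t", index=False)
        return paths


def _reads_per_gene(genes: list[GeneModel], cfg: ReadSimConfig) -> dict[str, int]:
    """Deterministic per-gene read counts.

    A gene's target fold-coverage is mean_depth * expression_weight, so a
    weight of 1.0 means exactly the configured depth and weights read
    directly as relative abundance.
    """
    counts = {}
    for g in genes:
        if g.expression_weight <= 0:
            continue
        depth = cfg.mean_depth * g.expression_weight
        counts[g.gene_id] = int(round(depth * g.length / cfg.read_length))
    return counts


def simulate_reads(
    genome: dict[str, str],
    ann: Annotation,
    edit_sites: list[EditSite],
    cfg: ReadSimConfig,
) -> SimResult:
    """Simulate single-end antisense-stranded reads with injected editing.

    Each transcript molecule is edited independently at each of its sites
    (Bernoulli at ``true_rate``, A->G in transcript space) before
    fragmentation; uniform substitution errors at ``cfg.error_rate`` are
    applied afterwards. One read is emitted per molecule, its start uniform
    over valid transcript positions. Truth alignments carry correct
    POS/CIGAR/strand; reads from decoy-duplicated genes get MAPQ 0 and an
    NH tag of decoy copies + 1. A fraction ``cfg.indel_read_fraction`` of
    reads carries a 1-bp insertion or deletion.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(genome)
    header = pysam.AlignmentHeader.from_references(
        names, [len(genome[n]) for n in names]
    )
    tid = {n: i for i, n in enumerate(names)}

    sites_by_gene: dict[str, list[EditSite]] = {}
    for site in edit_sites:
        gene = ann.by_id.get(site.gene_id)
        if gene is None:
            raise ValidationError(f"edit site references unknown gene {site.gene_id!r}")
        tx = transcript_seq(genome, gene)
        if not 0 <= site.offset < len(tx):
            raise ValidationError(
                f"edit site {site.gene_id}:{site.offset} outside transcript"
            )
        if tx[site.offset] != "A":
            raise ValidationError(
                f"edit site {site.gene_id}:{site.offset} ({site.label or 'unlabeled'}):"
                f" transcript base is {tx[site.offset]}, not A"
            )
        sites_by_gene.setdefault(site.gene_id, []).append(site)

    n_per_gene = _reads_per_gene(ann.genes, cfg)
    if cfg.mean_depth <= 0 or not n_per_gene:
        warnings.warn("simulate_reads: zero depth or no expressed genes; empty output")
        return SimResult(header, [], [], _empty_truth())

    for g in ann.genes:
        if g.expression_weight > 0 and g.length < cfg.read_length:
            raise ValidationError(
                f"read_length {cfg.read_length} exceeds transcript length of "
                f"expressed gene {g.gene_id} ({g.length} bp)"
            )

    rl = cfg.read_length
    alignments: list[pysam.AlignedSegment] = []
    fastq: list[tuple[str, str]] = []
    truth_rows = []
    quals = pysam.qualitystring_to_array(QUAL_CHAR * rl)

    for gene in ann.genes:
        n_mol = n_per_gene.get(gene.gene_id, 0)
        if n_mol == 0:
            continue
        tx_codes = encode_seq(transcript_seq(genome, gene))
        L = gene.length
        gsites = sites_by_gene.get(gene.gene_id, [])

        # per-molecule edit decisions, tallied over ALL molecules of the gene
        edit_flags = {}
        for site in gsites:
            flags = rng.random(n_mol) < site.true_rate
            edit_flags[site.offset] = flags
            truth_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "contig": gene.contig,
                    "genomic_pos": gene.transcript_to_genomic(site.offset),
                    "transcript_offset": site.offset,
                    "true_rate": site.true_rate,
                    "label": site.label,
                    "n_molecules_edited": int(flags.sum()),
                    "n_molecules_total": n_mol,
                }
            )

        starts = rng.integers(0, L - rl + 1, size=n_mol)
        indel_mask = (
            rng.random(n_mol) < cfg.indel_read_fraction
            if cfg.indel_read_fraction > 0
            else np.zeros(n_mol, dtype=bool)
        )

        plain_idx = np.flatnonzero(~indel_mask)
        reads = tx_codes[starts[plain_idx, None] + np.arange(rl)[None, :]]
        for offset, flags in edit_flags.items():
            sel = flags[plain_idx] & (starts[plain_idx] <= offset) & (
                offset < starts[plain_idx] + rl
            )
            reads[sel, offset - starts[plain_idx][sel]] = G
        if cfg.error_rate > 0:
            err = rng.random(reads.shape) < cfg.error_rate
            shifts = rng.integers(1, 4, size=int(err.sum()))
            reads[err] = (reads[err] + shifts).astype(np.uint8) % 4

        mol_payload: dict[int, tuple[np.ndarray, list[tuple[int, int]]]] = {}
        for row, mol in enumerate(plain_idx):
            mol_payload[mol] = (reads[row], [(0, rl)])

        # indel reads built one by one (rare path)
        for mol in np.flatnonzero(indel_mask):
            s = int(starts[mol])
            want_del = rng.random() < 0.5 and s <= L - rl - 1
            if want_del:
                frag = tx_codes[s : s + rl + 1].copy()
                span = rl + 1
            else:
                frag = tx_codes[s : s + rl].copy()
                span = rl
            for offset, flags in edit_flags.items():
                if flags[mol] and s <= offset < s + span:
                    frag[offset - s] = G
            pos = int(rng.integers(1, rl - 1))
            if want_del:
                frag = np.delete(frag, pos)
                cigar = [(0, pos), (2, 1), (0, rl - pos)]  # xM 1D yM
            else:
                frag = np.insert(frag, pos, rng.integers(0, 4))[:rl]
                cigar = [(0, pos), (1, 1), (0, rl - 1 - pos)]  # xM 1I yM
            if cfg.error_rate > 0:
                err = rng.random(rl) < cfg.error_rate
                shifts = rng.integers(1, 4, size=int(err.sum()))
                frag[err] = (frag[err] + shifts).astype(np.uint8) % 4
            mol_payload[mol] = (frag, cigar)

        is_decoy = gene.gene_id in ann.multimapping_genes
        nh = 1 + getattr(ann, "decoy_counts", {}).get(gene.gene_id, 0) if is_decoy else 1
        mapq = 0 if is_decoy else 60

        for mol in range(n_mol):
            frag, cigar_tx = mol_payload[mol]
            span = sum(n for op, n in cigar_tx if op in (0, 2))
            s = int(starts[mol])
            name = f"{gene.gene_id}|{mol:06d}"
            rec = pysam.AlignedSegment(header)
            rec.query_name = name
            rec.reference_id = tid[gene.contig]
            rec.mapping_quality = mapq
            if gene.strand == "+":
                # transcript orientation == genome orientation; read is revcomp
                rec.flag = 16
                rec.reference_start = gene.start + s
                rec.query_sequence = decode_seq(frag)
                rec.cigartuples = cigar_tx
                read_seq = decode_seq(COMPLEMENT_CODE[frag][::-1])
            else:
                rec.flag = 0
                rec.reference_start = gene.end - s - span
                fwd = COMPLEMENT_CODE[frag][::-1]
                rec.query_sequence = decode_seq(fwd)
                rec.cigartuples = cigar_tx[::-1]
                read_seq = rec.query_sequence
            rec.query_qualities = quals[: len(frag)]
            rec.set_tag("NH", nh)
            rec.set_tag("XG", gene.gene_id)
            alignments.append(rec)
            fastq.append((name, read_seq))

    return SimResult(header, alignments, fastq, pd.DataFrame(truth_rows, columns=_TRUTH_COLS))


_TRUTH_COLS = [
    "gene_id",
    "contig",
    "genomic_pos",
    "transcript_offset",
    "true_rate",
    "label",
    "n_molecules_edited",
    "n_molecules_total",
]


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=_TRUTH_COLS)


# ---------------------------------------------------------------------------
# FASTA I/O and a ready-made host+phage scenario


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def build_scenario(
    *,
    n_host_mrna: int = 20,
    n_phage_mrna: int = 5,
    n_rrna: int = 2,
    n_trna: int = 1,
    gene_length: int = 250,
    rrna_length: int = 1500,
    trna_length: int = 120,
    spacer: int = 400,
    gc: float = 0.5,
    phage_gc: float = 0.4,
    rrna_weight: float = 5.0,
    trna_weight: float = 5.0,
    phage_weight: float = 1.0,
    seed: int = 0,
) -> tuple[GenomeSpec, list[GeneModel]]:
    """Lay out a miniature host contig (mRNA + rRNA + tRNA genes) and a phage
    contig, alternating strands, with generous intergenic spacers so decoy
    copies can be planted."""
    genes: list[GeneModel] = []
    cursor = spacer
    strand_cycle = "+-"
    i = 0
    for _ in range(n_rrna):
        genes.append(
            GeneModel(f"rrn{i}", "host", cursor, cursor + rrna_length,
                      strand_cycle[i % 2], "rRNA", rrna_weight)
        )
        cursor += rrna_length + spacer
        i += 1
    for _ in range(n_trna):
        genes.append(
            GeneModel(f"trna{i}", "host", cursor, cursor + trna_length,
                      strand_cycle[i % 2], "tRNA", trna_weight)
        )
        cursor += trna_length + spacer
        i += 1
    for j in range(n_host_mrna):
        genes.append(
            GeneModel(f"hgene{j}", "host", cursor, cursor + gene_length,
                      strand_cycle[i % 2], "mRNA", 1.0)
        )
        cursor += gene_length + spacer
        i += 1
    host_len = max(cursor + spacer, 1000)

    pcursor = spacer
    for j in range(n_phage_mrna):
        genes.append(
            GeneModel(f"pgene{j}", "phage", pcursor, pcursor + gene_length,
                      strand_cycle[j % 2], "mRNA", phage_weight)
        )
        pcursor += gene_length + spacer
    phage_len = max(pcursor + spacer, 1000)

    contigs = [("host", host_len, gc)]
    if n_phage_mrna > 0:
        contigs.append(("phage", phage_len, phage_gc))
    return GenomeSpec(tuple(contigs), seed=seed), genes
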