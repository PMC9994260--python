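"""Per-reference-position base counting and per-site editing fractions.

The pileup is the quantitative core: every kept alignment contributes its
aligned base calls to a per-contig (length x 5) count matrix (A,C,G,T,N).
Insertion bases are skipped, deletion gaps contribute nothing, soft-clipped
bases are ignored, and base calls below a quality cutoff are excluded.
Editing is then read out in transcript space: a transcript A->G signature
corresponds to (ref A, alt G) counts for plus-strand genes and (ref T, alt C)
for minus-strand genes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .annotation import Annotation
from .models import A, COMPLEMENT_CODE, G, BASES, GeneModel, encode_seq

_MATCH_OPS = (0, 7, 8)  # M, =, X consume both query and reference


@dataclass
class PileupColumn:
    contig: str
    pos: int  # 0-based
    ref_base: str
    counts: np.ndarray  # length 5: A,C,G,T,N

    @property
    def coverage(self) -> int:
        return int(self.counts.sum())


@dataclass
class SiteStat:
    """Editing readout at one genomic position of one gene (transcript space)."""

    gene_id: str
    contig: str
    genomic_pos: int
    transcript_base: str
    alt_transcript_base: str
    n_ref: int
    n_alt: int
    coverage: int

    @property
    def editing_fraction(self) -> float:
        pair = self.n_ref + self.n_alt
        return self.n_alt / pair if pair else float("nan")


class PileupMatrix:
    """Per-contig base-count matrices over a reference genome."""

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self.counts: dict[str, np.ndarray] = {
            name: np.zeros((len(seq), 5), dtype=np.uint32)
            for name, seq in genome.items()
        }

    def column(self, contig: str, pos: int) -> PileupColumn:
        return PileupColumn(
            contig, pos, self.genome[contig][pos], self.counts[contig][pos].copy()
        )

    def iter_columns(self) -> Iterator[PileupColumn]:
        """Yield columns with non-zero coverage, in genomic order."""
        for contig in self.counts:
            cov = self.counts[contig].sum(axis=1)
            for pos in np.flatnonzero(cov):
                yield self.column(contig, int(pos))

    def to_dataframe(self) -> pd.DataFrame:
        """Covered positions as a table (counts in reference space)."""
        frames = []
        for contig, mat in self.counts.items():
            cov = mat.sum(axis=1)
            idx = np.flatnonzero(cov)
            if idx.size == 0:
                continue
            refs = encode_seq(self.genome[contig])[idx]
            frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": idx,
                        "ref_base": [BASES[c] for c in refs],
                        "A": mat[idx, 0],
                        "C": mat[idx, 1],
                        "G": mat[idx, 2],
                        "T": mat[idx, 3],
                        "N": mat[idx, 4],
                        "coverage": cov[idx],
                    }
                )
            )
        if not frames:
            return pd.DataFrame(
                columns=["contig", "pos", "ref_base", "A", "C", "G", "T", "N", "coverage"]
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, genome: dict[str, str]) -> "PileupMatrix":
        pm = cls(genome)
        for contig, sub in df.groupby("contig"):
            pos = sub["pos"].to_numpy()
            for i, base in enumerate("ACGTN"):
                pm.counts[contig][pos, i] = sub[base].to_numpy()
        return pm


def build_pileup(
    alignments: Iterable[pysam.AlignedSegment],
    genome: dict[str, str],
    min_base_quality: int = 20,
) -> PileupMatrix:
    """Accumulate base counts from kept alignments.

    Alignments extending past the contig end raise a ValueError naming the
    read. Pure-match alignments take a vectorised path; alignments with other
    CIGAR operations fall back to pysam's aligned-pairs walk.
    """
    pm = PileupMatrix(genome)
    batch_pos: dict[str, list[np.ndarray]] = {name: [] for name in genome}
    batch_code: dict[str, list[np.ndarray]] = {name: [] for name in genome}

    for read in alignments:
        if read.is_unmapped:
            continue
        contig = read.reference_name
        if contig not in pm.counts:
            raise ValueError(f"read {read.query_name}: unknown contig {contig}")
        if read.reference_end > len(genome[contig]):
            raise ValueError(
                f"read {read.query_name}: alignment extends past end of {contig}"
            )
        codes = encode_seq(read.query_sequence)
        quals = read.query_qualities
        qual_arr = (
            np.frombuffer(bytes(quals), dtype=np.uint8)
            if quals is not None
            else np.full(len(codes), 255, dtype=np.uint8)
        )
        cig = read.cigartuples
        if cig is not None and len(cig) == 1 and cig[0][0] in _MATCH_OPS:
            refpos = np.arange(read.reference_start, read.reference_end)
            qmask = qual_arr >= min_base_quality
            batch_pos[contig].append(refpos[qmask])
            batch_code[contig].append(codes[qmask])
        else:
            pairs = read.get_aligned_pairs(matches_only=True)
            if pairs:
                qidx = np.fromiter((q for q, _ in pairs), dtype=np.int64)
                ridx = np.fromiter((r for _, r in pairs), dtype=np.int64)
                qmask = qual_arr[qidx] >= min_base_quality
                batch_pos[contig].append(ridx[qmask])
                batch_code[contig].append(codes[qidx][qmask])

    for contig in pm.counts:
        if batch_pos[contig]:
            pos = np.concatenate(batch_pos[contig])
            code = np.concatenate(batch_code[contig])
            np.add.at(pm.counts[contig], (pos, code), 1)
    return pm


def site_stat(column: PileupColumn, gene: GeneModel) -> SiteStat:
    """Map a pileup column into transcript space for one gene.

    The transcript A->G editing class reads out as (ref A, alt G) counts for
    a plus-strand gene and (ref T, alt C) for a minus-strand gene. Positions
    whose transcript base is not A describe one of the other 11 mismatch
    classes; their alt is still reported as transcript G for symmetry.
    """
    if not gene.start <= column.pos < gene.end:
        raise ValueError(
            f"position {column.pos} outside gene {gene.gene_id} "
            f"[{gene.start},{gene.end})"
        )
    ref_code = encode_seq(column.ref_base)[0]
    if gene.strand == "+":
        tx_counts = column.counts[:4]
        t_ref = int(ref_code)
    else:
        tx_counts = column.counts[[3, 2, 1, 0]]
        t_ref = int(COMPLEMENT_CODE[ref_code])
    return SiteStat(
        gene_id=gene.gene_id,
        contig=column.contig,
        genomic_pos=column.pos,
        transcript_base=BASES[t_ref],
        alt_transcript_base="G",
        n_ref=int(tx_counts[t_ref]),
        n_alt=int(tx_counts[G]),
        coverage=column.coverage,
    )


def site_stats_table(
    pm: PileupMatrix,
    ann: Annotation,
    include_rrna: bool = False,
) -> pd.DataFrame:
    """Per-position transcript-space counts for every annotated gene position.

    Columns ``tx_A..tx_N`` are base-call counts oriented along the transcript;
    ``n_ref``/``n_alt``/``f`` read out the A->G editing pair (ref base vs
    transcript G). rRNA genes are excluded by default, matching the read
    filter.
    """
    rows = []
    for gene in ann.genes:
        if gene.biotype == "rRNA" and not include_rrna:
            continue
        # row t of mat/refs/pos is transcript offset t (5'->3')
        mat = pm.counts[gene.contig][gene.start : gene.end]
        refs = encode_seq(pm.genome[gene.contig][gene.start : gene.end])
        pos = np.arange(gene.start, gene.end)
        if gene.strand == "-":
            mat = mat[::-1][:, [3, 2, 1, 0, 4]]
            refs = COMPLEMENT_CODE[refs][::-1]
            pos = pos[::-1]
        offs = np.arange(gene.length)
        cov = mat.sum(axis=1)
        n_ref = mat[np.arange(len(refs)), refs.astype(np.intp)]
        n_alt = mat[:, G]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene.gene_id,
                    "contig": gene.contig,
                    "pos": pos,
                    "transcript_offset": offs,
                    "strand": gene.strand,
                    "biotype": gene.biotype,
                    "transcript_base": np.array(list(BASES))[refs],
                    "tx_A": mat[:, 0],
                    "tx_C": mat[:, 1],
                    "tx_G": mat[:, 2],
                    "tx_T": mat[:, 3],
                    "tx_N": mat[:, 4],
                    "coverage": cov,
                    "n_ref": n_ref,
                    "n_alt": n_alt,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "gene_id", "contig", "pos", "transcript_offset", "strand", "biotype",
                "transcript_base", "tx_A", "tx_C", "tx_G", "tx_T", "tx_N",
                "coverage", "n_ref", "n_alt", "f",
            ]
        )
    df = pd.concat(rows, ignore_index=True)
    pair = df["n_ref"] + df["n_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["f"] = np.where(pair > 0, df["n_alt"] / pair, np.nan)
    # f is the editing fraction only at transcript-A positions; elsewhere the
    # ref/alt pair describes a different mismatch class
    return df
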