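"""Annotation container with a strand-aware interval index, plus GFF3/BED I/O."""
from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, ValidationError

KNOWN_BIOTYPES = ("mRNA", "rRNA", "tRNA")


class Annotation:
    """A set of genes indexed for fast overlap queries.

    Same-strand genes must not overlap (bacterial annotation contract);
    opposite-strand overlap is allowed.
    """

    def __init__(self, genes: list[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self.by_id: dict[str, GeneModel] = {}
        self._tree: dict[str, IntervalTree] = {}
        self._rrna_tree: dict[str, IntervalTree] = {}
        #: gene_ids whose sequence has been duplicated elsewhere in the genome
        self.multimapping_genes: set[str] = set()
        for g in self.genes:
            if g.gene_id in self.by_id:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            self.by_id[g.gene_id] = g
            self._tree.setdefault(g.contig, IntervalTree())[g.start : g.end] = g
            if g.biotype == "rRNA":
                self._rrna_tree.setdefault(g.contig, IntervalTree())[
                    g.start : g.end
                ] = g
        self._check_same_strand_overlap()

    def _check_same_strand_overlap(self):
        for contig, tree in self._tree.items():
            for iv in tree:
                for other in tree.overlap(iv.begin, iv.end):
                    a, b = iv.data, other.data
                    if a.gene_id < b.gene_id and a.strand == b.strand:
                        raise ValidationError(
                            f"same-strand genes overlap on {contig}: "
                            f"{a.gene_id} and {b.gene_id}"
                        )

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, contig: str, start: int, end: int) -> list[GeneModel]:
        tree = self._tree.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda g: (g.start, g.gene_id))

    def overlaps_rrna(self, contig: str, start: int, end: int) -> bool:
        tree = self._rrna_tree.get(contig)
        return bool(tree) and tree.overlaps(start, end)


def write_gff3(ann: Annotation, path: str | Path) -> None:
    """Write genes as one GFF3 feature each, typed by biotype (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            attrs = f"ID={g.gene_id};expression_weight={g.expression_weight:g}"
            fh.write(
                f"{g.contig}\trnaedit\t{g.biotype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def _load_gff3(path: Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.all_features():
        if feat.strand not in ("+", "-"):
            raise ValidationError(
                f"{path}: feature {feat.id or '?'} has no strand ('{feat.strand}')"
            )
        biotype = feat.featuretype
        if biotype in ("gene", "CDS", "transcript"):
            biotype = feat.attributes.get("biotype", ["mRNA"])[0]
        if biotype not in KNOWN_BIOTYPES:
            warnings.warn(
                f"unknown biotype {biotype!r} for {feat.id}; treating as mRNA"
            )
            biotype = "mRNA"
        weight = float(feat.attributes.get("expression_weight", ["1.0"])[0])
        gene_id = feat.attributes.get("ID", [feat.id or f"{feat.seqid}:{feat.start}"])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based closed
                end=feat.end,
                strand=feat.strand,
                biotype=biotype,
                expression_weight=weight,
            )
        )
    return genes


def _load_bed(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValidationError(f"{path}: BED annotation needs >= 6 columns (with strand)")
    genes = []
    for row in df.itertuples(index=False):
        strand = row[5]
        if strand not in ("+", "-"):
            raise ValidationError(f"{path}: gene {row[3]!r} has no strand ({strand!r})")
        biotype = row[6] if df.shape[1] > 6 and not pd.isna(row[6]) else "mRNA"
        if biotype not in KNOWN_BIOTYPES:
            warnings.warn(f"unknown biotype {biotype!r} for {row[3]}; treating as mRNA")
            biotype = "mRNA"
        weight = float(row[7]) if df.shape[1] > 7 and not pd.isna(row[7]) else 1.0
        genes.append(
            GeneModel(
                gene_id=str(row[3]),
                contig=str(row[0]),
                start=int(row[1]),  # BED is already 0-based half-open
                end=int(row[2]),
                strand=strand,
                biotype=biotype,
                expression_weight=weight,
            )
        )
    return genes


def load_annotation(path: str | Path) -> Annotation:
    """Load a GFF3 (.gff/.gff3) or BED6+biotype annotation into an Annotation."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return Annotation(_load_gff3(path))
    if path.suffix.lower() == ".bed":
        return Annotation(_load_bed(path))
    raise ValidationError(f"unrecognised annotation format: {path}")
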