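"""Read-exclusion rules and antisense strand selection.

Raw alignments are reduced to the kept-read set used for mismatch counting:
unmapped reads, reads overlapping annotated rRNA genes (either strand),
multi-mappers, reads whose alignment contains insertions or deletions, and
reads not aligned antisense to exactly one annotated gene are discarded.
Each read is counted once, under the first failing rule, so the per-category
tally partitions the input exactly.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .annotation import Annotation
from .models import FilterParams

#: classification order is fixed; it affects only the audit tally, never the kept set
CATEGORIES = (
    "unmapped",
    "rrna",
    "multimapper",
    "indel",
    "wrong_strand",
    "unassigned",
    "ambiguous",
    "kept",
)


@dataclass
class FilterStats:
    """Per-category read tally; categories partition the input."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES} | {"input": 0}
    )

    def add(self, category: str) -> None:
        self.counts["input"] += 1
        self.counts[category] += 1

    @property
    def kept(self) -> int:
        return self.counts["kept"]

    def check_partition(self) -> bool:
        return self.counts["input"] == sum(self.counts[c] for c in CATEGORIES)

    def to_row(self) -> dict[str, int]:
        return dict(self.counts)


def _is_multimapper(read: pysam.AlignedSegment, params: FilterParams) -> bool:
    if read.has_tag(params.hit_count_tag) and read.get_tag(params.hit_count_tag) > 1:
        return True
    if read.mapping_quality == 0:
        return True
    if params.mapq_below is not None and read.mapping_quality < params.mapq_below:
        return True
    return False


def classify_read(
    read: pysam.AlignedSegment,
    ann: Annotation,
    params: FilterParams,
) -> tuple[str, str | None]:
    """Classify one alignment; returns (category, assigned gene_id or None).

    Rule order: unmapped -> rRNA overlap -> multi-mapper -> indel ->
    strand/assignment. A kept read is assigned to the single gene whose
    strand is opposite the alignment strand and that satisfies
    ``params.assigned_gene_policy``.
    """
    if read.is_unmapped:
        return "unmapped", None
    contig = read.reference_name
    start, end = read.reference_start, read.reference_end
    if params.drop_rrna and ann.overlaps_rrna(contig, start, end):
        return "rrna", None
    if params.drop_multimappers and _is_multimapper(read, params):
        return "multimapper", None
    if params.drop_indels and read.cigartuples is not None:
        if any(op in (1, 2) for op, _ in read.cigartuples):  # I or D
            return "indel", None
    overlapping = ann.overlapping(contig, start, end)
    if not overlapping:
        return "unassigned", None
    align_strand = "-" if read.is_reverse else "+"
    candidates = [g for g in overlapping if g.strand != align_strand]
    if params.assigned_gene_policy == "full_overlap":
        candidates = [g for g in candidates if g.start <= start and end <= g.end]
    if not candidates:
        return "wrong_strand", None
    if len(candidates) > 1:
        return "ambiguous", None
    return "kept", candidates[0].gene_id


def filter_alignments(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    ann: Annotation,
    params: FilterParams | None = None,
) -> tuple[list[pysam.AlignedSegment], FilterStats]:
    """Apply the exclusion rules to a SAM/BAM file or an alignment iterable.

    Returns the kept alignments (copies, each tagged ``XT:<assigned gene>``;
    input records are never mutated) and the audit tally. Filtering is
    deterministic; re-filtering the kept set keeps everything.
    """
    params = params or FilterParams()
    stats = FilterStats()
    kept: list[pysam.AlignedSegment] = []
    for read in _iter_alignments(alignments):
        category, gene_id = classify_read(read, ann, params)
        stats.add(category)
        if category == "kept":
            rec = copy.copy(read)
            rec.set_tag("XT", gene_id)
            kept.append(rec)
    assert stats.check_partition()
    return kept, stats


def _iter_alignments(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def write_sam(
    records: Iterable[pysam.AlignedSegment],
    header: pysam.AlignmentHeader,
    path: str | Path,
) -> int:
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            out.write(rec)
            n += 1
    return n
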