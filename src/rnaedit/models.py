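"""Shared domain types and base-encoding helpers.

Conventions used throughout the package:

* genomic coordinates are 0-based half-open internally; conversion to the
  1-based conventions of SAM/GFF3/locus lists happens only at file boundaries;
* transcript coordinates run 5'->3' along the mature transcript, so offset 0 of
  a minus-strand gene is the last genomic base of its interval;
* bases are encoded A=0, C=1, G=2, T=3, N=4 wherever numpy vectorisation is
  used.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)
COMPLEMENT_CODE = np.array([T, G, C, A, N], dtype=np.uint8)
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# lookup table: ASCII byte -> base code (unknown bases map to N)
_ENCODE_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i
_DECODE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    return _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into a nucleotide string."""
    return _DECODE_LUT[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return decode_seq(COMPLEMENT_CODE[encode_seq(seq)][::-1])


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for a random reference: contigs as (name, length, GC fraction)."""

    contigs: tuple[tuple[str, int, float], ...]
    seed: int = 0

    def __post_init__(self):
        names = [c[0] for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValidationError("contig names must be unique")
        for name, length, gc in self.contigs:
            if length < 1000:
                raise ValidationError(
                    f"contig {name!r}: length {length} < 1000 bp minimum"
                )
            if not 0.0 <= gc <= 1.0:
                raise ValidationError(f"contig {name!r}: GC fraction {gc} not in [0,1]")


@dataclass
class GeneModel:
    """An annotated gene: a stranded interval with a biotype and expression weight."""

    gene_id: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    biotype: str = "mRNA"  # mRNA | rRNA | tRNA
    expression_weight: float = 1.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.expression_weight < 0:
            raise ValidationError(f"gene {self.gene_id!r}: negative expression weight")

    @property
    def length(self) -> int:
        return self.end - self.start

    def transcript_to_genomic(self, offset: int) -> int:
        """Map a transcript offset (5'->3') to a genomic position."""
        if not 0 <= offset < self.length:
            raise ValidationError(
                f"offset {offset} outside transcript of {self.gene_id} "
                f"(length {self.length})"
            )
        if self.strand == "+":
            return self.start + offset
        return self.end - 1 - offset

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic position inside the gene to a transcript offset."""
        if not self.start <= pos < self.end:
            raise ValidationError(
                f"position {pos} outside gene {self.gene_id} "
                f"[{self.start},{self.end})"
            )
        if self.strand == "+":
            return pos - self.start
        return self.end - 1 - pos


@dataclass(frozen=True)
class EditSite:
    """An injected A-to-I editing site in transcript coordinates."""

    gene_id: str
    offset: int  # 0-based transcript offset; base there must be A
    true_rate: float  # per-molecule Bernoulli editing probability
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.true_rate <= 1.0:
            raise ValidationError(
                f"edit site {self.gene_id}:{self.offset}: rate {self.true_rate} "
                "not in [0,1]"
            )


@dataclass
class ReadSimConfig:
    """Parameters of the strand-specific (dUTP-style) read simulator.

    ``protocol='antisense_first_strand'`` encodes the library contract that a
    sequenced read is the reverse complement of its transcript fragment, so it
    aligns antisense to its source gene.
    """

    read_length: int = 75
    mean_depth: float = 50.0
    error_rate: float = 0.001
    seed: int = 0
    protocol: str = "antisense_first_strand"
    decoy_copies: int = 0
    indel_read_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 0.25:
            raise ValidationError(f"error_rate {self.error_rate} not in [0, 0.25)")
        if self.protocol != "antisense_first_strand":
            raise ValidationError(f"unsupported protocol {self.protocol!r}")
        if not 0.0 <= self.indel_read_fraction <= 1.0:
            raise ValidationError("indel_read_fraction must be in [0,1]")
        if self.read_length < 1:
            raise ValidationError("read_length must be positive")


@dataclass
class FilterParams:
    """Read-exclusion rules: all exclusion flags default on.

    ``mapq_below``: additionally treat MAPQ < mapq_below as multi-mapping
    (None disables the MAPQ-threshold dialect; MAPQ == 0 and a hit-count tag
    > 1 are always recognised when ``drop_multimappers`` is set).
    """

    drop_rrna: bool = True
    drop_multimappers: bool = True
    mapq_below: int | None = None
    hit_count_tag: str = "NH"
    drop_indels: bool = True
    strand_rule: str = "antisense_only"
    min_base_quality: int = 20
    assigned_gene_policy: str = "any_overlap"  # or 'full_overlap'

    def __post_init__(self):
        if self.min_base_quality < 0:
            raise ValidationError("min_base_quality must be >= 0")
        if self.strand_rule != "antisense_only":
            raise ValidationError(f"unsupported strand_rule {self.strand_rule!r}")
        if self.assigned_gene_policy not in ("any_overlap", "full_overlap"):
            raise ValidationError(
                f"unknown assigned_gene_policy {self.assigned_gene_policy!r}"
            )
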