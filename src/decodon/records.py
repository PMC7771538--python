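"""Core genome record types.

Coordinates are 1-based inclusive throughout (GenBank/GFF3 convention);
any half-open arithmetic is internal to the functions that slice sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS feature.

    ``parts`` holds exon segments as (start, end) 1-based inclusive tuples in
    genomic (ascending-coordinate) order; single-exon genes have one part.
    For minus-strand genes the coding sequence is the reverse complement of
    the concatenated parts.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    gene_name: str | None = None
    product: str | None = None
    is_pseudo: bool = False
    seqid: str | None = None
    parts: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.locus_tag}: start {self.start} > end {self.end}")
        if not self.parts:
            object.__setattr__(self, "parts", ((self.start, self.end),))
        for s, e in self.parts:
            if s > e:
                raise ValueError(f"{self.locus_tag}: malformed part ({s}, {e})")

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.parts)


@dataclass(frozen=True)
class CodingSequence:
    """A strand-corrected coding sequence on the coding strand."""

    locus_tag: str
    seq: str

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3


@dataclass(frozen=True)
class Exclusion:
    """A gene removed from downstream analysis, with the reason."""

    locus_tag: str
    reason: str


def resolve_contig(genome: str | Mapping[str, str], seqid: str | None) -> str:
    """Return the contig sequence for ``seqid`` from a string or mapping."""
    if isinstance(genome, str):
        return genome
    if seqid is not None:
        try:
            return genome[seqid]
        except KeyError:
            raise KeyError(f"sequence id {seqid!r} not present in genome "
                           f"(contigs: {sorted(genome)})") from None
    if len(genome) == 1:
        return next(iter(genome.values()))
    raise ValueError("multi-contig genome requires GeneRecord.seqid")


def records_equal(a: Sequence[GeneRecord], b: Sequence[GeneRecord]) -> bool:
    """Positional/strand equality of two record sets keyed by locus tag."""
    key = lambda r: (r.locus_tag, r.parts, r.strand, r.is_pseudo)
    return sorted(map(key, a)) == sorted(map(key, b))
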