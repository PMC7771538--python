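"""Synonymous-codon counting and decoding-tRNA usage fractions.

The model: each synonymous codon of an amino acid is read by a declared tRNA
isoacceptor. Per gene, codons are tallied in frame 0 and mapped onto their
decoders; the share of the amino acid supplied by a focal isoacceptor is then
reported under two denominator conventions:

``frac_pair``
    focal / (focal + partner) — the share within a designated two-codon pair
    (for proline in *M. tuberculosis*: proT(CCC) vs proY(CCG), the pair that
    together decodes ~86% of all proline).
``frac_all``
    focal / all synonymous codons of the amino acid.

Fractions with a zero denominator are carried as ``None`` (undefined), never
as 0 — a gene with no proline has no proT share.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable

from .records import CodingSequence

_BASES = set("ACGT")


def synonymous_codons(amino_acid: str, table_id: int = 11) -> tuple[str, ...]:
    """DNA codons translating to ``amino_acid`` under the given NCBI table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codons = tuple(sorted(c for c, aa in table.forward_table.items() if aa == amino_acid))
    if not codons:
        raise ValueError(f"unknown or non-coding amino-acid code {amino_acid!r}")
    return codons


@dataclass(frozen=True)
class DecoderTable:
    """Declarative codon → tRNA-isoacceptor assignment for one amino acid.

    ``focal`` and ``partner`` name the isoacceptor pair whose within-pair
    share ``frac_pair`` reports; every synonymous codon must be assigned.
    """

    amino_acid: str
    assignments: Mapping[str, str]
    focal: str
    partner: str
    table_id: int = 11

    def __post_init__(self) -> None:
        syn = set(synonymous_codons(self.amino_acid, self.table_id))
        extra = set(self.assignments) - syn
        if extra:
            raise ValueError(f"codons {sorted(extra)} do not encode {self.amino_acid!r} "
                             f"under translation table {self.table_id}")
        trnas = set(self.assignments.values())
        for role, name in (("focal", self.focal), ("partner", self.partner)):
            if name not in trnas:
                raise ValueError(f"{role} tRNA {name!r} not among assignments {sorted(trnas)}")

    def codons_of(self, trna: str) -> tuple[str, ...]:
        return tuple(sorted(c for c, t in self.assignments.items() if t == trna))


#: Proline decoding in M. tuberculosis: four isoacceptors, one per codon.
#: CCC→proT and CCG→proY follow the tRNA gene naming of the H37Rv genome;
#: CCA→proU and CCT→proX are the package's defaults for the remaining pair,
#: configurable because no standard fixes them.
PROLINE_DECODER = DecoderTable(
    amino_acid="P",
    assignments={"CCC": "proT", "CCG": "proY", "CCA": "proU", "CCT": "proX"},
    focal="proT",
    partner="proY",
)


@dataclass(frozen=True)
class CodonCounts:
    """Per-gene tally of one amino acid's synonymous codons."""

    locus_tag: str
    amino_acid: str
    counts: Mapping[str, int]
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class GeneUsage:
    """Per-gene decoding-tRNA counts and usage fractions (None = undefined)."""

    locus_tag: str
    trna_counts: Mapping[str, int]
    frac_pair: float | None
    frac_all: float | None

    def pct(self, denominator: str = "pair") -> float | None:
        frac = self.frac_pair if denominator == "pair" else self.frac_all
        return None if frac is None else 100.0 * frac


@dataclass(frozen=True)
class GenomeSummary:
    """Genome-pooled codon totals and isoacceptor shares (percent)."""

    amino_acid: str
    codon_totals: Mapping[str, int]
    n_genes: int
    pair_share_of_all: float
    focal_share_of_pair: float | None
    partner_share_of_pair: float | None
    focal: str = "proT"
    partner: str = "proY"

    @property
    def total(self) -> int:
        return sum(self.codon_totals.values())


def count_amino_acid_codons(cds: CodingSequence, amino_acid: str = "P", *,
                            table_id: int = 11) -> CodonCounts:
    """Tally the synonymous codons of ``amino_acid`` in frame 0.

    Triplets containing ambiguity codes (N etc.) are never tallied; they are
    reported in ``ambiguous``. Start and stop codons need no special casing —
    only triplets translating to the target amino acid are counted.
    """
    if len(cds.seq) % 3 != 0:
        raise ValueError(f"{cds.locus_tag}: CDS length {len(cds.seq)} not divisible by 3")
    syn = synonymous_codons(amino_acid, table_id)
    counts = dict.fromkeys(syn, 0)
    ambiguous = 0
    seq = cds.seq.upper()
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in counts:
            counts[codon] += 1
        elif not _BASES.issuperset(codon):
            ambiguous += 1
    return CodonCounts(cds.locus_tag, amino_acid, counts, ambiguous)


def assign_codons_to_trnas(counts: CodonCounts, table: DecoderTable = PROLINE_DECODER,
                           ) -> GeneUsage:
    """Map a gene's codon tally onto decoding tRNAs and compute usage fractions."""
    if table.amino_acid != counts.amino_acid:
        raise ValueError(f"decoder table is for {table.amino_acid!r}, "
                         f"counts are for {counts.amino_acid!r}")
    missing = [c for c, n in counts.counts.items() if n and c not in table.assignments]
    if missing:
        raise ValueError(f"{counts.locus_tag}: codons {missing} absent from decoder table")
    trna_counts: dict[str, int] = {t: 0 for t in dict.fromkeys(table.assignments.values())}
    for codon, n in counts.counts.items():
        if codon in table.assignments:
            trna_counts[table.assignments[codon]] += n
    focal_n = trna_counts[table.focal]
    pair_n = focal_n + trna_counts[table.partner]
    total = counts.total
    return GeneUsage(
        locus_tag=counts.locus_tag,
        trna_counts=trna_counts,
        frac_pair=focal_n / pair_n if pair_n else None,
        frac_all=focal_n / total if total else None,
    )


def genome_proline_summary(usages: Iterable[GeneUsage], counts: Iterable[CodonCounts], *,
                           table: DecoderTable = PROLINE_DECODER) -> GenomeSummary:
    """Genome-wide isoacceptor shares from pooled codon totals.

    Shares are computed from the summed counts, not from the mean of per-gene
    fractions, so long genes weigh proportionally to their codon content.
    """
    counts = list(counts)
    usages = list(usages)
    if not counts:
        raise ValueError("no codon counts supplied")
    totals = dict.fromkeys(synonymous_codons(counts[0].amino_acid, table.table_id), 0)
    for c in counts:
        for codon, n in c.counts.items():
            totals[codon] = totals.get(codon, 0) + n
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no codons of the target amino acid anywhere in the genome")
    focal_n = sum(totals[c] for c in table.codons_of(table.focal))
    partner_n = sum(totals[c] for c in table.codons_of(table.partner))
    pair_n = focal_n + partner_n
    return GenomeSummary(
        amino_acid=counts[0].amino_acid,
        codon_totals=totals,
        n_genes=len(usages),
        pair_share_of_all=100.0 * pair_n / grand,
        focal_share_of_pair=100.0 * focal_n / pair_n if pair_n else None,
        partner_share_of_pair=100.0 * partner_n / pair_n if pair_n else None,
        focal=table.focal,
        partner=table.partner,
    )


def render_rna(codon: str) -> str:
    """Display helper: DNA codon → RNA spelling (CCT → CCU)."""
    return codon.replace("T", "U").replace("t", "u")
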