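"""Readers for annotated genomes and functional-category maps.

Supports GenBank flat files and GFF3+FASTA pairs; both yield the same
:class:`~decodon.records.GeneRecord` representation so downstream code never
sees the input format. CDS extraction is strand-corrected and applies the
exclusion policy (pseudogenes, lengths not divisible by three) without
crashing on annotation noise.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable

from .records import CodingSequence, Exclusion, GeneRecord, resolve_contig, reverse_complement

logger = logging.getLogger("decodon")

#: The ten TubercuList/Mycobrowser functional categories used for
#: protein-coding genes of M. tuberculosis H37Rv.
TUBERCULIST_CATEGORIES = (
    "Virulence, detoxification, adaptation",
    "Lipid metabolism",
    "Information pathways",
    "Cell wall and cell processes",
    "Insertion sequences and phages",
    "PE/PPE",
    "Intermediary metabolism and respiration",
    "Unknown",
    "Regulatory proteins",
    "Conserved hypotheticals",
)

UNASSIGNED = "Unassigned"


class AnnotationFormatError(ValueError):
    """Raised when a genome file does not parse under its declared format."""


class ReferenceMismatchError(ValueError):
    """Raised when GFF3 sequence ids are absent from the companion FASTA."""


class CategoryMap(dict):
    """locus_tag -> functional category, with an optional controlled vocabulary."""

    def __init__(self, mapping: Mapping[str, str] | None = None,
                 vocabulary: Iterable[str] | None = None):
        super().__init__(mapping or {})
        self.vocabulary = frozenset(vocabulary) if vocabulary is not None else None
        if self.vocabulary is not None:
            bad = {c for c in self.values() if c not in self.vocabulary}
            if bad:
                raise ValueError(f"categories outside declared vocabulary: {sorted(bad)}")

    def category_of(self, locus_tag: str) -> str:
        return self.get(locus_tag, UNASSIGNED)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return "genbank"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    raise AnnotationFormatError(
        f"cannot infer format from {path.name!r}; pass fmt='genbank' or 'gff3'")


def _feature_parts(location) -> tuple[tuple[int, int], ...]:
    # Biopython locations are 0-based half-open; store 1-based inclusive,
    # in ascending genomic order regardless of how the join was written.
    parts = sorted((int(p.start) + 1, int(p.end)) for p in location.parts)
    return tuple(parts)


def _read_genbank(path: Path) -> tuple[dict[str, str], list[GeneRecord]]:
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # biopython raises bare ValueError with context
        raise AnnotationFormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not seq_records:
        raise AnnotationFormatError(f"{path}: no GenBank records found")
    genome: dict[str, str] = {}
    genes: list[GeneRecord] = []
    for rec in seq_records:
        genome[rec.id] = str(rec.seq).upper()
        for idx, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            tags = feat.qualifiers.get("locus_tag")
            if not tags:
                logger.warning("%s: CDS feature #%d has no locus_tag; skipped", path.name, idx)
                continue
            parts = _feature_parts(feat.location)
            if len(parts) > 1:
                logger.info("%s: compound location for %s (%d segments)",
                            path.name, tags[0], len(parts))
            genes.append(GeneRecord(
                locus_tag=tags[0],
                start=parts[0][0],
                end=parts[-1][1],
                strand="+" if feat.location.strand != -1 else "-",
                gene_name=feat.qualifiers.get("gene", [None])[0],
                product=feat.qualifiers.get("product", [None])[0],
                is_pseudo="pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers,
                seqid=rec.id,
                parts=parts,
            ))
    logger.info("%s: %d CDS records parsed", path.name, len(genes))
    return genome, genes


def _read_gff3(path: Path, fasta: Path) -> tuple[dict[str, str], list[GeneRecord]]:
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    if not genome:
        raise AnnotationFormatError(f"{fasta}: no FASTA records found")
    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True,
                                merge_strategy="create_unique")
    except Exception as exc:
        raise AnnotationFormatError(f"{path}: not parseable as GFF3: {exc}") from exc

    # multi-line CDS features (one segment per line, same locus tag) are grouped
    grouped: dict[str, list] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS", order_by="start"):
        tag = (feat.attributes.get("locus_tag") or feat.attributes.get("ID") or [None])[0]
        if tag is None:
            logger.warning("%s: CDS at %s:%d-%d has no locus_tag/ID; skipped",
                           path.name, feat.seqid, feat.start, feat.end)
            continue
        tag = tag.removeprefix("cds-")
        if tag not in grouped:
            order.append(tag)
        grouped.setdefault(tag, []).append(feat)

    genes: list[GeneRecord] = []
    for tag in order:
        feats = grouped[tag]
        seqid = feats[0].seqid
        if seqid not in genome:
            raise ReferenceMismatchError(
                f"{path.name}: sequence id {seqid!r} not present in {fasta.name} "
                f"(contigs: {sorted(genome)})")
        parts = tuple(sorted((f.start, f.end) for f in feats))
        if len(parts) > 1:
            logger.info("%s: compound location for %s (%d segments)", path.name, tag, len(parts))
        pseudo = any((f.attributes.get("pseudo") or ["false"])[0].lower() in ("", "true")
                     for f in feats if "pseudo" in f.attributes)
        genes.append(GeneRecord(
            locus_tag=tag,
            start=parts[0][0],
            end=parts[-1][1],
            strand=feats[0].strand if feats[0].strand in "+-" else "+",
            gene_name=(feats[0].attributes.get("gene") or [None])[0],
            product=(feats[0].attributes.get("product") or [None])[0],
            is_pseudo=pseudo,
            seqid=seqid,
            parts=parts,
        ))
    logger.info("%s: %d CDS records parsed", path.name, len(genes))
    return genome, genes


def read_annotated_genome(path: str | Path, *, fasta: str | Path | None = None,
                          fmt: str | None = None) -> tuple[dict[str, str], list[GeneRecord]]:
    """Read an annotated genome into (contig sequences, CDS gene records).

    Parameters
    ----------
    path
        GenBank flat file, or GFF3 file when ``fasta`` is given.
    fasta
        Companion FASTA for GFF3 input.
    fmt
        ``"genbank"`` or ``"gff3"``; inferred from the file suffix if omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _detect_format(path)
    if fmt == "genbank":
        return _read_genbank(path)
    if fmt == "gff3":
        if fasta is None:
            raise ValueError("GFF3 input requires the companion FASTA (fasta=...)")
        return _read_gff3(path, Path(fasta))
    raise AnnotationFormatError(f"unknown format {fmt!r}")


def extract_cds(record: GeneRecord, genome: str | Mapping[str, str]) -> CodingSequence:
    """Strand-corrected coding sequence of one gene.

    Exon segments are concatenated in genomic order; minus-strand genes are
    reverse-complemented after joining, which matches the GenBank
    ``complement(join(...))`` convention.
    """
    contig = resolve_contig(genome, record.seqid)
    if record.end > len(contig) or record.start < 1:
        raise ValueError(f"{record.locus_tag}: coordinates {record.start}-{record.end} "
                         f"outside genome of length {len(contig)}")
    joined = "".join(contig[s - 1:e] for s, e in record.parts)
    if record.strand == "-":
        joined = reverse_complement(joined)
    return CodingSequence(record.locus_tag, joined)


def _has_internal_stop(seq: str, table_id: int) -> bool:
    stops = set(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)
    return any(seq[i:i + 3] in stops for i in range(0, len(seq) - 3, 3))


def extract_all_cds(records: Iterable[GeneRecord], genome: str | Mapping[str, str], *,
                    include_pseudo: bool = False,
                    translation_table: int = 11,
                    ) -> tuple[list[CodingSequence], list[Exclusion]]:
    """Extract every gene's CDS, applying the exclusion policy.

    Pseudogenes are excluded unless ``include_pseudo``; genes whose length is
    not a multiple of three are excluded with reason
    ``"length_not_multiple_of_3"``. Internal stop codons are annotation noise
    and only logged — stops never encode the analysed amino acid, so keeping
    such genes cannot distort codon tallies.
    """
    kept: list[CodingSequence] = []
    excluded: list[Exclusion] = []
    for rec in records:
        if rec.is_pseudo and not include_pseudo:
            excluded.append(Exclusion(rec.locus_tag, "pseudogene"))
            continue
        cds = extract_cds(rec, genome)
        if len(cds.seq) % 3 != 0:
            excluded.append(Exclusion(rec.locus_tag, "length_not_multiple_of_3"))
            continue
        if _has_internal_stop(cds.seq, translation_table):
            logger.warning("%s: internal stop codon (kept)", rec.locus_tag)
        kept.append(cds)
    return kept, excluded


def read_category_map(path: str | Path, *, vocabulary: Iterable[str] | None = None,
                      ) -> CategoryMap:
    """Read a two-column ``locus_tag<TAB>category`` TSV.

    A header row is detected (first field equal to ``locus_tag`` or
    ``Gene ID``, case-insensitive) and skipped. Identical duplicate rows are
    deduplicated; conflicting duplicates are an error listing the offenders.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    conflicts: list[str] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path.name}:{i + 1}: expected 2 tab-separated columns")
            tag, cat = row[0].strip(), row[1].strip()
            if i == 0 and tag.lower() in ("locus_tag", "gene id", "gene_id"):
                continue
            if tag in mapping and mapping[tag] != cat:
                conflicts.append(f"{tag}: {mapping[tag]!r} vs {cat!r}")
            mapping[tag] = cat
    if conflicts:
        raise ValueError("conflicting categories for: " + "; ".join(conflicts))
    if not mapping:
        logger.warning("%s: empty category map", path.name)
    return CategoryMap(mapping, vocabulary=vocabulary)


def write_exclusion_report(exclusions: Iterable[Exclusion], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["locus_tag", "reason"])
        for exc in exclusions:
            writer.writerow([exc.locus_tag, exc.reason])
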