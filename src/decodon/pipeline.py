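"""End-to-end orchestration: genome → per-gene usage → category outputs.

``run_analysis`` is the pure in-memory pipeline; ``run_pipeline`` wraps it
with file input, artifact writing and logging. Data artifacts are
deterministic: identical inputs and configuration produce byte-identical
TSV/JSON files (float formatting is fixed at 8 decimals; the log file also
records wall-clock stage timings and is the one artifact excluded from the
byte-identity guarantee).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import category_analysis, codon_usage, genome_io
from .category_analysis import EnrichmentResult, ThresholdList
from .codon_usage import CodonCounts, DecoderTable, GeneUsage, GenomeSummary, PROLINE_DECODER
from .genome_io import CategoryMap
from .records import CodingSequence, Exclusion, GeneRecord

logger = logging.getLogger("decodon")

_F = "%.8f"


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run; persisted for provenance."""

    genome: Path
    outdir: Path
    fasta: Path | None = None
    fmt: str | None = None
    category_map: Path | None = None
    amino_acid: str = "P"
    denominator: str = "pair"
    threshold: float = 60.0
    enrich_target: str | None = "PE/PPE"
    include_pseudo: bool = False
    decoder: DecoderTable = field(default=PROLINE_DECODER)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.genome = Path(self.genome)
        self.outdir = Path(self.outdir)
        if self.fasta is not None:
            self.fasta = Path(self.fasta)
        if self.category_map is not None:
            self.category_map = Path(self.category_map)
        if self.denominator not in ("pair", "all"):
            raise ValueError(f"denominator must be 'pair' or 'all', got {self.denominator!r}")
        if not 0.0 <= self.threshold <= 100.0:
            raise ValueError("threshold must be in [0, 100]")
        if self.decoder.amino_acid != self.amino_acid:
            raise ValueError("decoder table amino acid does not match config amino_acid")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("genome", "outdir", "fasta", "category_map"):
            if d[key] is not None:
                d[key] = str(d[key])
        d["decoder"] = {"amino_acid": self.decoder.amino_acid,
                        "assignments": dict(self.decoder.assignments),
                        "focal": self.decoder.focal, "partner": self.decoder.partner}
        return d


@dataclass
class AnalysisResult:
    """In-memory results of the codon-usage pipeline."""

    records: list[GeneRecord]
    cds: list[CodingSequence]
    exclusions: list[Exclusion]
    counts: list[CodonCounts]
    usages: list[GeneUsage]
    summary: GenomeSummary
    threshold_list: ThresholdList
    category_report: pd.DataFrame
    enrichment: EnrichmentResult | None


def run_analysis(genome: dict[str, str], records: list[GeneRecord],
                 category_map: CategoryMap | None = None, *,
                 decoder: DecoderTable = PROLINE_DECODER,
                 amino_acid: str = "P",
                 denominator: str = "pair",
                 threshold: float = 60.0,
                 enrich_target: str | None = None,
                 include_pseudo: bool = False) -> AnalysisResult:
    """The full in-memory pipeline on parsed inputs."""
    category_map = category_map if category_map is not None else CategoryMap()
    cds, exclusions = genome_io.extract_all_cds(records, genome,
                                                include_pseudo=include_pseudo)
    counts = [codon_usage.count_amino_acid_codons(c, amino_acid) for c in cds]
    usages = [codon_usage.assign_codons_to_trnas(c, decoder) for c in counts]
    summary = codon_usage.genome_proline_summary(usages, counts, table=decoder)
    tlist = category_analysis.filter_by_threshold(
        usages, threshold, denominator=denominator, category_map=category_map)
    report = category_analysis.category_aggregate(usages, counts, category_map,
                                                  table=decoder)
    enrichment = None
    if enrich_target is not None and enrich_target in set(category_map.values()):
        enrichment = category_analysis.category_enrichment(
            usages, counts, category_map, enrich_target,
            denominator=denominator, table=decoder)
    return AnalysisResult(records, cds, exclusions, counts, usages, summary,
                          tlist, report, enrichment)


def _fmt(x) -> str:
    return "NA" if x is None or (isinstance(x, float) and x != x) else _F % x


def write_artifacts(result: AnalysisResult, config: RunConfig) -> dict[str, Path]:
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    codons = sorted(result.counts[0].counts) if result.counts else []

    paths["per_gene_usage"] = outdir / "per_gene_usage.tsv"
    by_tag = {u.locus_tag: u for u in result.usages}
    with open(paths["per_gene_usage"], "w") as fh:
        fh.write("locus_tag\t" + "\t".join(codons)
                 + "\ttotal_pro\tfrac_pair_pct\tfrac_all_pct\n")
        for c in result.counts:
            u = by_tag[c.locus_tag]
            fh.write(c.locus_tag + "\t"
                     + "\t".join(str(c.counts[cod]) for cod in codons)
                     + f"\t{c.total}\t{_fmt(u.pct('pair'))}\t{_fmt(u.pct('all'))}\n")

    paths["genome_summary"] = outdir / "genome_summary.json"
    s = result.summary
    with open(paths["genome_summary"], "w") as fh:
        json.dump({
            "amino_acid": s.amino_acid,
            "n_genes": s.n_genes,
            "codon_totals": dict(sorted(s.codon_totals.items())),
            "total": s.total,
            "pair_share_of_all_pct": round(s.pair_share_of_all, 8),
            f"{s.focal}_share_of_pair_pct":
                None if s.focal_share_of_pair is None else round(s.focal_share_of_pair, 8),
            f"{s.partner}_share_of_pair_pct":
                None if s.partner_share_of_pair is None else round(s.partner_share_of_pair, 8),
        }, fh, indent=2, sort_keys=False)
        fh.write("\n")

    paths["threshold_list"] = outdir / "threshold_list.tsv"
    with open(paths["threshold_list"], "w") as fh:
        fh.write("Gene ID\tFunctional category\t% proT\n")
        for e in result.threshold_list.entries:
            fh.write(f"{e.locus_tag}\t{e.category}\t{_F % e.pct}\n")

    paths["category_report"] = outdir / "category_report.tsv"
    rep = result.category_report.reset_index()
    for col in ("pooled_pct_pair", "pooled_pct_all", "median_gene_pct_pair"):
        rep[col] = rep[col].map(_fmt)
    rep.to_csv(paths["category_report"], sep="\t", index=False)

    if result.enrichment is not None:
        paths["enrichment"] = outdir / "enrichment.json"
        d = result.enrichment.to_dict()
        with open(paths["enrichment"], "w") as fh:
            json.dump({k: (None if isinstance(v, float) and v != v else v)
                       for k, v in d.items()}, fh, indent=2)
            fh.write("\n")

    paths["exclusions"] = outdir / "exclusions.tsv"
    genome_io.write_exclusion_report(result.exclusions, paths["exclusions"])

    paths["run_config"] = outdir / "run_config.json"
    with open(paths["run_config"], "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
        fh.write("\n")
    return paths


def run_pipeline(config: RunConfig) -> tuple[AnalysisResult, dict[str, Path]]:
    """File-to-file pipeline: read inputs, analyse, write the artifact bundle."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    log_path = config.outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    t0 = time.perf_counter()
    try:
        genome, records = genome_io.read_annotated_genome(
            config.genome, fasta=config.fasta, fmt=config.fmt)
        logger.info("stage=read_genome n_records=%d elapsed=%.3fs",
                    len(records), time.perf_counter() - t0)
        cmap = None
        if config.category_map is not None:
            cmap = genome_io.read_category_map(config.category_map)
        t1 = time.perf_counter()
        result = run_analysis(genome, records, cmap,
                              decoder=config.decoder,
                              amino_acid=config.amino_acid,
                              denominator=config.denominator,
                              threshold=config.threshold,
                              enrich_target=config.enrich_target,
                              include_pseudo=config.include_pseudo)
        logger.info("stage=analysis n_genes=%d n_excluded=%d elapsed=%.3fs",
                    len(result.counts), len(result.exclusions),
                    time.perf_counter() - t1)
        paths = write_artifacts(result, config)
        paths["log"] = log_path
        logger.info("stage=write n_artifacts=%d total_elapsed=%.3fs",
                    len(paths), time.perf_counter() - t0)
        return result, paths
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
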