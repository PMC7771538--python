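"""Synthetic annotated genomes and TnSeq count tables with known ground truth.

Every pipeline stage can be exercised without any external download: the
generator emits a single-contig genome in both annotation formats (GenBank
and GFF3+FASTA), a functional-category map, and a truth table that is exactly
consistent with the emitted sequences — re-counting codons in the emitted CDS
reproduces the truth tallies codon for codon.

Statistical model of a synthetic genome
---------------------------------------
Per gene: interior length (in codons) is lognormal; each interior codon is a
proline codon with a fixed per-gene rate; the gene's proline-codon
composition is a draw from its category's Dirichlet over (CCC, CCG, CCA,
CCT), so categories differ in their mean composition and genes scatter
around it — the same structure as the category-wise spread of real
codon-usage data. Non-proline positions draw uniformly from the non-proline,
non-stop sense codons. Genes alternate between the + and − strand with fixed
intergenic spacers, the simplest layout that still exercises strand logic.

TnSeq tables are negative-binomial: condition A has a per-gene lognormal
abundance around the chosen depth, condition B multiplies it by the planted
fold change, and both conditions draw NB counts with a common dispersion.

All randomness flows from one integer seed through a single
``numpy.random.Generator``; the same seed yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codon_usage import CodonCounts, synonymous_codons
from .genome_io import CategoryMap
from .records import GeneRecord, reverse_complement

PROLINE_CODONS = ("CCC", "CCG", "CCA", "CCT")  # fixed order used everywhere here

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_NON_PROLINE_SENSE = tuple(sorted(
    c for c, aa in _TABLE11.forward_table.items() if aa != "P"))
_STOPS = tuple(sorted(_TABLE11.stop_codons))


@dataclass(frozen=True)
class CategorySpec:
    """Gene count and proline-codon Dirichlet for one functional category."""

    n_genes: int
    dirichlet_alpha: tuple[float, float, float, float]  # over (CCC, CCG, CCA, CCT)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.dirichlet_alpha) != 4 or any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha must be 4 positive concentrations")

    @property
    def mean_fractions(self) -> tuple[float, ...]:
        s = sum(self.dirichlet_alpha)
        return tuple(a / s for a in self.dirichlet_alpha)

    @property
    def expected_pair_share(self) -> float:
        """Analytic E[CCC/(CCC+CCG)] under the Dirichlet (aggregation property)."""
        a_ccc, a_ccg = self.dirichlet_alpha[0], self.dirichlet_alpha[1]
        return a_ccc / (a_ccc + a_ccg)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a synthetic annotated genome.

    Defaults are sized for fast, well-powered pipeline tests: interior gene
    lengths lognormal around ~300 codons (bacterial scale), proline at 5.5%
    of codons (a GC-rich proteome figure), 100 bp intergenic spacers.
    """

    categories: Mapping[str, CategorySpec]
    seed: int = 0
    median_gene_length_codons: float = 300.0
    sigma_log_length: float = 0.45
    min_gene_length_codons: int = 50
    proline_rate: float = 0.055
    intergenic_bp: int = 100
    contig_id: str = "synthetic_1"

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("at least one category is required")
        if self.median_gene_length_codons <= 0 or self.min_gene_length_codons < 1:
            raise ValueError("gene lengths must be positive")
        if not 0.0 < self.proline_rate < 1.0:
            raise ValueError("proline_rate must be in (0, 1)")
        if self.intergenic_bp < 0:
            raise ValueError("intergenic_bp must be non-negative")

    @classmethod
    def default(cls, seed: int = 0) -> "SyntheticGenomeSpec":
        """A ten-category genome emulating the structure of real codon-usage data.

        One surface-antigen-like category ("PE/PPE") is planted with a high
        focal-codon share (pair mean 0.5625); the rest form a mild gradient
        around a CCG-dominant composition, as in a GC-rich proteome.
        """
        base = {
            "Virulence, detoxification, adaptation": (5.6, 11.2, 1.8, 1.4),
            "Lipid metabolism": (5.2, 11.6, 1.8, 1.4),
            "Information pathways": (6.0, 10.8, 1.8, 1.4),
            "Cell wall and cell processes": (6.4, 10.4, 1.8, 1.4),
            "Insertion sequences and phages": (6.8, 10.0, 1.8, 1.4),
            "PE/PPE": (9.0, 7.0, 2.2, 1.8),
            "Intermediary metabolism and respiration": (5.6, 11.2, 1.8, 1.4),
            "Unknown": (6.0, 10.8, 1.8, 1.4),
            "Regulatory proteins": (6.4, 10.4, 1.8, 1.4),
            "Conserved hypotheticals": (5.6, 11.2, 1.8, 1.4),
        }
        cats = {name: CategorySpec(100, alpha) for name, alpha in base.items()}
        return cls(categories=cats, seed=seed)


@dataclass
class SyntheticGenome:
    """A generated genome plus its exact ground truth."""

    spec: SyntheticGenomeSpec
    genome: dict[str, str]
    records: list[GeneRecord]
    category_map: CategoryMap
    gene_truth: pd.DataFrame       # per gene: category, codon draws, Dirichlet p
    category_truth: pd.DataFrame   # per category: alpha, analytic means

    def truth_codon_counts(self) -> list[CodonCounts]:
        """The planted per-gene proline codon tallies, as CodonCounts."""
        out = []
        for row in self.gene_truth.itertuples():
            counts = {c: int(getattr(row, c)) for c in PROLINE_CODONS}
            out.append(CodonCounts(row.locus_tag, "P", counts))
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write GenBank, GFF3+FASTA, category map and truth tables; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genbank": outdir / "genome.gbk",
            "gff3": outdir / "genome.gff3",
            "fasta": outdir / "genome.fasta",
            "category_map": outdir / "category_map.tsv",
            "gene_truth": outdir / "truth_genes.tsv",
            "category_truth": outdir / "truth_categories.tsv",
        }
        contig = self.spec.contig_id
        seq = self.genome[contig]
        _write_genbank(paths["genbank"], contig, seq, self.records)
        _write_gff3(paths["gff3"], contig, len(seq), self.records)
        _write_fasta(paths["fasta"], contig, seq)
        with open(paths["category_map"], "w") as fh:
            fh.write("locus_tag\tcategory\n")
            for tag in sorted(self.category_map):
                fh.write(f"{tag}\t{self.category_map[tag]}\n")
        self.gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False,
                               float_format="%.8f")
        self.category_truth.to_csv(paths["category_truth"], sep="\t", index=False,
                                   float_format="%.8f")
        return paths


def sample_gene_codon_draws(alpha: tuple[float, float, float, float], n_pro: int,
                            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw one gene's proline composition p ~ Dirichlet and counts ~ Multinomial."""
    p = rng.dirichlet(alpha)
    counts = rng.multinomial(n_pro, p)
    return p, counts


def generate_synthetic_genome(spec: SyntheticGenomeSpec,
                              outdir: str | Path | None = None) -> SyntheticGenome:
    """Generate a genome per ``spec``; optionally write all files to ``outdir``."""
    rng = np.random.default_rng(spec.seed)
    spacer = lambda: "".join(rng.choice(list("ACGT"), size=spec.intergenic_bp))
    chunks: list[str] = [spacer()]
    pos = spec.intergenic_bp
    records: list[GeneRecord] = []
    cat_map: dict[str, str] = {}
    truth_rows = []
    idx = 0
    for cat_name, cat in spec.categories.items():
        for _ in range(cat.n_genes):
            idx += 1
            tag = f"SYN{idx:04d}"
            n_interior = max(spec.min_gene_length_codons,
                             int(round(rng.lognormal(np.log(spec.median_gene_length_codons),
                                                     spec.sigma_log_length))))
            n_pro = rng.binomial(n_interior, spec.proline_rate)
            p, pro_counts = sample_gene_codon_draws(cat.dirichlet_alpha, n_pro, rng)
            pro_codons = np.repeat(PROLINE_CODONS, pro_counts)
            rng.shuffle(pro_codons)
            codons = rng.choice(_NON_PROLINE_SENSE, size=n_interior).astype(object)
            if n_pro:
                pro_pos = rng.choice(n_interior, size=n_pro, replace=False)
                codons[pro_pos] = pro_codons
            cds = "ATG" + "".join(codons) + rng.choice(_STOPS)
            strand = "+" if idx % 2 == 1 else "-"
            start = pos + 1
            end = pos + len(cds)
            chunks.append(cds if strand == "+" else reverse_complement(cds))
            chunks.append(spacer())
            pos = end + spec.intergenic_bp
            records.append(GeneRecord(
                locus_tag=tag, start=start, end=end, strand=strand,
                product="synthetic protein", seqid=spec.contig_id))
            cat_map[tag] = cat_name
            truth_rows.append({
                "locus_tag": tag, "category": cat_name,
                "n_codons": n_interior + 2, "n_proline": int(n_pro),
                **{c: int(n) for c, n in zip(PROLINE_CODONS, pro_counts)},
                **{f"p_{c}": p_i for c, p_i in zip(PROLINE_CODONS, p)},
            })
    genome = {spec.contig_id: "".join(chunks)}
    cat_truth = pd.DataFrame([
        {"category": name, "n_genes": cat.n_genes,
         **{f"alpha_{c}": a for c, a in zip(PROLINE_CODONS, cat.dirichlet_alpha)},
         **{f"mean_{c}": m for c, m in zip(PROLINE_CODONS, cat.mean_fractions)},
         "expected_pair_share": cat.expected_pair_share}
        for name, cat in spec.categories.items()
    ])
    result = SyntheticGenome(
        spec=spec, genome=genome, records=records,
        category_map=CategoryMap(cat_map),
        gene_truth=pd.DataFrame(truth_rows),
        category_truth=cat_truth,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def pooled_pair_share_se(pair_totals: np.ndarray, alpha_pair: tuple[float, float]) -> float:
    """Standard error of the pooled CCC/(CCC+CCG) estimator under the generator.

    Per gene, the CCC count given its pair total n_i is beta-binomial with the
    marginal Beta(a, b) of the Dirichlet (aggregation property):
    Var = n_i p(1-p) + n_i(n_i-1) * p(1-p)/(a+b+1). The pooled share divides
    the summed counts by the summed totals.
    """
    a, b = alpha_pair
    p = a / (a + b)
    v_gene = p * (1 - p) / (a + b + 1)
    n = np.asarray(pair_totals, dtype=float)
    var_sum = np.sum(n * p * (1 - p) + n * (n - 1) * v_gene)
    total = n.sum()
    if total == 0:
        raise ValueError("no pair codons at all")
    return float(np.sqrt(var_sum) / total)


# ---------------------------------------------------------------------------
# TnSeq


@dataclass
class SyntheticTnseq:
    """A generated two-condition count table plus its planted truth."""

    table: pd.DataFrame            # locus_tag, reads_A, reads_B
    truth: pd.DataFrame            # locus_tag, mean_A, mean_B, fold, dispersion

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"counts": outdir / "tnseq_counts.tsv", "truth": outdir / "tnseq_truth.tsv"}
        self.table.to_csv(paths["counts"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8f")
        return paths


def generate_synthetic_tnseq(n_genes: int = 100,
                             planted_fold_changes: Mapping[str, float] | None = None,
                             nb_dispersion: float = 0.2,
                             depth: float = 100.0,
                             seed: int = 0,
                             gene_effect_sigma: float = 0.4) -> SyntheticTnseq:
    """Negative-binomial insertion counts for two conditions with planted folds.

    ``planted_fold_changes`` maps locus tags (``TN0001`` ...) to the true
    mean ratio condition-B/condition-A; unlisted genes have fold 1. Dispersion
    is the NB overdispersion d in Var = m + d·m²; ``depth`` is the expected
    condition-A reads per gene, modulated by a per-gene lognormal abundance
    (mean 1) shared by both conditions so it cancels from the true ratio.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    folds = dict(planted_fold_changes or {})
    tags = [f"TN{i:04d}" for i in range(1, n_genes + 1)]
    unknown = set(folds) - set(tags)
    if unknown:
        raise ValueError(f"planted folds for unknown genes: {sorted(unknown)}")
    if any(f <= 0 for f in folds.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    abundance = np.exp(rng.normal(-gene_effect_sigma ** 2 / 2, gene_effect_sigma, n_genes))
    fold_vec = np.array([folds.get(t, 1.0) for t in tags])
    mean_a = depth * abundance
    mean_b = mean_a * fold_vec
    r = 1.0 / nb_dispersion

    def draw(mean: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(r, r / (r + mean))

    table = pd.DataFrame({"locus_tag": tags,
                          "reads_A": draw(mean_a), "reads_B": draw(mean_b)})
    truth = pd.DataFrame({"locus_tag": tags, "mean_A": mean_a, "mean_B": mean_b,
                          "fold": fold_vec, "dispersion": nb_dispersion})
    return SyntheticTnseq(table, truth)


# ---------------------------------------------------------------------------
# writers (GFF3/FASTA are line-oriented; GenBank goes through biopython)


def _write_genbank(path: Path, contig: str, seq: str, records: list[GeneRecord]) -> None:
    rec = SeqRecord(Seq(seq), id=contig, name=contig[:16],
                    description="synthetic genome for codon-usage pipeline tests")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "linear"
    rec.annotations["date"] = "01-JAN-2000"  # fixed for byte-identical output
    rec.features.append(SeqFeature(FeatureLocation(0, len(seq)), type="source"))
    for g in records:
        loc = FeatureLocation(g.start - 1, g.end, strand=1 if g.strand == "+" else -1)
        feat = SeqFeature(loc, type="CDS")
        feat.qualifiers["locus_tag"] = [g.locus_tag]
        if g.product:
            feat.qualifiers["product"] = [g.product]
        rec.features.append(feat)
    SeqIO.write(rec, str(path), "genbank")


def _write_gff3(path: Path, contig: str, length: int, records: list[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in records:
            attrs = f"ID=cds-{g.locus_tag};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(f"{contig}\tdecodon\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n")


def _write_fasta(path: Path, contig: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
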