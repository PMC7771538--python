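"""Shared fixtures: a hand-written two-gene genome in both annotation formats,
and small synthetic genomes. The GenBank/GFF3 texts are composed by hand here
(not by the package's own writers) so they exercise the readers independently."""

from __future__ import annotations

import textwrap

import pytest

from decodon import SyntheticGenomeSpec, CategorySpec, generate_synthetic_genome

# layout of the hand fixture (1-based inclusive):
#   1..60    flank (ACGT repeated)
#  61..78    TST_0001, + strand, CDS ATGCCCCCGCCACCTTAA
#  79..108   flank
# 109..120   TST_0002, - strand, coding seq ATGCCCGGGTAA (genomic: its revcomp)
# 121..140   flank
GENE_A_CDS = "ATGCCCCCGCCACCTTAA"
GENE_B_CDS = "ATGCCCGGGTAA"
FIXTURE_SEQ = (
    "ACGT" * 15
    + GENE_A_CDS
    + "GCATGCATGC" * 3
    + "TTACCCGGGCAT"          # reverse complement of GENE_B_CDS
    + "TTTTGGGGCCCCAAAATTTT"
)
assert len(FIXTURE_SEQ) == 140


def origin_block(seq: str) -> str:
    """Format a sequence as a GenBank ORIGIN section."""
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60].lower()
        groups = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    return "\n".join(lines)


def make_genbank(seq: str, features: str, name: str = "TSTCHR1") -> str:
    return textwrap.dedent(f"""\
        LOCUS       {name:<16}{len(seq):>12} bp    DNA     linear   BCT 01-JAN-2000
        DEFINITION  hand-written fixture.
        ACCESSION   {name}
        VERSION     {name}
        KEYWORDS    .
        SOURCE      synthetic
          ORGANISM  synthetic
        FEATURES             Location/Qualifiers
             source          1..{len(seq)}
        """) + features + "ORIGIN\n" + origin_block(seq) + "\n//\n"


TWO_GENE_FEATURES = """\
     CDS             61..78
                     /locus_tag="TST_0001"
                     /product="demo protein A"
     CDS             complement(109..120)
                     /locus_tag="TST_0002"
                     /product="demo protein B"
"""

TWO_GENE_GFF3 = """\
##gff-version 3
##sequence-region TSTCHR1 1 140
TSTCHR1\ttest\tCDS\t61\t78\t.\t+\t0\tID=cds-TST_0001;locus_tag=TST_0001;product=demo protein A
TSTCHR1\ttest\tCDS\t109\t120\t.\t-\t0\tID=cds-TST_0002;locus_tag=TST_0002;product=demo protein B
"""


@pytest.fixture
def two_gene_genbank(tmp_path):
    path = tmp_path / "two_gene.gbk"
    path.write_text(make_genbank(FIXTURE_SEQ, TWO_GENE_FEATURES))
    return path


@pytest.fixture
def two_gene_gff3(tmp_path):
    gff = tmp_path / "two_gene.gff3"
    gff.write_text(TWO_GENE_GFF3)
    fasta = tmp_path / "two_gene.fasta"
    fasta.write_text(">TSTCHR1\n" + FIXTURE_SEQ + "\n")
    return gff, fasta


def small_spec(seed: int = 42, n_genes: int = 10) -> SyntheticGenomeSpec:
    return SyntheticGenomeSpec(
        categories={
            "HI": CategorySpec(n_genes, (8.0, 2.0, 1.0, 1.0)),
            "LO": CategorySpec(n_genes, (2.0, 8.0, 1.0, 1.0)),
        },
        seed=seed,
        median_gene_length_codons=120.0,
        min_gene_length_codons=30,
        intergenic_bp=50,
    )


@pytest.fixture(scope="session")
def small_genome():
    return generate_synthetic_genome(small_spec())


@pytest.fixture(scope="session")
def default_genome():
    """The package's default ten-category synthetic genome (1000 genes)."""
    return generate_synthetic_genome(SyntheticGenomeSpec.default(seed=2024))
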