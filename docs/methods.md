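# Methods

## Codon → decoding-tRNA model

The analysis treats decoding as a declarative table: each synonymous codon
of one amino acid is assigned to exactly one tRNA isoacceptor
(`DecoderTable`). For proline in *M. tuberculosis* the default is
CCC→proT and CCG→proY, following the tRNA gene naming of the H37Rv genome;
CCA→proU and CCT→proX complete the table. The last two assignments are not
fixed by any published standard, so they are configurable defaults — they
do not affect the pair-denominator statistics, only the labels attached to
the minor codons. No wobble thermodynamics is modelled: if a different
assignment is wanted (e.g. superwobbling), supply a different table.

Counting is a non-overlapping frame-0 triplet scan of each strand-corrected
CDS under NCBI translation table 11. Start and stop codons need no special
casing because only triplets translating to the target amino acid are
tallied; triplets containing ambiguity codes are excluded from the tally and
reported separately. Codons are counted on the DNA alphabet (CCT, not CCU);
`render_rna` exists for display parity with RNA-style text.

### The two denominators

Per gene the focal-isoacceptor share is reported both as
`frac_pair = CCC/(CCC+CCG)` and `frac_all = CCC/(all proline codons)`.
Published per-gene percentages of this kind rarely state their denominator.
The pair convention is this package's default for the threshold list and the
summary split because the genome-level proY/proT figures it pairs with sum
to 100% — a pair-conditional reading — and because proT-vs-proY is the
biologically loaded contrast (the two decode ~86% of all proline in H37Rv).
The choice is a `denominator` switch everywhere, and both values are always
written to the per-gene table, so nothing is lost if the other convention is
preferred. Fractions with a zero denominator are carried as missing values,
never as 0: a gene with no CCC/CCG proline has no pair share.

Genome and category summaries pool **counts** before dividing (so genes
weigh by their codon content); the median of per-gene fractions is reported
alongside as the unweighted view. Percentages are kept at full float
precision internally and printed at 8 decimals in TSV output so individual
cells can be compared against published full-precision tables.

### Threshold list

The ≥60% gene list uses an inclusive comparison: published lists of this
kind contain entries at exactly 60, which forces ≥ rather than >. Genes
with undefined fractions are excluded from the list and reported apart.
Entries sort by category, then ascending percentage, then locus tag (the
last key only to make output deterministic under ties).

### Enrichment

Whether a category (e.g. PE/PPE, containing the glycine-rich PE-PGRS
surface antigens) over-uses the focal tRNA is tested two ways, and both are
always reported: a two-sided Mann-Whitney U on per-gene pair fractions
(target vs all other genes — robust, one vote per gene) and a Fisher exact
test on the pooled 2×2 table (focal vs partner counts × target vs rest —
one vote per codon, with the sample odds ratio as effect size). The two
answer different questions and can legitimately disagree when a category is
dominated by a few long genes; no single "correct" test is designated. A
degenerate table (zero margin) yields p = 1 with a `degenerate` flag rather
than an error.

## Genome input

GenBank and GFF3+FASTA inputs map onto the same `GeneRecord` type;
coordinates are stored 1-based inclusive (the native convention of both
formats). Compound (joined) locations are concatenated in genomic order and
reverse-complemented after joining for minus-strand genes, matching
`complement(join(...))`; each is logged. Exclusion policy: pseudogenes are
excluded by default (includable by flag — their codon content is not under
translational selection in the same sense); CDSs whose length is not a
multiple of three are excluded with a reasoned entry in the exclusion
report; internal stop codons are logged but the gene is kept, since
annotation noise should not silently drop genes and stops never enter the
tally of a sense amino acid. Included + excluded always partitions the
parsed records.

## TnSeq fold screen

The screen scores a per-gene two-condition count table. With TA-site
columns present, reads are divided by the gene's TA-site count first
("reads per TA insertion site"); the ratio is `(rate_B + pc)/(rate_A + pc)`
with pseudocount default 1 (zeros are inevitable in insertion data), and
the over-representation flag uses a strict > comparison against the fold
threshold (default 2). Library-size normalisation (scaling both conditions
to equal totals) is available but off by default, since per-TA-site rates
are typically depth-conditioned upstream; whether a given published screen
normalised first is usually unstated, hence a flag rather than an
assumption. Read mapping, TA-site calling and resampling-based essentiality
statistics are out of scope.

## Synthetic data generator

The generator exists so that every stage has a testable ground truth
without network access. Per gene: interior length ~ lognormal (median 300
codons, σ_log 0.45, floor 50 — bacterial scale); each interior codon is
proline with probability 0.055 (a GC-rich-proteome figure); the gene's
proline-codon composition is drawn from its category's Dirichlet over
(CCC, CCG, CCA, CCT); non-proline positions draw uniformly from the 57
non-proline sense codons; every CDS is ATG + interior + stop. Genes
alternate strands with 100 bp intergenic spacers on a single contig — the
simplest layout that exercises strand correction. The default ten-category
spec plants "PE/PPE" with pair mean 0.5625 and spreads the others over
pair means 0.31–0.40 around a CCG-dominant composition (pooled pair share
of all proline ≈ 84%, proT-within-pair ≈ 37–38%), mirroring the structure
of real mycobacterial codon-usage data at roughly quarter genome size
(1,000 genes) to keep test runs fast.

What it does **not** emulate: GC skew, operons, overlapping or nested genes,
amino-acid composition beyond proline, multi-contig assemblies, and any
correlation between gene length and category. Passing the recovery tests
therefore shows the pipeline measures what the model plants, not that real
genomes satisfy the model.

Analytic recovery targets: under a Dirichlet, the pair-conditional mean
E[p_CCC/(p_CCC+p_CCG)] equals α_CCC/(α_CCC+α_CCG) (aggregation property),
and each gene's CCC count given its pair total is beta-binomial, giving the
pooled-share standard error computed by `pooled_pair_share_se`. Recovery
checks assert agreement within 3 SE.

TnSeq generation draws negative-binomial counts (Var = m + d·m²) with a
per-gene lognormal abundance shared by both conditions (so it cancels from
the true ratio) and planted fold changes on chosen genes. Dispersion 0.2 is
a realistic per-library figure at which the fold estimate is noisy — median
recovery is tested there — while the perfect-recovery check runs at
dispersion 0.01 with depth 2000, the regime of counts pooled over many TA
sites at deep coverage, where a 4-fold planted effect separates cleanly
from nulls at a 2-fold cutoff.

All randomness flows through one `numpy.random.Generator` seeded from a
single integer; equal seeds give byte-identical output files (the GenBank
date field is pinned for this reason).

## Determinism and numerics

Pipeline data artifacts (TSV/JSON) are byte-identical across runs on
identical inputs: floats print at 8 decimals, dict orderings are fixed, and
sorting always ends in a locus-tag tie-break. The run log records
wall-clock stage timings and is the one artifact excluded from the
byte-identity guarantee. Undefined fractions propagate as `None`/`NA`, not
zero. The Mann-Whitney implementation follows scipy's `auto` method (exact
for small tie-free samples, tie-corrected normal approximation otherwise);
the suite verifies exactness against a brute-force permutation enumeration
on a small separated example and calibration (type-I error and p-value
uniformity) on simulated nulls.

## Reproduction of published H37Rv numbers

The reproduction tests require the AL123456 genome, an external ~4.4 Mb
download not bundled with the package; they run the real pipeline when the
file is placed under `data/h37rv/` and otherwise fail with instructions.
The bundled 136-gene reference list ships with the package
(`decodon.load_h37rv_reference`) and is used for per-gene regression
comparison. Two open points are resolved as follows: the per-gene
percentage denominator defaults to the pair convention (rationale above),
and PE-PGRS membership is taken from the annotation's product/gene names
(or a supplied category map) since no full roster is bundled.
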