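"""Full pipeline on a synthetic annotated genome with known ground truth.

Generates the default ten-category genome (1,000 genes, one high-proT
"PE/PPE"-like category), writes it in GenBank+GFF3+FASTA, re-reads it, and
runs codon counting → tRNA assignment → genome summary → ≥60% threshold list.
"""

import tempfile

from decodon import (
    SyntheticGenomeSpec,
    generate_synthetic_genome,
    read_annotated_genome,
    run_analysis,
)

sg = generate_synthetic_genome(SyntheticGenomeSpec.default(seed=7))
with tempfile.TemporaryDirectory() as tmp:
    paths = sg.write(tmp)
    genome, records = read_annotated_genome(paths["genbank"])

result = run_analysis(genome, records, sg.category_map, enrich_target="PE/PPE")

s = result.summary
print(f"genes analysed:            {s.n_genes}")
print(f"proline codons in genome:  {s.total}")
print(f"CCC+CCG share of proline:  {s.pair_share_of_all:.2f}%")
print(f"proT share within pair:    {s.focal_share_of_pair:.2f}%")
print(f"genes at >=60% proT:       {len(result.threshold_list)}")
print()
print("Planted vs recovered pooled proT share (pair denominator), per category:")
report = result.category_report
for row in sg.category_truth.itertuples():
    got = report.loc[row.category, "pooled_pct_pair"]
    print(f"  {row.category:<42} planted {100 * row.expected_pair_share:6.2f}%"
          f"  recovered {got:6.2f}%")
print()
print("The recovered shares track the planted Dirichlet means; the PE/PPE-like")
print("category stands out, which is what drives its threshold-list membership.")
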