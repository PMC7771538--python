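"""Is one functional category enriched for proT-decoded proline?

Generates a genome whose "PE/PPE" category is planted with a high CCC share,
then tests it against all other genes two ways: a Mann-Whitney U on per-gene
fractions (each gene weighs once) and a Fisher exact test on pooled codon
counts (each codon weighs once).
"""

from decodon import (
    SyntheticGenomeSpec,
    assign_codons_to_trnas,
    category_enrichment,
    count_amino_acid_codons,
    extract_all_cds,
    generate_synthetic_genome,
)

sg = generate_synthetic_genome(SyntheticGenomeSpec.default(seed=42))
cds, _ = extract_all_cds(sg.records, sg.genome)
counts = [count_amino_acid_codons(c) for c in cds]
usages = [assign_codons_to_trnas(c) for c in counts]

res = category_enrichment(usages, counts, sg.category_map, "PE/PPE")
print(f"target category:      PE/PPE ({res.n_target} genes vs {res.n_background})")
print(f"pooled proT of pair:  {res.pooled_pct_target:.2f}% vs "
      f"{res.pooled_pct_background:.2f}% in the rest")
print(f"Mann-Whitney U:       U={res.mannwhitney_u:.0f}, p={res.mannwhitney_p:.2e}")
print(f"Fisher exact (2x2):   OR={res.fisher_odds_ratio:.2f}, p={res.fisher_p:.2e}")
print()
print("Both tests agree the planted category over-uses the proT codon: the")
print("odds ratio says each of its proline codons is ~2-3x as likely to be CCC")
print("(vs CCG) as elsewhere in the genome.")
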