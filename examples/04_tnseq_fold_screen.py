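"""Transposon-screen curation: flag mutants over-represented >2-fold.

Simulates a two-condition insertion-count table (condition B = growth on an
alternative carbon source) with six genes planted at 4-fold over-representation,
then recovers them with the fold-change filter.
"""

from decodon import generate_synthetic_tnseq, screen

planted = {f"TN{i:04d}": 4.0 for i in range(1, 7)}
st = generate_synthetic_tnseq(n_genes=100, planted_fold_changes=planted,
                              nb_dispersion=0.01, depth=2000, seed=5)
annotated, flagged = screen(st.table, pseudocount=1.0, fold_threshold=2.0)

print(f"{len(flagged)} of {len(annotated)} genes exceed the 2-fold threshold:")
print(f"{'gene':<10}{'reads A':>9}{'reads B':>9}{'ratio':>8}  planted fold")
truth = st.truth.set_index("locus_tag")
for row in flagged.itertuples():
    print(f"{row.locus_tag:<10}{row.reads_A:>9}{row.reads_B:>9}{row.ratio:>8.2f}"
          f"  {truth.loc[row.locus_tag, 'fold']:.0f}")
print()
print("ratio = (B+1)/(A+1); the flag uses a strict > comparison. At deep,")
print("low-dispersion coverage exactly the six planted genes are recovered.")
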