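"""Count proline codons in a few coding sequences and map them to tRNAs.

Builds three tiny CDSs by hand, tallies their proline codons, and prints the
per-gene proT usage under both denominator conventions.
"""

from decodon import CodingSequence, assign_codons_to_trnas, count_amino_acid_codons

genes = {
    "demo1": "ATG" + "CCC" * 6 + "CCG" * 4 + "TAA",   # proT-rich: 6 CCC vs 4 CCG
    "demo2": "ATG" + "CCG" * 9 + "CCC" * 1 + "TAA",   # proY-dominated
    "demo3": "ATG" + "CCA" * 5 + "TAA",               # only proU codons: pair undefined
}

print(f"{'gene':<8}{'CCC':>5}{'CCG':>5}{'CCA':>5}{'CCT':>5}   pair%    all%")
for tag, seq in genes.items():
    counts = count_amino_acid_codons(CodingSequence(tag, seq))
    usage = assign_codons_to_trnas(counts)
    fmt = lambda p: "   undef" if p is None else f"{p:8.2f}"
    print(f"{tag:<8}"
          + "".join(f"{counts.counts[c]:>5}" for c in ("CCC", "CCG", "CCA", "CCT"))
          + fmt(usage.pct("pair")) + fmt(usage.pct("all")))

print()
print("pair% = CCC/(CCC+CCG): the share of the proT/proY pair decoded by proT.")
print("all%  = CCC/all proline codons. demo3 has no CCC or CCG, so its pair")
print("share is undefined (reported as missing, never as zero).")
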