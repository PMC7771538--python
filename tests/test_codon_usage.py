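"""Codon tallies, tRNA assignment, and genome-level shares.

The counting path is validated against an independent brute-force oracle
that translates every triplet with biopython and tallies matches.
"""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from decodon import (
    DecoderTable,
    PROLINE_DECODER,
    assign_codons_to_trnas,
    count_amino_acid_codons,
    genome_proline_summary,
    synonymous_codons,
)
from decodon.codon_usage import CodonCounts, render_rna
from decodon.records import CodingSequence


def oracle_counts(seq: str, amino_acid: str) -> dict[str, int]:
    """Naive per-triplet translate-and-count, independent of the package path."""
    out: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3].upper()
        if set(codon) <= set("ACGT") and str(Seq(codon).translate(table=11)) == amino_acid:
            out[codon] = out.get(codon, 0) + 1
    return out


class TestCounting:
    def test_all_four_proline_codons(self):
        c = count_amino_acid_codons(CodingSequence("g", "ATGCCCCCGCCACCTTAA"))
        assert c.counts == {"CCC": 1, "CCG": 1, "CCA": 1, "CCT": 1}
        assert c.total == 4

    def test_no_proline(self):
        assert count_amino_acid_codons(CodingSequence("g", "ATGTAA")).total == 0

    def test_ambiguous_triplets_skipped_and_tallied(self):
        c = count_amino_acid_codons(CodingSequence("g", "CCNCCCNNN"))
        assert c.counts["CCC"] == 1 and c.total == 1
        assert c.ambiguous == 2

    def test_unknown_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="amino-acid"):
            count_amino_acid_codons(CodingSequence("g", "ATGTAA"), "B")

    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible"):
            count_amino_acid_codons(CodingSequence("g", "ATGC"))

    @pytest.mark.parametrize("amino_acid", ["P", "L", "A", "G"])
    def test_matches_brute_force_oracle(self, amino_acid):
        """1,000 random CDSs: counts equal the translate-every-triplet oracle."""
        rng = np.random.default_rng(1234)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            n = int(rng.integers(10, 200)) * 3
            seq = "".join(rng.choice(bases, size=n))
            got = count_amino_acid_codons(CodingSequence("g", seq), amino_acid)
            expected = oracle_counts(seq, amino_acid)
            nonzero = {c: n_ for c, n_ in got.counts.items() if n_}
            assert nonzero == expected
            assert got.total == sum(expected.values())


def usage_of(ccc, ccg, cca, cct):
    counts = CodonCounts("g", "P", {"CCC": ccc, "CCG": ccg, "CCA": cca, "CCT": cct})
    return assign_codons_to_trnas(counts)


class TestAssignment:
    def test_symmetric_counts(self):
        u = usage_of(1, 1, 1, 1)
        assert u.frac_pair == 0.5 and u.frac_all == 0.25

    def test_undefined_pair_is_none_not_zero(self):
        u = usage_of(0, 0, 2, 0)
        assert u.frac_pair is None
        assert u.frac_all == 0.0

    def test_no_proline_both_undefined(self):
        u = usage_of(0, 0, 0, 0)
        assert u.frac_pair is None and u.frac_all is None
        assert u.pct("pair") is None

    def test_trna_counts_conserve_total(self):
        u = usage_of(3, 2, 1, 4)
        assert sum(u.trna_counts.values()) == 10

    def test_codon_missing_from_table_is_error(self):
        partial = DecoderTable("P", {"CCC": "proT", "CCG": "proY"},
                               focal="proT", partner="proY")
        counts = CodonCounts("g", "P", {"CCC": 1, "CCA": 2})
        with pytest.raises(ValueError, match="CCA"):
            assign_codons_to_trnas(counts, partial)

    def test_amino_acid_mismatch_is_error(self):
        ala = DecoderTable("A", {"GCA": "alaT", "GCC": "alaU"},
                           focal="alaT", partner="alaU")
        with pytest.raises(ValueError, match="decoder table"):
            assign_codons_to_trnas(CodonCounts("g", "P", {"CCC": 1}), ala)

    @given(ccc=st.integers(0, 50), ccg=st.integers(0, 50),
           cca=st.integers(0, 50), cct=st.integers(0, 50),
           k=st.integers(2, 5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_fraction_properties(self, ccc, ccg, cca, cct, k):
        """frac_all <= frac_pair; fractions invariant under count scaling."""
        u = usage_of(ccc, ccg, cca, cct)
        if u.frac_pair is not None and u.frac_all is not None:
            assert u.frac_all <= u.frac_pair + 1e-12
        scaled = usage_of(k * ccc, k * ccg, k * cca, k * cct)
        assert (u.frac_pair is None) == (scaled.frac_pair is None)
        if u.frac_pair is not None:
            assert scaled.frac_pair == pytest.approx(u.frac_pair)


class TestGenomeSummary:
    def test_hand_summable_two_genes(self):
        counts = [CodonCounts("a", "P", {"CCC": 1, "CCG": 0, "CCA": 0, "CCT": 1}),
                  CodonCounts("b", "P", {"CCC": 0, "CCG": 1, "CCA": 1, "CCT": 0})]
        usages = [assign_codons_to_trnas(c) for c in counts]
        s = genome_proline_summary(usages, counts)
        assert s.pair_share_of_all == pytest.approx(50.0)
        assert s.focal_share_of_pair == pytest.approx(50.0)

    def test_shares_within_pair_sum_to_100(self, small_genome):
        from decodon import extract_all_cds
        cds, _ = extract_all_cds(small_genome.records, small_genome.genome)
        counts = [count_amino_acid_codons(c) for c in cds]
        usages = [assign_codons_to_trnas(c) for c in counts]
        s = genome_proline_summary(usages, counts)
        assert s.focal_share_of_pair + s.partner_share_of_pair == pytest.approx(100.0)
        # conservation: per-gene totals sum to the genome total
        assert s.total == sum(c.total for c in counts)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            genome_proline_summary([], [])


class TestDecoderTable:
    def test_non_synonymous_codon_rejected(self):
        with pytest.raises(ValueError, match="do not encode"):
            DecoderTable("P", {"ATG": "proT", "CCG": "proY"},
                         focal="proT", partner="proY")

    def test_focal_must_be_assigned(self):
        with pytest.raises(ValueError, match="focal"):
            DecoderTable("P", {"CCC": "proT", "CCG": "proY"},
                         focal="proZ", partner="proY")

    def test_default_table_covers_all_proline_codons(self):
        assert set(PROLINE_DECODER.assignments) == set(synonymous_codons("P"))
        assert PROLINE_DECODER.codons_of("proT") == ("CCC",)

    def test_rna_rendering(self):
        assert render_rna("CCT") == "CCU"
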