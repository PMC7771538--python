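"""Threshold gene lists, category aggregation, and enrichment tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from decodon import (
    assign_codons_to_trnas,
    category_aggregate,
    category_enrichment,
    filter_by_threshold,
)
from decodon.codon_usage import CodonCounts, GeneUsage
from decodon.synthetic import PROLINE_CODONS, sample_gene_codon_draws


def usage(tag, pct):
    frac = None if pct is None else pct / 100.0
    return GeneUsage(tag, {}, frac_pair=frac, frac_all=frac)


def counts_from(tag, ccc, ccg, cca=0, cct=0):
    return CodonCounts(tag, "P", {"CCC": ccc, "CCG": ccg, "CCA": cca, "CCT": cct})


class TestThresholdFilter:
    def test_inclusive_at_the_threshold(self):
        """A gene at exactly 60 is kept; undefined fractions are set aside."""
        usages = [usage("g1", 60.0), usage("g2", 59.99), usage("g3", 100.0),
                  usage("g4", 0.0), usage("g5", None)]
        out = filter_by_threshold(usages, 60.0)
        assert out.locus_tags() == ["g1", "g3"]
        assert out.undefined == ("g5",)

    def test_zero_threshold_keeps_all_defined(self):
        usages = [usage("g1", 60.0), usage("g2", 0.0), usage("g3", None)]
        assert len(filter_by_threshold(usages, 0.0)) == 2

    def test_sorted_by_category_then_ascending_pct(self):
        usages = [usage("g1", 90.0), usage("g2", 70.0), usage("g3", 80.0)]
        cmap = {"g1": "B-cat", "g2": "A-cat", "g3": "A-cat"}
        out = filter_by_threshold(usages, 60.0, category_map=cmap)
        assert [(e.locus_tag, e.category) for e in out.entries] == [
            ("g2", "A-cat"), ("g3", "A-cat"), ("g1", "B-cat")]

    def test_raising_threshold_never_adds_genes(self, default_genome):
        from decodon import count_amino_acid_codons, extract_all_cds
        cds, _ = extract_all_cds(default_genome.records, default_genome.genome)
        usages = [assign_codons_to_trnas(count_amino_acid_codons(c)) for c in cds]
        previous = None
        for pct in [0, 20, 40, 50, 60, 70, 80, 90, 100]:
            current = set(filter_by_threshold(usages, pct).locus_tags())
            if previous is not None:
                assert current <= previous
            previous = current

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            filter_by_threshold([], 101.0)


class TestAggregate:
    def test_single_category_pooled_from_summed_counts(self):
        counts = [counts_from("a", 1, 0, 0, 1), counts_from("b", 0, 1, 1, 0)]
        usages = [assign_codons_to_trnas(c) for c in counts]
        report = category_aggregate(usages, counts, {"a": "X", "b": "X"})
        assert report.loc["X", "n_genes"] == 2
        assert report.loc["X", "pooled_pct_pair"] == pytest.approx(50.0)

    def test_unmapped_genes_pool_under_unassigned(self):
        counts = [counts_from("a", 2, 2), counts_from("b", 1, 3)]
        usages = [assign_codons_to_trnas(c) for c in counts]
        report = category_aggregate(usages, counts, {"a": "X"})
        assert set(report.index) == {"X", "Unassigned"}

    def test_category_counts_partition_genome_totals(self, default_genome):
        from decodon import count_amino_acid_codons, extract_all_cds, genome_proline_summary
        sg = default_genome
        cds, _ = extract_all_cds(sg.records, sg.genome)
        counts = [count_amino_acid_codons(c) for c in cds]
        usages = [assign_codons_to_trnas(c) for c in counts]
        report = category_aggregate(usages, counts, sg.category_map)
        summary = genome_proline_summary(usages, counts)
        for codon, total in summary.codon_totals.items():
            assert report[codon].sum() == total

    def test_planted_category_means_recovered(self, default_genome):
        """Pooled pair shares sit within 3 SE of each category's Dirichlet mean."""
        from decodon import count_amino_acid_codons, extract_all_cds, pooled_pair_share_se
        sg = default_genome
        cds, _ = extract_all_cds(sg.records, sg.genome)
        counts = [count_amino_acid_codons(c) for c in cds]
        usages = [assign_codons_to_trnas(c) for c in counts]
        report = category_aggregate(usages, counts, sg.category_map)
        truth = sg.gene_truth
        for row in sg.category_truth.itertuples():
            pooled = report.loc[row.category, "pooled_pct_pair"] / 100.0
            pair_totals = (truth.loc[truth.category == row.category, "CCC"]
                           + truth.loc[truth.category == row.category, "CCG"]).to_numpy()
            se = pooled_pair_share_se(pair_totals, (row.alpha_CCC, row.alpha_CCG))
            assert abs(pooled - row.expected_pair_share) <= 3 * se


def permutation_pvalue(target, background):
    """Brute-force two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = list(target) + list(background)
    n_t = len(target)
    mu = n_t * len(background) / 2.0

    def u_stat(idx):
        tgt = [pooled[i] for i in idx]
        bgr = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum((x > y) + 0.5 * (x == y) for x in tgt for y in bgr)

    observed = abs(u_stat(set(range(n_t))) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_t):
        total += 1
        hits += abs(u_stat(set(combo)) - mu) >= observed - 1e-12
    return hits / total


class TestEnrichment:
    def test_fully_separated_matches_permutation_oracle(self):
        """Tie-free separated groups: reported p equals the exact permutation p."""
        tgt_pcts = [80.0, 82.0, 84.0, 86.0, 88.0, 90.0]
        bgr_pcts = [10.0, 12.0, 14.0, 16.0, 18.0, 20.0]
        counts, usages, cmap = [], [], {}
        for i, pct in enumerate(tgt_pcts + bgr_pcts):
            tag = f"g{i}"
            cmap[tag] = "T" if i < len(tgt_pcts) else "B"
            ccc = int(round(pct))
            counts.append(counts_from(tag, ccc, 100 - ccc))
            usages.append(assign_codons_to_trnas(counts[-1]))
        res = category_enrichment(usages, counts, cmap, "T")
        expected = permutation_pvalue(tgt_pcts, bgr_pcts)
        assert res.mannwhitney_p == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(2 / 924)

    def test_odds_ratio_of_hand_table(self):
        counts = [counts_from("t", 90, 10), counts_from("b", 10, 90)]
        usages = [assign_codons_to_trnas(c) for c in counts]
        res = category_enrichment(usages, counts, {"t": "T", "b": "B"}, "T")
        assert res.fisher_odds_ratio == pytest.approx(81.0)

    def test_degenerate_table_reports_p_one(self):
        counts = [counts_from("t", 0, 0, 5, 0), counts_from("b", 0, 0, 0, 5)]
        usages = [assign_codons_to_trnas(c) for c in counts]
        res = category_enrichment(usages, counts, {"t": "T", "b": "B"}, "T")
        assert res.degenerate and res.fisher_p == 1.0

    def test_empty_target_is_error(self):
        counts = [counts_from("b", 1, 1)]
        usages = [assign_codons_to_trnas(c) for c in counts]
        with pytest.raises(ValueError, match="matches no genes"):
            category_enrichment(usages, counts, {"b": "B"}, "T")

    def test_null_pvalues_roughly_uniform(self):
        """Same Dirichlet for target and rest: p-values pass a KS uniformity check."""
        rng = np.random.default_rng(5)
        alpha = (6.0, 10.8, 1.8, 1.4)
        pvals = []
        for _ in range(200):
            counts, cmap = [], {}
            for i in range(60):
                tag = f"g{i}"
                _, draws = sample_gene_codon_draws(alpha, int(rng.poisson(15)), rng)
                counts.append(CodonCounts(tag, "P",
                                          dict(zip(PROLINE_CODONS, map(int, draws)))))
                cmap[tag] = "T" if i < 15 else "B"
            usages = [assign_codons_to_trnas(c) for c in counts]
            pvals.append(category_enrichment(usages, counts, cmap, "T").mannwhitney_p)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3
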