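"""Functional-category aggregation, threshold gene lists, and enrichment.

Per-category pooled percentages are computed from summed codon counts within
the category (length-weighted), with the median of per-gene fractions shown
alongside as the unweighted view. Enrichment of a target category (e.g. the
PE/PPE family) is tested twice, on deliberately different scales:

* Mann-Whitney U on per-gene usage fractions, target vs all other genes —
  every gene counts once regardless of length;
* Fisher's exact test on the pooled focal-vs-partner codon counts in a 2×2
  table (target vs rest), with the sample odds ratio as effect size.

Neither is privileged; they answer "are genes shifted?" and "are codons
shifted?" respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_usage import CodonCounts, DecoderTable, GeneUsage, PROLINE_DECODER
from .genome_io import CategoryMap, UNASSIGNED


@dataclass(frozen=True)
class ThresholdEntry:
    locus_tag: str
    category: str
    pct: float


@dataclass(frozen=True)
class ThresholdList:
    """Genes whose focal-tRNA usage meets a percentage threshold (inclusive)."""

    threshold: float
    denominator: str
    entries: tuple[ThresholdEntry, ...]
    undefined: tuple[str, ...]  # genes with no defined fraction, reported apart

    def __len__(self) -> int:
        return len(self.entries)

    def locus_tags(self) -> list[str]:
        return [e.locus_tag for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.locus_tag, e.category, e.pct) for e in self.entries],
            columns=["locus_tag", "category", "pct"],
        )


def filter_by_threshold(usages: Iterable[GeneUsage], min_pct: float = 60.0, *,
                        denominator: str = "pair",
                        category_map: CategoryMap | Mapping[str, str] | None = None,
                        ) -> ThresholdList:
    """Genes with focal-tRNA usage ≥ ``min_pct`` percent.

    The comparison is inclusive (a gene at exactly the threshold is kept).
    Genes whose fraction is undefined under the chosen denominator are
    excluded and listed separately. Entries are sorted by category, then
    ascending percentage, then locus tag.
    """
    if not 0.0 <= min_pct <= 100.0:
        raise ValueError(f"min_pct must be in [0, 100], got {min_pct}")
    if denominator not in ("pair", "all"):
        raise ValueError(f"denominator must be 'pair' or 'all', got {denominator!r}")
    cat = category_map or {}
    entries: list[ThresholdEntry] = []
    undefined: list[str] = []
    for u in usages:
        pct = u.pct(denominator)
        if pct is None:
            undefined.append(u.locus_tag)
        elif pct >= min_pct:
            entries.append(ThresholdEntry(u.locus_tag, cat.get(u.locus_tag, UNASSIGNED), pct))
    entries.sort(key=lambda e: (e.category, e.pct, e.locus_tag))
    return ThresholdList(min_pct, denominator, tuple(entries), tuple(sorted(undefined)))


def category_aggregate(usages: Sequence[GeneUsage], counts: Sequence[CodonCounts],
                       category_map: CategoryMap | Mapping[str, str], *,
                       table: DecoderTable = PROLINE_DECODER) -> pd.DataFrame:
    """Per-category codon totals and pooled/median usage percentages.

    Returns one row per category (loci absent from the map pooled under
    ``Unassigned``): gene count, summed counts per codon, pooled percentages
    under both denominators, and the median per-gene pair percentage. Pooled
    category counts partition the genome totals exactly.
    """
    if not counts:
        raise ValueError("no codon counts supplied")
    by_tag = {u.locus_tag: u for u in usages}
    codons = sorted(counts[0].counts)
    focal_codons = set(table.codons_of(table.focal))
    partner_codons = set(table.codons_of(table.partner))
    rows: dict[str, dict] = {}
    for c in counts:
        cat = category_map.get(c.locus_tag, UNASSIGNED)
        row = rows.setdefault(cat, {"category": cat, "n_genes": 0,
                                    **{cod: 0 for cod in codons}, "_pair_pcts": []})
        row["n_genes"] += 1
        for cod, n in c.counts.items():
            row[cod] += n
        u = by_tag.get(c.locus_tag)
        if u is not None and u.frac_pair is not None:
            row["_pair_pcts"].append(100.0 * u.frac_pair)
    out = []
    for cat in sorted(rows):
        row = rows[cat]
        focal_n = sum(row[cod] for cod in focal_codons)
        partner_n = sum(row[cod] for cod in partner_codons)
        pair_n = focal_n + partner_n
        total = sum(row[cod] for cod in codons)
        pcts = row.pop("_pair_pcts")
        row["total"] = total
        row["pooled_pct_pair"] = 100.0 * focal_n / pair_n if pair_n else np.nan
        row["pooled_pct_all"] = 100.0 * focal_n / total if total else np.nan
        row["median_gene_pct_pair"] = float(np.median(pcts)) if pcts else np.nan
        out.append(row)
    return pd.DataFrame(out).set_index("category")


@dataclass(frozen=True)
class EnrichmentResult:
    """Two-pronged enrichment of a target category in focal-tRNA usage."""

    target: str
    n_target: int
    n_background: int
    mannwhitney_u: float
    mannwhitney_p: float
    fisher_odds_ratio: float
    fisher_p: float
    pooled_pct_target: float
    pooled_pct_background: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def category_enrichment(usages: Sequence[GeneUsage], counts: Sequence[CodonCounts],
                        category_map: CategoryMap | Mapping[str, str], target: str, *,
                        denominator: str = "pair",
                        table: DecoderTable = PROLINE_DECODER) -> EnrichmentResult:
    """Test whether ``target`` genes over-use the focal tRNA vs the rest.

    A degenerate 2×2 table (a zero row or column margin) yields p = 1 with
    ``degenerate=True`` rather than an error.
    """
    in_target = {tag for tag, cat in category_map.items() if cat == target}
    if not any(u.locus_tag in in_target for u in usages):
        raise ValueError(f"target category {target!r} matches no genes")

    tgt_fracs, bgr_fracs = [], []
    for u in usages:
        pct = u.pct(denominator)
        if pct is None:
            continue
        (tgt_fracs if u.locus_tag in in_target else bgr_fracs).append(pct)
    if tgt_fracs and bgr_fracs:
        mwu = stats.mannwhitneyu(tgt_fracs, bgr_fracs, alternative="two-sided")
        u_stat, u_p = float(mwu.statistic), float(mwu.pvalue)
    else:
        u_stat, u_p = np.nan, 1.0

    focal_codons = table.codons_of(table.focal)
    partner_codons = table.codons_of(table.partner)

    def pooled(tags_in: bool) -> tuple[int, int]:
        sel = [c for c in counts if (c.locus_tag in in_target) == tags_in]
        f = sum(c.counts.get(cod, 0) for c in sel for cod in focal_codons)
        p = sum(c.counts.get(cod, 0) for c in sel for cod in partner_codons)
        return f, p

    tf, tp = pooled(True)
    bf, bp = pooled(False)
    contingency = np.array([[tf, tp], [bf, bp]])
    degenerate = bool((contingency.sum(axis=0) == 0).any() or (contingency.sum(axis=1) == 0).any())
    if degenerate:
        odds, fisher_p = np.nan, 1.0
    else:
        odds, fisher_p = (float(x) for x in stats.fisher_exact(contingency))
    return EnrichmentResult(
        target=target,
        n_target=len(tgt_fracs),
        n_background=len(bgr_fracs),
        mannwhitney_u=u_stat,
        mannwhitney_p=u_p,
        fisher_odds_ratio=odds,
        fisher_p=fisher_p,
        pooled_pct_target=100.0 * tf / (tf + tp) if tf + tp else np.nan,
        pooled_pct_background=100.0 * bf / (bf + bp) if bf + bp else np.nan,
        degenerate=degenerate,
    )
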