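"""Transposon-screen fold-change curation.

Scores a per-gene insertion read-count table from two growth conditions and
flags genes over-represented beyond a fold threshold in condition B relative
to condition A, the "reads per TA insertion site" convention: when TA-site
columns are present, raw reads are divided by the gene's TA-site count before
the ratio is formed. Read mapping and TA-site calling are upstream of this
module; it only curates a count table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("locus_tag", "reads_A", "reads_B")
OPTIONAL_SITE_COLUMNS = ("ta_sites_A", "ta_sites_B")


def load_tnseq_table(path: str | Path) -> pd.DataFrame:
    """Read a ``locus_tag, reads_A, reads_B[, ta_sites_A, ta_sites_B]`` TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {missing}")
    return df


def per_gene_read_ratio(table: pd.DataFrame, *, pseudocount: float = 1.0,
                        library_size_normalize: bool = False) -> pd.DataFrame:
    """Annotate the table with per-gene B/A read-rate ratios.

    ``rate = reads / ta_sites`` when TA-site columns are present, else the raw
    reads. With ``library_size_normalize``, each condition's rates are scaled
    so both conditions have equal totals (their mean) before the ratio —
    off by default, since reads-per-TA-site inputs are typically already
    depth-conditioned upstream. ``ratio = (rate_B + pc) / (rate_A + pc)``.
    """
    for col in REQUIRED_COLUMNS[1:]:
        if (table[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    df = table.copy()
    has_sites = all(c in df.columns for c in OPTIONAL_SITE_COLUMNS)
    if has_sites:
        for col in OPTIONAL_SITE_COLUMNS:
            if (df[col] < 1).any():
                raise ValueError(f"{col} must be >= 1 for every gene in raw-read mode")
        df["rate_A"] = df["reads_A"] / df["ta_sites_A"]
        df["rate_B"] = df["reads_B"] / df["ta_sites_B"]
    else:
        df["rate_A"] = df["reads_A"].astype(float)
        df["rate_B"] = df["reads_B"].astype(float)
    if library_size_normalize:
        tot_a, tot_b = df["rate_A"].sum(), df["rate_B"].sum()
        if tot_a == 0 or tot_b == 0:
            raise ValueError("cannot library-size normalize a condition with zero total")
        target = (tot_a + tot_b) / 2.0
        df["rate_A"] *= target / tot_a
        df["rate_B"] *= target / tot_b
    df["ratio"] = (df["rate_B"] + pseudocount) / (df["rate_A"] + pseudocount)
    return df


def flag_overrepresented(table: pd.DataFrame, fold_threshold: float = 2.0) -> pd.DataFrame:
    """Flag genes with ratio strictly greater than ``fold_threshold``.

    Adds a boolean ``flagged`` column and returns the flagged subset sorted
    by descending ratio (ties broken by locus tag for determinism).
    """
    if "ratio" not in table.columns:
        raise ValueError("table has no 'ratio' column; run per_gene_read_ratio first")
    table["flagged"] = table["ratio"] > fold_threshold
    flagged = table[table["flagged"]].sort_values(
        ["ratio", "locus_tag"], ascending=[False, True]).reset_index(drop=True)
    return flagged


def screen(table: pd.DataFrame, *, pseudocount: float = 1.0, fold_threshold: float = 2.0,
           library_size_normalize: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: ratio annotation + flagging in one call.

    Returns ``(annotated_table, flagged_subset)``.
    """
    annotated = per_gene_read_ratio(table, pseudocount=pseudocount,
                                    library_size_normalize=library_size_normalize)
    flagged = flag_overrepresented(annotated, fold_threshold)
    return annotated, flagged


def write_screen_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    for col in ("rate_A", "rate_B", "ratio"):
        if col in out.columns:
            out[col] = out[col].map(lambda x: f"{x:.8f}")
    out.to_csv(path, sep="\t", index=False)
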