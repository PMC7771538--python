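"""Bundled reference data for M. tuberculosis H37Rv.

The packaged table is the published curated list of the 136 H37Rv genes whose
proline is decoded at least 60% by the proT isoacceptor, with TubercuList
functional categories — usable as a regression fixture when re-running the
pipeline on the AL123456 genome, or as a ready-made gene set.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Spot values from the reference list, exact to the printed precision.
H37RV_SPOT_CHECKS = {"Rv3514": 90.32258065, "Rv1702c": 74.19354839, "Rv0596c": 60.0}

#: Published genome-wide proline decoding shares for H37Rv (percent).
H37RV_PAIR_SHARE_OF_ALL = 85.53   # CCC+CCG among all proline codons
H37RV_PROY_SHARE_OF_PAIR = 63.6   # CCG within the CCC/CCG pair
H37RV_PROT_SHARE_OF_PAIR = 36.4   # CCC within the CCC/CCG pair
H37RV_RPFA_PCT = 53.16            # rpfA (Rv0867c) proT percentage
H37RV_PE_PGRS_POOLED_PCT = 56.2   # PE-PGRS pooled proT percentage


def load_h37rv_reference() -> pd.DataFrame:
    """The 136-gene ≥60%-proT reference list (locus_tag, category, pct)."""
    with resources.files("decodon.data").joinpath(
            "h37rv_proT_ge60_reference.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df.columns = ["locus_tag", "category", "pct"]
    return df
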