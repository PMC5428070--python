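"""Differential-expression set construction and overlap/direction statistics.

A gene is called differential in a contrast when |log2 fold-change| >= 0.5,
BH-adjusted q <= 0.05, and the gene is expressed (>= 0.1 FPKM) in at least
one of the contrasted conditions — all boundaries inclusive. Two contrasts
against a common reference (e.g. two diets each vs control) yield an overlap
gene set; its size is tested with a hypergeometric upper tail against a
caller-supplied gene universe (the universe is never inferred silently), and
direction concordance within the overlap is tested with a two-sided Fisher
exact test on the 2x2 direction table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import benjamini_hochberg

#: expression-table column pairs per contrast label
CONTRAST_COLUMNS = {
    "A": ("log2fc_A", "q_A", ("fpkm_cd", "fpkm_a")),
    "B": ("log2fc_B", "q_B", ("fpkm_cd", "fpkm_b")),
}


@dataclass(frozen=True)
class DirectionTable:
    """Counts of overlap genes by direction in contrasts A x B."""

    up_up: int
    down_down: int
    up_down: int
    down_up: int

    def __post_init__(self) -> None:
        for v in (self.up_up, self.down_down, self.up_down, self.down_up):
            if v < 0:
                raise ValueError("direction counts must be non-negative")

    @property
    def total(self) -> int:
        return self.up_up + self.down_down + self.up_down + self.down_up

    @property
    def same_direction(self) -> int:
        return self.up_up + self.down_down

    def as_2x2(self) -> np.ndarray:
        """Rows: direction in A (up/down); columns: direction in B."""
        return np.array([[self.up_up, self.up_down], [self.down_up, self.down_down]])


def filter_differential(
    records: pd.DataFrame,
    contrast: str,
    lfc_min: float = 0.5,
    q_max: float = 0.05,
    fpkm_min: float = 0.1,
) -> set[str]:
    """Gene ids passing the differential-expression filter for a contrast."""
    if contrast not in CONTRAST_COLUMNS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of "
                         f"{sorted(CONTRAST_COLUMNS)}")
    lfc_col, q_col, fpkm_cols = CONTRAST_COLUMNS[contrast]
    needed = ["gene_id", lfc_col, q_col, *fpkm_cols]
    missing_cols = [c for c in needed if c not in records.columns]
    if missing_cols:
        raise ValueError(f"expression table missing columns: {missing_cols}")
    bad = records.loc[records[needed].isna().any(axis=1), "gene_id"]
    if len(bad):
        raise ValueError(f"records with missing fields: {sorted(bad)}")
    passing = (
        (records[lfc_col].abs() >= lfc_min)
        & (records[q_col] <= q_max)
        & (records[list(fpkm_cols)].max(axis=1) >= fpkm_min)
    )
    return set(records.loc[passing, "gene_id"])


def direction_table(
    records: pd.DataFrame, genes: set[str] | None = None
) -> DirectionTable:
    """Tabulate fold-change sign agreement between the two contrasts for the
    given genes (default: the A/B differential overlap)."""
    if genes is None:
        genes = filter_differential(records, "A") & filter_differential(records, "B")
    sub = records[records["gene_id"].isin(genes)]
    up_a = sub["log2fc_A"] > 0
    up_b = sub["log2fc_B"] > 0
    return DirectionTable(
        up_up=int((up_a & up_b).sum()),
        down_down=int((~up_a & ~up_b).sum()),
        up_down=int((up_a & ~up_b).sum()),
        down_up=int((~up_a & up_b).sum()),
    )


def overlap_significance(
    set_a: set[str], set_b: set[str], universe_size: int
) -> tuple[set[str], float]:
    """Overlap genes and the hypergeometric upper-tail p-value of observing
    at least that overlap between two sets drawn from a universe."""
    if universe_size < len(set_a | set_b):
        raise ValueError("universe smaller than the union of the gene sets")
    overlap = set_a & set_b
    p = float(stats.hypergeom.sf(len(overlap) - 1, universe_size, len(set_a), len(set_b)))
    return overlap, p


def direction_concordance(table: DirectionTable) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for the direction 2x2 table.

    Two-sided by Fisher's original rule: sum the probabilities of all tables
    (fixed margins) no more probable than the observed one. Extreme tables
    are handled in log space inside scipy, so p-values ~1e-20 are exact.
    """
    t = table.as_2x2()
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def gene_set_enrichment(
    query: set[str],
    annotation: dict[str, set[str]],
    universe_size: int,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a query gene set, BH-corrected
    across terms. The universe size must be supplied by the caller."""
    if universe_size < len(query):
        raise ValueError("universe smaller than the query set")
    rows = []
    for term in sorted(annotation):
        members = annotation[term]
        k = len(query & members)
        p = float(
            stats.hypergeom.sf(k - 1, universe_size, len(members), len(query))
        )
        rows.append({"term": term, "hits": k, "term_size": len(members), "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df
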