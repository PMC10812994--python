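"""Over-representation analysis of a gene list against named gene sets.

The test is the one-sided hypergeometric tail P(X >= overlap) with the
tested background ('universe') as the urn; q-values are Benjamini-Hochberg,
applied within each category (MF/CC/BP-style) by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import log_stage

RESULT_COLUMNS = ("category", "set_name", "overlap", "set_size",
                  "query_size", "universe_size", "p", "q")


def hypergeometric_test(query, gene_set, universe) -> float:
    """P(X >= overlap) for X ~ Hypergeom(|universe|, |set|, |query|)."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query) & universe
    gene_set = set(gene_set) & universe
    if not (set(query) <= universe and gene_set <= universe):
        raise ValueError("query and gene set must be subsets of the universe")
    k = len(query & gene_set)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(gene_set),
                                    len(query)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(query, collections: dict[str, dict[str, set]],
                   universe, q_max: float = 0.05,
                   min_overlap: int = 3,
                   per_category_fdr: bool = True) -> pd.DataFrame:
    """ORA table over every collection, BH-adjusted within category.

    Only sets overlapping the query by >= min_overlap are tested (smaller
    overlaps are singleton artifacts). Rows are sorted by q then p; the
    ``significant`` column marks q < q_max. Duplicate query genes are
    collapsed before testing.
    """
    universe = {str(g).upper() for g in universe}
    query = {str(g).upper() for g in query} & universe
    rows = []
    for category, sets in collections.items():
        for name, members in sets.items():
            members = {str(g).upper() for g in members} & universe
            overlap = len(query & members)
            if overlap < min_overlap:
                continue
            p = hypergeometric_test(query, members, universe)
            rows.append({"category": category, "set_name": name,
                         "overlap": overlap, "set_size": len(members),
                         "query_size": len(query),
                         "universe_size": len(universe), "p": p})
    df = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "q"])
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    if per_category_fdr:
        df["q"] = np.nan
        for cat, idx in df.groupby("category").groups.items():
            df.loc[idx, "q"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    else:
        df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < q_max
    df = df.sort_values(["q", "p", "set_name"]).reset_index(drop=True)
    log_stage("run_enrichment", tested=len(df),
              significant=int(df["significant"].sum()))
    return df
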