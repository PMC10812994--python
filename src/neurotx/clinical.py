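"""Group comparisons and imaging-clinical correlations.

Continuous measures: Mann-Whitney U (exact enumeration for small samples,
midrank normal approximation with tie and continuity correction otherwise).
Categorical measures: Fisher's exact test. Imaging-clinical relations:
Spearman rank correlation with BH-FDR over the tested family.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import log_stage
from .enrichment import bh_adjust

#: exact Mann-Whitney enumeration is used up to this combined sample size
EXACT_MAX_N = 20


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Mann-Whitney U (for sample a) and two-sided p.

    Small samples (n_a + n_b <= 20): exact permutation enumeration over all
    group assignments of the midranks — correct under ties. Larger samples:
    normal approximation with tie and continuity correction. The null
    distribution of U is symmetric about n_a*n_b/2 under exchangeability,
    so the two-sided p is P(|U - mu| >= |u_obs - mu|).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0
    n = na + nb
    if n <= EXACT_MAX_N:
        rank_sum_min = na * (na + 1) / 2.0
        obs_dev = abs(u - mu)
        hits = total = 0
        for combo in combinations(range(n), na):
            u_perm = ranks[list(combo)].sum() - rank_sum_min
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-9:
                hits += 1
        p = hits / total
    else:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
        sigma2 = na * nb / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            return u, 1.0
        z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
        p = float(2.0 * stats.norm.sf(max(z, 0.0)))
    return u, min(p, 1.0)


def fisher_exact(table) -> tuple[float, float]:
    """Sample odds ratio and two-sided conditional-hypergeometric p."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Midrank Spearman rho with t-approximation two-sided p."""
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def group_tests(clinical: pd.DataFrame, designs_df: pd.DataFrame,
                numeric_measures, categorical_measures=()) -> pd.DataFrame:
    """Case-control comparison per measure, FDR over the whole family."""
    merged = clinical.merge(designs_df[["subject_id", "group"]],
                            on="subject_id")
    case = merged[merged["group"] == "case"]
    control = merged[merged["group"] == "control"]
    rows = []
    for m in numeric_measures:
        u, p = mann_whitney(case[m], control[m])
        rows.append({"measure": m, "test": "mann_whitney",
                     "statistic": u, "p": p})
    for m in categorical_measures:
        levels = sorted(merged[m].unique())
        if len(levels) != 2:
            raise ValueError(f"categorical measure {m!r} must be binary")
        table = [[int((case[m] == lv).sum()) for lv in levels],
                 [int((control[m] == lv).sum()) for lv in levels]]
        odds, p = fisher_exact(np.asarray(table).T)
        rows.append({"measure": m, "test": "fisher_exact",
                     "statistic": odds, "p": p})
    df = pd.DataFrame(rows, columns=["measure", "test", "statistic", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else np.nan
    return df


def spearman_with_fdr(imaging: pd.DataFrame, clinical: pd.DataFrame,
                      measures, cases_only: bool = True,
                      designs_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """rho/p/q per (imaging cluster value, clinical measure) pair.

    ``imaging`` has one row per subject (subject_id plus one column per
    cluster, e.g. mean standardized ALFF inside the cluster). The FDR family
    is every tested pair. By default only cases enter the correlations.
    """
    merged = imaging.merge(clinical, on="subject_id")
    if cases_only:
        if designs_df is None:
            raise ValueError("cases_only requires the design table")
        cases = set(designs_df.loc[designs_df["group"] == "case",
                                   "subject_id"])
        merged = merged[merged["subject_id"].isin(cases)]
    cluster_cols = [c for c in imaging.columns if c != "subject_id"]
    rows = []
    for cl in cluster_cols:
        for m in measures:
            rho, p = spearman(merged[cl], merged[m])
            rows.append({"cluster": cl, "measure": m, "rho": rho, "p": p})
    df = pd.DataFrame(rows, columns=["cluster", "measure", "rho", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else np.nan
    log_stage("spearman_with_fdr", pairs=len(df),
              subjects=len(merged))
    return df


def format_correlation(rho: float, p: float) -> str:
    """Render a correlation the way results sections report them,
    e.g. ``r = -0.559, p = 0.002``."""
    return f"r = {rho:.3f}, p = {p:.3f}"


def cluster_mean_values(maps, subject_ids, cluster_masks: dict[str, np.ndarray]
                        ) -> pd.DataFrame:
    """Mean map value inside each cluster per subject (imaging summary)."""
    rows = []
    for sid, vol in zip(subject_ids, maps):
        row = {"subject_id": sid}
        for name, m in cluster_masks.items():
            row[name] = float(np.asarray(vol)[m].mean())
        rows.append(row)
    return pd.DataFrame(rows)
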