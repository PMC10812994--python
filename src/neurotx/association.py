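"""Spatial correlation between gene expression profiles and a t-map.

Each gene's regional expression profile is Pearson-correlated with the
vector of t-values extracted at the same voxels; genes pass when the
Bonferroni-corrected p is below alpha AND |r| exceeds r_min (the dual
criterion). Bonferroni uses the number of genes actually tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import StatMap, log_stage, logger
from .transcriptome import GeneBySampleMatrix

ASSOC_COLUMNS = ("gene", "r", "p", "passes", "direction")


def extract_t_at_samples(tmap: StatMap, regions: pd.DataFrame) -> np.ndarray:
    """t-value per matrix row (region voxel), in row order.

    ``regions`` is the region table of a :class:`GeneBySampleMatrix`
    (columns i, j, k index voxels of the t-map's grid).
    """
    vox = regions[["i", "j", "k"]].to_numpy(dtype=int)
    shape = np.array(tmap.grid.shape)
    if (vox < 0).any() or (vox >= shape).any():
        raise ValueError("region voxels fall outside the t-map grid")
    if not tmap.mask.inside[tuple(vox.T)].all():
        raise ValueError("region voxels must lie inside the t-map mask")
    return tmap.values[tuple(vox.T)]


def mass_correlation(matrix: GeneBySampleMatrix | pd.DataFrame,
                     tvec: np.ndarray) -> pd.DataFrame:
    """Per-gene Pearson r and two-sided p against the t-value vector.

    p comes from the exact t transform r * sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom. Constant genes are undefined and excluded (logged).
    """
    values = matrix.values if isinstance(matrix, GeneBySampleMatrix) else matrix
    tvec = np.asarray(tvec, dtype=float)
    n = len(tvec)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if values.shape[0] != n:
        raise ValueError("matrix rows must align with the t-value vector")
    X = values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = tvec - tvec.mean()
    xnorm = np.sqrt((Xc ** 2).sum(axis=0))
    ynorm = np.sqrt((yc ** 2).sum())
    ok = (xnorm > 0) & (ynorm > 0)
    if (~ok).sum():
        logger.info("mass_correlation: %d constant genes excluded",
                    int((~ok).sum()))
    r = np.full(X.shape[1], np.nan)
    r[ok] = (Xc.T @ yc)[ok] / (xnorm[ok] * ynorm)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    out = pd.DataFrame({"gene": values.columns, "r": r, "p": p})
    out = out[ok].reset_index(drop=True)
    out["n"] = n
    log_stage("mass_correlation", genes=len(out), samples=n)
    return out


def dual_threshold(associations: pd.DataFrame, alpha: float = 0.01,
                   r_min: float = 0.2,
                   n_tests: int | None = None) -> pd.DataFrame:
    """Apply the dual criterion: Bonferroni p < alpha AND |r| > r_min.

    Returns the association table with ``passes`` and ``direction`` columns
    plus the per-test threshold in ``attrs`` for provenance.
    """
    out = associations.copy()
    n_tests = len(out) if n_tests is None else int(n_tests)
    per_test = alpha / max(n_tests, 1)
    out["passes"] = (out["p"] < per_test) & (out["r"].abs() > r_min)
    out["direction"] = np.sign(out["r"]).astype(int)
    out.attrs["per_test_threshold"] = per_test
    out.attrs["n_tests"] = n_tests
    log_stage("dual_threshold", tested=n_tests,
              selected=int(out["passes"].sum()),
              per_test_threshold=per_test)
    return out


def selected_genes(associations: pd.DataFrame) -> list[str]:
    """Sorted list of genes passing the dual criterion."""
    return sorted(associations.loc[associations["passes"], "gene"])


def rank_genes(associations: pd.DataFrame,
               top_k: int = 5) -> tuple[list[str], list[str]]:
    """Top positively and negatively correlated genes among the selected.

    Falls back to all tested genes when no ``passes`` column is present.
    Ties in r break by gene symbol.
    """
    df = associations
    if "passes" in df.columns:
        df = df[df["passes"]]
    pos = df[df["r"] > 0].sort_values(["r", "gene"],
                                      ascending=[False, True])
    neg = df[df["r"] < 0].sort_values(["r", "gene"],
                                      ascending=[True, True])
    return (pos["gene"].head(top_k).tolist(),
            neg["gene"].head(top_k).tolist())


def intersect_gene_lists(list_a, list_b) -> list[str]:
    """Crossover genes: sorted set intersection."""
    return sorted(set(list_a) & set(list_b))
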