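"""Donor probe-level expression samples -> clean samples x genes matrix.

The nine-step refinement mirrors the de-facto standard workflow for
multi-donor postmortem expression atlases: (1) revise probe-to-gene
annotations, (2) intensity-based probe filter, (3) probe selection by
differential stability, (4) match samples to mask voxels, (5) missing-data
handling, (6) sample normalization, (7) gene normalization (scaled robust
sigmoid, per donor), (8) aggregate samples per voxel, (9) keep spatially
stable genes. Every step logs the (probes, genes, samples) it retains, and
the counts travel with the output matrix as provenance.

Differential stability — the mean over donor pairs of the spatial
correlation of a probe's (or gene's) expression profile — needs a common
spatial support across donors. Donors here occupy disjoint sample
locations, so profiles are first averaged within coarse spatial blocks
(default 12 mm cubes) and correlated over blocks where both donors of a
pair have samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import BinaryMask, log_stage, logger

SAMPLE_COLUMNS = ("sample_id", "donor", "x", "y", "z", "structure")
DEFAULT_BLOCK_MM = 12.0
IQR_NORMAL_SCALE = 1.34897950039  # IQR of a standard normal


@dataclass
class ExpressionSampleSet:
    """Donor-tagged expression samples with probe intensities.

    samples: one row per sample (sample_id, donor, x, y, z, structure);
    intensity: probes (rows) x samples (columns);
    background: per-probe noise floor;
    annotations: probe_id -> gene_symbol (possibly stale).
    """

    samples: pd.DataFrame
    intensity: pd.DataFrame
    background: pd.Series
    annotations: pd.DataFrame

    def __post_init__(self):
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if not np.isfinite(self.intensity.to_numpy()).all():
            raise ValueError("intensities must be finite")
        if list(self.intensity.columns) != list(self.samples["sample_id"]):
            raise ValueError("intensity columns must match sample ids")
        if self.annotations["probe_id"].duplicated().any():
            raise ValueError("probe_id must be unique in annotations")

    @property
    def donors(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.samples["donor"]))

    @property
    def n_probes(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[1]


@dataclass
class GeneBySampleMatrix:
    """Normalized expression, regions/samples (rows) x genes (columns).

    ``regions`` carries one row per matrix row: voxel indices (i, j, k) and
    world coordinates of the aggregation voxel. ``provenance`` records the
    (probes, genes, samples) retained after every preprocessing step.
    """

    values: pd.DataFrame
    regions: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("matrix must have no missing values")
        if self.values.columns.duplicated().any():
            raise ValueError("gene symbols must be unique")
        if len(self.regions) != len(self.values):
            raise ValueError("regions must align with matrix rows")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Step 1: probe reannotation
# ---------------------------------------------------------------------------

def reannotate_probes(annotations: pd.DataFrame,
                      current_map: pd.DataFrame | dict) -> pd.DataFrame:
    """Replace stale gene symbols; drop probes absent from the current map."""
    if isinstance(current_map, pd.DataFrame):
        mapping = dict(zip(current_map["probe_id"], current_map["gene_symbol"]))
    else:
        mapping = dict(current_map)
    keep = annotations["probe_id"].isin(mapping)
    dropped = int((~keep).sum())
    out = annotations.loc[keep].copy()
    if out.empty:
        raise ValueError("reannotation dropped every probe")
    new_symbols = out["probe_id"].map(mapping)
    revised = int((new_symbols != out["gene_symbol"]).sum())
    out["gene_symbol"] = new_symbols
    out["is_current"] = True
    log_stage("reannotate_probes", probes=len(out), dropped=dropped,
              revised=revised)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Step 2: intensity filter
# ---------------------------------------------------------------------------

def intensity_filter(samples: ExpressionSampleSet,
                     min_fraction: float = 0.5) -> ExpressionSampleSet:
    """Keep probes above their background in >= min_fraction of samples."""
    above = samples.intensity.gt(samples.background, axis=0)
    frac = above.mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValueError("intensity filter removed every probe")
    kept_probes = samples.intensity.index[keep]
    out = ExpressionSampleSet(
        samples=samples.samples,
        intensity=samples.intensity.loc[kept_probes],
        background=samples.background.loc[kept_probes],
        annotations=samples.annotations[
            samples.annotations["probe_id"].isin(kept_probes)
        ].reset_index(drop=True),
    )
    log_stage("intensity_filter", probes_in=samples.n_probes,
              probes_kept=len(kept_probes), min_fraction=min_fraction)
    return out


# ---------------------------------------------------------------------------
# Spatial blocks (shared by probe selection and gene stability)
# ---------------------------------------------------------------------------

def _block_keys(samples: pd.DataFrame, block_mm: float) -> pd.Series:
    xyz = samples[["x", "y", "z"]].to_numpy(dtype=float)
    blocks = np.floor(xyz / block_mm).astype(int)
    return pd.Series([tuple(b) for b in blocks], index=samples.index)


def _donor_block_profiles(values: pd.DataFrame, samples: pd.DataFrame,
                          block_mm: float) -> dict[str, pd.DataFrame]:
    """Per donor: rows (probes/genes) x blocks matrix of block means.

    ``values`` is features x samples with columns = sample ids.
    """
    keys = _block_keys(samples, block_mm)
    out = {}
    for donor, sub in samples.groupby("donor", sort=False):
        cols = sub["sample_id"]
        grouped = values[cols].T.groupby(keys.loc[sub.index].to_numpy()).mean()
        out[donor] = grouped.T  # features x blocks
    return out


def differential_stability(values: pd.DataFrame, samples: pd.DataFrame,
                           block_mm: float = DEFAULT_BLOCK_MM,
                           min_common_blocks: int = 3) -> pd.Series:
    """Mean inter-donor spatial correlation of each feature's profile.

    Features with no donor pair sharing >= min_common_blocks blocks get NaN.
    """
    profiles = _donor_block_profiles(values, samples, block_mm)
    donors = list(profiles)
    n_feat = values.shape[0]
    acc = np.zeros(n_feat)
    n_pairs = np.zeros(n_feat)
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            a, b = profiles[donors[i]], profiles[donors[j]]
            common = a.columns.intersection(b.columns)
            if len(common) < min_common_blocks:
                continue
            av = a[common].to_numpy(dtype=float)
            bv = b[common].to_numpy(dtype=float)
            av = av - av.mean(axis=1, keepdims=True)
            bv = bv - bv.mean(axis=1, keepdims=True)
            denom = np.sqrt((av ** 2).sum(axis=1) * (bv ** 2).sum(axis=1))
            ok = denom > 0
            r = np.zeros(n_feat)
            r[ok] = (av * bv).sum(axis=1)[ok] / denom[ok]
            acc += np.where(ok, r, 0.0)
            n_pairs += ok
    ds = np.full(n_feat, np.nan)
    seen = n_pairs > 0
    ds[seen] = acc[seen] / n_pairs[seen]
    return pd.Series(ds, index=values.index)


# ---------------------------------------------------------------------------
# Step 3: probe selection
# ---------------------------------------------------------------------------

def select_probes(samples: ExpressionSampleSet,
                  annotations: pd.DataFrame | None = None,
                  method: str = "differential_stability",
                  block_mm: float = DEFAULT_BLOCK_MM) -> pd.DataFrame:
    """One probe per gene.

    Multi-probe genes with >= 2 donors: keep the probe with the highest
    differential stability; single-donor data (or method="max_intensity"):
    highest mean intensity. Exact ties break to the lexicographically
    smaller probe_id.
    """
    ann = samples.annotations if annotations is None else annotations
    ann = ann[ann["probe_id"].isin(samples.intensity.index)]
    multi_donor = len(samples.donors) >= 2
    if method == "differential_stability" and multi_donor:
        score = differential_stability(samples.intensity, samples.samples,
                                       block_mm)
    elif method in ("differential_stability", "max_intensity"):
        score = samples.intensity.mean(axis=1)
    else:
        raise ValueError(f"unknown probe selection method {method!r}")
    score = score.fillna(-np.inf)
    chosen = []
    for gene, sub in ann.groupby("gene_symbol", sort=True):
        probes = sorted(sub["probe_id"])  # lexicographic tie-break
        best = max(probes, key=lambda p: (score.loc[p], ))
        # max() keeps the first of equals, i.e. the smaller probe_id
        chosen.append({"gene_symbol": gene, "probe_id": best})
    out = pd.DataFrame(chosen, columns=["gene_symbol", "probe_id"])
    log_stage("select_probes", genes=len(out), method=method)
    return out


# ---------------------------------------------------------------------------
# Step 4: sample-to-voxel matching
# ---------------------------------------------------------------------------

def match_samples_to_mask(samples: pd.DataFrame, mask: BinaryMask,
                          max_distance_mm: float = 2.0,
                          left_only: bool = False) -> pd.DataFrame:
    """Assign each sample to the nearest in-mask voxel center within tolerance.

    Returns one row per retained sample: sample_id, voxel indices (i, j, k),
    voxel-center world coordinates and the match distance. Unmatched samples
    are dropped (counted); ``left_only`` keeps only world x < 0 samples.
    """
    sub = samples
    if left_only:
        sub = sub[sub["x"] < 0]
    if sub.empty:
        raise ValueError("no samples to match")
    voxels = mask.voxel_indices()
    centers = mask.grid.voxel_to_world(voxels)
    tree = cKDTree(centers)
    dist, idx = tree.query(sub[["x", "y", "z"]].to_numpy(dtype=float))
    keep = dist <= max_distance_mm
    if not keep.any():
        raise ValueError("no sample lies within the matching tolerance")
    matched = sub.loc[keep].reset_index(drop=True)
    vox = voxels[idx[keep]]
    ctr = centers[idx[keep]]
    out = pd.DataFrame({
        "sample_id": matched["sample_id"],
        "donor": matched["donor"],
        "i": vox[:, 0], "j": vox[:, 1], "k": vox[:, 2],
        "voxel_x": ctr[:, 0], "voxel_y": ctr[:, 1], "voxel_z": ctr[:, 2],
        "distance_mm": dist[keep],
    })
    log_stage("match_samples_to_mask", samples_in=len(sub),
              samples_kept=len(out), dropped=int((~keep).sum()),
              left_only=left_only)
    return out


# ---------------------------------------------------------------------------
# Step 5: missing data
# ---------------------------------------------------------------------------

def handle_missing(matrix: pd.DataFrame, donors: pd.Series,
                   max_missing_fraction: float = 0.5) -> pd.DataFrame:
    """Drop genes with too many missing values; impute the rest.

    ``matrix`` is samples x genes; ``donors`` maps matrix index -> donor.
    Remaining missing entries are replaced by the gene's median within the
    sample's donor (falling back to the gene's overall median if a donor has
    no observed value at all).
    """
    frac = matrix.isna().mean(axis=0)
    kept = matrix.loc[:, frac <= max_missing_fraction].copy()
    dropped = int((frac > max_missing_fraction).sum())
    if kept.isna().any().any():
        donor_median = kept.groupby(donors.loc[kept.index]).transform("median")
        kept = kept.fillna(donor_median)
        kept = kept.fillna(kept.median(axis=0))  # donor entirely missing
    log_stage("handle_missing", genes_in=matrix.shape[1],
              genes_kept=kept.shape[1], genes_dropped=dropped)
    return kept


# ---------------------------------------------------------------------------
# Steps 6-7: normalization
# ---------------------------------------------------------------------------

def _scaled_robust_sigmoid(x: np.ndarray, axis: int) -> np.ndarray:
    """SRS along ``axis``: sigmoid of (x - median)/(IQR/1.349), then unit range.

    Zero-spread slices are flagged constant and set to 0.5.
    """
    import warnings as _warnings

    med = np.median(x, axis=axis, keepdims=True)
    q75, q25 = np.percentile(x, [75, 25], axis=axis, keepdims=True)
    iqr = (q75 - q25) / IQR_NORMAL_SCALE
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"), \
            _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        y = 1.0 / (1.0 + np.exp(-(x - med) / iqr))
        lo = np.nanmin(np.where(iqr > 0, y, np.nan), axis=axis, keepdims=True)
        hi = np.nanmax(np.where(iqr > 0, y, np.nan), axis=axis, keepdims=True)
        out = (y - lo) / (hi - lo)
    constant = np.broadcast_to(~(iqr > 0), x.shape) | ~np.isfinite(out)
    out = np.where(constant, 0.5, out)
    return out


def normalize(matrix: pd.DataFrame, donors: pd.Series,
              within: str = "donor") -> pd.DataFrame:
    """Scaled-robust-sigmoid normalization, sample-wise then gene-wise.

    Step 6 normalizes each sample across genes; step 7 each gene across the
    samples of one donor. Both are monotone, bounded in [0, 1], and
    invariant to affine rescaling of a donor's raw intensities.
    """
    if within != "donor":
        raise ValueError("only within='donor' is supported")
    out = matrix.copy()
    for _, idx in donors.loc[out.index].groupby(donors, sort=False).groups.items():
        block = out.loc[idx].to_numpy(dtype=float)
        block = _scaled_robust_sigmoid(block, axis=1)  # per sample over genes
        block = _scaled_robust_sigmoid(block, axis=0)  # per gene over samples
        out.loc[idx] = block
    log_stage("normalize", samples=out.shape[0], genes=out.shape[1])
    return out


# ---------------------------------------------------------------------------
# Steps 8-9: aggregation and stable genes
# ---------------------------------------------------------------------------

def aggregate_and_stabilize(matrix: pd.DataFrame, assignment: pd.DataFrame,
                            stability_threshold: float = 0.2,
                            block_mm: float = DEFAULT_BLOCK_MM,
                            provenance: dict | None = None) -> GeneBySampleMatrix:
    """Average co-located samples per voxel and drop unstable genes.

    ``matrix`` is samples x genes (normalized); ``assignment`` comes from
    :func:`match_samples_to_mask`. Gene differential stability is the mean
    inter-donor correlation of block-aggregated profiles; genes below the
    threshold are dropped.
    """
    assignment = assignment.set_index("sample_id").loc[matrix.index]
    donors = assignment["donor"]
    n_donors = donors.nunique()
    if n_donors >= 2:
        sample_table = pd.DataFrame({
            "sample_id": matrix.index, "donor": donors.to_numpy(),
            "x": assignment["voxel_x"].to_numpy(),
            "y": assignment["voxel_y"].to_numpy(),
            "z": assignment["voxel_z"].to_numpy(),
        })
        ds = differential_stability(matrix.T, sample_table, block_mm)
        stable = ds.fillna(-np.inf) >= stability_threshold
    else:
        ds = pd.Series(np.nan, index=matrix.columns)
        stable = pd.Series(True, index=matrix.columns)
    kept = matrix.loc[:, stable]

    vox = assignment[["i", "j", "k"]].to_numpy()
    keys = pd.Series([tuple(v) for v in vox], index=matrix.index)
    aggregated = kept.groupby(keys).mean()
    first = assignment.loc[~keys.duplicated()]
    region_keys = pd.Series([tuple(v) for v in
                             first[["i", "j", "k"]].to_numpy()],
                            index=first.index)
    regions = (pd.DataFrame({
        "i": first["i"].to_numpy(), "j": first["j"].to_numpy(),
        "k": first["k"].to_numpy(),
        "x": first["voxel_x"].to_numpy(), "y": first["voxel_y"].to_numpy(),
        "z": first["voxel_z"].to_numpy()},
        index=region_keys.to_numpy()).loc[aggregated.index]
        .reset_index(drop=True))
    prov = dict(provenance or {})
    prov["aggregate_and_stabilize"] = {
        "genes_in": matrix.shape[1], "genes_kept": int(stable.sum()),
        "regions": len(aggregated),
    }
    log_stage("aggregate_and_stabilize", regions=len(aggregated),
              genes_kept=int(stable.sum()), genes_in=matrix.shape[1])
    return GeneBySampleMatrix(aggregated.reset_index(drop=True), regions, prov)


# ---------------------------------------------------------------------------
# Orchestration: steps 1 -> 9
# ---------------------------------------------------------------------------

def prepare_expression(sample_set: ExpressionSampleSet,
                       current_map: pd.DataFrame | dict,
                       mask: BinaryMask,
                       min_fraction: float = 0.5,
                       max_distance_mm: float = 2.0,
                       stability_threshold: float = 0.2,
                       left_only: bool = False,
                       block_mm: float = DEFAULT_BLOCK_MM,
                       ) -> tuple[GeneBySampleMatrix, pd.DataFrame]:
    """Run the nine preprocessing steps in order.

    Returns the gene-by-region matrix and the sample-to-voxel assignment
    restricted to the retained samples (matrix row order = unique voxels in
    assignment order).
    """
    prov: dict = {}

    ann = reannotate_probes(sample_set.annotations, current_map)
    sample_set = ExpressionSampleSet(
        sample_set.samples,
        sample_set.intensity.loc[ann["probe_id"]],
        sample_set.background.loc[ann["probe_id"]], ann)
    prov["reannotate_probes"] = {"probes": sample_set.n_probes,
                                 "samples": sample_set.n_samples}

    sample_set = intensity_filter(sample_set, min_fraction)
    prov["intensity_filter"] = {"probes": sample_set.n_probes}

    probe_map = select_probes(sample_set, block_mm=block_mm)
    prov["select_probes"] = {"genes": len(probe_map)}

    assignment = match_samples_to_mask(sample_set.samples, mask,
                                       max_distance_mm, left_only)
    prov["match_samples_to_mask"] = {"samples": len(assignment)}

    # samples x genes matrix from the selected probes, matched samples only
    chosen = sample_set.intensity.loc[probe_map["probe_id"],
                                      assignment["sample_id"]]
    matrix = chosen.T
    matrix.columns = probe_map["gene_symbol"].to_numpy()
    donors = assignment.set_index("sample_id")["donor"]

    matrix = handle_missing(matrix, donors)
    prov["handle_missing"] = {"genes": matrix.shape[1]}

    matrix = normalize(matrix, donors)
    prov["normalize"] = {"genes": matrix.shape[1],
                         "samples": matrix.shape[0]}

    result = aggregate_and_stabilize(matrix, assignment,
                                     stability_threshold, block_mm, prov)
    return result, assignment
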