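"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the structure of a two-group
resting-state + morphometry + postmortem-expression study: band-limited
BOLD-like 4D series whose low-frequency amplitude is modulated inside
seeded clusters for cases, gray-matter-volume-like 3D maps with additive
seeded effects, and multi-donor probe-level expression samples a subset of
whose genes track the true effect map. Everything is a pure function of
(parameters, seed).

Defaults define the study conditions: a 24x28x24 grid at 3 mm, 31 subjects
per arm (the cohort ratio of the motivating design at matched power), 200
time points at TR 2 s, 2,000 genes of which 50 are true at coupling r 0.5,
300 samples from 3 donors, 2 probes per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .alff import FWHM_TO_SIGMA, band_bins
from .core_io import (BinaryMask, StatMap, SubjectDesign, TimeSeriesImage,
                      VolumeGrid, log_stage)
from .transcriptome import ExpressionSampleSet

DEFAULT_SHAPE = (24, 28, 24)
DEFAULT_VOXEL_MM = (3.0, 3.0, 3.0)
DEFAULT_N_PER_GROUP = 31
DEFAULT_BAND = (0.01, 0.08)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


@dataclass(frozen=True)
class EffectSpec:
    """Seeded group-difference clusters shared by the fMRI and GMV generators.

    ``signs`` gives the direction per cluster (+1: case > control). The
    amplitude effect is a fractional modulation of the band-limited signal
    (multiplied by 1 + effect for positive clusters in cases, divided for
    negative ones); the GMV effect is additive in GMV units.
    """

    cluster_centers: tuple[tuple[int, int, int], ...]
    cluster_radius_mm: float = 7.5
    amplitude_effect: float = 0.5
    gmv_effect: float = 0.03
    signs: tuple[int, ...] = (1, -1)

    def __post_init__(self):
        if self.cluster_radius_mm <= 0:
            raise ValueError("cluster radius must be positive")
        if len(self.signs) != len(self.cluster_centers):
            raise ValueError("need one sign per cluster")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")


@dataclass(frozen=True)
class ExpressionTruth:
    """Ground truth and distortion knobs for the expression generator."""

    n_genes: int = 2000
    true_gene_ids: tuple[str, ...] = ()
    coupling_r: float = 0.5
    noise_sd: float = 1.0
    n_donors: int = 3
    probes_per_gene: int = 2
    low_intensity_fraction: float = 0.10
    stale_fraction: float = 0.05
    retired_fraction: float = 0.02
    unstable_fraction: float = 0.05
    null_smooth_fwhm_mm: float = 15.0

    def __post_init__(self):
        if not 0 < self.coupling_r < 1:
            raise ValueError("coupling_r must be in (0, 1)")
        if self.n_donors < 1:
            raise ValueError("need at least one donor")
        bad = set(self.true_gene_ids) - set(gene_ids(self.n_genes))
        if bad:
            raise ValueError(f"true genes outside the universe: {sorted(bad)}")


def gene_ids(n_genes: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n_genes + 1)]


def default_truth(n_genes: int = 2000, n_true: int = 50,
                  seed: int = 0, **kwargs) -> ExpressionTruth:
    """Truth with a seeded random subset of true genes."""
    ids = gene_ids(n_genes)
    rng = _rng(seed)
    true = tuple(sorted(rng.choice(ids, size=n_true, replace=False))) \
        if n_true else ()
    return ExpressionTruth(n_genes=n_genes, true_gene_ids=true, **kwargs)


# ---------------------------------------------------------------------------
# Mask and effect geometry
# ---------------------------------------------------------------------------

def make_mask(shape=DEFAULT_SHAPE, voxel_size=DEFAULT_VOXEL_MM,
              seed: int = 0) -> BinaryMask:
    """A connected ellipsoidal 'brain' filling 30-50% of the grid.

    The affine is diag(-vx, vy, vz) with the grid center at world origin,
    so world x < 0 is the left half — MNI-like handedness for the
    hemisphere filter.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 8:
        raise ValueError("grid too small for an ellipsoidal mask")
    vx, vy, vz = (float(v) for v in voxel_size)
    rng = _rng(seed)
    center = (np.array(shape) - 1) / 2.0
    frac = rng.uniform(0.85, 0.95, size=3)  # keeps volume fraction in range
    semi = frac * np.array(shape) / 2.0
    idx = np.indices(shape)
    d2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    inside = d2 <= 1.0
    affine = np.diag([-vx, vy, vz, 1.0])
    affine[:3, 3] = -affine[:3, :3] @ center
    return BinaryMask(VolumeGrid(shape, affine), inside)


def default_effect_spec(mask: BinaryMask, **overrides) -> EffectSpec:
    """Two clusters, one positive (left half) and one negative (right half)."""
    shape = np.array(mask.grid.shape)
    centers = (
        tuple(int(x) for x in (0.68 * shape[0], 0.52 * shape[1], 0.50 * shape[2])),
        tuple(int(x) for x in (0.32 * shape[0], 0.45 * shape[1], 0.52 * shape[2])),
    )
    spec = EffectSpec(cluster_centers=centers, **overrides)
    effect_masks(mask, spec)  # validate placement
    return spec


def effect_masks(mask: BinaryMask, effect: EffectSpec) -> list[np.ndarray]:
    """Boolean ball per cluster; errors if a cluster leaves the mask."""
    balls = []
    idx = np.indices(mask.grid.shape)
    for center in effect.cluster_centers:
        world_c = mask.grid.voxel_to_world(np.asarray(center))[0]
        coords = np.stack([idx[a].ravel() for a in range(3)], axis=1)
        world = mask.grid.voxel_to_world(coords)
        d = np.linalg.norm(world - world_c, axis=1).reshape(mask.grid.shape)
        ball = d <= effect.cluster_radius_mm
        if not ball.any() or (ball & ~mask.inside).any():
            raise ValueError(f"effect cluster at {center} is not inside the mask")
        balls.append(ball)
    return balls


def truth_effect_volume(mask: BinaryMask, effect: EffectSpec,
                        smooth_fwhm_mm: float = 6.0) -> np.ndarray:
    """Signed ground-truth effect pattern (smoothed cluster indicator)."""
    vol = np.zeros(mask.grid.shape)
    for ball, sign in zip(effect_masks(mask, effect), effect.signs):
        vol[ball] = float(sign)
    if smooth_fwhm_mm > 0:
        sigma = smooth_fwhm_mm * FWHM_TO_SIGMA / mask.grid.voxel_size
        vol = ndimage.gaussian_filter(vol, sigma)
    vol[~mask.inside] = 0.0
    return vol


def make_smooth_stat_map(mask: BinaryMask, fwhm_mm: float = 6.0,
                         seed: int = 0, dof: int = 56) -> StatMap:
    """A smooth pseudo t-field over the mask (unit variance in-mask).

    Used as the reference spatial pattern for expression-screen checks: a
    full-support field with the smoothness of a fitted group-difference map
    conditions the correlation screen the way the real pipeline does.
    """
    rng = _rng(seed)
    sigma = fwhm_mm * FWHM_TO_SIGMA / mask.grid.voxel_size
    field = ndimage.gaussian_filter(rng.standard_normal(mask.grid.shape), sigma)
    vals = field[mask.inside]
    field = (field - vals.mean()) / vals.std()
    field[~mask.inside] = 0.0
    return StatMap(mask.grid, field, dof, mask)


# ---------------------------------------------------------------------------
# Subject designs and clinical measures
# ---------------------------------------------------------------------------

def make_designs(n_cases: int = DEFAULT_N_PER_GROUP,
                 n_controls: int = DEFAULT_N_PER_GROUP,
                 seed: int = 0) -> list[SubjectDesign]:
    """Covariate table: matched age/education, higher BMI in cases."""
    rng = _rng(seed)
    designs = []
    for i in range(n_cases + n_controls):
        case = i < n_cases
        designs.append(SubjectDesign(
            subject_id=f"sub-{i + 1:03d}",
            group="case" if case else "control",
            age=float(np.round(rng.normal(45, 9), 1)),
            sex="male" if rng.random() < (0.85 if case else 0.75) else "female",
            education=float(np.round(rng.normal(14, 2.5), 1)),
            bmi=float(np.round(rng.normal(28 if case else 24, 2.5), 1)),
        ))
    return designs


CLINICAL_NUMERIC = ("ahi", "ess", "moca", "stroop_word")


def make_clinical_table(designs, seed: int = 0) -> pd.DataFrame:
    """Sleep/neurocognitive measures with group shifts, plus a smoker flag."""
    rng = _rng(seed)
    rows = []
    for d in designs:
        case = d.group == "case"
        rows.append({
            "subject_id": d.subject_id,
            "ahi": float(np.round(rng.gamma(6, 9) if case
                                  else rng.gamma(4, 1), 1)),
            "ess": float(np.round(rng.normal(11 if case else 3, 3), 1)),
            "moca": float(np.round(np.clip(rng.normal(22 if case else 25, 2.5),
                                           5, 30), 0)),
            "stroop_word": float(np.round(rng.normal(80 if case else 92, 9), 0)),
            "smoker": "yes" if rng.random() < (0.65 if case else 0.5) else "no",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fMRI generator
# ---------------------------------------------------------------------------

def _smooth_field(mask: BinaryMask, rng, fwhm_mm: float,
                  unit_variance: bool = True) -> np.ndarray:
    sigma = fwhm_mm * FWHM_TO_SIGMA / mask.grid.voxel_size
    f = ndimage.gaussian_filter(rng.standard_normal(mask.grid.shape), sigma)
    if unit_variance:
        v = f[mask.inside]
        f = (f - v.mean()) / v.std()
    return f


def _bandlimited_noise(rng, n_vox: int, n_t: int, tr: float,
                       band=DEFAULT_BAND) -> np.ndarray:
    """Unit-variance noise confined to the band (ideal DFT filter)."""
    white = rng.standard_normal((n_vox, n_t))
    spec = np.fft.rfft(white, axis=1)
    keep = np.zeros(spec.shape[1], dtype=bool)
    keep[band_bins(n_t, tr, *band)] = True
    spec = np.where(keep, spec, 0.0)
    sig = np.fft.irfft(spec, n=n_t, axis=1)
    # in-band fraction of white-noise variance, exact for the ideal filter
    scale = np.sqrt(2.0 * keep.sum() / n_t)
    return sig / scale


def generate_group_fmri(designs, mask: BinaryMask, effect: EffectSpec,
                        tr: float = 2.0, n_timepoints: int = 200,
                        seed: int = 0, baseline: float = 100.0,
                        signal_sd: float = 1.0, noise_sd: float = 0.5,
                        amplitude_heterogeneity: float = 0.3,
                        subject_amplitude_sd: float = 0.15,
                        band=DEFAULT_BAND):
    """Yield (design, TimeSeriesImage) per subject.

    Each voxel's series = smooth spatial baseline + band-limited stochastic
    signal + white noise. The band-limited amplitude varies smoothly over
    space (shared across subjects — real ALFF maps have regional structure,
    which the one-sample masking step relies on), varies between subjects
    (a smooth subject-specific modulation of ``subject_amplitude_sd``, so
    group t-values are on a realistic scale rather than bounded only by
    spectral sampling noise), and is multiplied by (1 + amplitude_effect)
    inside positive clusters for cases (divided for negative clusters).
    Generation streams one subject at a time.
    """
    if n_timepoints < 64:
        raise ValueError("need n_timepoints >= 64")
    balls = effect_masks(mask, effect)
    master = np.random.SeedSequence(seed)
    shared_rng = np.random.default_rng(master.spawn(1)[0])
    baseline_field = baseline * (1.0 + 0.1 * _smooth_field(mask, shared_rng, 12.0))
    amp_field = 1.0 + amplitude_heterogeneity * _smooth_field(
        mask, shared_rng, 15.0)
    amp_field = np.clip(amp_field, 0.3, None)

    modulation = np.ones(mask.grid.shape)
    for ball, sign in zip(balls, effect.signs):
        factor = 1.0 + effect.amplitude_effect
        modulation[ball] = factor if sign > 0 else 1.0 / factor

    inside = mask.inside
    n_vox = mask.n_voxels
    subject_seeds = master.spawn(len(designs) + 1)[1:]
    for design, sseq in zip(designs, subject_seeds):
        rng = np.random.default_rng(sseq)
        sig = _bandlimited_noise(rng, n_vox, n_timepoints, tr, band)
        subj_mod = 1.0 + subject_amplitude_sd * _smooth_field(mask, rng, 15.0)
        amp = signal_sd * amp_field[inside] * np.clip(subj_mod, 0.2, None)[inside]
        if design.group == "case":
            amp = amp * modulation[inside]
        data = np.empty(mask.grid.shape + (n_timepoints,), dtype=np.float32)
        data[...] = 0.0
        series = (baseline_field[inside, None]
                  + amp[:, None] * sig
                  + noise_sd * rng.standard_normal((n_vox, n_timepoints)))
        data[inside] = series.astype(np.float32)
        yield design, TimeSeriesImage(mask.grid, data, tr, mask)


# ---------------------------------------------------------------------------
# GMV generator
# ---------------------------------------------------------------------------

def generate_group_gmv(designs, mask: BinaryMask, effect: EffectSpec,
                       smoothing_fwhm_mm: float = 8.0, seed: int = 0,
                       baseline: float = 0.5,
                       noise_sd: float = 0.1) -> list[np.ndarray]:
    """Per-subject GMV-like 3D maps with an additive seeded group effect.

    map = shared smooth baseline + (cases) signed gmv_effect inside clusters
    + Gaussian-smoothed subject noise; the residual field's smoothness is
    therefore the applied kernel, which the smoothness estimator should
    recover.
    """
    balls = effect_masks(mask, effect)
    master = np.random.SeedSequence(seed)
    shared_rng = np.random.default_rng(master.spawn(1)[0])
    baseline_field = baseline * (1.0 + 0.15 * _smooth_field(mask, shared_rng, 15.0))
    effect_term = np.zeros(mask.grid.shape)
    for ball, sign in zip(balls, effect.signs):
        effect_term[ball] = sign * effect.gmv_effect

    sigma = smoothing_fwhm_mm * FWHM_TO_SIGMA / mask.grid.voxel_size
    maps = []
    for sseq, design in zip(master.spawn(len(designs) + 1)[1:], designs):
        rng = np.random.default_rng(sseq)
        noise = noise_sd * rng.standard_normal(mask.grid.shape)
        if smoothing_fwhm_mm > 0:
            noise = ndimage.gaussian_filter(noise, sigma)
        vol = baseline_field + noise
        if design.group == "case":
            vol = vol + effect_term
        vol[~mask.inside] = 0.0
        maps.append(vol)
    log_stage("generate_group_gmv", subjects=len(maps),
              fwhm=smoothing_fwhm_mm)
    return maps


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExpression:
    sample_set: ExpressionSampleSet
    current_map: pd.DataFrame
    truth: ExpressionTruth
    sample_voxels: np.ndarray  # (n_samples, 3) voxel indices
    unstable_gene_ids: tuple[str, ...] = ()


def generate_expression_samples(mask: BinaryMask, truth: ExpressionTruth,
                                effect_map: StatMap, n_samples: int = 300,
                                seed: int = 0,
                                base_intensity: float = 8.0,
                                background_level: float = 6.0,
                                ) -> SyntheticExpression:
    """Probe-level expression samples scattered in the mask.

    Samples sit at distinct in-mask voxels (jittered < 1 mm off center to
    exercise nearest-voxel matching) and cycle round-robin over donors.
    Every gene except the ``unstable_fraction`` carries a smooth spatial
    field shared across donors (expression atlases have long-range regional
    gradients; this is what the stability screen keys on). True genes add
    a * t(sample) on top, with ``a`` solving for the target coupling r
    given the field-plus-noise variance; unstable genes are pure
    donor-independent noise and should fall to the stability filter.
    Each gene is carried by ``probes_per_gene`` probes with per-probe
    offsets and per-donor scale/offset distortions; a fraction of probes
    sits below background, and a fraction of annotations is stale.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_samples > mask.n_voxels:
        raise ValueError("more samples than in-mask voxels")
    if not effect_map.grid.matches(mask.grid):
        raise ValueError("effect map grid does not match the mask")
    rng = _rng(seed)
    ids = gene_ids(truth.n_genes)
    true_set = set(truth.true_gene_ids)

    voxels = mask.voxel_indices()
    pick = rng.choice(len(voxels), size=n_samples, replace=False)
    sample_vox = voxels[pick]
    centers = mask.grid.voxel_to_world(sample_vox)
    jitter = rng.uniform(-0.5, 0.5, size=centers.shape)
    coords = centers + jitter
    donors = [f"donor{1 + i % truth.n_donors}" for i in range(n_samples)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    samples = pd.DataFrame({
        "sample_id": sample_ids, "donor": donors,
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "structure": "synthetic",
    })

    t_at = effect_map.values[tuple(sample_vox.T)]
    t_std = (t_at - t_at.mean()) / (t_at.std() if t_at.std() > 0 else 1.0)

    # non-signal variance of a true gene: unit-sd shared field + residual
    r = truth.coupling_r
    resid_sd = 0.5 * truth.noise_sd
    a = r / np.sqrt(1.0 - r * r) * np.sqrt(1.0 + resid_sd ** 2)

    # gene-level expression (n_genes x n_samples), before probe expansion
    sigma_vox = (truth.null_smooth_fwhm_mm * FWHM_TO_SIGMA
                 / mask.grid.voxel_size)
    unstable = rng.random(truth.n_genes) < truth.unstable_fraction
    gene_expr = np.empty((truth.n_genes, n_samples))
    chunk = 256
    for start in range(0, truth.n_genes, chunk):
        stop = min(start + chunk, truth.n_genes)
        fields = rng.standard_normal((stop - start,) + mask.grid.shape)
        fields = ndimage.gaussian_filter(
            fields, (0, *sigma_vox)).astype(float)
        sampled = fields[:, sample_vox[:, 0], sample_vox[:, 1],
                         sample_vox[:, 2]]
        sd = sampled.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        gene_expr[start:stop] = sampled / sd
    noise = truth.noise_sd * rng.standard_normal((truth.n_genes, n_samples))
    for g, gid in enumerate(ids):
        if gid in true_set:
            gene_expr[g] = a * t_std + gene_expr[g] + 0.5 * noise[g]
        elif unstable[g]:
            gene_expr[g] = noise[g]  # donor-independent structure absent
        else:
            gene_expr[g] = gene_expr[g] + 0.5 * noise[g]

    # probe expansion with per-donor distortions
    n_probes = truth.n_genes * truth.probes_per_gene
    probe_ids, probe_gene = [], []
    for gid in ids:
        for p in range(truth.probes_per_gene):
            probe_ids.append(f"P_{gid}_{p + 1}")
            probe_gene.append(gid)
    probe_offset = rng.normal(0, 0.3, size=n_probes)
    low = rng.random(n_probes) < truth.low_intensity_fraction
    donor_names = sorted(set(donors))
    donor_scale = {d: s for d, s in zip(
        donor_names, rng.uniform(0.8, 1.2, size=len(donor_names)))}
    donor_offset = {d: o for d, o in zip(
        donor_names, rng.normal(0, 0.5, size=len(donor_names)))}
    scale_vec = np.array([donor_scale[d] for d in donors])
    offset_vec = np.array([donor_offset[d] for d in donors])

    intensity = np.empty((n_probes, n_samples))
    for p in range(n_probes):
        g = p // truth.probes_per_gene
        base = (background_level - 1.5) if low[p] else base_intensity
        level = base + probe_offset[p] + (0.0 if low[p] else gene_expr[g])
        intensity[p] = (scale_vec * level + offset_vec
                        + rng.normal(0, 0.15, size=n_samples))

    background = pd.Series(background_level, index=probe_ids, name="background")
    stale = rng.random(n_probes) < truth.stale_fraction
    retired = rng.random(n_probes) < truth.retired_fraction
    recorded = [f"OLD_{g}" if s else g for g, s in zip(probe_gene, stale)]
    annotations = pd.DataFrame({"probe_id": probe_ids,
                                "gene_symbol": recorded})
    current_map = pd.DataFrame({
        "probe_id": [p for p, r_ in zip(probe_ids, retired) if not r_],
        "gene_symbol": [g for g, r_ in zip(probe_gene, retired) if not r_],
    })

    sample_set = ExpressionSampleSet(
        samples=samples,
        intensity=pd.DataFrame(intensity, index=probe_ids, columns=sample_ids),
        background=background, annotations=annotations)
    log_stage("generate_expression_samples", samples=n_samples,
              genes=truth.n_genes, probes=n_probes, donors=truth.n_donors)
    unstable_ids = tuple(gid for gid, u in zip(ids, unstable)
                         if u and gid not in true_set)
    return SyntheticExpression(sample_set, current_map, truth, sample_vox,
                               unstable_ids)


# ---------------------------------------------------------------------------
# Gene-set fixtures
# ---------------------------------------------------------------------------

def make_gene_sets(all_genes, true_genes, n_sets: int = 20,
                   set_size: int = 100, planted_fraction: float = 0.8,
                   seed: int = 0) -> dict[str, dict[str, set[str]]]:
    """One planted set (80% of the true genes plus fillers) among random sets.

    Returned as {category: {set_name: members}}; sets are split over MF/CC/BP
    style categories so category-wise FDR is exercised.
    """
    rng = _rng(seed)
    all_genes = list(all_genes)
    true_genes = list(true_genes)
    n_true_in = int(round(planted_fraction * len(true_genes)))
    planted = set(rng.choice(true_genes, size=n_true_in, replace=False)) \
        if n_true_in else set()
    others = [g for g in all_genes
              if g not in planted and g not in set(true_genes)]
    fill = rng.choice(others, size=max(set_size - len(planted), 0),
                      replace=False)
    planted |= set(fill)
    categories = ("MF", "CC", "BP")
    collections: dict[str, dict[str, set[str]]] = {c: {} for c in categories}
    collections["MF"]["PLANTED_SET"] = planted
    for i in range(n_sets - 1):
        cat = categories[i % 3]
        members = set(rng.choice(all_genes, size=set_size, replace=False))
        collections[cat][f"RANDOM_SET_{i + 1:02d}"] = members
    return collections
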