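"""End-to-end orchestration: simulate -> ALFF -> group GLMs -> expression
prep -> spatial association -> enrichment -> clinical correlations, with one
config, file-based stage handoff (every stage is resumable from the files of
the previous one), and scoring against the synthetic ground truth.

The ALFF branch uses GRF cluster correction; the GMV branch uses the
Monte-Carlo extent threshold; both t-maps feed the gene screen, whose
intersection (crossover genes) is enriched against the gene-set fixtures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import association as assoc_mod
from . import clinical as clinical_mod
from . import enrichment as enrich_mod
from . import synthetic
from . import transcriptome as tx
from .alff import NuisanceSet, compute_alff
from .core_io import (BinaryMask, StatMap, log_stage, read_design_table,
                      read_gene_sets, read_mask, read_volume, write_gene_sets,
                      write_mask, write_table, write_design_table,
                      write_volume, logger)
from .group_glm import (DesignMatrix, SmoothnessEstimate,
                        estimate_smoothness, extent_threshold_clusters,
                        fit_two_sample_glm, grf_cluster_correction,
                        make_cluster_table, monte_carlo_cluster_threshold,
                        one_sample_mask)

STAGE_NAMES = ("mask", "designs", "fmri", "gmv", "expression", "gene_sets",
               "clinical", "monte_carlo")


@dataclass
class PipelineConfig:
    """Every stage parameter in one place; serialized into each output dir."""

    seed: int = 0
    # geometry / cohort
    grid_shape: tuple[int, int, int] = synthetic.DEFAULT_SHAPE
    voxel_size_mm: tuple[float, float, float] = synthetic.DEFAULT_VOXEL_MM
    n_cases: int = synthetic.DEFAULT_N_PER_GROUP
    n_controls: int = synthetic.DEFAULT_N_PER_GROUP
    # fMRI / ALFF
    tr_seconds: float = 2.0
    n_timepoints: int = 200
    discard_volumes: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    alff_smoothing_fwhm_mm: float = 6.0
    amplitude_effect: float = 0.5
    # GMV
    gmv_smoothing_fwhm_mm: float = 8.0
    gmv_effect: float = 0.03
    # group inference
    one_sample_alpha: float = 0.05
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    connectivity: int = 26
    mc_iterations: int = 1000
    # expression
    n_genes: int = 2000
    n_true_genes: int = 50
    coupling_r: float = 0.5
    n_expression_samples: int = 300
    n_donors: int = 3
    probes_per_gene: int = 2
    stability_threshold: float = 0.2
    left_only: bool = False
    # gene screen
    screen_alpha: float = 0.01
    screen_r_min: float = 0.2
    # enrichment
    n_gene_sets: int = 20
    gene_set_size: int = 100
    planted_fraction: float = 0.8
    min_overlap: int = 3
    q_max: float = 0.05
    # modality toggle: "alff" | "gmv" | "both"
    modality: str = "both"
    cases_only_correlations: bool = True
    version: str = "1"

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.modality not in ("alff", "gmv", "both"):
            raise ValueError("modality must be alff, gmv or both")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("bad band edges")

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_low_hz, self.band_high_hz)

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage child seeds expanded from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(
            len(STAGE_NAMES))
        return {name: int(s & 0x7FFFFFFF)
                for name, s in zip(STAGE_NAMES, state)}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RecoveryScore:
    """How well the pipeline recovered the synthetic ground truth."""

    cluster_sensitivity: dict = field(default_factory=dict)
    cluster_specificity: dict = field(default_factory=dict)
    gene_sensitivity: float | None = None
    gene_precision: float | None = None
    enrichment_rank: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Stage: simulate
# ---------------------------------------------------------------------------

def _subject_path(outdir: Path, sub: str, kind: str) -> Path:
    return outdir / kind / f"{sub}_{kind}.nii"


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    mask = synthetic.make_mask(cfg.grid_shape, cfg.voxel_size_mm,
                               seeds["mask"])
    effect = synthetic.default_effect_spec(
        mask, amplitude_effect=cfg.amplitude_effect,
        gmv_effect=cfg.gmv_effect)
    designs = synthetic.make_designs(cfg.n_cases, cfg.n_controls,
                                     seeds["designs"])
    write_mask(outdir / "mask.nii", mask)
    write_design_table(outdir / "design.tsv", designs)
    clinical = synthetic.make_clinical_table(designs, seeds["clinical"])
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)

    (outdir / "fmri").mkdir(exist_ok=True)
    for design, ts in synthetic.generate_group_fmri(
            designs, mask, effect, cfg.tr_seconds, cfg.n_timepoints,
            seeds["fmri"], band=cfg.band):
        write_volume(_subject_path(outdir, design.subject_id, "fmri"),
                     mask.grid, ts.data, tr_seconds=cfg.tr_seconds)
    (outdir / "gmv").mkdir(exist_ok=True)
    gmv_maps = synthetic.generate_group_gmv(
        designs, mask, effect, cfg.gmv_smoothing_fwhm_mm, seeds["gmv"])
    for design, vol in zip(designs, gmv_maps):
        write_volume(_subject_path(outdir, design.subject_id, "gmv"),
                     mask.grid, vol)

    truth = synthetic.default_truth(cfg.n_genes, cfg.n_true_genes,
                                    seeds["expression"],
                                    coupling_r=cfg.coupling_r,
                                    n_donors=cfg.n_donors,
                                    probes_per_gene=cfg.probes_per_gene)
    effect_vol = synthetic.truth_effect_volume(mask, effect)
    effect_map = StatMap(mask.grid, effect_vol, max(cfg.n_cases +
                                                    cfg.n_controls - 6, 1),
                         mask)
    expr = synthetic.generate_expression_samples(
        mask, truth, effect_map, cfg.n_expression_samples,
        seeds["expression"])
    edir = outdir / "expression"
    edir.mkdir(exist_ok=True)
    expr.sample_set.samples.to_csv(edir / "samples.tsv", sep="\t", index=False)
    expr.sample_set.intensity.to_csv(edir / "intensity.tsv", sep="\t",
                                     index_label="probe_id")
    expr.sample_set.background.rename("background").to_frame().to_csv(
        edir / "background.tsv", sep="\t", index_label="probe_id")
    expr.sample_set.annotations.to_csv(edir / "annotations.tsv", sep="\t",
                                       index=False)
    expr.current_map.to_csv(edir / "current_map.tsv", sep="\t", index=False)

    collections = synthetic.make_gene_sets(
        synthetic.gene_ids(cfg.n_genes), truth.true_gene_ids,
        cfg.n_gene_sets, cfg.gene_set_size, cfg.planted_fraction,
        seeds["gene_sets"])
    for category, sets in collections.items():
        write_gene_sets(outdir / f"gene_sets_{category}.gmt", sets)

    balls = synthetic.effect_masks(mask, effect)
    truth_json = {
        "true_genes": list(truth.true_gene_ids),
        "clusters": [
            {"center": list(map(int, c)), "sign": int(s),
             "voxels": np.argwhere(b).tolist()}
            for c, s, b in zip(effect.cluster_centers, effect.signs, balls)
        ],
        "stage_seeds": seeds,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
    log_stage("simulate", subjects=len(designs), voxels=mask.n_voxels)


# ---------------------------------------------------------------------------
# Stage: ALFF
# ---------------------------------------------------------------------------

def stage_alff(cfg: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    mask = read_mask(outdir / "mask.nii")
    designs = read_design_table(outdir / "design.tsv")
    (outdir / "malff").mkdir(exist_ok=True)
    for d in designs:
        ts = read_volume(_subject_path(outdir, d.subject_id, "fmri"),
                         mask=mask)
        if cfg.discard_volumes:
            ts.data = ts.data[..., cfg.discard_volumes:]
        amap = compute_alff(ts, NuisanceSet(), cfg.band,
                            smoothing_fwhm_mm=cfg.alff_smoothing_fwhm_mm)
        write_volume(_subject_path(outdir, d.subject_id, "malff"),
                     mask.grid, amap.standardized_alff)


# ---------------------------------------------------------------------------
# Stage: group difference (either modality)
# ---------------------------------------------------------------------------

def _read_subject_maps(outdir: Path, designs, kind: str) -> list[np.ndarray]:
    return [read_volume(_subject_path(outdir, d.subject_id, kind))[1]
            for d in designs]


def _write_cluster_outputs(outdir: Path, prefix: str, tmap: StatMap,
                           records, smoothness: SmoothnessEstimate,
                           extra: dict | None = None,
                           voxel_p: float = 0.001,
                           connectivity: int = 26) -> None:
    write_volume(outdir / f"{prefix}_tmap.nii", tmap.grid,
                 np.nan_to_num(tmap.values))
    table = make_cluster_table(records)
    write_table(outdir / f"{prefix}_clusters.tsv", table)
    # store cluster membership for downstream per-subject summaries
    lab_vol = _cluster_label_volume(tmap, records, voxel_p, connectivity)
    write_volume(outdir / f"{prefix}_cluster_labels.nii", tmap.grid, lab_vol)
    info = {"fwhm_mm": [float(x) for x in smoothness.fwhm_mm],
            "resel_count": float(smoothness.resel_count),
            "dof": int(smoothness.dof)}
    info.update(extra or {})
    (outdir / f"{prefix}_smoothness.json").write_text(
        json.dumps(info, indent=1))


def _cluster_label_volume(tmap: StatMap, records,
                          voxel_p: float = 0.001,
                          connectivity: int = 26) -> np.ndarray:
    """Volume whose value is the record label inside each surviving cluster."""
    from scipy import stats as sps

    from .group_glm import CONNECTIVITY_STRUCTURES
    u = float(sps.t.isf(voxel_p / 2.0, tmap.dof))
    values = np.where(tmap.mask.inside, np.nan_to_num(tmap.values), 0.0)
    out = np.zeros(tmap.grid.shape, dtype=np.float32)
    structure = CONNECTIVITY_STRUCTURES[connectivity]
    for sign, signed in (("increase", values), ("decrease", -values)):
        labels, n = ndimage.label(signed > u, structure=structure)
        for rec in records:
            if rec.sign != sign:
                continue
            peak_vox = np.round(tmap.grid.world_to_voxel(
                np.asarray(rec.peak_world_mm))[0]).astype(int)
            lab = labels[tuple(peak_vox)]
            if lab > 0:
                out[labels == lab] = rec.label
    return out


def stage_groupdiff(cfg: PipelineConfig, outdir: Path, modality: str) -> None:
    outdir = Path(outdir)
    mask = read_mask(outdir / "mask.nii")
    designs = read_design_table(outdir / "design.tsv")
    design = DesignMatrix.from_designs(designs)
    if modality == "alff":
        maps = _read_subject_maps(outdir, designs, "malff")
        null_value = 1.0
    elif modality == "gmv":
        maps = _read_subject_maps(outdir, designs, "gmv")
        null_value = 0.0
    else:
        raise ValueError(modality)

    tmap_full, resid_full = fit_two_sample_glm(maps, design, mask,
                                               return_residuals=True)

    if modality == "alff":
        # restrict cluster inference to voxels with group-typical signal
        by_group = {
            "case": [m for m, d in zip(maps, designs) if d.group == "case"],
            "control": [m for m, d in zip(maps, designs)
                        if d.group == "control"],
        }
        union = one_sample_mask(by_group, mask, null_value,
                                cfg.one_sample_alpha)
        if union.sum() < 10:
            logger.warning("one-sample mask nearly empty; using full mask")
            union = mask.inside
        search = BinaryMask(mask.grid, union & mask.inside)
        sel = search.inside[mask.inside]
        tmap = StatMap(mask.grid,
                       np.where(search.inside,
                                np.nan_to_num(tmap_full.values), 0.0),
                       tmap_full.dof, search)
        smoothness = estimate_smoothness(resid_full[:, sel], search,
                                         tmap.dof)
        records = grf_cluster_correction(tmap, smoothness, cfg.voxel_p,
                                         cfg.cluster_p,
                                         connectivity=cfg.connectivity)
        extra = {"correction": "grf"}
    else:
        smoothness = estimate_smoothness(resid_full, mask, tmap_full.dof)
        k_min = monte_carlo_cluster_threshold(
            mask, smoothness.fwhm_mm, cfg.voxel_p, cfg.cluster_p,
            cfg.mc_iterations, cfg.stage_seeds()["monte_carlo"],
            cfg.connectivity)
        records = extent_threshold_clusters(tmap_full, k_min, cfg.voxel_p,
                                            connectivity=cfg.connectivity)
        extra = {"correction": "monte_carlo", "min_extent_voxels": int(k_min)}

    _write_cluster_outputs(outdir, modality, tmap_full, records,
                           smoothness, extra, cfg.voxel_p, cfg.connectivity)


# ---------------------------------------------------------------------------
# Stage: expression preprocessing
# ---------------------------------------------------------------------------

def load_expression_inputs(outdir: Path) -> tx.ExpressionSampleSet:
    edir = Path(outdir) / "expression"
    samples = pd.read_csv(edir / "samples.tsv", sep="\t")
    intensity = pd.read_csv(edir / "intensity.tsv", sep="\t",
                            index_col="probe_id")
    background = pd.read_csv(edir / "background.tsv", sep="\t",
                             index_col="probe_id")["background"]
    annotations = pd.read_csv(edir / "annotations.tsv", sep="\t")
    return tx.ExpressionSampleSet(samples, intensity, background, annotations)


def stage_prep_expression(cfg: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    mask = read_mask(outdir / "mask.nii")
    sample_set = load_expression_inputs(outdir)
    current_map = pd.read_csv(outdir / "expression" / "current_map.tsv",
                              sep="\t")
    matrix, assignment = tx.prepare_expression(
        sample_set, current_map, mask,
        stability_threshold=cfg.stability_threshold,
        left_only=cfg.left_only)
    out = pd.concat([matrix.regions.reset_index(drop=True),
                     matrix.values.reset_index(drop=True)], axis=1)
    out.to_csv(outdir / "gene_matrix.tsv", sep="\t", index=False)
    assignment.to_csv(outdir / "sample_assignment.tsv", sep="\t", index=False)
    (outdir / "prep_provenance.json").write_text(
        json.dumps(matrix.provenance, indent=1))


def load_gene_matrix(outdir: Path) -> tx.GeneBySampleMatrix:
    df = pd.read_csv(Path(outdir) / "gene_matrix.tsv", sep="\t")
    region_cols = ["i", "j", "k", "x", "y", "z"]
    return tx.GeneBySampleMatrix(df.drop(columns=region_cols),
                                 df[region_cols])


# ---------------------------------------------------------------------------
# Stage: association
# ---------------------------------------------------------------------------

def _modalities(cfg: PipelineConfig) -> list[str]:
    return ["alff", "gmv"] if cfg.modality == "both" else [cfg.modality]


def stage_associate(cfg: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    mask = read_mask(outdir / "mask.nii")
    matrix = load_gene_matrix(outdir)
    selected: dict[str, list[str]] = {}
    tops = {}
    for modality in _modalities(cfg):
        grid, tvol = read_volume(outdir / f"{modality}_tmap.nii")
        dof = len(read_design_table(outdir / "design.tsv")) - 6
        tmap = StatMap(grid, tvol, dof, mask)
        tvec = assoc_mod.extract_t_at_samples(tmap, matrix.regions)
        assoc = assoc_mod.mass_correlation(matrix, tvec)
        assoc = assoc_mod.dual_threshold(assoc, cfg.screen_alpha,
                                         cfg.screen_r_min)
        write_table(outdir / f"assoc_{modality}.tsv", assoc)
        sel = assoc_mod.selected_genes(assoc)
        selected[modality] = sel
        (outdir / f"selected_{modality}.txt").write_text(
            "\n".join(sel) + ("\n" if sel else ""))
        tops[modality] = assoc_mod.rank_genes(assoc, top_k=5)
    if len(selected) == 2:
        crossover = assoc_mod.intersect_gene_lists(selected["alff"],
                                                   selected["gmv"])
    else:
        crossover = sorted(next(iter(selected.values())))
    (outdir / "crossover.txt").write_text(
        "\n".join(crossover) + ("\n" if crossover else ""))
    (outdir / "top_genes.json").write_text(json.dumps(
        {m: {"positive": t[0], "negative": t[1]} for m, t in tops.items()},
        indent=1))


# ---------------------------------------------------------------------------
# Stage: enrichment
# ---------------------------------------------------------------------------

def stage_enrich(cfg: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    matrix = load_gene_matrix(outdir)
    universe = matrix.genes
    query = [g for g in
             (outdir / "crossover.txt").read_text().splitlines() if g]
    collections = {}
    for gmt in sorted(outdir.glob("gene_sets_*.gmt")):
        category = gmt.stem.replace("gene_sets_", "")
        collections[category] = read_gene_sets(gmt)
    table = enrich_mod.run_enrichment(query, collections, universe,
                                      cfg.q_max, cfg.min_overlap)
    write_table(outdir / "enrichment.tsv", table)


# ---------------------------------------------------------------------------
# Stage: clinical statistics
# ---------------------------------------------------------------------------

def stage_clinical(cfg: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    designs = read_design_table(outdir / "design.tsv")
    designs_df = pd.read_csv(outdir / "design.tsv", sep="\t")
    clin = pd.read_csv(outdir / "clinical.tsv", sep="\t")
    tests = clinical_mod.group_tests(clin, designs_df,
                                     synthetic.CLINICAL_NUMERIC, ("smoker",))
    write_table(outdir / "clinical_group_tests.tsv", tests)

    rows = []
    for modality in _modalities(cfg):
        labels_path = outdir / f"{modality}_cluster_labels.nii"
        if not labels_path.exists():
            continue
        _, labels = read_volume(labels_path)
        cluster_masks = {f"{modality}_cluster{int(lab)}": labels == lab
                         for lab in np.unique(labels) if lab > 0}
        if not cluster_masks:
            continue
        kind = "malff" if modality == "alff" else "gmv"
        maps = _read_subject_maps(outdir, designs, kind)
        imaging = clinical_mod.cluster_mean_values(
            maps, [d.subject_id for d in designs], cluster_masks)
        corr = clinical_mod.spearman_with_fdr(
            imaging, clin, synthetic.CLINICAL_NUMERIC,
            cases_only=cfg.cases_only_correlations, designs_df=designs_df)
        rows.append(corr)
    if rows:
        corr_all = pd.concat(rows, ignore_index=True)
        corr_all["q"] = enrich_mod.bh_adjust(corr_all["p"].to_numpy())
    else:
        corr_all = pd.DataFrame(columns=["cluster", "measure", "rho",
                                         "p", "q"])
    write_table(outdir / "clinical_correlations.tsv", corr_all)


# ---------------------------------------------------------------------------
# Stage: scoring against ground truth
# ---------------------------------------------------------------------------

def score_recovery(outdir: Path, cfg: PipelineConfig) -> RecoveryScore:
    outdir = Path(outdir)
    truth = json.loads((outdir / "truth.json").read_text())
    mask = read_mask(outdir / "mask.nii")
    truth_vox = np.zeros(mask.grid.shape, dtype=bool)
    cluster_vox = []
    for cl in truth["clusters"]:
        vv = np.array(cl["voxels"], dtype=int)
        truth_vox[tuple(vv.T)] = True
        cluster_vox.append(vv)

    score = RecoveryScore()
    for modality in _modalities(cfg):
        labels_path = outdir / f"{modality}_cluster_labels.nii"
        found = np.zeros(mask.grid.shape, dtype=bool)
        if labels_path.exists():
            _, labels = read_volume(labels_path)
            found = labels > 0
        recovered = sum(1 for vv in cluster_vox
                        if found[tuple(vv.T)].any())
        score.cluster_sensitivity[modality] = recovered / len(cluster_vox)
        neg = mask.inside & ~truth_vox
        fp = int((found & neg).sum())
        score.cluster_specificity[modality] = 1.0 - fp / int(neg.sum())

    true_genes = set(truth["true_genes"])
    crossover = {g for g in
                 (outdir / "crossover.txt").read_text().splitlines() if g}
    if true_genes:
        score.gene_sensitivity = len(crossover & true_genes) / len(true_genes)
    score.gene_precision = (len(crossover & true_genes) / len(crossover)
                            if crossover else None)

    enr_path = outdir / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        hit = enr.index[enr["set_name"] == "PLANTED_SET"]
        score.enrichment_rank = int(hit[0]) + 1 if len(hit) else None
    (outdir / "recovery.json").write_text(
        json.dumps(score.to_dict(), indent=1))
    return score


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

STAGES = ("simulate", "alff", "groupdiff", "prep-expression", "associate",
          "enrich", "clinical", "score")


def run_all(cfg: PipelineConfig, outdir) -> RecoveryScore:
    """Run every stage in order; provenance and config land in outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    counts = {}
    try:
        stage_simulate(cfg, outdir)
        counts["simulate"] = {"subjects": cfg.n_cases + cfg.n_controls}
        if cfg.modality in ("alff", "both"):
            stage_alff(cfg, outdir)
            stage_groupdiff(cfg, outdir, "alff")
        if cfg.modality in ("gmv", "both"):
            stage_groupdiff(cfg, outdir, "gmv")
        for modality in _modalities(cfg):
            table = pd.read_csv(outdir / f"{modality}_clusters.tsv", sep="\t")
            counts[f"clusters_{modality}"] = int(len(table))
        stage_prep_expression(cfg, outdir)
        stage_associate(cfg, outdir)
        counts["crossover_genes"] = len(
            [g for g in (outdir / "crossover.txt").read_text().splitlines()
             if g])
        stage_enrich(cfg, outdir)
        stage_clinical(cfg, outdir)
        score = score_recovery(outdir, cfg)
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    provenance = {
        "config_hash": hashlib.sha256(
            (outdir / "config.yaml").read_bytes()).hexdigest(),
        "stage_seeds": cfg.stage_seeds(),
        "counts": counts,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return score


def output_table_hashes(outdir) -> dict[str, str]:
    """SHA-256 of every tabular/text artifact (determinism check)."""
    outdir = Path(outdir)
    hashes = {}
    for pattern in ("*.tsv", "*.json", "*.txt", "*.gmt", "*.yaml"):
        for path in sorted(outdir.rglob(pattern)):
            hashes[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return hashes


# ---------------------------------------------------------------------------
# Calibration utilities (null simulations shared by tests and reporting)
# ---------------------------------------------------------------------------

def grf_fwe_simulation(mask: BinaryMask, designs, fwhm_mm: float = 6.0,
                       n_reps: int = 500, voxel_p: float = 0.001,
                       cluster_p: float = 0.05, seed: int = 0) -> float:
    """Family-wise error of the GRF path on null smoothed-noise cohorts.

    Each replicate draws one subject map per design row (white noise
    smoothed to ``fwhm_mm``), fits the covariate GLM, estimates smoothness
    from the residuals, and applies the cluster correction; returns the
    fraction of replicates with >= 1 surviving cluster.
    """
    import warnings as _warnings
    rng = np.random.default_rng(seed)
    design = DesignMatrix.from_designs(designs)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / mask.grid.voxel_size
    n_sub = len(designs)
    hits = 0
    for _ in range(n_reps):
        maps = [ndimage.gaussian_filter(
            rng.standard_normal(mask.grid.shape), sigma)
            for _ in range(n_sub)]
        tmap, resid = fit_two_sample_glm(maps, design, mask,
                                         return_residuals=True)
        smoothness = estimate_smoothness(resid, mask, tmap.dof)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            records = grf_cluster_correction(tmap, smoothness, voxel_p,
                                             cluster_p)
        hits += bool(records)
    return hits / n_reps
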