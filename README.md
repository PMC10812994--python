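# neurotx

Two-group resting-state and morphometry statistics coupled to spatial
transcriptomics, runnable end-to-end on synthetic data with known ground
truth. The package is aimed at methodologists who want a fully scriptable,
testable version of the now-common "imaging-transcriptomics" analysis
chain: group-difference brain maps, spatially matched gene expression, a
correlation screen, and gene-set enrichment — without needing clinical
scans or the Allen expression atlas.

## What it computes

**ALFF.** For each voxel time series the amplitude of low-frequency
fluctuations is the mean one-sided amplitude spectrum over 0.01–0.08 Hz
after linear detrending, optional nuisance regression, and an ideal DFT
bandpass: with `a_k = 2|X_k|/N`, `ALFF = mean_{0.01 ≤ f_k ≤ 0.08} a_k`.
Standardized ALFF (mALFF) divides by the in-mask mean.

**Group inference.** Voxel-wise OLS of subject maps on
`[1, group, age, sex, education, BMI]` with `t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)`,
positive t meaning case > control. Cluster-level correction is available by
Gaussian-random-field theory (expected cluster count `E[m] = R · ρ₃(u)`
from the 3D t-field EC density, cluster-extent tail
`P(n ≥ k) = exp(−βk^{2/3})`) and by Monte-Carlo extent thresholding
(max-cluster-extent quantile of smoothness-matched null fields). Residual
smoothness is estimated per axis from the gradient-variance ratio,
`FWHM = d·√(4 ln 2 / (var Δr / var r))`.

**Transcriptomics.** Donor probe-level samples are refined in nine steps
(probe reannotation, intensity filter, probe selection by differential
stability, sample-to-voxel matching, missing-data handling, scaled-robust-
sigmoid sample and gene normalization, per-voxel aggregation, stable-gene
filter) into a regions × genes matrix. Each gene's profile is Pearson-
correlated with the t-values at the same voxels; genes pass when
Bonferroni-corrected p < 0.01 **and** |r| > 0.2, and the ALFF∩GMV
"crossover" list is tested for gene-set over-representation
(hypergeometric tail, BH-FDR per category). Clinical comparisons use
Mann–Whitney U (exact for small samples), Fisher's exact test, and
Spearman correlations with FDR.

**Synthetic bench.** `neurotx.synthetic` generates every input with known
truth: band-limited 4D series whose low-frequency amplitude is modulated
inside seeded clusters for cases, GMV-like maps with additive effects, and
multi-donor probe-level expression in which 50 of 2,000 genes track the
effect map at a target coupling of r = 0.5.

## Worked example

```
neurotx run-all --seed 11 --outdir out/
# or: python -m neurotx.cli ... / neurotx.pipeline.run_all(PipelineConfig(seed=11), "out")
```

completes in well under a minute at the default desk scale
(24×28×24 grid at 3 mm, 31 cases / 31 controls, 200 time points,
2,000 genes, 300 expression samples) and prints the recovery score:

```json
{
 "cluster_sensitivity": {"alff": 1.0, "gmv": 1.0},
 "cluster_specificity": {"alff": 0.9998, "gmv": 1.0},
 "gene_sensitivity": 0.08,
 "gene_precision": 1.0,
 "enrichment_rank": 1
}
```

Both seeded effect clusters are recovered by both correction paths
(`alff_clusters.tsv`, GRF path):

```
index  side  peak_x_mm  peak_y_mm  peak_z_mm  extent_voxels  peak_t    corrected_p  direction
1      R     13.5       -1.5       1.5        76             -7.78185  0.00563      decrease
2      L     -13.5      1.5        -1.5       63             6.99595   0.00965      increase
```

The crossover gene list contains only true genes (precision 1.0 — the
double Bonferroni screen against two independently fitted maps is strict,
hence the low end-to-end sensitivity), and the planted gene set still
ranks first in the enrichment table with q ≈ 5×10⁻⁴. Every output
(t-maps, cluster tables, gene matrix, association tables, enrichment,
clinical correlations, provenance) lands in `out/` as NIfTI/TSV/JSON.

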