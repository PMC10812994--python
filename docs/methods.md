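# Methods

This note records the models, conventions and numerical choices behind
`neurotx`, and what the synthetic bench does and does not establish.

## ALFF

A voxel's series is linearly detrended (least-squares line, mean
included), optionally residualized against a nuisance matrix (intercept
always added; rank-deficiency is an error that names the collinear
columns), and bandpassed with an ideal frequency-domain boxcar: DFT
coefficients whose bin-center frequency lies outside [0.01, 0.08] Hz are
zeroed, inclusively at both edges. ALFF is the *mean* of the one-sided
amplitude spectrum `a_k = 2|X_k|/N` over in-band bins — the mean rather
than the sum makes the statistic invariant to series length at a fixed
band. The series is filtered first and the spectrum of the filtered series
averaged over the same band; the filter is redundant given the band
average, but it is the order in which these steps are conventionally
described, and it is harmless.

Standardized ALFF is mALFF: division by the in-mask mean. A z-score
variant was considered and rejected as the less common convention; the
choice is recorded in output metadata and only affects the null value used
by the one-sample masking step (1 for mALFF). Smoothing (default 6 mm
FWHM, σ = FWHM/2√(2 ln 2) per axis converted to voxels) is applied to the
ALFF map with mask-aware renormalization — the map is smoothed as
`smooth(map·mask)/smooth(mask)` so constants survive to the mask edge.
The first 10 volumes of each run are discarded before any statistic
(configurable). Whether a global-mean regressor belongs in the nuisance
set is left as a flag (`NuisanceSet` carries whatever columns the caller
enables); the pipeline default for synthetic data is an empty nuisance set
because the generator has no motion or physiological confounds.

## Group inference

The design matrix is `[1, group(case=1), age, sex(male=1), education,
BMI]`; `t = c'β̂ / √(σ̂²c'(X'X)⁻¹c)` with dof = n − rank(X). Zero-variance
voxels are flagged and set to t = 0 rather than propagating NaN.

For the ALFF branch the two-sample search region is the union of voxels
where either group's one-sample t against the mALFF null value of 1 is
significant at α = 0.05 uncorrected (two-sided) — the α is a package
default, configurable. The GLM itself is fitted over the full mask so the
t-map remains defined everywhere for the transcriptomic screen; only
cluster inference is restricted.

Smoothness: per axis, `FWHM = d·√(4 ln 2/ρ)` with ρ the ratio of the
variance of in-mask first spatial differences to the residual variance,
pooled over residual maps. For a Gaussian kernel this simple estimator is
biased mildly upward (a 6 mm kernel on a 3 mm grid reads ≈ 6.5 mm); the
bias is inherited by both correction paths equally and is well inside the
recovery band the tests enforce. Spatially independent noise reads
`d·√(2 ln 2)` ≈ 1.18 voxels, the estimator's analytic floor. Resels =
mask volume / ∏FWHM.

GRF cluster correction thresholds each tail separately at voxel-p/2
(t quantile), labels clusters with 26-connectivity (6/18 configurable; no
convention is canonical), and computes the corrected cluster p as
`1 − exp(−E[m]·P(n ≥ k))` with `E[m] = 2·R·ρ₃(u)` — the factor 2 counts
expected clusters over *both* excursion sets, so the family-wise rate over
signed clusters stays at the nominal level rather than doubling.
`ρ₃` is the standard 3D t-field EC density;
`P(n ≥ k) = exp(−βk^{2/3})`, `β = (Γ(5/2)·E[m,tail]/E[N,tail])^{2/3}`,
extents in voxels. Validity warnings fire when resels < 1 or smoothness
< 2 voxels FWHM. Simulated over 500 null cohorts (white noise smoothed at
6 mm, full covariate GLM, smoothness re-estimated per replicate) the
observed family-wise rate sits below the nominal 0.05 — the approximation
is conservative at this smoothness and threshold.

The Monte-Carlo path simulates Gaussian fields smoothed to the estimated
FWHM (plain stationary smoothing, then in-mask standardization),
thresholds two-tailed, records the maximum cluster extent per iteration
(both tails), and returns the ceiling of the (1 − cluster_p) quantile over
1000 iterations; clusters at least that large are reported. The pipeline
uses GRF for the ALFF branch and Monte-Carlo for the GMV branch, mirroring
how the two map types are conventionally treated; either is available for
either input.

## Expression preprocessing

Steps run strictly 1→9 and each logs the (probes, genes, samples)
retained; the counts travel in the output provenance. Defaults follow the
abagen-style conventions: intensity filter keeps probes above their
background in ≥ 50% of samples; probe selection by differential stability
(fallback: highest mean intensity for single-donor data; exact ties break
to the lexicographically smaller probe id); sample-to-voxel matching by
nearest in-mask voxel center within 2 mm (KD-tree), with an optional
left-hemisphere filter (world x < 0, off by default for synthetic data);
genes > 50% missing are dropped, the rest imputed by donor-wise median;
normalization is the scaled robust sigmoid `1/(1+exp(−(x−med)/(IQR/1.349)))`
min-max rescaled to [0, 1], applied per sample across genes and then per
gene across a donor's samples (zero-spread slices are set to 0.5);
samples sharing a voxel are averaged; genes with differential stability
below 0.2 are dropped (threshold configurable — no canonical value
exists).

Differential stability needs a common spatial support across donors, but
donors occupy disjoint sample locations. Profiles are therefore averaged
within 12 mm cubic blocks and donor pairs are correlated over blocks where
both have samples (≥ 3 common blocks required); stability is the mean over
pairs. Block size trades support overlap against spatial resolution; 12 mm
(4 voxels) gives each donor pair ~40 common blocks at the default sampling
density, enough to separate planted stable genes (shared smooth fields,
stability ≈ 0.5–0.8) from donor-specific noise genes (≈ 0 ± 0.1).

## Gene screen, enrichment, clinical statistics

Per gene, Pearson r against the t-values at the matrix's voxels with the
exact t-transform p (n − 2 dof); constant genes are excluded and logged.
The dual criterion is a single conjunction, `p < α/m ∧ |r| > 0.2`, with m
the number of genes actually tested (the Bonferroni denominator follows
the screen actually performed, not the pre-filter universe) and α = 0.01.
p-values are parametric and two-sided; positive and negative lists are
ranked by r with lexicographic tie-breaks.

Enrichment is the hypergeometric upper tail `P(X ≥ k)` with the tested
background as the universe (configurable; the background choice follows
the screen actually performed), BH-adjusted within each category
(MF/CC/BP-style; a global-FDR flag exists), sets with overlap < 3 are not
tested.

Mann–Whitney uses exact enumeration of all group assignments of the
pooled midranks for n ≤ 20 (correct under ties; the null U distribution
is symmetric about n₁n₂/2 under exchangeability, so the two-sided p is
`P(|U−μ| ≥ |u−μ|)`) and a tie- and continuity-corrected normal
approximation otherwise. Fisher's exact test and Spearman's rho delegate
to scipy; BH to statsmodels. Imaging–clinical correlations use the mean
standardized map value inside each surviving cluster (peak-voxel summary
would be an easy variant), cases only by default, with BH over all
(cluster × measure) pairs.

## The synthetic bench

Defaults define the study conditions: 24×28×24 grid at 3 mm (an
ellipsoidal "brain" filling 30–50% of the grid, left = world x < 0),
31 subjects per arm, TR 2 s, 200 time points, two seeded spherical effect
clusters of 7.5 mm radius with opposite signs, amplitude effect 0.5
(multiplicative on the band-limited component only, so ALFF rather than
mean signal carries the difference), GMV effect 0.03 on a smooth baseline
of ~0.5 with 8 mm-smoothed noise of σ 0.1 (post-smoothing residual σ ≈
0.012, i.e. a strong but not degenerate effect), 2,000 genes with 50 true
at coupling r = 0.5, 300 samples from 3 donors, 2 probes per gene, with
10% below-background probes, 5% stale annotations, 2% retired probes and
5% donor-specific (unstable) genes to exercise steps 1–3 and 9.

Subjects share a smooth baseline and a smooth amplitude-heterogeneity
field (15 mm, ±30%) — real ALFF maps have regional structure, which the
one-sample masking step relies on — plus a subject-specific smooth
amplitude modulation (±15%) so group t-values land on a realistic scale
(|t| ≈ 7–9 at the seeded peaks) instead of being bounded only by spectral
sampling noise. True genes are `a·t(sample) + field + ε` with the
coefficient solved so the population correlation with the reference map
is 0.5 given the field-plus-noise variance; null genes carry a shared
smooth spatial field (15 mm FWHM) because stability filtering is only
meaningful for genes with longer-range structure than the inter-donor
sample spacing. Per-donor scale/offset distortions exercise the
normalization steps. All generators are pure functions of (parameters,
seed); the master seed expands into per-stage children recorded in the
provenance file.

What the bench does *not* emulate: hemodynamics, head motion, scanner
artifacts, anatomical parcellations, microarray background-correction
physics, or realistic gene-gene correlation structure. Passing tests
therefore demonstrate the statistical machinery under its own
assumptions (Gaussian, stationary, correctly specified designs), not
robustness to real-data violations of them.

## Known limitations

- The Bonferroni gene screen assumes exchangeable samples. When both the
  t-map and the gene fields are spatially smooth at the sample spacing,
  the parametric null is anticonservative: under a fully null pipeline
  the per-modality gene lists admit false positives (a few percent of
  genes) even though cluster tables and the crossover list stay empty.
  This is the documented motivation for spin-type null models, which are
  deliberately out of scope here; the screen's operating characteristics
  are certified in the regime where sample spacing decorrelates the map
  (sensitivity ≈ 0.98, FDP ≈ 0.02, null mean ≈ 0.6 selected genes over
  20 replicates).
- End-to-end gene recovery through two independently fitted t-maps is
  attenuated (r shrinks by the truth-to-fitted map correlation on each
  branch), so the crossover list is small and high-precision rather than
  sensitive — the same asymmetry the screen design produces on real data.
- The GRF correction is conservative at 2-voxel smoothness; the
  Monte-Carlo path is the safer default for rough maps.
- Problem sizes in tests and the acceptance script (replicate counts of
  20–500, 10⁵-draw oracles) are the package's chosen desk-scale
  conditions; all of them run on a single CPU in minutes.
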