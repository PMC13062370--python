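# Methods

This note documents the models, conventions and design choices behind
`lnmcircuit`: what each stage computes, the generative model of the
synthetic study, the tunable parameters, and the numerical edge-case rules.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Severity banding

MMSE and MoCA are integer 0–30 screening scores.  Each is banded on an
ordinal 0–3 scale (MoCA: 26–30 → 0, 18–25 → 1, 10–17 → 2, 0–9 → 3;
MMSE: 24–30 → 0, 18–23 → 1, 10–17 → 2, 0–9 → 3; all bands inclusive), the
two levels are summed (0–6), and the sum alone assigns the group
(0–1 → G1, 2–3 → G2, 4–6 → G3).  Fractional scores are rejected rather
than rounded: both instruments are integer-scored and silent rounding
could flip a band.  The banding is exhaustively enumerable (31 × 31 cases)
and the suite checks every case.

## Lesion network mapping

All volumes live on one `VolumeGrid` (shape, RAS+ affine in mm, brain
mask); maps from different sources are accepted only if shape and affine
agree within 1e-6.  Voxel indices are 0-based internally; user-facing
coordinates are world mm.

**Connectivity.** The seed series is the unweighted mean over seed voxels;
per-voxel Pearson r against the seed is Fisher-transformed with r clipped
to ±(1 − 1e-7), so seed self-correlations stay finite (z ≈ 8.4).  Fisher z
is applied *before* all averaging and t-testing: variance-stabilised z is
the standard scale for inference on correlations.

**t statistics.** One-sample: t = mean/(sd/√n), df = n − 1.  Two-sample:
pooled-variance Student t, df = n_A + n_B − 2, sign = mean(A) − mean(B).
Zero-variance voxels carry a deterministic sentinel: t = ±∞ when the mean
is nonzero (always "significant"), t = 0 when both are zero; counts are
logged.

**Thresholding and FWE.** Voxelwise family-wise-error control is Bonferroni
over in-mask voxels — conservative, exactly reproducible, and recorded in
every map's provenance — rather than random-field theory, whose smoothness
estimation is not reproducible from the published protocol.  The printed
sensitivity criteria (t > 7 *and* FWE p < 10⁻⁶) are applied jointly, and
likewise (t > 5, p < 10⁻⁶) for the circuit: the protocol prints both in
one parenthesis and the joint reading is the safe one.  "Overlap exceeding
95%" is read strictly: a voxel present in exactly 95% of networks is
excluded.  An optional max-|t| permutation FWE
(`specificity_map_permutation`) is provided for the two-sample contrast.

**Specificity input.** The per-patient observation entering the two-sample
test is the subject-mean Fisher-z map across the normative cohort (one map
per patient); the protocol does not state whether means or t-maps were
used, and the mean map is the conventional choice.

**LOI and circuit.** The LOI is the voxelwise AND of sensitivity and
specificity maps; an empty intersection raises an explicit error rather
than writing an empty file.  The circuit re-uses the seed-correlation
machinery with the LOI as seed.  Because the seed's own voxels correlate
with the seed mean at roughly 1/√k (k seed voxels) systematically, the
derived circuit always contains the LOI voxels, even for a pure-noise
cohort — the null expectation is therefore "no circuit voxels beyond the
seed", and that is what the null tests assert.

## Synthetic study: generative model

The generator's role is to give every downstream stage a recovery-based
test.  Defaults define the study conditions: 3 mm isotropic RAS+ grid of
20 × 24 × 20 voxels spanning x ∈ [−28.5, 28.5], y ∈ [−48, 21],
z ∈ [−30, 27] mm with an ellipsoidal brain mask (~3800 voxels, x symmetric
about the midline so mirroring is exact); 30 controls × 150 frames in the
test fixture (91 × 250 in the acceptance run); 55 patients in groups
25/15/15; lesions of 3–8 voxels; latent amplitude 1, noise SD 1.

**BOLD.** Every in-mask voxel carries i.i.d. Gaussian noise (SD
`noise_sd`).  The planted circuit is a union of spherical regions in the
left hemisphere — the LOI plus eight "distractor" regions.  Circuit voxels
additionally carry (a) one zero-mean *global* latent series shared by the
whole circuit (amplitude `latent_strength`) and (b) one *local* latent per
region (amplitude 0.8 × `latent_strength`), all drawn independently per
subject.  BOLD is simulated directly as latent-plus-noise series, not via
hemodynamic convolution: the pipeline consumes correlation structure only.

The local latents are what make the LOI identifiable.  A single
exchangeable circuit latent would make every circuit-seeded network
identical in expectation, so the G3-vs-G1 specificity contrast would be
flat and no LOI could ever be derived.  With per-region local latents of
*equal* amplitude, (i) every lesion on the circuit sees the same seed
variance, so cross-region connectivity is matched between groups, and
(ii) only the severe group's lesions — seeded inside the LOI — share the
LOI's local latent, so the group difference is localised exactly there.
G1/G2 lesions start on circuit voxels outside the LOI and never grow into
it; G3 lesions start inside the LOI.  With `latent_strength = 0` the whole
volume is pure noise and every null construction follows.

**Scores.**  Drawn from group-conditional integer bands (choose a combined
level in the group's range, split it uniformly over valid scale pairs,
draw each raw score uniformly within its band), so the group label is
recoverable from the scores by construction.  This is banding logic, not a
psychometric model — only the banding is under test.

**Patient BOLD.** Follows the normative model with the global-latent
amplitude scaled by 1 + 0.5·(3 − combined)/3 (better cognition → stronger
circuit coupling; the factor spans 1.5 down to 0.5) and the lesion's own
voxels silenced to pure noise.  This plants the monotone FC–behaviour
coupling and the G3 < G1 connectivity deficit that the group-comparison
stage is tested against.

**Annotation maps.** Independent Gaussian fields smoothed with a 1-voxel
kernel, standardised within the analysis mask.  The designated map is an
exact mixture target_r·ẑ(t) + √(1−target_r²)·ê of the standardised circuit
t-map and orthogonalised noise, so its in-mask correlation with the
criterion equals `target_r` by construction.

**Gene matrix.** Signal genes follow effect_size × z(regional t) + N(0,1);
all genes are then z-scored across regions (the standardised-matrix
convention of imaging-transcriptomics pipelines).  The atlas parcellates
left-hemisphere in-mask voxels into compact regions by seeded k-means on
world coordinates.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: realistic lesion morphology and vascular
territories, hemodynamics and physiological noise, spatial autocorrelation
of receptor/gene maps beyond the planted structure, registration error,
and ageing effects in the normative cohort.  Recovery results demonstrate
correctness of the machinery under the planted model, not field
performance.

## Dominance analysis

Subset R² values are computed from centred cross-products (Gram matrix),
so each subset costs one O(k³) solve with no data pass; solves are batched
by subset size, keeping the full P = 18 enumeration (262 143 submodels) in
the seconds range.  Total dominance uses the two-level (within-size, then
across-size) average of ΔR²: the protocol's verbal description reads as a
simple mean over all submodels, but only the two-level average satisfies
the also-stated identity Σ total = R²_full, and the identity wins; the
simple mean is kept as a diagnostic (`simple_mean_dominance`).  Singular
subsets fall back to a 1e-10 ridge with a logged warning, so degenerate
fixtures cannot crash the enumeration.  Permutation inference permutes the
criterion and compares full-model adjusted R² =
1 − (1 − R²)(n−1)/(n−P−1); p uses the add-one estimator
(1 + #{null ≥ obs})/(n_perm + 1), which is never exactly zero.

## PLS1 transcriptomics

First-component weights are the closed form w ∝ Xᵀ(y − ȳ), unit-normalised,
with the sign convention corr(Xw, y) ≥ 0; variance explained is the squared
correlation of scores with the response.  Later components are out of
scope.  Bootstrap resamples regions (rows) with replacement — the estimand
is the stability of gene weights across brain regions — sign-aligning each
replicate to the original and dividing original weights by bootstrap SEs.
Degenerate replicates (constant resampled response) are redrawn and
logged.  Gene tails: two-sided normal p on the bootstrap Z, BH-FDR, then
up to `top_n` genes per tail among q < 0.05, ranked by |Z| — the reading
of "rank, then FDR-select tails" that makes the selection well-defined.

## Circuit statistics

Sphere ROIs contain voxels whose centre lies within the radius (inclusive,
Euclidean world mm).  Circuit overlap uses the impairment circuit as the
denominator (matching "the circuit overlapped N% with the reference");
Dice is available via `symmetric=True`.  Lesion-in-circuit proportions
default to patient-level any-overlap counting with group size as
denominator; a voxel-fraction variant is exposed for sensitivity analysis.
The midline is world x = 0; contralateral masking reflects world
coordinates exactly and takes the nearest voxel, falling back to the
nearest in-mask voxel (logged) when the mirror lands outside the mask.

Cluster-level inference replaces Gaussian-random-field correction with a
max-extent permutation null: group labels are permuted (seeded), the
largest face-connected suprathreshold cluster extent is recorded per draw,
and an observed cluster survives iff its extent strictly exceeds the
(1 − cluster_p) quantile of that null; per-cluster corrected p uses the
add-one estimator.  Fewer than 100 permutations are refused as an unstable
null.  Suprathreshold voxels are clustered per sign at the two-tailed
voxel_p critical t.  Spearman brain–behaviour correlation with a covariate
is computed as the Pearson correlation of ranks residualised on the
covariate's ranks (df = n − 3) — the standard partial-rank construction.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| t_sensitivity / p_sensitivity | 7 / 10⁻⁶ | t, FWE p | per-lesion network threshold |
| overlap_fraction | 0.95 | proportion | sensitivity-map strict overlap |
| fwe_alpha_specificity | 0.05 | FWE p | group-difference threshold |
| t_circuit / p_circuit | 5 / 10⁻⁶ | t, FWE p | circuit threshold |
| sphere_radius_mm | 3 | mm | seed/peak spheres |
| voxel_p / cluster_p | 0.01 / 0.05 | p | cluster-defining / cluster-level |
| n_perm_dominance | 10 000 | draws | criterion permutations |
| n_perm_pls / n_boot_pls | 1000 / 1000 | draws | response permutations / region bootstrap |
| top_n_genes / fdr_alpha | 1500 / 0.05 | genes, q | exported tails |

Thresholds default to the printed protocol values; the bootstrap count is
not printed anywhere and defaults to 1000.  All randomness flows from a
single seed through `numpy.random.SeedSequence` spawns, so every stage is
reproducible and every CLI subcommand is deterministic under `--seed`.

## Problem sizes

The test suite runs the full pipeline on the 20 × 24 × 20 desk grid with
30 controls × 150 frames; calibration tests use 100–200 replicates with
199-draw permutation nulls.  `scripts/acceptance.py` uses the same grid
with the protocol-scale cohorts (91 controls × 250 frames, 55 patients,
18 annotation maps, 112 × 10 027 genes, 10 000/1000-draw nulls).  These
sizes are the package's documented study conditions for synthetic
validation; all scale linearly in voxels × frames × subjects.

## Known limitations

Bonferroni FWE is more conservative than the random-field correction used
by common SPM workflows, so absolute voxel counts are not comparable
across implementations.  The two-sample specificity test is parametric; at
voxels with strongly bimodal per-patient values (e.g. lesion
self-correlation footprints) its tail calibration is approximate, and the
permutation variant is preferred when exactness matters.  The pipeline
operates voxelwise within masks and does not resample inputs to a common
resolution; annotation and gene analyses use permutation nulls, not
spatial-autocorrelation-preserving ("spin") nulls.  Meta-analytic
decoding, external enrichment services and raw donor-expression processing
are out of scope: the package exports ranked gene lists and consumes a
processed region × gene matrix.
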