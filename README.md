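# lnmcircuit

Lesion network mapping of post-stroke cognitive impairment (PSCI), as a
reusable, tested Python pipeline.

Stroke lesions cause dysfunction far beyond the infarct, through the
connections of the lesioned tissue (diaschisis).  Lesion network mapping
(LNM) localises that remote effect: each patient's binary lesion mask is
used as a seed in resting-state fMRI from a *normative* healthy cohort, so
that the network functionally connected to the lesion site can be estimated
without the patient's own (already-disrupted) connectivity.  This package
implements the full derivation chain for cognitive impairment after mild
stroke, plus the analyses that characterise the resulting circuit.  It is
aimed at imaging-neuroscience researchers who want the method itself —
the study's clinical data are not public, so a synthetic-data module with a
planted ground truth stands in for them and makes every stage testable.

## The method

Patients are graded on both screening instruments (MMSE and MoCA, each
0–30), banded to ordinal 0–3 severity scales, and grouped by the summed
level: 0–1 → G1 (no/mild), 2–3 → G2 (moderate), 4–6 → G3 (severe).

For each lesion *l* and each healthy control *s*, the seed series is the
mean BOLD series over the lesion's voxels, and the lesion network is the
voxelwise Fisher-transformed Pearson correlation
*z*(v) = atanh r(seed, v).  From there:

1. **Sensitivity map** — per-lesion one-sample *t* over controls,
   thresholded jointly at *t* > 7 and Bonferroni FWE *p* < 10⁻⁶; keep
   voxels present in **more than 95%** of the binarised networks.
2. **Specificity map** — voxelwise two-sample pooled *t* (G3 − G1) on the
   per-patient subject-mean *z* maps, FWE *p* < 0.05.
3. **Lesion of interest (LOI)** — the voxelwise AND of the two maps.
4. **Cognitive impairment circuit** — LOI-seeded connectivity across the
   cohort, one-sample *t*, thresholded at *t* > 5, FWE *p* < 10⁻⁶ (the
   unthresholded *t*-map is kept for the annotation analyses).

The circuit is then characterised four ways:

* **Dominance analysis** against *P* annotation maps (e.g. 18 receptor/
  transporter densities): the circuit *t*-values within the circuit mask
  are regressed on the maps; each predictor's **total dominance** is the
  two-level average of ΔR² over all 2ᴾ−1 submodels (mean within each
  subset size, then across sizes), which makes Σᵢ totalᵢ = R²_full exactly.
  Model significance comes from permuting the criterion (10 000 draws).
* **PLS1 imaging transcriptomics**: with a univariate response the first
  partial-least-squares component has weights **w** ∝ Xᵀy for the
  standardised regions × genes matrix X and regional circuit *t*-values y.
  Gene Z-scores come from region-bootstrap standard errors; model
  significance from 1000 response permutations; ranked positive/negative
  gene tails (up to 1500 each) are exported after Benjamini–Hochberg FDR.
* **Circuit overlap** with a reference (memory) circuit seeded by 3 mm
  spheres at published template coordinates, reported as
  100·|circuit ∩ reference| / |circuit|.
* **Group FC comparison**: patient BOLD with lesion voxels replaced by
  their mirror-hemisphere series, LOI-seeded FC restricted to the circuit,
  two-sample *t* (voxel *p* < 0.01) with **max-extent permutation**
  cluster correction (cluster *p* < 0.05), then Spearman correlation of
  peak-sphere FC with cognition scores (optionally partialling lesion
  volume).

## Worked example

```python
import lnmcircuit as lc

study = lc.simulate_study(seed=7)          # planted synthetic study
by = study.lesions_by_group()
result = lc.run_pipeline(by["G1"], by["G3"], study.hc_bold)

print("LOI voxels:", result.loi.n_voxels)
print("circuit voxels:", result.circuit.n_voxels)
print("LOI Dice vs planted:", lc.dice(result.loi, study.ground_truth.true_loi))
print("circuit Dice vs planted:",
      lc.dice(result.circuit, study.ground_truth.true_circuit))
```

prints

```
LOI voxels: 28
circuit voxels: 194
LOI Dice vs planted: 1.0
circuit Dice vs planted: 1.0
```

i.e. on the default planted study (30 controls, 55 patients, 3 mm
desk-scale grid) the derived LOI and circuit recover the planted ground
truth exactly at the protocol thresholds.  The same stages are available
from the shell via the `lnmcircuit` command (`simulate`, `group`,
`map-lesions`, `sensitivity`, `specificity`, `derive-loi`, `circuit`,
`overlap`, `proportions`, `compare-groups`, `dominance`, `pls`).

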