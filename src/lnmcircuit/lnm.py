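"""Lesion-seeded connectivity mapping on a normative cohort.

The method: seed each patient's lesion in resting-state data from healthy
controls, Fisher-transform the voxelwise Pearson correlations, and derive

* per-lesion networks (one-sample t over the cohort),
* a sensitivity map (voxels shared by >95% of thresholded networks),
* a specificity map (two-sample t between severity groups, FWE-corrected),
* the lesion of interest, LOI (sensitivity AND specificity), and
* the cognitive impairment circuit (thresholded one-sample t of LOI-seeded
  connectivity).

Voxelwise FWE correction is implemented as Bonferroni over in-mask voxels:
conservative, exactly reproducible, and recorded in each map's provenance.
Fisher z is applied before all averaging and t-testing.  Zero-variance
voxels in t-maps carry a +/-inf sentinel when the mean is nonzero and 0
when it is zero; counts are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .grid import BinaryMap, Bold4D, StatMap, VolumeGrid, fisher_z
from .io import PipelineConfig

logger = logging.getLogger("lnmcircuit")


class EmptyLOIError(RuntimeError):
    """Raised when sensitivity and specificity maps do not overlap."""


# ---------------------------------------------------------------------------
# seed-based connectivity
# ---------------------------------------------------------------------------

class NormativeCohort:
    """Pre-demeaned in-mask series of a healthy-control cohort, so that many
    seeds can be mapped without re-touching the raw 4D data."""

    def __init__(self, bolds: Sequence[Bold4D]):
        if len(bolds) < 1:
            raise ValueError("cohort is empty")
        self.grid = bolds[0].grid
        self._demeaned: List[np.ndarray] = []
        self._norms: List[np.ndarray] = []
        for b in bolds:
            self.grid.require_match(b.grid)
            x = b.in_mask_series()
            x = x - x.mean(axis=1, keepdims=True)
            self._demeaned.append(x)
            self._norms.append(np.linalg.norm(x, axis=1))

    def __len__(self) -> int:
        return len(self._demeaned)

    @property
    def n_timepoints(self) -> int:
        return self._demeaned[0].shape[1]

    def seed_zmaps(self, seed: BinaryMap, name: str = "seed") -> np.ndarray:
        """(n_subjects, n_in_mask) Fisher-z maps for a binary seed."""
        self.grid.require_match(seed.grid)
        seed_rows = seed.values[self.grid.brain_mask]
        if not seed_rows.any():
            raise ValueError(f"{name}: no seed voxels inside the brain mask")
        out = np.empty((len(self), self.grid.n_in_mask))
        for s, (x, norms) in enumerate(zip(self._demeaned, self._norms)):
            out[s] = _seed_z(x, norms, seed_rows, name, subject=s)
        return out


def _seed_z(demeaned: np.ndarray, norms: np.ndarray, seed_rows: np.ndarray,
            name: str, subject: Optional[int] = None) -> np.ndarray:
    series = demeaned[seed_rows].mean(axis=0)
    series_norm = np.linalg.norm(series)
    if series_norm == 0.0:
        where = f" (subject {subject})" if subject is not None else ""
        raise ValueError(f"{name}: seed series has zero variance{where}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (demeaned @ series) / (norms * series_norm)
    dead = norms == 0.0
    if dead.any():
        logger.debug("%s: %d zero-variance voxel series set to r=0", name, int(dead.sum()))
        r[dead] = 0.0
    return fisher_z(r)


def lesion_fc_map(lesion: BinaryMap, bold: Bold4D) -> StatMap:
    """Fisher-z map of Pearson correlation between the mean series over the
    lesion's voxels and every in-mask voxel, for one subject.

    Seed voxels are included (large positive z there by construction).
    """
    lesion.grid.require_match(bold.grid)
    if bold.n_timepoints < 8:
        raise ValueError(f"need >= 8 timepoints, got {bold.n_timepoints}")
    x = bold.in_mask_series()
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    seed_rows = lesion.values[bold.grid.brain_mask]
    if not seed_rows.any():
        raise ValueError("lesion has no voxels inside the brain mask")
    z = _seed_z(x, norms, seed_rows, name="lesion")
    values = np.zeros(bold.grid.shape)
    values[bold.grid.brain_mask] = z
    return StatMap(grid=bold.grid, values=values, kind="fisher_z")


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def _stack_values(stack, grid: Optional[VolumeGrid], kind: str):
    """Accept list[StatMap] or an (n, n_in_mask) array; return (array, grid)."""
    if isinstance(stack, np.ndarray):
        if grid is None:
            raise ValueError("grid is required when passing a raw array stack")
        if stack.ndim != 2 or stack.shape[1] != grid.n_in_mask:
            raise ValueError(f"stack must be (n, {grid.n_in_mask}), got {stack.shape}")
        return np.asarray(stack, dtype=np.float64), grid
    maps = list(stack)
    if not maps:
        raise ValueError("empty map stack")
    g = maps[0].grid
    rows = []
    for m in maps:
        g.require_match(m.grid)
        if m.kind != kind:
            raise ValueError(f"expected {kind} maps, got {m.kind}")
        rows.append(m.values_in_mask)
    return np.asarray(rows), g


def _t_from_moments(mean: np.ndarray, sd: np.ndarray, n_eff: float) -> np.ndarray:
    """t = mean / (sd / sqrt-term); zero-variance sentinel handling."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd * n_eff)
    zero_var = sd == 0.0
    if zero_var.any():
        t[zero_var & (mean > 0)] = np.inf
        t[zero_var & (mean < 0)] = -np.inf
        t[zero_var & (mean == 0)] = 0.0
        logger.debug("t-map: %d zero-variance voxels mapped to sentinels", int(zero_var.sum()))
    return t


def one_sample_tmap(stack, grid: Optional[VolumeGrid] = None) -> StatMap:
    """Voxelwise one-sample t against zero over a stack of Fisher-z maps;
    df = n - 1."""
    data, grid = _stack_values(stack, grid, kind="fisher_z")
    n = data.shape[0]
    if n < 3:
        raise ValueError(f"one-sample t needs >= 3 maps, got {n}")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    t = _t_from_moments(mean, sd, 1.0 / np.sqrt(n))
    values = np.zeros(grid.shape)
    values[grid.brain_mask] = t
    return StatMap(grid=grid, values=values, kind="t", df=n - 1)


def two_sample_tmap(stack_a, stack_b, grid: Optional[VolumeGrid] = None) -> StatMap:
    """Voxelwise pooled-variance Student t, sign = mean(A) - mean(B);
    df = nA + nB - 2."""
    a, grid_a = _stack_values(stack_a, grid, kind="fisher_z")
    b, grid_b = _stack_values(stack_b, grid, kind="fisher_z")
    grid_a.require_match(grid_b)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError(f"both groups need >= 2 maps, got {na} and {nb}")
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = np.sqrt(
        ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1))
        / (na + nb - 2)
    )
    t = _t_from_moments(diff, pooled, np.sqrt(1.0 / na + 1.0 / nb))
    values = np.zeros(grid_a.shape)
    values[grid_a.brain_mask] = t
    return StatMap(grid=grid_a, values=values, kind="t", df=na + nb - 2)


def threshold_tmap(
    tmap: StatMap,
    t_min: float,
    p_max: float,
    n_comparisons: Optional[int] = None,
) -> BinaryMap:
    """Joint threshold: keep a voxel iff t > t_min (strict) AND its
    Bonferroni-corrected two-tailed p (p * n_comparisons) < p_max.

    ``n_comparisons`` defaults to the in-mask voxel count.
    """
    if tmap.kind != "t" or tmap.df is None:
        raise ValueError("threshold_tmap needs a t-map with df")
    n = int(n_comparisons) if n_comparisons is not None else tmap.grid.n_in_mask
    t = tmap.values_in_mask
    p = 2.0 * stats.t.sf(np.abs(t), tmap.df)
    kept_rows = (t > t_min) & (p * n < p_max)
    values = np.zeros(tmap.grid.shape, dtype=bool)
    values[tmap.grid.brain_mask] = kept_rows
    prov = {
        "op": "threshold_tmap", "t_min": t_min, "p_max": p_max,
        "n_comparisons": n, "df": tmap.df, "n_survivors": int(kept_rows.sum()),
    }
    logger.info("threshold t>%g, FWE p<%g: %d voxels survive", t_min, p_max, prov["n_survivors"])
    return BinaryMap(grid=tmap.grid, values=values, provenance=prov)


def sensitivity_map(maps: Sequence[BinaryMap], overlap_fraction: float = 0.95) -> BinaryMap:
    """Voxels present in strictly more than ``overlap_fraction`` of the
    thresholded per-lesion networks."""
    if len(maps) < 1:
        raise ValueError("sensitivity_map needs >= 1 map")
    grid = maps[0].grid
    counts = np.zeros(grid.shape, dtype=np.int64)
    for m in maps:
        grid.require_match(m.grid)
        counts += m.values
    kept = counts / len(maps) > overlap_fraction
    prov = {"op": "sensitivity_map", "overlap_fraction": overlap_fraction,
            "n_maps": len(maps), "n_survivors": int(kept.sum())}
    logger.info("sensitivity map (> %.0f%% of %d networks): %d voxels",
                100 * overlap_fraction, len(maps), prov["n_survivors"])
    return BinaryMap(grid=grid, values=kept, provenance=prov)


def specificity_map(
    tmap: StatMap,
    fwe_alpha: float = 0.05,
    n_comparisons: Optional[int] = None,
) -> BinaryMap:
    """Voxels whose Bonferroni-corrected two-tailed p falls below
    ``fwe_alpha`` in the group-difference t-map (both signs retained; the
    sign split is recorded in provenance)."""
    if tmap.kind != "t" or tmap.df is None:
        raise ValueError("specificity_map needs a t-map with df")
    n = int(n_comparisons) if n_comparisons is not None else tmap.grid.n_in_mask
    t = tmap.values_in_mask
    p = 2.0 * stats.t.sf(np.abs(t), tmap.df)
    kept_rows = p * n < fwe_alpha
    values = np.zeros(tmap.grid.shape, dtype=bool)
    values[tmap.grid.brain_mask] = kept_rows
    prov = {
        "op": "specificity_map", "fwe_alpha": fwe_alpha, "n_comparisons": n,
        "df": tmap.df, "n_survivors": int(kept_rows.sum()),
        "n_positive": int((kept_rows & (t > 0)).sum()),
        "n_negative": int((kept_rows & (t < 0)).sum()),
    }
    logger.info("specificity map (FWE p<%g): %d voxels (%d pos, %d neg)",
                fwe_alpha, prov["n_survivors"], prov["n_positive"], prov["n_negative"])
    return BinaryMap(grid=tmap.grid, values=values, provenance=prov)


def specificity_map_permutation(
    stack_a, stack_b, fwe_alpha: float = 0.05, n_perm: int = 1000,
    seed: int = 0, grid: Optional[VolumeGrid] = None,
) -> BinaryMap:
    """Optional max-statistic permutation FWE for the two-sample contrast:
    a voxel survives iff its |t| exceeds the (1 - fwe_alpha) quantile of the
    null max-|t| distribution under group-label permutation."""
    a, ga = _stack_values(stack_a, grid, kind="fisher_z")
    b, gb = _stack_values(stack_b, grid, kind="fisher_z")
    ga.require_match(gb)
    rng = np.random.default_rng(seed)
    pooled = np.vstack([a, b])
    na = a.shape[0]
    obs = two_sample_tmap(a, b, grid=ga).values_in_mask
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        t = two_sample_tmap(pooled[idx[:na]], pooled[idx[na:]], grid=ga).values_in_mask
        null_max[i] = np.abs(t).max()
    crit = np.quantile(null_max, 1.0 - fwe_alpha)
    kept_rows = np.abs(obs) > crit
    values = np.zeros(ga.shape, dtype=bool)
    values[ga.brain_mask] = kept_rows
    prov = {"op": "specificity_map_permutation", "fwe_alpha": fwe_alpha,
            "n_perm": n_perm, "seed": seed, "critical_abs_t": float(crit),
            "n_survivors": int(kept_rows.sum())}
    return BinaryMap(grid=ga, values=values, provenance=prov)


def derive_loi(sensitivity: BinaryMap, specificity: BinaryMap) -> BinaryMap:
    """Lesion of interest: voxelwise AND of the sensitivity and specificity
    maps.  An empty intersection is an explicit error, not an empty map."""
    sensitivity.grid.require_match(specificity.grid)
    values = sensitivity.values & specificity.values
    if not values.any():
        raise EmptyLOIError(
            "sensitivity and specificity maps do not overlap: no LOI at these thresholds"
        )
    prov = {"op": "derive_loi", "n_survivors": int(values.sum()),
            "sensitivity": sensitivity.provenance, "specificity": specificity.provenance}
    logger.info("LOI: %d voxels", prov["n_survivors"])
    return BinaryMap(grid=sensitivity.grid, values=values, provenance=prov)


# ---------------------------------------------------------------------------
# per-lesion networks and the circuit
# ---------------------------------------------------------------------------

@dataclass
class LesionNetwork:
    """One lesion's network on the normative cohort: the per-subject Fisher-z
    stack, its voxelwise mean, and the one-sample t-map."""

    lesion_id: str
    per_subject_fc: np.ndarray  # (n_subjects, n_in_mask)
    subject_mean: StatMap
    tmap: StatMap


def map_lesion(lesion: BinaryMap, cohort: Union[NormativeCohort, Sequence[Bold4D]],
               lesion_id: str = "lesion") -> LesionNetwork:
    """Seed one lesion across every subject of the normative cohort."""
    if not isinstance(cohort, NormativeCohort):
        cohort = NormativeCohort(cohort)
    z = cohort.seed_zmaps(lesion, name=lesion_id)
    grid = cohort.grid
    mean_values = np.zeros(grid.shape)
    mean_values[grid.brain_mask] = z.mean(axis=0)
    subject_mean = StatMap(grid=grid, values=mean_values, kind="fisher_z")
    tmap = one_sample_tmap(z, grid=grid)
    return LesionNetwork(lesion_id=lesion_id, per_subject_fc=z,
                         subject_mean=subject_mean, tmap=tmap)


def circuit_map(
    loi: BinaryMap,
    cohort: Union[NormativeCohort, Sequence[Bold4D]],
    t_circuit: float = 5.0,
    p_circuit: float = 1e-6,
) -> Tuple[StatMap, BinaryMap]:
    """LOI-seeded connectivity across the cohort, one-sample t, and the
    joint threshold (t > t_circuit, Bonferroni FWE p < p_circuit).

    Returns the unthresholded t-map (consumed by the dominance and
    transcriptomics stages) and the binary circuit.
    """
    if loi.n_voxels == 0:
        raise ValueError("LOI is empty")
    if not isinstance(cohort, NormativeCohort):
        cohort = NormativeCohort(cohort)
    z = cohort.seed_zmaps(loi, name="LOI")
    tmap = one_sample_tmap(z, grid=cohort.grid)
    circuit = threshold_tmap(tmap, t_min=t_circuit, p_max=p_circuit)
    circuit = BinaryMap(grid=circuit.grid, values=circuit.values,
                        provenance={**(circuit.provenance or {}), "op": "circuit_map"})
    return tmap, circuit


@dataclass
class PipelineResult:
    networks_g1: List[LesionNetwork]
    networks_g3: List[LesionNetwork]
    sensitivity: BinaryMap
    specificity_t: StatMap
    specificity: BinaryMap
    loi: BinaryMap
    circuit_t: StatMap
    circuit: BinaryMap


def run_pipeline(
    lesions_g1: Sequence[BinaryMap],
    lesions_g3: Sequence[BinaryMap],
    cohort: Union[NormativeCohort, Sequence[Bold4D]],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Full map derivation: per-lesion networks for the mild (G1) and severe
    (G3) groups, sensitivity over all networks, specificity (G3 - G1) on the
    per-patient subject-mean maps, LOI, and the impairment circuit."""
    config = config or PipelineConfig()
    if not isinstance(cohort, NormativeCohort):
        cohort = NormativeCohort(cohort)
    nets_g1 = [map_lesion(l, cohort, lesion_id=f"G1-{i:03d}")
               for i, l in enumerate(lesions_g1)]
    nets_g3 = [map_lesion(l, cohort, lesion_id=f"G3-{i:03d}")
               for i, l in enumerate(lesions_g3)]
    thresholded = [
        threshold_tmap(n.tmap, config.t_sensitivity, config.p_sensitivity)
        for n in nets_g1 + nets_g3
    ]
    sens = sensitivity_map(thresholded, config.overlap_fraction)
    means_g3 = np.asarray([n.subject_mean.values_in_mask for n in nets_g3])
    means_g1 = np.asarray([n.subject_mean.values_in_mask for n in nets_g1])
    spec_t = two_sample_tmap(means_g3, means_g1, grid=cohort.grid)
    spec = specificity_map(spec_t, config.fwe_alpha_specificity)
    loi = derive_loi(sens, spec)
    circuit_t, circuit = circuit_map(loi, cohort, config.t_circuit, config.p_circuit)
    return PipelineResult(
        networks_g1=nets_g1, networks_g3=nets_g3, sensitivity=sens,
        specificity_t=spec_t, specificity=spec, loi=loi,
        circuit_t=circuit_t, circuit=circuit,
    )
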