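"""Synthetic study generator with a planted ground truth.

Every downstream stage gets a recovery-based test from this module: a
normative BOLD cohort carrying a planted circuit covariance structure, a
patient cohort whose lesion placement is tied to severity group, annotation
(receptor-density-like) maps one of which is calibrated to the circuit, and
a region x gene expression matrix with a planted signal-gene set.

Generative model for BOLD (documented in docs/methods.md): every in-mask
voxel carries i.i.d. Gaussian noise; voxels of the planted circuit
additionally carry a shared zero-mean global latent series (amplitude
``latent_strength``) plus one local latent per circuit region (the LOI and
several "distractor" regions, equal local amplitude), drawn independently
per subject.  The local latents are what make the LOI separable: lesions of
severely impaired patients are seeded in the LOI and share its local
latent, so their networks exceed the mild group's exactly at LOI voxels,
while matched local variance everywhere on the circuit keeps the
group-difference map flat elsewhere.  With ``latent_strength = 0`` the
whole volume is pure noise.

Default desk-scale geometry is a 20 x 24 x 20 grid at 3 mm (an MNI-like
RAS+ affine spanning x in [-28.5, 28.5], y in [-48, 21], z in [-30, 27] mm)
so full-pipeline tests run in minutes while preserving voxelwise
multiple-testing behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .grid import BinaryMap, Bold4D, StatMap, VolumeGrid, dice
from .severity import MMSE_BANDS, MOCA_BANDS, PatientRecord, grade_record

#: ratio of local (per-region) to global latent amplitude
LOCAL_RATIO = 0.8

# planted circuit regions: (world-mm centre, radius mm); the first is the LOI
LOI_SPHERE = ((-9.0, -6.0, 3.0), 5.5)
DISTRACTOR_SPHERES = (
    ((-6.0, -40.5, 3.0), 6.0),   # retrosplenial-like, contains the memory-seed coordinate
    ((-12.0, 9.0, 0.0), 6.0),    # medial-frontal-like
    ((-9.0, 15.0, -9.0), 5.0),
    ((-21.0, -24.0, 9.0), 6.0),  # parietal-like
    ((-15.0, -33.0, 12.0), 5.0),
    ((-12.0, -30.0, -21.0), 6.0),  # cerebellar-like
    ((-21.0, -9.0, -12.0), 6.0),   # temporal-like
    ((-9.0, -18.0, -3.0), 5.0),
)


@dataclass
class GroundTruth:
    """Planted geometry and signal parameters of a synthetic study."""

    true_loi: BinaryMap
    true_circuit: BinaryMap
    region_labels: np.ndarray  # 0 background, 1 LOI, 2.. distractor regions
    latent_strength: float
    local_strength: float
    noise_sd: float
    signal_predictor_index: Optional[int] = None
    signal_gene_ids: Optional[List[str]] = None

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.latent_strength < 0:
            raise ValueError("latent_strength must be >= 0")
        if not (self.true_loi.values <= self.true_circuit.values).all():
            raise ValueError("true_loi must be a voxelwise subset of true_circuit")


def default_grid(shape: Tuple[int, int, int] = (20, 24, 20),
                 voxel_mm: float = 3.0) -> VolumeGrid:
    """Desk-scale MNI-like grid: RAS+, 3 mm isotropic, x symmetric about 0,
    ellipsoidal brain mask."""
    nx, ny, nz = shape
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    # x centres symmetric about the midsagittal plane so mirroring is exact
    affine[0, 3] = -(nx - 1) / 2.0 * voxel_mm
    affine[1, 3] = -2.0 * ny * voxel_mm / 3.0  # MNI-like: more space behind y=0
    affine[2, 3] = -(nz - 1) / 2.0 * voxel_mm - 1.5
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    xyz = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) @ affine[:3, :3].T + affine[:3, 3]
    centre = np.array([0.0, affine[1, 3] + (ny - 1) / 2.0 * voxel_mm, -1.5])
    semi = np.array([27.0, 33.0, 27.0])
    mask = (((xyz - centre) / semi) ** 2).sum(axis=1) <= 1.0
    return VolumeGrid(shape=shape, affine=affine, brain_mask=mask.reshape(shape))


def _sphere_voxels(grid: VolumeGrid, centre_mm, radius_mm: float) -> np.ndarray:
    ijk = np.argwhere(np.ones(grid.shape, dtype=bool))
    xyz = np.atleast_2d(grid.voxel_to_world(ijk))
    inside = np.linalg.norm(xyz - np.asarray(centre_mm), axis=1) <= radius_mm
    vol = np.zeros(grid.shape, dtype=bool)
    vol[tuple(ijk[inside].T)] = True
    return vol & grid.brain_mask


def make_ground_truth(grid: Optional[VolumeGrid] = None,
                      latent_strength: float = 1.0,
                      noise_sd: float = 1.0,
                      local_ratio: float = LOCAL_RATIO) -> GroundTruth:
    """Plant the LOI and circuit regions on the grid."""
    grid = grid or default_grid()
    labels = np.zeros(grid.shape, dtype=np.int32)
    for idx, (centre, radius) in enumerate([LOI_SPHERE, *DISTRACTOR_SPHERES], start=1):
        vox = _sphere_voxels(grid, centre, radius) & (labels == 0)
        if not vox.any():
            raise ValueError(f"planted region {idx} at {centre} has no in-mask voxels")
        labels[vox] = idx
    loi = BinaryMap(grid=grid, values=labels == 1, provenance={"op": "planted_loi"})
    circuit = BinaryMap(grid=grid, values=labels > 0, provenance={"op": "planted_circuit"})
    return GroundTruth(
        true_loi=loi, true_circuit=circuit, region_labels=labels,
        latent_strength=latent_strength,
        local_strength=local_ratio * latent_strength, noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# BOLD cohorts
# ---------------------------------------------------------------------------

def _simulate_bold(grid: VolumeGrid, gt: GroundTruth, n_timepoints: int,
                   rng: np.random.Generator, global_amp: float,
                   silent: Optional[np.ndarray] = None) -> Bold4D:
    """One subject's series: noise everywhere, latents on circuit voxels.
    ``silent`` voxels (e.g. the patient's own lesion) get noise only."""
    data = rng.standard_normal((*grid.shape, n_timepoints)) * gt.noise_sd
    if gt.latent_strength > 0 or gt.local_strength > 0:
        g = rng.standard_normal(n_timepoints)
        n_regions = int(gt.region_labels.max())
        for r in range(1, n_regions + 1):
            l_r = rng.standard_normal(n_timepoints)
            vox = gt.region_labels == r
            if silent is not None:
                vox = vox & ~silent
            data[vox] += global_amp * g + gt.local_strength * l_r
    return Bold4D(grid=grid, data=data.astype(np.float32))


def generate_normative_cohort(
    grid: Optional[VolumeGrid] = None,
    ground_truth: Optional[GroundTruth] = None,
    n_subjects: int = 30,
    n_timepoints: int = 150,
    latent_strength: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> Tuple[List[Bold4D], GroundTruth]:
    """Healthy-control cohort carrying the planted circuit covariance.

    Per-subject latents are independent; off-circuit voxels carry noise
    only.  With ``latent_strength = 0`` the volume is pure noise.
    """
    if n_subjects < 3:
        raise ValueError("need >= 3 subjects")
    if n_timepoints < 20:
        raise ValueError("need >= 20 timepoints")
    grid = grid or (ground_truth.true_circuit.grid if ground_truth else default_grid())
    if ground_truth is None:
        ground_truth = make_ground_truth(grid, latent_strength=latent_strength,
                                         noise_sd=noise_sd)
    if ground_truth.true_circuit.n_voxels < 2:
        raise ValueError("planted circuit needs >= 2 voxels")
    if (ground_truth.true_circuit.values & ~grid.brain_mask).any():
        raise ValueError("planted circuit exceeds the brain mask")
    rng = np.random.default_rng(seed)
    cohort = [
        _simulate_bold(grid, ground_truth, n_timepoints, rng,
                       global_amp=ground_truth.latent_strength)
        for _ in range(n_subjects)
    ]
    return cohort, ground_truth


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPatient:
    record: PatientRecord
    lesion: BinaryMap
    bold: Bold4D


_GROUP_COMBINED = {"G1": (0, 1), "G2": (2, 3), "G3": (4, 5, 6)}
_FACES = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def _grow_lesion(rng: np.random.Generator, start: np.ndarray, size: int,
                 allowed: np.ndarray) -> Optional[np.ndarray]:
    """Random face-connected growth from ``start`` within ``allowed``."""
    shape = allowed.shape
    taken = {tuple(start)}
    frontier = [tuple(start)]
    while len(taken) < size:
        candidates = []
        for v in frontier:
            for f in _FACES:
                n = (v[0] + f[0], v[1] + f[1], v[2] + f[2])
                if (0 <= n[0] < shape[0] and 0 <= n[1] < shape[1]
                        and 0 <= n[2] < shape[2] and n not in taken and allowed[n]):
                    candidates.append(n)
        if not candidates:
            return None
        pick = candidates[rng.integers(len(candidates))]
        taken.add(pick)
        frontier.append(pick)
    vol = np.zeros(shape, dtype=bool)
    vol[tuple(np.array(sorted(taken)).T)] = True
    return vol


def _draw_scores(rng: np.random.Generator, group: str) -> Tuple[int, int, int]:
    combined = int(rng.choice(_GROUP_COMBINED[group]))
    pairs = [(a, b) for a in range(4) for b in range(4) if a + b == combined]
    a, b = pairs[rng.integers(len(pairs))]
    moca_lo, moca_hi, _ = MOCA_BANDS[a]
    mmse_lo, mmse_hi, _ = MMSE_BANDS[b]
    moca = int(rng.integers(moca_lo, moca_hi + 1))
    mmse = int(rng.integers(mmse_lo, mmse_hi + 1))
    return moca, mmse, combined


def generate_patient_cohort(
    grid: Optional[VolumeGrid] = None,
    ground_truth: Optional[GroundTruth] = None,
    n_per_group: Tuple[int, int, int] = (25, 15, 15),
    lesion_size_range: Tuple[int, int] = (3, 8),
    placement_rules: Optional[dict] = None,
    n_timepoints: int = 150,
    score_coupling: float = 0.5,
    seed: int = 0,
    max_rejections: int = 1000,
) -> Tuple[List[SyntheticPatient], GroundTruth]:
    """Patient cohort: lesions, severity-banded scores, and own BOLD series.

    Placement rules per group (defaults G1/G2 ``avoid``, G3 ``intersect``):
    ``intersect`` starts the lesion inside the planted LOI; ``avoid`` starts
    it on a circuit voxel outside the LOI and never grows into the LOI.
    Scores are drawn from group-conditional integer bands so the group label
    is recoverable from them.  Each patient's BOLD follows the normative
    generative model with the global-latent amplitude scaled by
    ``1 + score_coupling * (3 - combined) / 3`` (better cognition, stronger
    circuit coupling) and the lesion's own voxels silenced to noise.
    """
    if min(n_per_group) < 0 or sum(n_per_group) < 1:
        raise ValueError("groups must be nonempty in total")
    if lesion_size_range[0] < 1:
        raise ValueError("lesion sizes must be >= 1 voxel")
    grid = grid or (ground_truth.true_circuit.grid if ground_truth else default_grid())
    if ground_truth is None:
        ground_truth = make_ground_truth(grid)
    rules = {"G1": "avoid", "G2": "avoid", "G3": "intersect"}
    rules.update(placement_rules or {})
    rng = np.random.default_rng(seed)
    loi = ground_truth.true_loi.values
    circuit = ground_truth.true_circuit.values
    starts = {
        "avoid": np.argwhere(circuit & ~loi),
        "intersect": np.argwhere(loi),
    }
    allowed = {
        "avoid": grid.brain_mask & ~loi,
        "intersect": grid.brain_mask,
    }
    patients: List[SyntheticPatient] = []
    counter = 0
    for group, n in zip(("G1", "G2", "G3"), n_per_group):
        rule = rules[group]
        if rule not in starts:
            raise ValueError(f"unknown placement rule {rule!r}")
        for _ in range(n):
            size = int(rng.integers(lesion_size_range[0], lesion_size_range[1] + 1))
            lesion_vol = None
            for _attempt in range(max_rejections):
                start = starts[rule][rng.integers(len(starts[rule]))]
                lesion_vol = _grow_lesion(rng, start, size, allowed[rule])
                if lesion_vol is not None:
                    break
            if lesion_vol is None:
                raise RuntimeError(
                    f"could not place a {size}-voxel {group} lesion after "
                    f"{max_rejections} rejections"
                )
            lesion = BinaryMap(grid=grid, values=lesion_vol,
                               provenance={"op": "synthetic_lesion", "group": group})
            moca, mmse, combined = _draw_scores(rng, group)
            amp = ground_truth.latent_strength * (1.0 + score_coupling * (3 - combined) / 3.0)
            bold = _simulate_bold(grid, ground_truth, n_timepoints, rng,
                                  global_amp=amp, silent=lesion_vol)
            record = grade_record(PatientRecord(
                subject_id=f"P{counter:03d}", mmse=mmse, moca=moca,
                lesion_volume=int(lesion_vol.sum()),
            ))
            assert record.group == group
            patients.append(SyntheticPatient(record=record, lesion=lesion, bold=bold))
            counter += 1
    return patients, ground_truth


# ---------------------------------------------------------------------------
# annotation maps
# ---------------------------------------------------------------------------

def generate_annotation_maps(
    grid: VolumeGrid,
    circuit_tmap: StatMap,
    n_maps: int = 18,
    target_r: float = 0.7,
    signal_index: int = 0,
    mask: Optional[BinaryMap] = None,
    smooth_sigma_vox: float = 1.0,
    seed: int = 0,
) -> List[StatMap]:
    """Spatially smoothed annotation maps; the designated map is an exact
    mixture of the circuit t-map and orthogonalised noise so that its
    in-mask Pearson r with the t-map equals ``target_r``.

    The remaining maps are independent smoothed noise fields (mutually
    correlated < 0.2 in expectation).
    """
    if not 0 <= signal_index < n_maps:
        raise ValueError(f"signal_index {signal_index} outside [0, {n_maps})")
    if not abs(target_r) < 1:
        raise ValueError("|target_r| must be < 1")
    grid.require_match(circuit_tmap.grid)
    mask_values = (mask.values if mask is not None else grid.brain_mask)
    rows = np.flatnonzero(mask_values[grid.brain_mask])
    if rows.size < 10:
        raise ValueError(f"mask has {rows.size} voxels; need >= 10 to calibrate target_r")
    t = circuit_tmap.values_in_mask[rows]
    if np.ptp(t) == 0:
        raise ValueError("circuit t-map is constant inside the mask")
    t_std = (t - t.mean()) / t.std()
    rng = np.random.default_rng(seed)
    maps: List[StatMap] = []
    for m in range(n_maps):
        noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), smooth_sigma_vox)
        values = np.zeros(grid.shape)
        e = noise[grid.brain_mask][rows]
        e = (e - e.mean()) / e.std()
        if m == signal_index:
            e_orth = e - (e @ t_std / (t_std @ t_std)) * t_std
            e_orth /= e_orth.std()
            mixed = target_r * t_std + np.sqrt(1.0 - target_r**2) * e_orth
            values[grid.brain_mask] = noise[grid.brain_mask]  # out-of-mask filler
            flat = values[grid.brain_mask]
            flat[rows] = mixed
            values[grid.brain_mask] = flat
        else:
            values[grid.brain_mask] = noise[grid.brain_mask]
            flat = values[grid.brain_mask]
            flat[rows] = e
            values[grid.brain_mask] = flat
        maps.append(StatMap(grid=grid, values=values, kind="generic"))
    return maps


# ---------------------------------------------------------------------------
# atlas and gene expression
# ---------------------------------------------------------------------------

def make_atlas(grid: VolumeGrid, n_regions: int = 112, side: str = "left",
               seed: int = 0) -> np.ndarray:
    """Label volume (0 outside, 1..n_regions) parcellating one hemisphere's
    in-mask voxels into compact regions (k-means on world coordinates)."""
    ijk = np.argwhere(grid.brain_mask)
    xyz = np.atleast_2d(grid.voxel_to_world(ijk))
    if side == "left":
        keep = xyz[:, 0] < 0
    elif side == "right":
        keep = xyz[:, 0] > 0
    elif side == "both":
        keep = np.ones(len(xyz), dtype=bool)
    else:
        raise ValueError(f"unknown side {side!r}")
    if keep.sum() < n_regions:
        raise ValueError(f"{int(keep.sum())} voxels cannot form {n_regions} regions")
    km = KMeans(n_clusters=n_regions, n_init=1, random_state=seed)
    assign = km.fit_predict(xyz[keep])
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[tuple(ijk[keep].T)] = assign + 1
    return labels


def generate_gene_matrix(
    region_tvalues: np.ndarray,
    n_genes: int = 10_027,
    n_signal_genes: int = 50,
    effect_size: float = 2.0,
    seed: int = 0,
    region_ids: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """Regions x genes expression matrix with a planted signal-gene set.

    Signal genes follow ``effect_size * z(t) + noise``; every gene is then
    z-scored across regions (the standardised-matrix convention of
    imaging-transcriptomics pipelines).  With ``effect_size = 0`` signal
    genes are indistinguishable from noise.
    """
    t = np.asarray(region_tvalues, dtype=np.float64)
    if t.ndim != 1 or t.size < 10:
        raise ValueError("region_tvalues must be a vector of >= 10 regions")
    if np.ptp(t) == 0:
        raise ValueError("region t-values are constant; planted signal undefined")
    if not n_signal_genes < n_genes:
        raise ValueError("n_signal_genes must be < n_genes")
    rng = np.random.default_rng(seed)
    t_std = (t - t.mean()) / t.std()
    values = rng.standard_normal((t.size, n_genes))
    signal_cols = np.sort(rng.choice(n_genes, size=n_signal_genes, replace=False))
    values[:, signal_cols] += effect_size * t_std[:, None]
    values = (values - values.mean(axis=0)) / values.std(axis=0)
    genes = [f"SYN{i:05d}" for i in range(n_genes)]
    if region_ids is None:
        region_ids = [f"R{i + 1:03d}" for i in range(t.size)]
    frame = pd.DataFrame(values, index=list(region_ids), columns=genes)
    frame.index.name = "region"
    return frame, [genes[c] for c in signal_cols]


# ---------------------------------------------------------------------------
# bundled study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Everything the pipeline consumes, with its planted ground truth."""

    grid: VolumeGrid
    ground_truth: GroundTruth
    hc_bold: List[Bold4D]
    patients: List[SyntheticPatient]
    annotation_maps: List[StatMap]
    atlas_labels: np.ndarray
    region_ids: List[str]
    gene_matrix: pd.DataFrame
    true_circuit_tmap: StatMap  # LOI-seeded t-map used to calibrate annotations/genes

    def lesions_by_group(self) -> dict:
        out = {"G1": [], "G2": [], "G3": []}
        for p in self.patients:
            out[p.record.group].append(p.lesion)
        return out


def simulate_study(
    seed: int = 7,
    n_hc: int = 30,
    n_timepoints: int = 150,
    n_per_group: Tuple[int, int, int] = (25, 15, 15),
    latent_strength: float = 1.0,
    noise_sd: float = 1.0,
    n_annotation_maps: int = 18,
    target_r: float = 0.7,
    signal_predictor_index: int = 0,
    n_regions: int = 112,
    n_genes: int = 10_027,
    n_signal_genes: int = 50,
    gene_effect_size: float = 2.0,
    grid: Optional[VolumeGrid] = None,
) -> SimulatedStudy:
    """Generate a complete synthetic study under one master seed."""
    from . import lnm, transcriptomics  # local import to avoid a cycle at import time

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    grid = grid or default_grid()
    gt = make_ground_truth(grid, latent_strength=latent_strength, noise_sd=noise_sd)
    hc, gt = generate_normative_cohort(grid, gt, n_subjects=n_hc,
                                       n_timepoints=n_timepoints, seed=seeds[0])
    patients, gt = generate_patient_cohort(grid, gt, n_per_group=n_per_group,
                                           n_timepoints=n_timepoints, seed=seeds[1])
    tmap, _ = lnm.circuit_map(gt.true_loi, hc)
    annotations = generate_annotation_maps(
        grid, tmap, n_maps=n_annotation_maps, target_r=target_r,
        signal_index=signal_predictor_index, mask=gt.true_circuit, seed=seeds[2],
    )
    gt.signal_predictor_index = signal_predictor_index
    atlas = make_atlas(grid, n_regions=n_regions, seed=seeds[3])
    region_ids = [f"R{i + 1:03d}" for i in range(n_regions)]
    region_t = transcriptomics.region_tvalues(tmap, atlas, list(range(1, n_regions + 1)))
    genes, signal_ids = generate_gene_matrix(
        region_t, n_genes=n_genes, n_signal_genes=n_signal_genes,
        effect_size=gene_effect_size, seed=seeds[4], region_ids=region_ids,
    )
    gt.signal_gene_ids = signal_ids
    return SimulatedStudy(
        grid=grid, ground_truth=gt, hc_bold=hc, patients=patients,
        annotation_maps=annotations, atlas_labels=atlas, region_ids=region_ids,
        gene_matrix=genes, true_circuit_tmap=tmap,
    )
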