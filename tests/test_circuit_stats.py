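"""Spheres, overlap, contralateral masking, cluster inference, behaviour."""

import numpy as np
import pytest
from scipy import stats

import lnmcircuit as lc
from lnmcircuit import circuit_stats as cs


# ---------------------------------------------------------------------------
# sphere ROIs
# ---------------------------------------------------------------------------

def test_sphere_on_voxel_center_is_seven_voxel_cross(toy_grid):
    grid = toy_grid(shape=(7, 7, 7))
    center = grid.voxel_to_world((3, 3, 3))
    seed = cs.sphere_roi(center, 3.0, grid)
    got = {tuple(v) for v in np.argwhere(seed.mask.values)}
    expected = {(3, 3, 3), (2, 3, 3), (4, 3, 3), (3, 2, 3), (3, 4, 3),
                (3, 3, 2), (3, 3, 4)}
    assert got == expected


def test_sphere_radius_zero_is_single_voxel(toy_grid):
    grid = toy_grid(shape=(5, 5, 5))
    seed = cs.sphere_roi(grid.voxel_to_world((2, 2, 2)), 0.0, grid)
    assert seed.mask.n_voxels == 1


def test_memory_seed_coordinate_lands_in_synthetic_grid():
    grid = lc.default_grid()
    for coord in ((-6.0, -41.0, 3.0), (8.0, -39.0, 3.0)):
        seed = cs.sphere_roi(coord, 3.0, grid)
        assert seed.mask.n_voxels >= 1


def test_sphere_outside_mask_errors(toy_grid):
    mask = np.zeros((7, 7, 7), dtype=bool)
    mask[3, 3, 3] = True
    grid = toy_grid(shape=(7, 7, 7), mask=mask)
    with pytest.raises(ValueError, match="no in-mask voxel"):
        cs.sphere_roi(grid.voxel_to_world((0, 0, 0)), 1.0, grid)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def _binary(grid, idx_list):
    values = np.zeros(grid.shape, dtype=bool)
    for idx in idx_list:
        values[idx] = True
    return lc.BinaryMap(grid=grid, values=values)


def test_overlap_identity_disjoint_and_subset(toy_grid):
    grid = toy_grid()
    a = _binary(grid, [(0, 0, 0), (1, 1, 1)])
    b = _binary(grid, [(2, 2, 2)])
    assert cs.overlap_fraction(a, a) == 100.0
    assert cs.overlap_fraction(a, b) == 0.0
    big = _binary(grid, [(0, 0, 0), (1, 1, 1), (3, 3, 3)])
    assert cs.overlap_fraction(a, big) == 100.0  # A subset of B -> 100


def test_overlap_headline_style_counts(toy_grid):
    """200-voxel circuit with a 144-voxel intersection -> 72.0%."""
    grid = toy_grid(shape=(10, 10, 10))
    circuit_idx = [tuple(v) for v in np.argwhere(np.ones((10, 10, 10)))[:200]]
    ref_idx = circuit_idx[:144] + [tuple(v) for v in
                                   np.argwhere(np.ones((10, 10, 10)))[500:600]]
    circuit = _binary(grid, circuit_idx)
    reference = _binary(grid, ref_idx)
    assert cs.overlap_fraction(circuit, reference) == pytest.approx(72.0)
    dice_pct = cs.overlap_fraction(circuit, reference, symmetric=True)
    assert dice_pct == pytest.approx(100 * 2 * 144 / (200 + 244))


def test_overlap_requires_nonempty(toy_grid):
    grid = toy_grid()
    a = _binary(grid, [(0, 0, 0)])
    with pytest.raises(ValueError, match="nonempty"):
        cs.overlap_fraction(a, lc.BinaryMap(grid=grid, values=np.zeros(grid.shape)))


# ---------------------------------------------------------------------------
# lesion-in-circuit proportions
# ---------------------------------------------------------------------------

def test_proportions_counting(toy_grid):
    grid = toy_grid()
    region = _binary(grid, [(2, 2, 2), (2, 2, 3)])
    touching = _binary(grid, [(2, 2, 2), (0, 0, 0)])
    missing = _binary(grid, [(5, 5, 5)])
    table = cs.lesion_circuit_proportions(
        {"G1": [touching, missing, missing, missing],
         "G3": [touching, touching, touching]},
        {"regionA": region},
    )
    assert table.loc["regionA", "G1"] == pytest.approx(0.25)
    assert table.loc["regionA", "G3"] == pytest.approx(1.0)
    frac = cs.lesion_circuit_proportions({"G3": [touching]}, {"regionA": region},
                                         statistic="voxel_fraction")
    assert frac.loc["regionA", "G3"] == pytest.approx(0.5)
    with pytest.raises(ValueError, match="empty"):
        cs.lesion_circuit_proportions({"G1": []}, {"regionA": region})


# ---------------------------------------------------------------------------
# contralateral masking
# ---------------------------------------------------------------------------

def test_contralateral_masking_mirror_pair(toy_grid):
    grid = toy_grid(shape=(7, 5, 5))  # x centres at -9..9 mm
    rng = np.random.default_rng(0)
    data = rng.standard_normal((*grid.shape, 20))
    bold = lc.Bold4D(grid=grid, data=data)
    # lesion at world x = +9 mm -> series must become that of x = -9 mm
    idx = tuple(np.rint(grid.world_to_voxel((9.0, 0.0, 0.0))).astype(int))
    mirror = tuple(np.rint(grid.world_to_voxel((-9.0, 0.0, 0.0))).astype(int))
    lesion_values = np.zeros(grid.shape, dtype=bool)
    lesion_values[idx] = True
    masked = cs.mask_lesion_contralateral(bold, lc.BinaryMap(grid=grid, values=lesion_values))
    np.testing.assert_array_equal(masked.data[idx], data[mirror])
    # non-lesion voxels bit-identical
    untouched = ~lesion_values
    np.testing.assert_array_equal(masked.data[untouched], data[untouched])


def test_contralateral_masking_identity_on_symmetric_input(toy_grid):
    grid = toy_grid(shape=(8, 5, 5))
    rng = np.random.default_rng(1)
    half = rng.standard_normal((4, 5, 5, 20))
    data = np.concatenate([half, half[::-1]], axis=0)  # mirror-symmetric in x
    bold = lc.Bold4D(grid=grid, data=data)
    lesion_values = np.zeros(grid.shape, dtype=bool)
    lesion_values[6, 2, 2] = True
    masked = cs.mask_lesion_contralateral(bold, lc.BinaryMap(grid=grid, values=lesion_values))
    np.testing.assert_array_equal(masked.data, data)


def test_contralateral_fallback_to_nearest_in_mask(toy_grid):
    mask = np.ones((8, 5, 5), dtype=bool)
    mask[:3] = False  # mirror side partially outside the mask
    grid = toy_grid(shape=(8, 5, 5), mask=mask)
    rng = np.random.default_rng(2)
    bold = lc.Bold4D(grid=grid, data=rng.standard_normal((*grid.shape, 15)))
    lesion_values = np.zeros(grid.shape, dtype=bool)
    lesion_values[7, 2, 2] = True  # mirror voxel (0,2,2) is outside the mask
    masked = cs.mask_lesion_contralateral(bold, lc.BinaryMap(grid=grid, values=lesion_values))
    # replaced by some in-mask voxel's series, not left in place
    assert not np.array_equal(masked.data[7, 2, 2], bold.data[7, 2, 2])
    donors = bold.data[mask].reshape(-1, 15)
    assert any(np.array_equal(masked.data[7, 2, 2], d) for d in donors)


# ---------------------------------------------------------------------------
# patient-level circuit FC
# ---------------------------------------------------------------------------

def test_patient_circuit_fc_restriction_identity(toy_grid):
    grid = toy_grid(shape=(6, 6, 6))
    rng = np.random.default_rng(3)
    bold = lc.Bold4D(grid=grid, data=rng.standard_normal((*grid.shape, 30)))
    loi = _binary(grid, [(1, 1, 1), (1, 1, 2)])
    whole = lc.BinaryMap(grid=grid, values=grid.brain_mask.copy())
    restricted = cs.patient_circuit_fc(bold, loi, whole)
    full = lc.lesion_fc_map(loi, bold)
    np.testing.assert_allclose(restricted.values, full.values, atol=1e-12)
    single = _binary(grid, [(4, 4, 4)])
    scalar_map = cs.patient_circuit_fc(bold, loi, single)
    assert np.count_nonzero(scalar_map.values) == 1
    assert scalar_map.values[4, 4, 4] == full.values[4, 4, 4]


# ---------------------------------------------------------------------------
# cluster inference
# ---------------------------------------------------------------------------

def _noise_maps(grid, n, rng, sd=1.0):
    out = []
    for _ in range(n):
        v = np.zeros(grid.shape)
        v[grid.brain_mask] = rng.standard_normal(grid.n_in_mask) * sd
        out.append(lc.StatMap(grid=grid, values=v, kind="fisher_z"))
    return out


def test_cluster_compare_detects_planted_effect(toy_grid):
    grid = toy_grid(shape=(14, 14, 12))
    domain_values = np.zeros(grid.shape, dtype=bool)
    domain_values[1:13, 1:13, 1:11] = True   # ~1700-voxel domain
    domain = lc.BinaryMap(grid=grid, values=domain_values)
    blob = np.zeros(grid.shape, dtype=bool)
    blob[5:8, 5:8, 4:8] = True               # planted 3x3x4 region, within domain
    rng = np.random.default_rng(4)
    maps_a = _noise_maps(grid, 15, rng)
    maps_b = []
    for m in _noise_maps(grid, 15, rng):
        v = np.array(m.values)
        v[blob] += 2.0
        maps_b.append(lc.StatMap(grid=grid, values=v, kind="fisher_z"))
    res = cs.cluster_compare(maps_a, maps_b, domain, n_perm=199, seed=0)
    assert len(res.clusters) == 1
    peak_idx = tuple(np.rint(grid.world_to_voxel(res.clusters[0].peak_mm)).astype(int))
    assert blob[peak_idx]
    assert res.clusters[0].corrected_p < 0.05


def test_cluster_compare_identical_groups_silent(toy_grid):
    grid = toy_grid(shape=(10, 10, 10))
    domain = lc.BinaryMap(grid=grid, values=grid.brain_mask.copy())
    maps = _noise_maps(grid, 10, np.random.default_rng(5))
    res = cs.cluster_compare(maps, [lc.StatMap(grid=grid, values=m.values, kind="fisher_z")
                                    for m in maps], domain, n_perm=120, seed=1)
    assert res.clusters == []


def test_cluster_compare_refuses_unstable_null(toy_grid):
    grid = toy_grid()
    domain = lc.BinaryMap(grid=grid, values=grid.brain_mask.copy())
    maps = _noise_maps(grid, 4, np.random.default_rng(6))
    with pytest.raises(ValueError, match="unstable null"):
        cs.cluster_compare(maps[:2], maps[2:], domain, n_perm=50)


# ---------------------------------------------------------------------------
# brain-behaviour association
# ---------------------------------------------------------------------------

def test_spearman_exact_and_hand_ranked():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert cs.fc_behaviour_assoc(x, x)[0] == pytest.approx(1.0)
    assert cs.fc_behaviour_assoc(x, -x)[0] == pytest.approx(-1.0)
    # hand computation: d² = (1, 1, 1, 1, 0), rho = 1 - 6*4/(5*24) = 0.8
    rho, _ = cs.fc_behaviour_assoc(x, np.array([2.0, 1.0, 4.0, 3.0, 5.0]))
    assert rho == pytest.approx(0.8)


def test_partial_spearman_removes_covariate_driven_association():
    rng = np.random.default_rng(7)
    confound = rng.standard_normal(60)
    fc = confound + 0.05 * rng.standard_normal(60)
    scores = confound + 0.05 * rng.standard_normal(60)
    rho_raw, _ = cs.fc_behaviour_assoc(fc, scores)
    rho_partial, _ = cs.fc_behaviour_assoc(fc, scores, covariate=confound)
    assert rho_raw > 0.9
    assert abs(rho_partial) < 0.5


def test_behaviour_assoc_preconditions():
    x = np.arange(5.0)
    with pytest.raises(ValueError, match="constant"):
        cs.fc_behaviour_assoc(x, np.ones(5))
    with pytest.raises(ValueError, match=">= 5"):
        cs.fc_behaviour_assoc(x[:4], x[:4])


def test_planted_fc_score_coupling_yields_positive_rho(study):
    """In the synthetic cohort, LOI-circuit FC rises with cognition scores."""
    gt = study.ground_truth
    fc_all, scores = [], []
    for p in study.patients:
        masked = cs.mask_lesion_contralateral(p.bold, p.lesion)
        fc = cs.patient_circuit_fc(masked, gt.true_loi, gt.true_circuit)
        fc_all.append(float(fc.values[gt.true_circuit.values].mean()))
        scores.append(p.record.mmse + p.record.moca)
    rho, p_val = cs.fc_behaviour_assoc(np.asarray(fc_all), np.asarray(scores, float))
    assert rho > 0 and p_val < 0.05
    # lesion-volume control leaves the association positive
    vols = np.asarray([p.record.lesion_volume for p in study.patients], float)
    rho_partial, p_partial = cs.fc_behaviour_assoc(
        np.asarray(fc_all), np.asarray(scores, float), covariate=vols)
    assert rho_partial > 0 and p_partial < 0.05
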