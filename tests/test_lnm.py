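"""Lesion network mapping: correlation maps, t-maps, thresholds, recovery."""

import numpy as np
import pytest
from scipy import integrate, stats

import lnmcircuit as lc
from lnmcircuit import lnm
from lnmcircuit.grid import R_CLIP

Z_CAP = np.arctanh(1 - R_CLIP)


def _toy_bold(grid, seed=0, T=50):
    rng = np.random.default_rng(seed)
    return lc.Bold4D(grid=grid, data=rng.standard_normal((*grid.shape, T)))


def _one_voxel_lesion(grid, idx):
    values = np.zeros(grid.shape, dtype=bool)
    values[idx] = True
    return lc.BinaryMap(grid=grid, values=values)


# ---------------------------------------------------------------------------
# lesion_fc_map
# ---------------------------------------------------------------------------

def test_fc_map_self_and_anti_correlation(toy_grid):
    grid = toy_grid(shape=(4, 1, 1))
    rng = np.random.default_rng(0)
    seed_series = rng.standard_normal(40)
    data = np.empty((4, 1, 1, 40))
    data[0, 0, 0] = seed_series
    data[1, 0, 0] = seed_series          # identical -> r = 1
    data[2, 0, 0] = -seed_series         # anti -> r = -1
    data[3, 0, 0] = rng.standard_normal(40)
    bold = lc.Bold4D(grid=grid, data=data)
    z = lc.lesion_fc_map(_one_voxel_lesion(grid, (0, 0, 0)), bold).values
    assert z[0, 0, 0] == pytest.approx(Z_CAP)
    assert z[1, 0, 0] == pytest.approx(Z_CAP)
    assert z[2, 0, 0] == pytest.approx(-Z_CAP)
    assert abs(z[3, 0, 0]) < Z_CAP / 2


def test_fc_map_matches_bruteforce_oracle(toy_grid):
    grid = toy_grid(shape=(10, 1, 1))
    bold = _toy_bold(grid, seed=1, T=50)
    lesion_values = np.zeros(grid.shape, dtype=bool)
    lesion_values[2:4, 0, 0] = True
    lesion = lc.BinaryMap(grid=grid, values=lesion_values)
    z = lc.lesion_fc_map(lesion, bold).values
    seed_series = bold.data[lesion_values].mean(axis=0)
    for i in range(10):
        r = np.corrcoef(bold.data[i, 0, 0], seed_series)[0, 1]
        expected = np.arctanh(np.clip(r, -1 + R_CLIP, 1 - R_CLIP))
        assert abs(z[i, 0, 0] - expected) < 1e-10


def test_fc_map_preconditions(toy_grid):
    grid = toy_grid(shape=(4, 1, 1))
    flat = lc.Bold4D(grid=grid, data=np.ones((4, 1, 1, 30)))
    with pytest.raises(ValueError, match="zero variance"):
        lc.lesion_fc_map(_one_voxel_lesion(grid, (0, 0, 0)), flat)
    short = lc.Bold4D(grid=grid, data=np.random.default_rng(0).standard_normal((4, 1, 1, 5)))
    with pytest.raises(ValueError, match="timepoints"):
        lc.lesion_fc_map(_one_voxel_lesion(grid, (0, 0, 0)), short)


# ---------------------------------------------------------------------------
# t-maps
# ---------------------------------------------------------------------------

def test_one_sample_t_hand_value(toy_grid):
    grid = toy_grid(shape=(2, 1, 1))
    stack = np.array([[v, 0.0] for v in (1.0, 2.0, 3.0, 4.0, 5.0)])
    tmap = lnm.one_sample_tmap(stack, grid=grid)
    assert tmap.df == 4
    assert tmap.values[0, 0, 0] == pytest.approx(4.242640687119285, abs=1e-12)
    assert tmap.values[1, 0, 0] == 0.0


def test_one_sample_t_zero_variance_sentinels(toy_grid):
    grid = toy_grid(shape=(3, 1, 1))
    stack = np.array([[1.0, -2.0, 0.0]] * 5)
    t = lnm.one_sample_tmap(stack, grid=grid).values
    assert t[0, 0, 0] == np.inf and t[1, 0, 0] == -np.inf and t[2, 0, 0] == 0.0
    with pytest.raises(ValueError, match=">= 3"):
        lnm.one_sample_tmap(stack[:2], grid=grid)


def test_two_sample_t_hand_value(toy_grid):
    grid = toy_grid(shape=(1, 1, 1))
    a = np.array([[1.0], [2.0], [3.0]])
    b = np.array([[4.0], [5.0], [6.0]])
    tmap = lnm.two_sample_tmap(a, b, grid=grid)
    assert tmap.df == 4
    assert tmap.values[0, 0, 0] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
    same = lnm.two_sample_tmap(a, a, grid=grid)
    assert same.values[0, 0, 0] == 0.0


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def test_threshold_boundary_is_strict(toy_grid):
    grid = toy_grid(shape=(3, 1, 1))
    values = np.array([7.0, 7.0001, -9.0]).reshape(3, 1, 1)
    tmap = lc.StatMap(grid=grid, values=values, kind="t", df=90)
    kept = lnm.threshold_tmap(tmap, t_min=7.0, p_max=0.5, n_comparisons=1)
    assert not kept.values[0, 0, 0]      # t == t_min excluded
    assert kept.values[1, 0, 0]
    assert not kept.values[2, 0, 0]      # negative t never kept


def test_threshold_degenerate_keeps_positive_t(toy_grid):
    grid = toy_grid(shape=(4, 1, 1))
    values = np.array([0.5, -0.5, 0.0, 3.0]).reshape(4, 1, 1)
    tmap = lc.StatMap(grid=grid, values=values, kind="t", df=10)
    kept = lnm.threshold_tmap(tmap, t_min=0.0, p_max=1.0, n_comparisons=1)
    assert kept.values.ravel().tolist() == [True, False, False, True]


def test_threshold_agrees_with_independent_t_cdf(toy_grid):
    """Bonferroni decision at df=90 over 5000 comparisons vs a numerically
    integrated t density."""
    grid = toy_grid(shape=(2, 1, 1))
    values = np.array([7.5, 8.5]).reshape(2, 1, 1)
    tmap = lc.StatMap(grid=grid, values=values, kind="t", df=90)
    kept = lnm.threshold_tmap(tmap, t_min=7.0, p_max=1e-6, n_comparisons=5000)

    def t_pdf(x, df):
        from math import gamma, sqrt, pi
        return (gamma((df + 1) / 2) / (gamma(df / 2) * sqrt(df * pi))
                * (1 + x**2 / df) ** (-(df + 1) / 2))

    for i, t in enumerate((7.5, 8.5)):
        sf, _ = integrate.quad(t_pdf, t, np.inf, args=(90,))
        expected = 2 * sf * 5000 < 1e-6
        assert bool(kept.values[i, 0, 0]) == expected


def test_threshold_monotone_in_both_criteria(toy_grid):
    grid = toy_grid()
    rng = np.random.default_rng(3)
    tmap = lc.StatMap(grid=grid, values=3 * rng.standard_normal(grid.shape),
                      kind="t", df=30)
    base = lnm.threshold_tmap(tmap, 1.0, 0.5).values
    assert not (lnm.threshold_tmap(tmap, 2.0, 0.5).values & ~base).any()
    assert not (lnm.threshold_tmap(tmap, 1.0, 0.05).values & ~base).any()


# ---------------------------------------------------------------------------
# sensitivity / specificity / LOI
# ---------------------------------------------------------------------------

def test_sensitivity_strict_overlap_rule(toy_grid):
    grid = toy_grid(shape=(2, 1, 1))
    present = lc.BinaryMap(grid=grid, values=np.ones(grid.shape))
    absent_values = np.ones(grid.shape)
    absent_values[0, 0, 0] = 0
    absent = lc.BinaryMap(grid=grid, values=absent_values)
    # voxel 0 in 38/40 maps: 0.95, excluded; in 39/40: 0.975, included
    maps38 = [present] * 38 + [absent] * 2
    maps39 = [present] * 39 + [absent]
    assert not lnm.sensitivity_map(maps38, 0.95).values[0, 0, 0]
    assert lnm.sensitivity_map(maps39, 0.95).values[0, 0, 0]
    unanimous = lnm.sensitivity_map([present] * 40, 0.95)
    np.testing.assert_array_equal(unanimous.values, present.values)


def test_sensitivity_matches_counting_oracle_and_monotone(toy_grid):
    grid = toy_grid()
    rng = np.random.default_rng(8)
    maps = [lc.BinaryMap(grid=grid, values=rng.random(grid.shape) > 0.3)
            for _ in range(20)]
    counts = sum(m.values.astype(int) for m in maps)
    for frac in (0.5, 0.75, 0.95):
        got = lnm.sensitivity_map(maps, frac).values
        np.testing.assert_array_equal(got, counts / 20 > frac)
    loose = lnm.sensitivity_map(maps, 0.5).values
    tight = lnm.sensitivity_map(maps, 0.8).values
    assert not (tight & ~loose).any()


def test_specificity_planted_single_voxel(toy_grid):
    grid = toy_grid(shape=(10, 10, 10))
    rng = np.random.default_rng(9)
    n_vox = grid.n_in_mask
    a = rng.standard_normal((12, n_vox)) * 0.1
    b = rng.standard_normal((12, n_vox)) * 0.1
    a[:, 123] += 5.0  # planted group difference at one voxel
    tmap = lnm.two_sample_tmap(a, b, grid=grid)
    kept = lnm.specificity_map(tmap, fwe_alpha=0.05)
    assert kept.values_in_mask[123]
    assert kept.n_voxels == 1


def test_specificity_identical_groups_empty(toy_grid):
    grid = toy_grid()
    rng = np.random.default_rng(10)
    a = rng.standard_normal((8, grid.n_in_mask))
    tmap = lnm.two_sample_tmap(a, a.copy(), grid=grid)
    assert lnm.specificity_map(tmap, 0.05).n_voxels == 0


def test_derive_loi_subset_and_disjoint(toy_grid):
    grid = toy_grid()
    big = np.zeros(grid.shape, dtype=bool)
    big[1:4, 1:4, 1:4] = True
    small = np.zeros(grid.shape, dtype=bool)
    small[2, 2, 2] = True
    sens = lc.BinaryMap(grid=grid, values=big)
    spec = lc.BinaryMap(grid=grid, values=small)
    np.testing.assert_array_equal(lnm.derive_loi(sens, spec).values, small)
    other = np.zeros(grid.shape, dtype=bool)
    other[5, 5, 5] = True
    with pytest.raises(lnm.EmptyLOIError, match="no LOI"):
        lnm.derive_loi(sens, lc.BinaryMap(grid=grid, values=other))


# ---------------------------------------------------------------------------
# recovery on the planted study
# ---------------------------------------------------------------------------

def test_loi_recovery_on_planted_study(study, pipeline):
    assert lc.dice(pipeline.loi, study.ground_truth.true_loi) >= 0.8


def test_circuit_recovery_and_contains_seed(study, cohort):
    gt = study.ground_truth
    tmap, circuit = lnm.circuit_map(gt.true_loi, cohort)
    assert lc.dice(circuit, gt.true_circuit) >= 0.8
    # the circuit always contains the seed voxels themselves
    assert (circuit.values & gt.true_loi.values).sum() == gt.true_loi.n_voxels


def test_permuted_group_labels_give_empty_specificity(pipeline, study):
    """With patient group labels permuted, the specificity map is empty in
    ~95% of reruns (the group contrast carries the localisation).  The bound
    allows the binomial Monte-Carlo margin of 100 reruns at rate 0.05."""
    means = np.asarray(
        [n.subject_mean.values_in_mask for n in pipeline.networks_g3]
        + [n.subject_mean.values_in_mask for n in pipeline.networks_g1])
    n3 = len(pipeline.networks_g3)
    rng = np.random.default_rng(17)
    empty = 0
    for _ in range(100):
        idx = rng.permutation(means.shape[0])
        tmap = lnm.two_sample_tmap(means[idx[:n3]], means[idx[n3:]], grid=study.grid)
        empty += int(lnm.specificity_map(tmap, 0.05).n_voxels == 0)
    margin = 2 * np.sqrt(100 * 0.05 * 0.95)  # ~4.4 reruns
    assert empty >= 95 - margin


def test_max_stat_permutation_specificity(toy_grid):
    grid = toy_grid(shape=(8, 8, 8))
    rng = np.random.default_rng(12)
    a = rng.standard_normal((10, grid.n_in_mask)) * 0.1
    b = rng.standard_normal((10, grid.n_in_mask)) * 0.1
    a[:, 42] += 4.0
    kept = lnm.specificity_map_permutation(a, b, fwe_alpha=0.05, n_perm=200,
                                           seed=0, grid=grid)
    assert kept.values_in_mask[42]
    assert kept.n_voxels <= 3
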