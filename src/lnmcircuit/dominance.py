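"""General dominance analysis of a spatial criterion map.

Dominance analysis (Budescu) decomposes a regression's explained variance
into per-predictor contributions: for predictor i, the increment
ΔR²(i | S) = R²(S ∪ {i}) - R²(S) is averaged over all subsets S of each
size k = 0..P-1 not containing i, and those size-conditional means are then
averaged across sizes.  This two-level averaging is what makes the total
dominances sum exactly to the full-model R² (the identity the method is
known for); the single-level mean over all 2^P - 1 submodels does not, and
is kept only as a diagnostic (:func:`simple_mean_dominance`).

All 2^P - 1 subset R² values are computed from centred cross-products, so
each subset costs one O(k³) solve and no data pass; solves are batched by
subset size, which keeps the full P = 18 enumeration (262 143 submodels)
in the seconds range.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .grid import BinaryMap, StatMap

logger = logging.getLogger("lnmcircuit")

_RIDGE = 1e-10


@dataclass(frozen=True)
class DominanceResult:
    """Total dominance (ΔR² units) and relative importance per predictor.

    Invariants: sum(total_dominance) = r2_full to 1e-10;
    relative_importance sums to 1.
    """

    predictors: Tuple[str, ...]
    total_dominance: np.ndarray
    relative_importance: np.ndarray
    r2_full: float
    adjusted_r2_full: float
    perm_p: Optional[float] = None
    n_perm: Optional[int] = None
    seed: Optional[int] = None


@dataclass(frozen=True)
class DominancePermutation:
    perm_p: float
    observed_adjusted_r2: float
    null_adjusted_r2: np.ndarray
    n_perm: int
    seed: int


def extract_map_values(maps: Sequence[StatMap], mask: BinaryMap) -> np.ndarray:
    """(n_voxels, n_maps) matrix of map values inside the mask.

    Row order is the canonical deterministic voxel ordering (ascending
    C-order linear index); columns follow the input order.
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    cols = []
    for i, m in enumerate(maps):
        mask.grid.require_match(m.grid)
        vals = m.values[mask.values]
        if not np.isfinite(vals).all():
            raise ValueError(
                f"map {i}: {int((~np.isfinite(vals)).sum())} non-finite values inside the mask"
            )
        cols.append(vals)
    return np.column_stack(cols)


def scatter_to_map(values: np.ndarray, mask: BinaryMap) -> StatMap:
    """Inverse of :func:`extract_map_values` for one column."""
    out = np.zeros(mask.grid.shape)
    out[mask.values] = values
    return StatMap(grid=mask.grid, values=out, kind="generic")


# ---------------------------------------------------------------------------
# subset R² machinery
# ---------------------------------------------------------------------------

def _gram(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, P) and y (n,) with matching n")
    if np.ptp(y) == 0:
        raise ValueError("criterion y is constant")
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        raise ValueError(f"all-constant predictor columns: {np.flatnonzero(constant)}")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return Xc.T @ Xc, Xc.T @ yc, float(yc @ yc)


def _solve_batch(sub: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Batched SPD solve with a logged ridge fallback for singular subsets."""
    try:
        beta = np.linalg.solve(sub, rhs[..., None])[..., 0]
        if np.isfinite(beta).all():
            return beta
    except np.linalg.LinAlgError:
        pass
    logger.warning("singular predictor subset encountered; ridge fallback %g applied", _RIDGE)
    eye = np.eye(sub.shape[-1])
    return np.linalg.solve(sub + _RIDGE * eye, rhs[..., None])[..., 0]


def subset_r2(X: np.ndarray, y: np.ndarray, subset: Sequence[int]) -> float:
    """OLS R² (with intercept) of y on the given predictor subset."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    Sxx, sxy, syy = _gram(X, y)
    idx = np.asarray(subset)
    beta = _solve_batch(Sxx[np.ix_(idx, idx)], sxy[idx])
    return float(sxy[idx] @ beta / syy)


def _all_subset_r2(Sxx: np.ndarray, sxy: np.ndarray, syy: float, P: int) -> np.ndarray:
    """R² for every nonempty predictor subset, indexed by bitmask."""
    r2 = np.zeros(2**P)
    for k in range(1, P + 1):
        combos = np.asarray(list(itertools.combinations(range(P), k)), dtype=np.int64)
        sub = Sxx[combos[:, :, None], combos[:, None, :]]
        rhs = sxy[combos]
        beta = _solve_batch(sub, rhs)
        vals = np.einsum("ck,ck->c", rhs, beta) / syy
        masks = (1 << combos).sum(axis=1)
        r2[masks] = vals
    return r2


def general_dominance(
    X: np.ndarray,
    y: np.ndarray,
    names: Optional[Sequence[str]] = None,
) -> DominanceResult:
    """Budescu general (total) dominance of each predictor, with relative
    importance normalised by the full-model R²."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, P = X.shape
    if P < 1:
        raise ValueError("need >= 1 predictor")
    if n <= P + 1:
        raise ValueError(f"need n > P + 1 observations (n={n}, P={P})")
    names = tuple(names) if names is not None else tuple(f"X{i}" for i in range(P))
    if len(names) != P:
        raise ValueError("names length must equal the number of predictors")
    Sxx, sxy, syy = _gram(X, y)
    r2 = _all_subset_r2(Sxx, sxy, syy, P)
    full = float(r2[-1])

    all_masks = np.arange(1, 2**P, dtype=np.uint64)
    sizes = np.bitwise_count(all_masks).astype(np.int64)
    total = np.empty(P)
    # counts of subsets of each size k drawn from the other P-1 predictors
    from math import comb
    denom = np.asarray([comb(P - 1, k) for k in range(P)], dtype=np.float64)
    for i in range(P):
        bit = np.uint64(1 << i)
        with_i = all_masks[(all_masks & bit) != 0]
        deltas = r2[with_i] - r2[with_i ^ bit]
        k = np.bitwise_count(with_i ^ bit).astype(np.int64)  # |S|, 0..P-1
        per_size = np.bincount(k, weights=deltas, minlength=P) / denom
        total[i] = per_size.mean()
    if abs(total.sum() - full) > 1e-8:
        raise AssertionError("dominance sum identity violated beyond numerical tolerance")
    rel = total / full if full != 0 else np.full(P, np.nan)
    adj = adjusted_r2(full, n, P)
    return DominanceResult(
        predictors=names, total_dominance=total, relative_importance=rel,
        r2_full=full, adjusted_r2_full=adj,
    )


def simple_mean_dominance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Diagnostic: single-level mean of ΔR²(i | S) over all subsets S not
    containing i.  Does not satisfy the sum-to-R² identity in general."""
    X = np.asarray(X, dtype=np.float64)
    P = X.shape[1]
    Sxx, sxy, syy = _gram(X, y)
    r2 = _all_subset_r2(Sxx, sxy, syy, P)
    all_masks = np.arange(1, 2**P, dtype=np.uint64)
    out = np.empty(P)
    for i in range(P):
        bit = np.uint64(1 << i)
        with_i = all_masks[(all_masks & bit) != 0]
        out[i] = (r2[with_i] - r2[with_i ^ bit]).mean()
    return out


def adjusted_r2(r2: float, n: int, p: int) -> float:
    if n <= p + 1:
        raise ValueError(f"adjusted R² undefined for n={n}, P={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def dominance_permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> DominancePermutation:
    """Significance of the full model: permute y, refit the full model, and
    compare adjusted R² with the observed value.

    perm_p uses the add-one estimator (1 + #{null >= observed}) / (n_perm + 1)
    so it is never exactly zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, P = X.shape
    Sxx, sxy, syy = _gram(X, y)
    beta = _solve_batch(Sxx, sxy)
    observed = adjusted_r2(float(sxy @ beta / syy), n, P)
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yperm = (y - y.mean())[perm_idx].T  # (n, n_perm)
    Xc = X - X.mean(axis=0)
    Sxy_all = Xc.T @ Yperm  # (P, n_perm)
    beta_all = _solve_batch(Sxx, Sxy_all.T)
    r2_null = np.einsum("cp,cp->c", Sxy_all.T, beta_all) / syy
    null_adj = 1.0 - (1.0 - r2_null) * (n - 1) / (n - P - 1)
    perm_p = float((1 + (null_adj >= observed).sum()) / (n_perm + 1))
    return DominancePermutation(
        perm_p=perm_p, observed_adjusted_r2=observed,
        null_adjusted_r2=null_adj, n_perm=n_perm, seed=seed,
    )


def run_dominance(
    criterion: StatMap,
    predictors: Sequence[StatMap],
    mask: BinaryMap,
    names: Optional[Sequence[str]] = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> DominanceResult:
    """Dominance analysis of a criterion map against predictor maps within a
    mask, with permutation inference on the full model."""
    y = extract_map_values([criterion], mask)[:, 0]
    X = extract_map_values(predictors, mask)
    result = general_dominance(X, y, names=names)
    perm = dominance_permutation_test(X, y, n_perm=n_perm, seed=seed)
    return DominanceResult(
        predictors=result.predictors, total_dominance=result.total_dominance,
        relative_importance=result.relative_importance, r2_full=result.r2_full,
        adjusted_r2_full=result.adjusted_r2_full,
        perm_p=perm.perm_p, n_perm=n_perm, seed=seed,
    )
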