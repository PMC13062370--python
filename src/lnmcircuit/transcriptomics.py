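"""PLS1 association between regional gene expression and circuit t-values.

With a univariate response, the first partial-least-squares component's
weight vector is proportional to Xᵀy (predictor-response covariance); that
closed form is the implementation here, and later components are out of
scope.  Gene-level stability is assessed by bootstrap resampling of regions
(rows) — the estimand is the stability of gene weights across brain
regions — with each replicate's component sign-aligned to the original.
Model-level significance permutes the response across regions and compares
the variance explained by component 1 with its null distribution.  Ranked
gene tails are exported after two-sided normal p-values on the bootstrap
Z-scores and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grid import BinaryMap, StatMap

logger = logging.getLogger("lnmcircuit")


@dataclass
class GeneExpressionMatrix:
    """Regions x genes expression values, z-scored per gene across regions."""

    regions: List[str]
    genes: List[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.regions), len(self.genes)):
            raise ValueError("values shape must be (n_regions, n_genes)")
        if not np.isfinite(v).all():
            raise ValueError("gene matrix contains missing/non-finite values")
        mean = np.abs(v.mean(axis=0)).max()
        sd = np.abs(v.std(axis=0) - 1.0).max()
        if mean > 1e-6 or sd > 1e-6:
            raise ValueError(
                f"matrix is not standardised per gene (max |mean|={mean:.2g}, "
                f"max |sd-1|={sd:.2g}); pass standardize=True when loading"
            )
        object.__setattr__(self, "values", v)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, standardize: bool = False) -> "GeneExpressionMatrix":
        values = frame.to_numpy(dtype=np.float64)
        if standardize:
            values = (values - values.mean(axis=0)) / values.std(axis=0)
        return cls(regions=[str(r) for r in frame.index],
                   genes=[str(g) for g in frame.columns], values=values)


def read_gene_matrix(path, standardize: bool = False) -> GeneExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return GeneExpressionMatrix.from_frame(frame, standardize=standardize)


def region_tvalues(
    circuit_tmap: StatMap,
    atlas_labels: np.ndarray,
    region_ids: Sequence[int],
) -> np.ndarray:
    """Per-region mean of the unthresholded circuit t-map over each atlas
    region's voxels.  A region with no voxels is an error naming it."""
    labels = np.asarray(atlas_labels)
    if labels.shape != circuit_tmap.grid.shape:
        raise ValueError("atlas labels must live on the t-map grid")
    out = np.empty(len(region_ids))
    for i, rid in enumerate(region_ids):
        vox = labels == rid
        if not vox.any():
            raise ValueError(f"atlas region {rid} has no voxels")
        out[i] = float(circuit_tmap.values[vox].mean())
    return out


# ---------------------------------------------------------------------------
# PLS component 1
# ---------------------------------------------------------------------------

def pls1_fit(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """First PLS component for a univariate response.

    Returns (weights, scores, variance_explained): w ∝ Xᵀy normalised to
    unit length, scores = Xw, variance explained = squared correlation of
    scores with y.  Sign convention: correlation(scores, y) >= 0.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (R, G) with R matching y")
    if X.shape[0] < 5:
        raise ValueError("need >= 5 regions")
    if np.ptp(y) == 0:
        raise ValueError("response y is constant")
    yc = y - y.mean()
    w = X.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("Xᵀy is exactly zero; no first component")
    w = w / norm
    scores = X @ w
    r = np.corrcoef(scores, y)[0, 1]
    if r < 0:  # enforce the sign convention (already nonnegative for PLS1)
        w, scores, r = -w, -scores, -r
    return w, scores, float(r**2)


def pls_bootstrap_z(
    X: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    max_redraws: int = 100,
) -> np.ndarray:
    """Bootstrap Z-scores of the component-1 gene weights.

    Regions are resampled with replacement; each replicate's weight vector
    is sign-aligned to the original (flipped when their correlation is
    negative); z = original weight / bootstrap standard error, per gene.
    Replicates with a constant resampled response are redrawn (logged).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w0, _, _ = pls1_fit(X, y)
    rng = np.random.default_rng(seed)
    R = y.size
    boots = np.empty((n_boot, w0.size))
    redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, R, size=R)
            if np.ptp(y[idx]) > 0:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap replicate")
        wb, _, _ = pls1_fit(X[idx], y[idx])
        if float(wb @ w0) < 0:
            wb = -wb
        boots[b] = wb
    if redraws:
        logger.info("pls_bootstrap_z: %d degenerate replicates redrawn", redraws)
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, w0 / se, np.sign(w0) * np.inf)
    return z


def pls_permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Permute y across regions; perm_p = add-one fraction of null variance
    explained >= observed.  Returns (perm_p, observed_variance_explained)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _, _, observed = pls1_fit(X, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        _, _, null[i] = pls1_fit(X, rng.permutation(y))
    perm_p = float((1 + (null >= observed).sum()) / (n_perm + 1))
    return perm_p, observed


def top_gene_tails(
    genes: Sequence[str],
    z_scores: np.ndarray,
    top_n: int = 1500,
    fdr_alpha: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked significant gene tails.

    Two-sided normal p per gene from its bootstrap Z, Benjamini-Hochberg q;
    the positive tail holds up to ``top_n`` genes with the largest Z among
    q < fdr_alpha (descending), the negative tail symmetrically (ascending
    Z, i.e. most negative first).  Tails are disjoint by construction.
    """
    z = np.asarray(z_scores, dtype=np.float64)
    if len(genes) != z.size:
        raise ValueError("genes and z_scores must pair")
    if top_n > z.size:
        raise ValueError("top_n exceeds the number of genes")
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"gene": list(genes), "z": z, "p": p, "q": q})
    sig = table[table.q < fdr_alpha]
    pos = sig[sig.z > 0].sort_values("z", ascending=False).head(top_n).reset_index(drop=True)
    neg = sig[sig.z < 0].sort_values("z", ascending=True).head(top_n).reset_index(drop=True)
    return pos, neg


@dataclass
class PlsResult:
    """Component-1 summary: gene weights, bootstrap Z, variance explained,
    permutation p, and the ranked FDR-significant tails."""

    genes: List[str]
    weights: np.ndarray
    z_scores: np.ndarray
    variance_explained: float
    perm_p: float
    pos_tail: pd.DataFrame
    neg_tail: pd.DataFrame
    n_boot: int
    n_perm: int
    seed: int

    def table(self) -> pd.DataFrame:
        p = 2.0 * stats.norm.sf(np.abs(self.z_scores))
        q = multipletests(p, method="fdr_bh")[1]
        tail = np.where(np.isin(self.genes, self.pos_tail.gene), "pos",
                        np.where(np.isin(self.genes, self.neg_tail.gene), "neg", ""))
        return pd.DataFrame({"gene": self.genes, "weight": self.weights,
                             "z": self.z_scores, "p": p, "q": q, "tail": tail})


def run_pls(
    expression: Union[GeneExpressionMatrix, pd.DataFrame],
    region_t: np.ndarray,
    n_boot: int = 1000,
    n_perm: int = 1000,
    top_n: int = 1500,
    fdr_alpha: float = 0.05,
    seed: int = 0,
) -> PlsResult:
    """Full transcription-neuroimaging association for one circuit t-vector."""
    if isinstance(expression, pd.DataFrame):
        expression = GeneExpressionMatrix.from_frame(expression)
    X = expression.values
    y = np.asarray(region_t, dtype=np.float64)
    if y.size != len(expression.regions):
        raise ValueError("region_t length must equal the number of regions")
    ss = np.random.SeedSequence(seed)
    seed_boot, seed_perm = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    w, _, variance_explained = pls1_fit(X, y)
    z = pls_bootstrap_z(X, y, n_boot=n_boot, seed=seed_boot)
    perm_p, _ = pls_permutation_test(X, y, n_perm=n_perm, seed=seed_perm)
    top_n = min(top_n, len(expression.genes))
    pos, neg = top_gene_tails(expression.genes, z, top_n=top_n, fdr_alpha=fdr_alpha)
    return PlsResult(
        genes=expression.genes, weights=w, z_scores=z,
        variance_explained=variance_explained, perm_p=perm_p,
        pos_tail=pos, neg_tail=neg, n_boot=n_boot, n_perm=n_perm, seed=seed,
    )
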