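"""Wheatsheaf strength-of-convergence index with bootstrap CI and p-value.

Traits are z-scored across all species so the index is scale-free. Pairwise
Euclidean distances are penalized for phylogenetic closeness,

    d'_ij = d_ij * (1 + s_ij),   s_ij = depth(MRCA(i,j)) / max tip depth,

and  w = mean(d' over all species pairs) / mean(d' over focal pairs).

Close relatives (s near 1) have their distances inflated, so focal species
that are phenotypically similar despite being phylogenetically distant push
the index up. The p-value compares w against the null of randomly drawn
focal sets of the same size; the CI comes from a stratified species
bootstrap. Both resampling schemes are conventions (isolated in
``_null_w`` / ``_bootstrap_w`` so they can be swapped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from phyloconv.shapes import TraitMatrix
from phyloconv.treeio import Phylogeny, shared_depth_matrix

__all__ = ["WheatsheafResult", "wheatsheaf_index", "wheatsheaf_test"]


@dataclass
class WheatsheafResult:
    w: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    p: float
    n_boot: int
    focal: tuple

    def to_dict(self) -> dict:
        return {"wheatsheaf_index": self.w, "lower_95_ci": self.ci_low,
                "upper_95_ci": self.ci_high, "p_value": self.p,
                "n_boot": self.n_boot, "focal": list(self.focal)}


def _standardize(y: np.ndarray) -> np.ndarray:
    sd = y.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = list(np.flatnonzero(sd <= 0))
        raise ValueError(f"zero-variance trait column(s): {bad}")
    return (y - y.mean(axis=0)) / sd


def _penalized_distances(y: np.ndarray, s_mat: np.ndarray) -> np.ndarray:
    d = squareform(pdist(_standardize(y)))
    return d * (1.0 + s_mat)


def _similarity_matrix(tree: Phylogeny) -> np.ndarray:
    shared = shared_depth_matrix(tree).to_numpy()
    max_depth = float(np.max(np.diag(shared)))
    s_mat = shared / max_depth
    np.fill_diagonal(s_mat, 0.0)
    return s_mat


def _pair_means(dp: np.ndarray, focal_idx: np.ndarray):
    n = dp.shape[0]
    iu = np.triu_indices(n, k=1)
    all_mean = dp[iu].mean()
    fi = np.asarray(focal_idx)
    sub = dp[np.ix_(fi, fi)]
    fu = np.triu_indices(len(fi), k=1)
    focal_mean = sub[fu].mean()
    return all_mean, focal_mean


def _w_from_matrices(dp: np.ndarray, focal_idx: np.ndarray) -> float:
    all_mean, focal_mean = _pair_means(dp, focal_idx)
    if focal_mean <= 0:
        return np.inf
    return float(all_mean / focal_mean)


def _focal_indices(tree_or_labels, focal: Sequence[str]) -> np.ndarray:
    labels = (tree_or_labels.tip_labels
              if isinstance(tree_or_labels, Phylogeny) else
              list(tree_or_labels))
    missing = [s for s in focal if s not in labels]
    if missing:
        raise KeyError(f"focal taxa absent: {missing}")
    return np.array([labels.index(s) for s in focal])


def wheatsheaf_index(tree: Phylogeny, traits: TraitMatrix,
                     focal: Sequence[str]) -> float:
    """The index for one focal set; inf (degenerate) for identical focals."""
    focal = list(focal)
    if not 2 <= len(focal) <= tree.n_tips:
        raise ValueError("need 2 <= |focal| <= number of tips")
    tm = traits.reorder(tree.tip_labels)
    s_mat = _similarity_matrix(tree)
    dp = _penalized_distances(tm.traits, s_mat)
    w = _w_from_matrices(dp, _focal_indices(tree, focal))
    if not np.isfinite(w):
        raise ValueError(
            "degenerate focal set: all focal phenotypes identical")
    return w


def _null_w(dp: np.ndarray, n_focal: int, n_boot: int,
            rng: np.random.Generator) -> np.ndarray:
    """Null distribution: w for random focal sets of the observed size."""
    n = dp.shape[0]
    out = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.choice(n, size=n_focal, replace=False)
        out[i] = _w_from_matrices(dp, idx)
    return out


def _bootstrap_w(y: np.ndarray, s_mat: np.ndarray, focal_idx: np.ndarray,
                 n_boot: int, rng: np.random.Generator,
                 max_redraws: int = 100) -> np.ndarray:
    """Stratified species bootstrap: resample within focal / non-focal."""
    n = y.shape[0]
    focal_idx = np.asarray(focal_idx)
    nonfocal = np.setdiff1d(np.arange(n), focal_idx)
    out = np.empty(n_boot)
    for i in range(n_boot):
        for _ in range(max_redraws):
            f = rng.choice(focal_idx, size=len(focal_idx), replace=True)
            nf = rng.choice(nonfocal, size=len(nonfocal), replace=True)
            idx = np.concatenate([f, nf])
            yb = y[idx]
            if np.any(yb.std(axis=0, ddof=1) <= 0):
                continue  # degenerate draw: redraw
            dp = _penalized_distances(yb, s_mat[np.ix_(idx, idx)])
            w = _w_from_matrices(dp, np.arange(len(f)))
            if np.isfinite(w):
                out[i] = w
                break
        else:
            raise RuntimeError("bootstrap kept drawing degenerate samples")
    return out


def wheatsheaf_test(tree: Phylogeny, traits: TraitMatrix,
                    focal: Sequence[str], n_boot: int = 1000,
                    seed: Optional[int] = None,
                    compute_ci: bool = True) -> WheatsheafResult:
    """Index plus bootstrap 95% CI and permutation-null p-value.

    p = #{null w >= observed} / n_boot over random focal sets of the same
    size; the CI is the 2.5/97.5 percentile band of the stratified species
    bootstrap. ``compute_ci=False`` skips the (costlier) CI resampling.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    focal = list(focal)
    if len(focal) >= tree.n_tips:
        raise ValueError("focal set must be a proper subset of the tips")
    rng = np.random.default_rng(seed)
    tm = traits.reorder(tree.tip_labels)
    s_mat = _similarity_matrix(tree)
    dp = _penalized_distances(tm.traits, s_mat)
    focal_idx = _focal_indices(tree, focal)
    w = _w_from_matrices(dp, focal_idx)
    null = _null_w(dp, len(focal), n_boot, rng)
    p = float(np.count_nonzero(null >= w) / n_boot)
    ci_low = ci_high = None
    if compute_ci:
        boots = _bootstrap_w(tm.traits, s_mat, focal_idx, n_boot, rng)
        ci_low, ci_high = (float(np.percentile(boots, 2.5)),
                           float(np.percentile(boots, 97.5)))
    return WheatsheafResult(w=float(w), ci_low=ci_low, ci_high=ci_high,
                            p=p, n_boot=n_boot, focal=tuple(focal))
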