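"""Brownian-motion and multi-regime Hansen (OU) model fits; SURFACE search.

Model conventions
-----------------
* Root state is fixed at the root regime's optimum (no separate z0), so a
  one-regime Hansen model has per-trait parameters (alpha, sigma_sq, theta).
* Each trait gets its own alpha and sigma_sq; the regime painting is shared
  and the joint log-likelihood is the sum over traits.
* Parameter count p = m * (2 + k') where k' is the number of distinct
  regimes and m the number of traits; shift locations are not counted.
  AICc sample size n = tips * traits.
* alpha is profiled on a fixed log-spaced grid (bounds [1e-6/T, 1e3/T] with
  T the tree height); the stepwise search uses grid-only profiles so every
  model comparison is internally consistent, and `hansen_fit` can refine
  the final estimate between the bracketing grid points.

The expensive objects (patristic/shared-time matrices, Cholesky factors of
the OU correlation at each grid alpha, and whitened per-branch segment
weights) depend only on the tree and the grid, never on the painting, so a
single `HansenContext` makes each candidate painting in the SURFACE search
cost a handful of small matrix products.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize_scalar

from phyloconv.shapes import TraitMatrix
from phyloconv.treeio import (
    Phylogeny,
    is_ultrametric,
    patristic_matrix,
    shared_depth_matrix,
)

__all__ = [
    "RegimePainting",
    "BMFit",
    "HansenFit",
    "SurfaceResult",
    "aicc",
    "bm_fit",
    "bm_loglik",
    "hansen_weight_matrix",
    "hansen_loglik",
    "hansen_fit",
    "HansenContext",
    "surface_forward",
    "surface_backward",
    "run_surface",
    "summarize_painting",
]

ALPHA_LO_FACTOR = 1e-6   # lower profile bound = 1e-6 / tree height
ALPHA_HI_FACTOR = 1e3    # upper profile bound = 1e3 / tree height
DEFAULT_GRID_SIZE = 24
MIN_SIGMA_SQ = 1e-12


# ---------------------------------------------------------------------------
# Regime paintings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegimePainting:
    """Assignment of every branch (keyed by child-node id) to a regime.

    A branch inherits its parent branch's regime unless it is listed in
    ``shift_branches``, where a regime origin sits. Regime ids are compact
    integers 0..k'-1 with every id used.
    """

    regime_of_branch: dict[int, int]
    root_regime: int
    shift_branches: frozenset[int]

    @property
    def n_regimes(self) -> int:
        return len(set(self.regime_of_branch.values()) | {self.root_regime})

    @staticmethod
    def from_shifts(tree: Phylogeny, shifts: dict[int, int],
                    root_regime: int = 0) -> "RegimePainting":
        """Propagate regimes down the tree from shift origins."""
        regime: dict[int, int] = {}
        for nid in tree.preorder():
            if nid == tree.root_id:
                continue
            if nid in shifts:
                regime[nid] = shifts[nid]
            else:
                pid = tree.nodes[nid].parent_id
                regime[nid] = regime.get(pid, root_regime)
        return RegimePainting(regime_of_branch=regime,
                              root_regime=root_regime,
                              shift_branches=frozenset(shifts))

    def validate(self, tree: Phylogeny) -> None:
        branches = set(tree.branch_ids)
        if set(self.regime_of_branch) != branches:
            raise ValueError("painting must cover every branch exactly")
        used = set(self.regime_of_branch.values()) | {self.root_regime}
        if used != set(range(len(used))):
            raise ValueError("regime ids must be compact 0..k'-1")
        for cid in branches:
            pid = tree.nodes[cid].parent_id
            parent_regime = (self.root_regime if pid == tree.root_id or
                             pid not in self.regime_of_branch
                             else self.regime_of_branch[pid])
            if pid == tree.root_id:
                parent_regime = self.root_regime
            if cid not in self.shift_branches and \
                    self.regime_of_branch[cid] != parent_regime:
                raise ValueError(
                    f"branch {cid} changes regime without a shift")

    def single(self) -> bool:
        return self.n_regimes == 1


def summarize_painting(painting: RegimePainting) -> dict[str, int]:
    """Table-1 style bookkeeping for a painting.

    ``k`` counts regime origins (the root origin plus every shift branch),
    ``k_prime`` the distinct regimes, ``c`` the origins pointing at regimes
    reached by two or more origins (the convergent ones).
    """
    origins = [painting.root_regime] + [
        painting.regime_of_branch[b] for b in sorted(painting.shift_branches)]
    k = len(origins)
    counts: dict[int, int] = {}
    for r in origins:
        counts[r] = counts.get(r, 0) + 1
    k_prime = painting.n_regimes
    conv_regimes = {r for r, cnt in counts.items() if cnt >= 2}
    c = sum(1 for r in origins if r in conv_regimes)
    k_conv = len(conv_regimes)
    k_nonconv = k_prime - k_conv
    return {"k": k, "k_prime": k_prime, "delta_k": k - k_prime, "c": c,
            "k_conv": k_conv, "k_nonconv": k_nonconv}


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------

@dataclass
class BMFit:
    sigma_sq: np.ndarray   # (m,) per-trait rates
    z0: np.ndarray         # (m,) root states
    loglik: float
    n_params: int
    aicc: float


@dataclass
class HansenFit:
    alpha: np.ndarray      # (m,)
    sigma_sq: np.ndarray   # (m,)
    theta: np.ndarray      # (k', m) per-regime optima
    painting: RegimePainting
    loglik: float
    n_params: int
    aicc: float
    per_trait_loglik: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class SurfaceResult:
    k: int
    k_prime: int
    delta_k: int
    c: int
    k_conv: int
    k_nonconv: int
    aicc_ouc: float
    aicc_ounc: float
    aicc_ou1: float
    aicc_bm: float
    painting: RegimePainting
    forward_history: list
    backward_history: list
    fits: dict

    def to_dict(self) -> dict:
        return {
            "k": self.k, "k_prime": self.k_prime, "delta_k": self.delta_k,
            "c": self.c, "k_conv": self.k_conv, "k_nonconv": self.k_nonconv,
            "aicc": {"ouc": self.aicc_ouc, "ounc": self.aicc_ounc,
                     "ou1": self.aicc_ou1, "bm": self.aicc_bm},
        }


def aicc(loglik: float, p: int, n: int) -> float:
    """-2 lnL + 2p + 2p(p+1)/(n-p-1); +inf when the correction blows up."""
    if n - p - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# Brownian motion
# ---------------------------------------------------------------------------

def _bm_cov(tree: Phylogeny) -> np.ndarray:
    return shared_depth_matrix(tree).to_numpy()


def bm_fit(tree: Phylogeny, traits: TraitMatrix) -> BMFit:
    """Analytic ML fit of independent per-trait Brownian motion."""
    _warn_if_not_ultrametric(tree)
    tm = traits.reorder(tree.tip_labels)
    y = tm.traits
    n, m = y.shape
    c_mat = _bm_cov(tree)
    factor = cho_factor(c_mat)
    logdet = 2.0 * np.log(np.diag(factor[0])).sum()
    ones = np.ones(n)
    ci_one = cho_solve(factor, ones)
    denom = ones @ ci_one
    z0 = (ci_one @ y) / denom
    resid = y - z0
    ci_resid = cho_solve(factor, resid)
    sigma_sq = np.maximum(np.einsum("ij,ij->j", resid, ci_resid) / n,
                          MIN_SIGMA_SQ)
    if np.any(sigma_sq <= MIN_SIGMA_SQ):
        warnings.warn("degenerate (constant) trait: sigma_sq at floor",
                      RuntimeWarning, stacklevel=2)
    loglik = float(np.sum(
        -0.5 * n * np.log(2 * np.pi * sigma_sq) - 0.5 * logdet - 0.5 * n))
    p = 2 * m
    return BMFit(sigma_sq=sigma_sq, z0=z0, loglik=loglik, n_params=p,
                 aicc=aicc(loglik, p, n * m))


def bm_loglik(tree: Phylogeny, traits: TraitMatrix, sigma_sq, z0) -> float:
    """BM log-likelihood at explicit parameters (per-trait arrays)."""
    tm = traits.reorder(tree.tip_labels)
    y = tm.traits
    n, m = y.shape
    sigma_sq = np.broadcast_to(np.asarray(sigma_sq, dtype=float), (m,))
    z0 = np.broadcast_to(np.asarray(z0, dtype=float), (m,))
    c_mat = _bm_cov(tree)
    factor = cho_factor(c_mat)
    logdet = 2.0 * np.log(np.diag(factor[0])).sum()
    resid = y - z0
    quad = np.einsum("ij,ij->j", resid, cho_solve(factor, resid)) / sigma_sq
    return float(np.sum(-0.5 * n * np.log(2 * np.pi * sigma_sq)
                        - 0.5 * logdet - 0.5 * quad))


def _warn_if_not_ultrametric(tree: Phylogeny) -> None:
    ok, spread = is_ultrametric(tree, rel_tol=1e-6)
    if not ok:
        warnings.warn(
            f"tree is not ultrametric (tip-depth spread {spread:.3g}); "
            f"per-tip depths are used exactly", RuntimeWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# Hansen machinery
# ---------------------------------------------------------------------------

def _tip_path_segments(tree: Phylogeny):
    """Flattened (tip_index, branch_index, t_begin, t_end) over all paths."""
    depths = tree.depths()
    branch_ids = tree.branch_ids
    branch_pos = {b: j for j, b in enumerate(branch_ids)}
    rows, cols, t0s, t1s = [], [], [], []
    for i, tid in enumerate(tree.tip_ids):
        for nid in tree.path_to_root(tid):
            if nid == tree.root_id:
                continue
            rows.append(i)
            cols.append(branch_pos[nid])
            t0s.append(depths[tree.nodes[nid].parent_id])
            t1s.append(depths[nid])
    return (np.array(rows), np.array(cols), np.array(t0s), np.array(t1s),
            branch_ids)


def _segment_weight_matrix(tree: Phylogeny, alpha: float, segs=None):
    """(P, r): per-branch segment weights (tips x branches) and root weights."""
    if segs is None:
        segs = _tip_path_segments(tree)
    rows, cols, t0s, t1s, branch_ids = segs
    depths = tree.depths()
    tip_depth = np.array([depths[t] for t in tree.tip_ids])
    n, nb = len(tip_depth), len(branch_ids)
    p_mat = np.zeros((n, nb))
    w = (np.exp(-alpha * (tip_depth[rows] - t1s))
         - np.exp(-alpha * (tip_depth[rows] - t0s)))
    np.add.at(p_mat, (rows, cols), w)
    r = np.exp(-alpha * tip_depth)
    return p_mat, r


def hansen_weight_matrix(tree: Phylogeny, painting: RegimePainting,
                         alpha: float) -> np.ndarray:
    """(tips x regimes) design matrix W; rows sum to 1 for any alpha."""
    p_mat, r = _segment_weight_matrix(tree, alpha)
    branch_ids = tree.branch_ids
    k = painting.n_regimes
    w_mat = np.zeros((p_mat.shape[0], k))
    for j, b in enumerate(branch_ids):
        w_mat[:, painting.regime_of_branch[b]] += p_mat[:, j]
    w_mat[:, painting.root_regime] += r
    return w_mat


def _ou_correlation(d_mat: np.ndarray, t_mat: np.ndarray,
                    alpha: float) -> np.ndarray:
    """V / sigma_sq: (1/2a) * exp(-a d_ij) * (1 - exp(-2a t_ij))."""
    return (np.exp(-alpha * d_mat) * (1.0 - np.exp(-2.0 * alpha * t_mat))
            / (2.0 * alpha))


def hansen_loglik(tree: Phylogeny, traits: TraitMatrix,
                  painting: RegimePainting, alpha, sigma_sq,
                  theta) -> float:
    """Hansen log-likelihood at explicit parameters.

    ``alpha`` and ``sigma_sq`` are scalars or per-trait arrays; ``theta`` is
    (k', m). The root state is fixed at the root regime's optimum.
    """
    tm = traits.reorder(tree.tip_labels)
    y = tm.traits
    n, m = y.shape
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (m,)).copy()
    sigma_sq = np.broadcast_to(np.asarray(sigma_sq, dtype=float), (m,)).copy()
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape != (painting.n_regimes, m):
        raise ValueError(f"theta must be (k', m) = "
                         f"({painting.n_regimes}, {m})")
    if np.any(~np.isfinite(alpha)) or np.any(alpha <= 0) or \
            np.any(~np.isfinite(sigma_sq)) or np.any(sigma_sq <= 0):
        raise ValueError("alpha and sigma_sq must be finite and positive")
    painting.validate(tree)
    d_mat = patristic_matrix(tree).to_numpy()
    t_mat = shared_depth_matrix(tree).to_numpy()
    total = 0.0
    for j in range(m):
        w_mat = hansen_weight_matrix(tree, painting, alpha[j])
        mean = w_mat @ theta[:, j]
        v_mat = sigma_sq[j] * _ou_correlation(d_mat, t_mat, alpha[j])
        factor = cho_factor(v_mat)
        logdet = 2.0 * np.log(np.diag(factor[0])).sum()
        resid = y[:, j] - mean
        quad = resid @ cho_solve(factor, resid)
        total += -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    return float(total)


class HansenContext:
    """Per-tree precomputation enabling fast profile fits over paintings."""

    def __init__(self, tree: Phylogeny, traits: TraitMatrix,
                 grid_size: int = DEFAULT_GRID_SIZE,
                 alpha_bounds: Optional[tuple[float, float]] = None):
        _warn_if_not_ultrametric(tree)
        self.tree = tree
        tm = traits.reorder(tree.tip_labels)
        self.trait_names = list(tm.trait_names)
        self.y = tm.traits
        self.n, self.m = self.y.shape
        self.d_mat = patristic_matrix(tree).to_numpy()
        self.t_mat = shared_depth_matrix(tree).to_numpy()
        self.height = float(np.max(np.diag(self.t_mat)))
        if alpha_bounds is None:
            alpha_bounds = (ALPHA_LO_FACTOR / self.height,
                            ALPHA_HI_FACTOR / self.height)
        self.alpha_bounds = alpha_bounds
        self.alphas = np.geomspace(alpha_bounds[0], alpha_bounds[1],
                                   grid_size)
        self.branch_ids = tree.branch_ids
        self.branch_pos = {b: j for j, b in enumerate(self.branch_ids)}
        self._segs = _tip_path_segments(tree)

        g, n = len(self.alphas), self.n
        nb = len(self.branch_ids)
        self.logdet = np.empty(g)
        self.whitened_y = np.empty((g, n, self.m))
        self.whitened_p = np.empty((g, n, nb))
        self.whitened_r = np.empty((g, n))
        eye = np.eye(n)
        for gi, a in enumerate(self.alphas):
            v0 = _ou_correlation(self.d_mat, self.t_mat, a)
            l_mat = cholesky(v0, lower=True)
            self.logdet[gi] = 2.0 * np.log(np.diag(l_mat)).sum()
            li = solve_triangular(l_mat, eye, lower=True)
            self.whitened_y[gi] = li @ self.y
            p_mat, r = _segment_weight_matrix(tree, a, self._segs)
            self.whitened_p[gi] = li @ p_mat
            self.whitened_r[gi] = li @ r
        self._cache: dict[tuple, dict] = {}

    # -- painting plumbing ---------------------------------------------

    def _canonical(self, painting: RegimePainting):
        """Regime array relabeled by first appearance (root regime -> 0).

        Returns ``(arr, relabel)``: paintings that differ only by regime
        labels share the same canonical array, so profile results cached on
        it (including theta rows) are portable across them.
        """
        raw = [painting.regime_of_branch[b] for b in self.branch_ids]
        relabel: dict[int, int] = {painting.root_regime: 0}
        for r in raw:
            if r not in relabel:
                relabel[r] = len(relabel)
        return np.array([relabel[r] for r in raw]), relabel

    # -- profile fit -----------------------------------------------------

    def profile(self, painting: RegimePainting) -> dict:
        """Grid-profile fit of a painting; cached by painting signature.

        All regime-indexed outputs (theta rows) are in canonical label
        order; use the painting's relabel map from ``_canonical`` to read
        them back.
        """
        arr, _ = self._canonical(painting)
        sig = tuple(arr)
        hit = self._cache.get(sig)
        if hit is not None:
            return hit
        k = painting.n_regimes
        g, n, m = len(self.alphas), self.n, self.m

        a_mat = np.empty((g, n, k))
        for r in range(k):
            idx = np.flatnonzero(arr == r)
            a_mat[:, :, r] = self.whitened_p[:, :, idx].sum(axis=2)
        a_mat[:, :, 0] += self.whitened_r  # canonical root regime is 0

        ata = np.einsum("gik,gil->gkl", a_mat, a_mat)
        atb = np.einsum("gik,gim->gkm", a_mat, self.whitened_y)
        ridge = 1e-10 * np.maximum(
            np.einsum("gkk->g", ata), 1.0)[:, None, None] * np.eye(k)
        theta = np.linalg.solve(ata + ridge, atb)        # (g, k, m)
        resid = self.whitened_y - a_mat @ theta          # (g, n, m)
        rss = np.maximum(np.einsum("gim,gim->gm", resid, resid),
                         MIN_SIGMA_SQ * n)
        sigma_sq = rss / n
        loglik = (-0.5 * n * np.log(2 * np.pi * sigma_sq)
                  - 0.5 * self.logdet[:, None] - 0.5 * n)  # (g, m)
        best = np.argmax(loglik, axis=0)                 # per trait
        traits_idx = np.arange(m)
        per_trait = loglik[best, traits_idx]
        out = {
            "loglik": float(per_trait.sum()),
            "per_trait_loglik": per_trait,
            "alpha": self.alphas[best],
            "alpha_idx": best,
            "sigma_sq": sigma_sq[best, traits_idx],
            "theta": theta[best, :, traits_idx].T.copy(),  # (k, m)
            "k_prime": k,
        }
        out["n_params"] = m * (2 + k)
        out["aicc"] = aicc(out["loglik"], out["n_params"], n * m)
        self._cache[sig] = out
        return out

    def profile_aicc(self, painting: RegimePainting) -> float:
        return self.profile(painting)["aicc"]

    # -- refinement ------------------------------------------------------

    def _loglik_single_alpha(self, arr: np.ndarray, root_regime: int,
                             k: int, alpha: float, trait: int):
        """Exact per-trait profile log-likelihood at an off-grid alpha."""
        v0 = _ou_correlation(self.d_mat, self.t_mat, alpha)
        l_mat = cholesky(v0, lower=True)
        logdet = 2.0 * np.log(np.diag(l_mat)).sum()
        p_mat, r = _segment_weight_matrix(self.tree, alpha, self._segs)
        w_mat = np.zeros((self.n, k))
        for reg in range(k):
            idx = np.flatnonzero(arr == reg)
            w_mat[:, reg] = p_mat[:, idx].sum(axis=1)
        w_mat[:, root_regime] += r
        a_mat = solve_triangular(l_mat, w_mat, lower=True)
        b = solve_triangular(l_mat, self.y[:, trait], lower=True)
        theta, *_ = np.linalg.lstsq(a_mat, b, rcond=None)
        resid = b - a_mat @ theta
        rss = max(float(resid @ resid), MIN_SIGMA_SQ * self.n)
        sigma_sq = rss / self.n
        loglik = (-0.5 * self.n * np.log(2 * np.pi * sigma_sq)
                  - 0.5 * logdet - 0.5 * self.n)
        return float(loglik), sigma_sq, theta

    def fit(self, painting: RegimePainting, refine: bool = False) -> HansenFit:
        prof = self.profile(painting)
        arr, relabel = self._canonical(painting)
        k = painting.n_regimes
        alpha = prof["alpha"].copy()
        sigma_sq = prof["sigma_sq"].copy()
        theta_canon = prof["theta"].copy()
        per_trait = prof["per_trait_loglik"].copy()
        if refine:
            la = np.log(self.alphas)
            for j in range(self.m):
                gi = prof["alpha_idx"][j]
                lo = la[max(gi - 1, 0)]
                hi = la[min(gi + 1, len(la) - 1)]
                res = minimize_scalar(
                    lambda x: -self._loglik_single_alpha(
                        arr, 0, k, math.exp(x), j)[0],
                    bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-4})
                ll, ss, th = self._loglik_single_alpha(
                    arr, 0, k, math.exp(res.x), j)
                if ll > per_trait[j]:
                    per_trait[j] = ll
                    alpha[j] = math.exp(res.x)
                    sigma_sq[j] = ss
                    theta_canon[:, j] = th
        # map theta rows from canonical labels back to the painting's labels
        theta = np.empty_like(theta_canon)
        for orig, canon in relabel.items():
            theta[orig] = theta_canon[canon]
        loglik = float(per_trait.sum())
        p = prof["n_params"]
        return HansenFit(alpha=alpha, sigma_sq=sigma_sq, theta=theta,
                         painting=painting, loglik=loglik, n_params=p,
                         aicc=aicc(loglik, p, self.n * self.m),
                         per_trait_loglik=per_trait)


def hansen_fit(tree: Phylogeny, traits: TraitMatrix,
               painting: Optional[RegimePainting] = None,
               grid_size: int = 40, refine: bool = True) -> HansenFit:
    """Fit a Hansen model for a given painting (default: one regime)."""
    if painting is None:
        painting = RegimePainting.from_shifts(tree, {})
    painting.validate(tree)
    if painting.n_regimes >= tree.n_tips:
        raise ValueError("more regimes than tips: over-parameterized")
    ctx = HansenContext(tree, traits, grid_size=grid_size)
    return ctx.fit(painting, refine=refine)


# ---------------------------------------------------------------------------
# SURFACE search
# ---------------------------------------------------------------------------

def surface_forward(tree: Phylogeny, traits: TraitMatrix,
                    ctx: Optional[HansenContext] = None,
                    threshold: float = 0.0,
                    max_shifts: Optional[int] = None):
    """Stepwise addition of regime shifts, best-AICc-first.

    Returns ``(painting, history, ctx)``; each history entry records the
    accepted shift branch and the AICc after acceptance (strictly
    decreasing). Candidate shifts sit at branch origins; the root stem is
    not a candidate. Ties break on the smallest post-order branch id.
    """
    if tree.n_tips < 4:
        raise ValueError("SURFACE needs at least 4 tips")
    if not 1 <= traits.n_traits <= 10:
        raise ValueError("SURFACE supports 1-10 traits")
    if ctx is None:
        ctx = HansenContext(tree, traits)
    if max_shifts is None:
        max_shifts = tree.n_tips - 2
    shifts: dict[int, int] = {}
    painting = RegimePainting.from_shifts(tree, shifts)
    current = ctx.profile_aicc(painting)
    history = [{"step": 0, "shift_branch": None, "aicc": current}]
    step = 0
    while len(shifts) < max_shifts:
        best_branch, best_aicc = None, current
        new_regime = len(set(shifts.values()) | {0})
        for b in ctx.branch_ids:          # post-order: deterministic ties
            if b in shifts:
                continue
            cand = RegimePainting.from_shifts(tree, {**shifts, b: new_regime})
            val = ctx.profile_aicc(cand)
            if val < best_aicc - 1e-12:
                best_branch, best_aicc = b, val
        if best_branch is None or current - best_aicc <= threshold:
            break
        shifts[best_branch] = new_regime
        painting = RegimePainting.from_shifts(tree, shifts)
        current = best_aicc
        step += 1
        history.append({"step": step, "shift_branch": best_branch,
                        "aicc": current})
    return painting, history, ctx


def _merge_regimes(tree: Phylogeny, painting: RegimePainting,
                   a: int, b: int) -> RegimePainting:
    """Relabel regime b as a and compact regime ids."""
    if a == b:
        raise ValueError("cannot merge a regime with itself")
    mapping = {r: (a if r == b else r)
               for r in range(painting.n_regimes)}
    used = sorted(set(mapping.values()))
    compact = {r: i for i, r in enumerate(used)}
    regime = {cid: compact[mapping[r]]
              for cid, r in painting.regime_of_branch.items()}
    return RegimePainting(
        regime_of_branch=regime,
        root_regime=compact[mapping[painting.root_regime]],
        shift_branches=painting.shift_branches)


def surface_backward(tree: Phylogeny, traits: TraitMatrix,
                     painting: RegimePainting,
                     ctx: Optional[HansenContext] = None,
                     threshold: float = 0.0,
                     forward_history: Optional[list] = None) -> SurfaceResult:
    """Pairwise regime collapsing followed by Table-1 style bookkeeping.

    Also fits the OUnc (input painting), OU1 and BM reference models so the
    four-model comparison is part of the result.
    """
    if ctx is None:
        ctx = HansenContext(tree, traits)
    painting.validate(tree)
    ounc_aicc = ctx.profile_aicc(painting)
    current_painting = painting
    current = ounc_aicc
    history = []
    step = 0
    while current_painting.n_regimes > 1:
        k = current_painting.n_regimes
        best_pair, best_aicc = None, current
        for a in range(k):
            for b in range(a + 1, k):
                cand = _merge_regimes(tree, current_painting, a, b)
                val = ctx.profile_aicc(cand)
                if val < best_aicc - 1e-12:
                    best_pair, best_aicc = (a, b), val
        if best_pair is None or current - best_aicc <= threshold:
            break
        current_painting = _merge_regimes(tree, current_painting, *best_pair)
        current = best_aicc
        step += 1
        history.append({"step": step, "merged": best_pair, "aicc": current})

    ou1 = RegimePainting.from_shifts(tree, {})
    ou1_aicc = ctx.profile_aicc(ou1)
    bm = bm_fit(tree, traits)
    books = summarize_painting(current_painting)
    fits = {
        "ouc": ctx.fit(current_painting),
        "ounc": ctx.fit(painting),
        "ou1": ctx.fit(ou1),
        "bm": bm,
    }
    return SurfaceResult(
        k=books["k"], k_prime=books["k_prime"], delta_k=books["delta_k"],
        c=books["c"], k_conv=books["k_conv"], k_nonconv=books["k_nonconv"],
        aicc_ouc=current, aicc_ounc=ounc_aicc, aicc_ou1=ou1_aicc,
        aicc_bm=bm.aicc, painting=current_painting,
        forward_history=forward_history or [], backward_history=history,
        fits=fits)


def run_surface(tree: Phylogeny, traits: TraitMatrix,
                grid_size: int = DEFAULT_GRID_SIZE,
                threshold: float = 0.0) -> SurfaceResult:
    """Full SURFACE search: forward shift addition, backward collapsing."""
    ctx = HansenContext(tree, traits, grid_size=grid_size)
    painting, fwd, ctx = surface_forward(tree, traits, ctx=ctx,
                                         threshold=threshold)
    return surface_backward(tree, traits, painting, ctx=ctx,
                            threshold=threshold, forward_history=fwd)
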