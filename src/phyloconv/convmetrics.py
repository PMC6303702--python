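"""Distance-based convergence measures C1-C4 and the frequency measure C5.

For a focal pair, ``Dtip`` is the Euclidean distance between the tip trait
vectors and ``Dmax`` the maximum distance between any node on the lineage
from the pair's MRCA to one tip and any node on the lineage to the other
(both lineages include the MRCA and the tip). Then

    C1 = 1 - Dtip / Dmax
    C2 = Dmax - Dtip
    C3 = C2 / (summed ancestor->descendant change along both lineages)
    C4 = C2 / (summed change over every branch of the MRCA's clade)

Multi-taxon focal sets average C1-C3 over unordered pairs; the group C4
divides the summed pair C2 by the total change in the clade rooted at the
MRCA of the whole set (this summed-numerator convention allows C4 > C3).
Significance comes from re-running the identical computation on Brownian
datasets simulated with the tree-estimated rate matrix; ancestral states
are re-reconstructed for every simulated dataset.

C5 counts root-to-tip lineages whose phylomorphospace path (on two chosen
axes) intersects the convex hull of the focal tips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, MultiPoint

from phyloconv.ancestral import AncestralStateMap, scp_linear_system
from phyloconv.shapes import TraitMatrix
from phyloconv.treeio import Phylogeny

__all__ = [
    "ConvergenceMetrics",
    "pair_c_metrics",
    "group_c_metrics",
    "c_significance",
    "c5",
    "convergence_analysis",
    "estimate_bm_rate_matrix",
]


@dataclass
class ConvergenceMetrics:
    c1: float
    c2: float
    c3: float
    c4: float
    c5: Optional[int] = None
    p1: Optional[float] = None
    p2: Optional[float] = None
    p3: Optional[float] = None
    p4: Optional[float] = None
    p5: Optional[float] = None
    n_sim: int = 0
    focal: tuple = ()
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "focal": list(self.focal),
            "c1": self.c1, "p1": self.p1,
            "c2": self.c2, "p2": self.p2,
            "c3": self.c3, "p3": self.p3,
            "c4": self.c4, "p4": self.p4,
            "c5": self.c5, "p5": self.p5,
            "n_sim": self.n_sim,
        }


# ---------------------------------------------------------------------------
# Engine: tree-indexed plumbing reused across simulation replicates
# ---------------------------------------------------------------------------

class _MetricEngine:
    """Precomputed lineage/clade index structures for one (tree, focal)."""

    def __init__(self, tree: Phylogeny, focal_labels: Sequence[str]):
        self.tree = tree
        n_nodes = len(tree.nodes)
        if set(tree.nodes) != set(range(n_nodes)):
            raise ValueError("node ids must be contiguous integers")
        self.n_nodes = n_nodes
        self.tip_ids = tree.tip_ids
        label_to_id = tree.tip_id_of_label()
        missing = [s for s in focal_labels if s not in label_to_id]
        if missing:
            raise KeyError(f"focal taxa absent from tree: {missing}")
        self.focal_ids = [label_to_id[s] for s in focal_labels]
        if len(set(self.focal_ids)) < 2:
            raise ValueError("need at least 2 distinct focal taxa")

        self.branch_children = np.array(tree.branch_ids)
        self.branch_parents = np.array(
            [tree.nodes[c].parent_id for c in self.branch_children])
        self.branch_pos = {int(c): j
                           for j, c in enumerate(self.branch_children)}

        self.pairs = []
        for a, b in combinations(self.focal_ids, 2):
            mrca = tree.mrca(a, b)
            lin_a = self._lineage(mrca, a)
            lin_b = self._lineage(mrca, b)
            lineage_branch_idx = np.array(
                [self.branch_pos[n] for n in lin_a[1:] + lin_b[1:]])
            clade_idx = self._clade_branch_idx(mrca)
            self.pairs.append({
                "tips": (a, b),
                "lin_a": np.array(lin_a), "lin_b": np.array(lin_b),
                "lineage_branch_idx": lineage_branch_idx,
                "clade_idx": clade_idx,
            })
        group_mrca = self.focal_ids[0]
        for t in self.focal_ids[1:]:
            group_mrca = tree.mrca(group_mrca, t)
        self.group_clade_idx = self._clade_branch_idx(group_mrca)

    def _lineage(self, mrca: int, tip: int) -> list[int]:
        path = []
        nid = tip
        while nid != mrca:
            path.append(nid)
            nid = self.tree.nodes[nid].parent_id
        path.append(mrca)
        return path[::-1]

    def _clade_branch_idx(self, mrca: int) -> np.ndarray:
        ids = [n for n in self.tree.subtree_ids(mrca) if n != mrca]
        return np.array([self.branch_pos[n] for n in ids], dtype=int)

    def pair_metrics(self, values: np.ndarray):
        """Per-pair (c1, c2, c3, c4, dtip, dmax) given node-value array."""
        change = np.linalg.norm(
            values[self.branch_children] - values[self.branch_parents],
            axis=1)
        tol = 1e-12 * (1.0 + float(np.abs(values).max()))
        out = []
        for pr in self.pairs:
            a, b = pr["tips"]
            dtip = float(np.linalg.norm(values[a] - values[b]))
            dmax = float(cdist(values[pr["lin_a"]],
                               values[pr["lin_b"]]).max())
            if dmax <= tol:
                out.append((0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
                continue
            c2 = dmax - dtip
            c1 = c2 / dmax
            lin_total = change[pr["lineage_branch_idx"]].sum()
            clade_total = change[pr["clade_idx"]].sum()
            c3 = c2 / lin_total if lin_total > 0 else 0.0
            c4 = c2 / clade_total if clade_total > 0 else 0.0
            out.append((c1, c2, c3, c4, dtip, dmax))
        return out, change

    def group_metrics(self, values: np.ndarray):
        pairs, change = self.pair_metrics(values)
        arr = np.array([p[:4] for p in pairs])
        c1, c2, c3 = arr[:, 0].mean(), arr[:, 1].mean(), arr[:, 2].mean()
        group_total = change[self.group_clade_idx].sum()
        c4 = arr[:, 1].sum() / group_total if group_total > 0 else 0.0
        return float(c1), float(c2), float(c3), float(c4)


def _node_value_solver(tree: Phylogeny):
    """Map (n_tips, m) tip values -> (n_nodes, m) node values (SCP states)."""
    internal, solve = scp_linear_system(tree)
    tip_ids = tree.tip_ids
    n_nodes = len(tree.nodes)

    def node_values(tip_values: np.ndarray) -> np.ndarray:
        tip_values = np.atleast_2d(tip_values)
        out = np.empty((n_nodes, tip_values.shape[1]))
        out[tip_ids] = tip_values
        out[internal] = solve(tip_values)
        return out

    return node_values


# ---------------------------------------------------------------------------
# Public metric operations
# ---------------------------------------------------------------------------

def pair_c_metrics(tree: Phylogeny, traits: TraitMatrix,
                   anc: AncestralStateMap, tip_a: str, tip_b: str):
    """(C1, C2, C3, C4pair, Dtip, Dmax) for one focal pair (by tip label)."""
    if tip_a == tip_b:
        raise ValueError("focal tips must differ")
    engine = _MetricEngine(tree, [tip_a, tip_b])
    values = anc.array(range(engine.n_nodes))
    pairs, _ = engine.pair_metrics(values)
    return pairs[0]


def group_c_metrics(tree: Phylogeny, traits: TraitMatrix,
                    focal: Sequence[str]) -> ConvergenceMetrics:
    """C1-C4 for a focal set (ancestral states reconstructed internally)."""
    focal = list(focal)
    engine = _MetricEngine(tree, focal)
    tm = traits.reorder(tree.tip_labels)
    values = _node_value_solver(tree)(tm.traits)
    c1, c2, c3, c4 = engine.group_metrics(values)
    degenerate = all(p[5] <= 0 for p in engine.pair_metrics(values)[0])
    return ConvergenceMetrics(c1=c1, c2=c2, c3=c3, c4=c4,
                              focal=tuple(focal), degenerate=degenerate)


def estimate_bm_rate_matrix(tree: Phylogeny, traits: TraitMatrix):
    """(R, z0): GLS evolutionary rate matrix and root estimate.

    R is the cross-trait covariance of phylogenetically whitened changes
    (the independent-contrasts covariance up to its REML scaling).
    """
    from phyloconv.treeio import shared_depth_matrix
    tm = traits.reorder(tree.tip_labels)
    y = tm.traits
    n = y.shape[0]
    c_mat = shared_depth_matrix(tree).to_numpy()
    factor = cho_factor(c_mat)
    ones = np.ones(n)
    ci_one = cho_solve(factor, ones)
    z0 = (ci_one @ y) / (ones @ ci_one)
    resid = y - z0
    rate = resid.T @ cho_solve(factor, resid) / (n - 1)
    return rate, z0


def _simulate_bm_tips(tree: Phylogeny, rate: np.ndarray, z0: np.ndarray,
                      n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """(n_sim, n_tips, m) multivariate-BM tip data, vectorized over sims."""
    m = rate.shape[0]
    chol = np.linalg.cholesky(rate + 1e-15 * np.eye(m))
    branch_ids = tree.branch_ids
    bl = np.array([tree.nodes[b].branch_length for b in branch_ids])
    incr = rng.standard_normal((n_sim, len(branch_ids), m)) @ chol.T
    incr *= np.sqrt(bl)[None, :, None]
    pos = {b: j for j, b in enumerate(branch_ids)}
    n_nodes = len(tree.nodes)
    vals = np.empty((n_sim, n_nodes, m))
    vals[:, tree.root_id, :] = z0
    for nid in tree.preorder():
        if nid == tree.root_id:
            continue
        pid = tree.nodes[nid].parent_id
        vals[:, nid, :] = vals[:, pid, :] + incr[:, pos[nid], :]
    tips = tree.tip_ids
    return vals[:, tips, :]


def c_significance(tree: Phylogeny, traits: TraitMatrix,
                   focal: Sequence[str], n_sim: int = 500,
                   seed: Optional[int] = None,
                   conservative: bool = False) -> dict[str, float]:
    """Brownian-null p-values for the group C1-C4 (p = #{sim >= obs}/n_sim).

    ``conservative=True`` switches to the (+1)/(+1) estimator that never
    reports an exact zero.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    focal = list(focal)
    rng = np.random.default_rng(seed)
    engine = _MetricEngine(tree, focal)
    solver = _node_value_solver(tree)
    tm = traits.reorder(tree.tip_labels)
    observed = np.array(engine.group_metrics(solver(tm.traits)))
    rate, z0 = estimate_bm_rate_matrix(tree, traits)
    sims = _simulate_bm_tips(tree, rate, z0, n_sim, rng)
    counts = np.zeros(4)
    for s in range(n_sim):
        sim_vals = solver(sims[s])
        counts += np.array(engine.group_metrics(sim_vals)) >= observed
    if conservative:
        p = (counts + 1.0) / (n_sim + 1.0)
    else:
        p = counts / n_sim
    return {"p1": float(p[0]), "p2": float(p[1]),
            "p3": float(p[2]), "p4": float(p[3])}


# ---------------------------------------------------------------------------
# C5: lineages entering the focal region of phylomorphospace
# ---------------------------------------------------------------------------

class _ConvexRegion:
    """Convex hull of the focal tips with fast inside/crossing tests.

    Points on the boundary count as inside. Degenerate hulls (collinear or
    coincident focal points) fall back to an epsilon-buffered polygon.
    """

    def __init__(self, points: np.ndarray, eps: float):
        points = np.asarray(points, dtype=float)
        uniq = np.unique(points, axis=0)
        poly = MultiPoint([tuple(p) for p in points]).convex_hull
        if poly.geom_type != "Polygon":
            warnings.warn("degenerate focal hull; applying epsilon buffer",
                          RuntimeWarning, stacklevel=4)
            poly = poly.buffer(max(eps, 1e-300), quad_segs=4)
        self.polygon = poly
        verts = np.asarray(poly.exterior.coords)[:-1]
        # orient counter-clockwise so edge cross-products are >= 0 inside
        area2 = np.sum(verts[:, 0] * np.roll(verts[:, 1], -1)
                       - np.roll(verts[:, 0], -1) * verts[:, 1])
        if area2 < 0:
            verts = verts[::-1]
        self._a = verts
        self._e = np.roll(verts, -1, axis=0) - verts
        scale = float(np.abs(verts).max()) or 1.0
        self._tol = 1e-12 * scale
        lo, hi = verts.min(axis=0), verts.max(axis=0)
        self._lo, self._hi = lo - self._tol, hi + self._tol
        del uniq

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Boundary-inclusive point-in-convex-polygon, vectorized."""
        points = np.atleast_2d(points)
        rel = points[:, None, :] - self._a[None, :, :]
        cross = (self._e[None, :, 0] * rel[:, :, 1]
                 - self._e[None, :, 1] * rel[:, :, 0])
        return np.all(cross >= -self._tol, axis=1)

    def segment_crosses(self, p0: np.ndarray, p1: np.ndarray) -> bool:
        """Does the (both-endpoints-outside) segment touch the region?"""
        lo = np.minimum(p0, p1)
        hi = np.maximum(p0, p1)
        if np.any(hi < self._lo) or np.any(lo > self._hi):
            return False
        return bool(LineString([p0, p1]).intersects(self.polygon))


def _count_entering_lineages(tree: Phylogeny, coords: np.ndarray,
                             focal_tip_ids: Sequence[int]) -> int:
    """Number of root-to-tip paths that enter the focal region from outside.

    A lineage whose whole path lies inside the region never *enters* it and
    is not counted; this is what makes large Brownian-null hulls (root
    inside) score low.
    """
    scale = float(np.ptp(coords, axis=0).max()) or 1.0
    region = _ConvexRegion(coords[list(focal_tip_ids)], 1e-9 * scale)
    inside = region.inside(coords)
    count = 0
    for tid in tree.tip_ids:
        path = tree.path_to_root(tid)[::-1]  # root -> tip
        entered = False
        for i in range(len(path) - 1):
            if inside[path[i]]:
                continue  # segment starts inside: not an entry
            if inside[path[i + 1]] or region.segment_crosses(
                    coords[path[i]], coords[path[i + 1]]):
                entered = True
                break
        if entered:
            count += 1
    return count


def c5(tree: Phylogeny, traits: TraitMatrix,
       anc: Optional[AncestralStateMap], focal: Sequence[str],
       axes: tuple[int, int] = (0, 1), n_sim: int = 500,
       seed: Optional[int] = None) -> tuple[int, float]:
    """Observed C5 and its Brownian-null p-value.

    The focal region is the convex hull of the focal tips on two trait
    axes; each simulated dataset defines the hull from its own simulated
    focal tips.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    focal = list(focal)
    engine = _MetricEngine(tree, focal)
    solver = _node_value_solver(tree)
    tm = traits.reorder(tree.tip_labels)
    ax = list(axes)
    if anc is not None:
        values = anc.array(range(engine.n_nodes))
    else:
        values = solver(tm.traits)
    observed = _count_entering_lineages(tree, values[:, ax],
                                        engine.focal_ids)
    rng = np.random.default_rng(seed)
    rate, z0 = estimate_bm_rate_matrix(tree, traits)
    sims = _simulate_bm_tips(tree, rate, z0, n_sim, rng)
    count_ge = 0
    for s in range(n_sim):
        sim_vals = solver(sims[s])
        if _count_entering_lineages(tree, sim_vals[:, ax],
                                    engine.focal_ids) >= observed:
            count_ge += 1
    return observed, count_ge / n_sim


def convergence_analysis(tree: Phylogeny, traits: TraitMatrix,
                         focal: Sequence[str], axes: tuple[int, int] = (0, 1),
                         n_sim: int = 500,
                         seed: Optional[int] = None) -> ConvergenceMetrics:
    """Full Table-2 style row: C1-C5 with simulation p-values."""
    metrics = group_c_metrics(tree, traits, focal)
    pvals = c_significance(tree, traits, focal, n_sim=n_sim, seed=seed)
    c5_obs, c5_p = c5(tree, traits, None, focal, axes=axes, n_sim=n_sim,
                      seed=None if seed is None else seed + 1)
    return ConvergenceMetrics(
        c1=metrics.c1, c2=metrics.c2, c3=metrics.c3, c4=metrics.c4,
        c5=c5_obs, p1=pvals["p1"], p2=pvals["p2"], p3=pvals["p3"],
        p4=pvals["p4"], p5=c5_p, n_sim=n_sim, focal=tuple(focal),
        degenerate=metrics.degenerate)
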