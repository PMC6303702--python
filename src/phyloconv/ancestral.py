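"""Ancestral continuous states by squared-change parsimony; phylomorphospace.

The branch-length-weighted variant minimizes

    sum over branches (x_child - x_parent)^2 / branch_length

per trait, which coincides with the Brownian-motion maximum-likelihood
interior reconstruction. The minimizer solves the (graph-Laplacian) normal
equations exactly; internal states therefore always lie within the tip
range of each trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from phyloconv.shapes import TraitMatrix
from phyloconv.treeio import Phylogeny, TreeError

__all__ = [
    "AncestralStateMap",
    "Phylomorphospace",
    "squared_change_parsimony",
    "scp_linear_system",
    "phylomorphospace",
]


@dataclass
class AncestralStateMap:
    values: dict[int, np.ndarray]  # node id -> trait vector
    tree: Phylogeny
    trait_names: list[str] = field(default_factory=list)

    def array(self, node_ids) -> np.ndarray:
        return np.vstack([self.values[n] for n in node_ids])


@dataclass
class Phylomorphospace:
    points: dict[int, tuple[float, float]]
    segments: list[tuple[int, int]]  # (parent_id, child_id) per branch
    axes: tuple[int, int]


def scp_linear_system(tree: Phylogeny, weighted: bool = True,
                      zero_length_policy: str = "epsilon"):
    """Factor the squared-change-parsimony normal equations for a tree.

    Returns ``(internal_ids, solve)`` where ``solve(tip_values)`` maps a
    (n_tips, m) array (rows in ``tree.tip_ids`` order) to internal states
    (len(internal_ids), m). Factoring once lets simulation nulls
    re-reconstruct thousands of datasets cheaply.
    """
    tips = tree.tip_ids
    internal = [n for n in tree.postorder() if not tree.nodes[n].is_tip]
    tip_pos = {t: i for i, t in enumerate(tips)}
    int_pos = {n: i for i, n in enumerate(internal)}
    k = len(internal)

    depth = sum(tree.nodes[b].branch_length for b in tree.branch_ids)
    eps = 1e-8 * max(depth, 1.0)

    lap = np.zeros((k, k))
    b_mat = np.zeros((k, len(tips)))
    for cid in tree.branch_ids:
        node = tree.nodes[cid]
        bl = node.branch_length
        if weighted:
            if bl <= 0:
                if zero_length_policy != "epsilon":
                    raise TreeError(f"zero-length branch at node {cid}")
                warnings.warn(
                    f"zero-length branch at node {cid}; using epsilon "
                    f"{eps:.3g}", RuntimeWarning, stacklevel=2)
                bl = eps
            w = 1.0 / bl
        else:
            w = 1.0
        pid = node.parent_id
        pi = int_pos[pid]
        lap[pi, pi] += w
        if node.is_tip:
            b_mat[pi, tip_pos[cid]] += w
        else:
            ci = int_pos[cid]
            lap[ci, ci] += w
            lap[pi, ci] -= w
            lap[ci, pi] -= w

    from scipy.linalg import cho_factor, cho_solve
    factor = cho_factor(lap)

    def solve(tip_values: np.ndarray) -> np.ndarray:
        tip_values = np.atleast_2d(np.asarray(tip_values, dtype=float))
        return cho_solve(factor, b_mat @ tip_values)

    return internal, solve


def squared_change_parsimony(tree: Phylogeny, traits: TraitMatrix,
                             weighted: bool = True) -> AncestralStateMap:
    """Exact minimum squared-change reconstruction, one trait at a time."""
    tm = traits.reorder(tree.tip_labels)
    internal, solve = scp_linear_system(tree, weighted=weighted)
    interior = solve(tm.traits)
    values: dict[int, np.ndarray] = {}
    for i, tid in enumerate(tree.tip_ids):
        values[tid] = tm.traits[i].copy()
    for i, nid in enumerate(internal):
        values[nid] = interior[i]
    return AncestralStateMap(values=values, tree=tree,
                             trait_names=list(tm.trait_names))


def phylomorphospace(tree: Phylogeny, traits: TraitMatrix,
                     anc: AncestralStateMap | None = None,
                     axes: tuple[int, int] = (0, 1)) -> Phylomorphospace:
    """Node layout on two trait axes with one segment per branch."""
    if anc is None:
        anc = squared_change_parsimony(tree, traits)
    m = traits.n_traits
    for ax in axes:
        if not (0 <= ax < m):
            raise IndexError(f"axis {ax} out of range for {m} traits")
    a1, a2 = axes
    points = {nid: (float(v[a1]), float(v[a2]))
              for nid, v in anc.values.items()}
    segments = [(tree.nodes[cid].parent_id, cid) for cid in tree.branch_ids]
    return Phylomorphospace(points=points, segments=segments, axes=axes)
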