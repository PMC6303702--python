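"""Generators for trees, traits and landmarks with known ground truth.

The flagship scenario mirrors the structure the analysis pipeline expects:
a young ultrametric radiation plus one anciently diverged lineage, three
continuous traits evolved under a two-regime Ornstein-Uhlenbeck process,
and a handful of focal tips scattered across the tree that share the
convergent optimum. Every generator is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from phyloconv.oumodels import RegimePainting
from phyloconv.shapes import LandmarkConfiguration, N_LANDMARKS, TraitMatrix
from phyloconv.treeio import Phylogeny, parse_newick, write_newick_file

__all__ = [
    "SimulationScenario",
    "ScenarioData",
    "simulate_yule_tree",
    "simulate_bm",
    "simulate_hansen",
    "make_convergence_scenario",
    "synthesize_landmarks",
    "write_scenario",
]

SeedLike = Union[int, np.random.Generator, None]


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed (or Generator) is required")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("birth", "end", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.end: Optional[float] = None
        self.children: list["_SimNode"] = []
        self.label = ""


def simulate_yule_tree(n_tips: int, seed: SeedLike,
                       depth_rescale: Optional[float] = 1.0,
                       label_prefix: str = "t") -> Phylogeny:
    """Pure-birth tree (rate 1), rescaled so every tip sits at
    ``depth_rescale``; ``None`` keeps the raw simulation time scale."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _as_rng(seed)
    root = _SimNode(0.0)
    root.end = 0.0
    left, right = _SimNode(0.0), _SimNode(0.0)
    root.children = [left, right]
    active = [left, right]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node = active.pop(i)
        node.end = t
        kids = [_SimNode(t), _SimNode(t)]
        node.children = kids
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.end = t_end
    scale = 1.0 if depth_rescale is None else depth_rescale / t_end
    counter = [0]

    def emit(node: _SimNode) -> str:
        if not node.children:
            counter[0] += 1
            node.label = f"{label_prefix}{counter[0]}"
            return f"{node.label}:{(node.end - node.birth) * scale:.12g}"
        inner = ",".join(emit(c) for c in node.children)
        bl = (node.end - node.birth) * scale
        return f"({inner}):{bl:.12g}"

    newick = emit(root).rsplit(":", 1)[0] + ";"
    return parse_newick(newick)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

def _rate_cholesky(rates) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    if rates.ndim == 0:
        rates = rates.reshape(1)
    if rates.ndim == 1:
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        return np.diag(np.sqrt(rates))
    return np.linalg.cholesky(rates)


def simulate_bm(tree: Phylogeny, rates, root_state=0.0,
                seed: SeedLike = None,
                trait_names: Optional[Sequence[str]] = None) -> TraitMatrix:
    """Brownian tips: child = parent + Normal(0, rate * branch length).

    ``rates`` is a scalar, per-trait vector, or full m x m rate matrix.
    """
    rng = _as_rng(seed)
    chol = _rate_cholesky(rates)
    m = chol.shape[0]
    root_state = np.broadcast_to(np.asarray(root_state, dtype=float), (m,))
    values: dict[int, np.ndarray] = {tree.root_id: root_state.copy()}
    for nid in tree.preorder():
        if nid == tree.root_id:
            continue
        node = tree.nodes[nid]
        step = chol @ rng.standard_normal(m) * np.sqrt(node.branch_length)
        values[nid] = values[node.parent_id] + step
    tips = tree.tip_ids
    return TraitMatrix(tree.tip_labels, np.vstack([values[t] for t in tips]),
                       trait_names)


def simulate_hansen(tree: Phylogeny, painting: RegimePainting, alpha,
                    sigma_sq, theta, seed: SeedLike = None,
                    trait_names: Optional[Sequence[str]] = None,
                    branch_noise_scale: Optional[dict[int, float]] = None
                    ) -> TraitMatrix:
    """OU tips via the exact per-branch transition density.

    child ~ Normal(theta_r + (parent - theta_r) e^{-a t},
                   sigma^2/(2a) (1 - e^{-2a t}))
    with r the branch's regime; the root starts at its regime's optimum.
    ``branch_noise_scale`` multiplies the transition standard deviation on
    selected branches (used to plant extra-tight convergence).
    """
    rng = _as_rng(seed)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    k, m = theta.shape
    if k != painting.n_regimes:
        raise ValueError("theta rows must match number of regimes")
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (m,))
    sigma_sq = np.broadcast_to(np.asarray(sigma_sq, dtype=float), (m,))
    if np.any(alpha <= 0) or np.any(sigma_sq < 0):
        raise ValueError("alpha must be positive, sigma_sq non-negative")
    values = {tree.root_id: theta[painting.root_regime].copy()}
    for nid in tree.preorder():
        if nid == tree.root_id:
            continue
        node = tree.nodes[nid]
        r = painting.regime_of_branch[nid]
        t = node.branch_length
        decay = np.exp(-alpha * t)
        mean = theta[r] + (values[node.parent_id] - theta[r]) * decay
        var = sigma_sq / (2.0 * alpha) * (1.0 - decay ** 2)
        sd = np.sqrt(var)
        if branch_noise_scale is not None:
            sd = sd * branch_noise_scale.get(nid, 1.0)
        values[nid] = mean + sd * rng.standard_normal(m)
    tips = tree.tip_ids
    return TraitMatrix(tree.tip_labels, np.vstack([values[t] for t in tips]),
                       trait_names)


# ---------------------------------------------------------------------------
# Full convergence scenario
# ---------------------------------------------------------------------------

@dataclass
class SimulationScenario:
    """Configuration of the paper-like two-regime convergence scenario."""

    n_tips: int = 57
    tree_depth: float = 12.0          # depth of the young radiation (My)
    outgroup_depth: float = 77.0      # split of the old divergent lineage
    n_traits: int = 3
    n_focal: int = 6
    alpha: float = 3.0                # 1/My, shared across traits
    sigma_sq: float = 0.02            # trait^2/My
    optimum_separation: float = 0.5   # per-trait offset of the shared peak
    focal_noise_scale: float = 0.35   # how tightly focal tips hug the peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outgroup_depth <= self.tree_depth:
            raise ValueError("outgroup split must predate the radiation")
        if not 2 <= self.n_focal <= self.n_tips:
            raise ValueError("focal count out of range")

    @classmethod
    def strong_signal(cls, seed: int = 0, **kw) -> "SimulationScenario":
        return cls(seed=seed, **kw)

    @classmethod
    def weak_signal(cls, seed: int = 0, **kw) -> "SimulationScenario":
        kw.setdefault("alpha", 0.3)
        kw.setdefault("optimum_separation", 0.12)
        kw.setdefault("focal_noise_scale", 1.0)
        return cls(seed=seed, **kw)

    @property
    def stationary_sd(self) -> float:
        return float(np.sqrt(self.sigma_sq / (2.0 * self.alpha)))


@dataclass
class ScenarioData:
    tree: Phylogeny
    traits: TraitMatrix
    focal: list[str]
    painting: RegimePainting
    theta: np.ndarray
    scenario: SimulationScenario


def make_convergence_scenario(config: SimulationScenario) -> ScenarioData:
    """Yule radiation + old divergent lineage, two OU regimes, focal tips.

    The convergent regime is painted on the terminal branch of every focal
    tip (including the whole stem of the old lineage), so the true painting
    has one regime reached by multiple independent origins.
    """
    rng = np.random.default_rng(config.seed)
    ingroup = simulate_yule_tree(config.n_tips - 1, rng,
                                 depth_rescale=config.tree_depth,
                                 label_prefix="sp")
    from phyloconv.treeio import write_newick
    stem = config.outgroup_depth - config.tree_depth
    ingroup_nwk = write_newick(ingroup)[:-1]  # strip ';'
    newick = (f"(outgroup:{config.outgroup_depth:.12g},"
              f"{ingroup_nwk}:{stem:.12g});")
    tree = parse_newick(newick)

    # candidate focal tips need terminal branches long enough for the
    # attraction to act (the regime is painted on the terminal branch only)
    tip_of_all = tree.tip_id_of_label()
    ingroup_tips = [lab for lab in tree.tip_labels if lab != "outgroup"]
    term_bl = np.array([tree.nodes[tip_of_all[lab]].branch_length
                        for lab in ingroup_tips])
    cutoff = np.median(term_bl)
    eligible = [lab for lab, bl in zip(ingroup_tips, term_bl)
                if bl >= cutoff]
    if len(eligible) < config.n_focal - 1:
        eligible = ingroup_tips
    others = rng.choice(len(eligible), size=config.n_focal - 1,
                        replace=False)
    focal = ["outgroup"] + sorted(eligible[i] for i in sorted(others))
    tip_of = tree.tip_id_of_label()
    painting = RegimePainting.from_shifts(
        tree, {tip_of[name]: 1 for name in focal})

    m = config.n_traits
    theta = np.vstack([np.zeros(m),
                       np.full(m, config.optimum_separation)])
    noise = {tip_of[name]: config.focal_noise_scale for name in focal}
    traits = simulate_hansen(tree, painting, config.alpha, config.sigma_sq,
                             theta, rng,
                             trait_names=[f"PC{i+1}" for i in range(m)],
                             branch_noise_scale=noise)
    return ScenarioData(tree=tree, traits=traits, focal=focal,
                        painting=painting, theta=theta, scenario=config)


def write_scenario(data: ScenarioData, outdir) -> dict:
    """Write Newick + trait CSV + JSON truth record; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree_path = outdir / "tree.nwk"
    traits_path = outdir / "traits.csv"
    truth_path = outdir / "truth.json"
    write_newick_file(data.tree, tree_path)
    data.traits.write_csv(traits_path)
    truth = {
        "focal": data.focal,
        "theta": data.theta.tolist(),
        "root_regime": data.painting.root_regime,
        "shift_branches": sorted(data.painting.shift_branches),
        "regime_of_branch": {str(k): v for k, v
                             in data.painting.regime_of_branch.items()},
        "scenario": asdict(data.scenario),
    }
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"tree": str(tree_path), "traits": str(traits_path),
            "truth": str(truth_path)}


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def synthesize_landmarks(mean_shape: np.ndarray, n_specimens: int,
                         shape_noise_sd: float = 0.01,
                         rotation_range: float = np.pi,
                         translation_range: float = 5.0,
                         log_scale_range: float = 0.5,
                         seed: SeedLike = None,
                         species: str = "synthetic",
                         prefix: str = "spec"
                         ) -> list[LandmarkConfiguration]:
    """Mean shape + isotropic noise, then nuisance rotation/translation/scale
    that GPA must remove."""
    if n_specimens < 2:
        raise ValueError("need at least 2 specimens")
    mean_shape = np.asarray(mean_shape, dtype=float)
    if mean_shape.shape != (N_LANDMARKS, 2):
        raise ValueError(f"mean_shape must be ({N_LANDMARKS}, 2)")
    rng = _as_rng(seed)
    out = []
    for i in range(n_specimens):
        coords = mean_shape + rng.normal(0.0, shape_noise_sd,
                                         mean_shape.shape)
        ang = rng.uniform(-rotation_range, rotation_range)
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        scale = np.exp(rng.uniform(-log_scale_range, log_scale_range))
        shift = rng.uniform(-translation_range, translation_range, 2)
        coords = coords @ rot.T * scale + shift
        out.append(LandmarkConfiguration(
            specimen_id=f"{prefix}_{i:03d}", species=species, coords=coords))
    return out
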