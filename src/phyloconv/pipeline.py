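"""End-to-end analysis: shapes -> species means -> SURFACE -> C1-C5 ->
Wheatsheaf, with machine-readable reports shaped like the study tables."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from phyloconv import __version__
from phyloconv.ancestral import phylomorphospace, squared_change_parsimony
from phyloconv.convmetrics import ConvergenceMetrics, convergence_analysis
from phyloconv.oumodels import SurfaceResult, run_surface
from phyloconv.shapes import (
    TraitMatrix,
    gpa,
    pca,
    read_tps,
    species_mean_scores,
)
from phyloconv.treeio import (
    Phylogeny,
    prune_to_taxa,
    read_newick_file,
    write_newick_file,
)
from phyloconv.wheatsheaf import WheatsheafResult, wheatsheaf_test

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis",
           "summarize_tables", "InputError"]

log = logging.getLogger("phyloconv")


class InputError(ValueError):
    """Bad user input (missing taxa, malformed config, ...)."""


@dataclass
class AnalysisConfig:
    tree_path: str
    focal_sets: list[list[str]]
    traits_path: Optional[str] = None    # species x trait CSV
    tps_path: Optional[str] = None       # raw landmarks (alternative input)
    n_components: int = 3
    n_sim: int = 500
    n_boot: int = 1000
    seed: int = 0
    output_dir: Optional[str] = None
    grid_size: int = 24
    axes: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if not self.focal_sets:
            raise InputError("at least one focal set is required")
        if (self.traits_path is None) == (self.tps_path is None):
            raise InputError("provide exactly one of traits_path/tps_path")
        if self.n_sim < 1 or self.n_boot < 1:
            raise InputError("n_sim and n_boot must be >= 1")

    @classmethod
    def from_json(cls, path, **overrides) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "axes" in data:
            data["axes"] = tuple(data["axes"])
        return cls(**data)


@dataclass
class AnalysisReport:
    config: dict
    surface: SurfaceResult
    metrics: list[ConvergenceMetrics]
    wheatsheaf: list[WheatsheafResult]
    pruned_tips: list[str]
    version: str = __version__
    segments: list = field(default_factory=list)

    def to_dict(self) -> dict:
        model_table = {}
        for name in ("ouc", "ounc", "ou1", "bm"):
            fit = self.surface.fits[name]
            model_table[name] = {
                "loglik": fit.loglik,
                "p": fit.n_params,
                "aicc": fit.aicc,
            }
        return {
            "provenance": {"config": self.config, "version": self.version,
                           "pruned_tips": self.pruned_tips},
            "models": model_table,
            "surface": self.surface.to_dict(),
            "painting": {str(k): v for k, v in
                         self.surface.painting.regime_of_branch.items()},
            "focal_results": [
                {**m.to_dict(), "wheatsheaf": w.to_dict()}
                for m, w in zip(self.metrics, self.wheatsheaf)
            ],
        }


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2fs", name,
                     time.perf_counter() - self.t0)

    return _Timer()


def _load_traits(config: AnalysisConfig) -> TraitMatrix:
    if config.traits_path is not None:
        return TraitMatrix.read_csv(config.traits_path)
    configs = read_tps(config.tps_path)
    with _stage("gpa"):
        aligned = gpa(configs)
    with _stage("pca"):
        pc = pca(aligned)
    return species_mean_scores(pc, pc.species, config.n_components)


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Deterministic full pipeline; writes report files when output_dir set."""
    tree = read_newick_file(config.tree_path)
    traits = _load_traits(config)

    species = set(traits.species)
    tips = set(tree.tip_labels)
    missing = sorted(species - tips)
    if missing:
        raise InputError(f"species absent from the tree: {missing}")
    pruned = sorted(tips - species)
    if pruned:
        log.info("pruning %d tips without trait data: %s",
                 len(pruned), pruned)
        tree = prune_to_taxa(tree, species)
    for fs in config.focal_sets:
        bad = sorted(set(fs) - species)
        if bad:
            raise InputError(f"focal taxa without trait data: {bad}")

    with _stage("surface"):
        surface = run_surface(tree, traits, grid_size=config.grid_size)

    with _stage("phylomorphospace"):
        anc = squared_change_parsimony(tree, traits)
        pms = phylomorphospace(tree, traits, anc, axes=config.axes)

    rng = np.random.default_rng(config.seed)
    stage_seeds = rng.integers(0, 2 ** 31 - 1, size=2 * len(config.focal_sets))
    metrics, wheat = [], []
    for i, fs in enumerate(config.focal_sets):
        with _stage(f"cmetrics[{i}]"):
            metrics.append(convergence_analysis(
                tree, traits, fs, axes=config.axes, n_sim=config.n_sim,
                seed=int(stage_seeds[2 * i])))
        with _stage(f"wheatsheaf[{i}]"):
            wheat.append(wheatsheaf_test(
                tree, traits, fs, n_boot=config.n_boot,
                seed=int(stage_seeds[2 * i + 1])))

    segments = [
        {"parent": p, "child": c,
         "x0": pms.points[p][0], "y0": pms.points[p][1],
         "x1": pms.points[c][0], "y1": pms.points[c][1]}
        for p, c in pms.segments
    ]
    report = AnalysisReport(config=asdict(config), surface=surface,
                            metrics=metrics, wheatsheaf=wheat,
                            pruned_tips=pruned, segments=segments)

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        t1, t2 = summarize_tables(report)
        (outdir / "model_table.tsv").write_text(t1)
        (outdir / "convergence_table.tsv").write_text(t2)
        write_newick_file(tree, outdir / "pruned_tree.nwk")
        with open(outdir / "phylomorphospace_segments.tsv", "w") as fh:
            fh.write("parent\tchild\tx0\ty0\tx1\ty1\n")
            for s in segments:
                fh.write(f"{s['parent']}\t{s['child']}\t{s['x0']:.10g}\t"
                         f"{s['y0']:.10g}\t{s['x1']:.10g}\t{s['y1']:.10g}\n")
    return report


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{x:.8g}"


def summarize_tables(report: AnalysisReport) -> tuple[str, str]:
    """(model table TSV, convergence table TSV) at 8 significant digits."""
    sr = report.surface
    lines1 = ["parameter\touc\tounc\tou1\tbm"]
    books = {
        "k": (sr.k, len(sr.fits["ounc"].painting.shift_branches) + 1, 1, 0),
        "k_prime": (sr.k_prime, sr.fits["ounc"].painting.n_regimes, 1, 0),
    }
    lines1.append("k\t" + "\t".join(_fmt(v) for v in books["k"]))
    lines1.append("k_prime\t" + "\t".join(_fmt(v) for v in books["k_prime"]))
    lines1.append(f"delta_k\t{_fmt(sr.delta_k)}\t0\t0\t0")
    lines1.append(f"c\t{_fmt(sr.c)}\t0\t0\t0")
    lines1.append(f"k_conv\t{_fmt(sr.k_conv)}\t0\t0\t0")
    lines1.append(f"k_nonconv\t{_fmt(sr.k_nonconv)}\t"
                  f"{_fmt(sr.fits['ounc'].painting.n_regimes)}\t1\t0")
    lines1.append("aicc\t" + "\t".join(
        _fmt(v) for v in (sr.aicc_ouc, sr.aicc_ounc, sr.aicc_ou1,
                          sr.aicc_bm)))

    lines2 = ["focal\tc1\tp1\tc2\tp2\tc3\tp3\tc4\tp4\tc5\tp5\t"
              "wheatsheaf_index\tlower_95_ci\tupper_95_ci\tp_value"]
    for m, w in zip(report.metrics, report.wheatsheaf):
        row = [",".join(m.focal)]
        for val in (m.c1, m.p1, m.c2, m.p2, m.c3, m.p3, m.c4, m.p4,
                    m.c5, m.p5, w.w, w.ci_low, w.ci_high, w.p):
            row.append(_fmt(val))
        lines2.append("\t".join(row))
    return "\n".join(lines1) + "\n", "\n".join(lines2) + "\n"
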