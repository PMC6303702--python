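"""Landmark ingestion, Generalized Procrustes superimposition and PCA.

Configurations carry exactly ``N_LANDMARKS`` 2-D landmarks. GPA is the
full-Procrustes variant: every configuration is centred and scaled to unit
centroid size at each iteration and rotated (no reflection) onto the running
consensus. PCA is the covariance eigendecomposition of flattened deviations
from the consensus; eigenvector signs are fixed so the largest-magnitude
loading of each component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

N_LANDMARKS = 10

__all__ = [
    "N_LANDMARKS",
    "ShapeError",
    "TPSFormatError",
    "LandmarkConfiguration",
    "AlignedShapes",
    "PCResult",
    "TraitMatrix",
    "read_tps",
    "write_tps",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "pca",
    "species_mean_scores",
]


class ShapeError(ValueError):
    """Degenerate or invalid landmark data."""


class TPSFormatError(ShapeError):
    """Malformed TPS record."""


@dataclass
class LandmarkConfiguration:
    specimen_id: str
    species: str
    coords: np.ndarray  # (N_LANDMARKS, 2)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ShapeError(
                f"expected {N_LANDMARKS} (x, y) landmarks, got shape "
                f"{self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ShapeError("non-finite landmark coordinate")


@dataclass
class AlignedShapes:
    consensus: np.ndarray          # (N_LANDMARKS, 2), centred, unit size
    aligned: np.ndarray            # (n, N_LANDMARKS, 2)
    centroid_sizes: np.ndarray     # (n,) original sizes
    specimen_ids: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)
    n_iterations: int = 0


@dataclass
class PCResult:
    eigenvalues: np.ndarray   # non-increasing, >= 0
    proportions: np.ndarray   # sum to 1
    scores: np.ndarray        # (n_specimens, n_components)
    loadings: np.ndarray      # (n_components, 2 * N_LANDMARKS)
    specimen_ids: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)


class TraitMatrix:
    """Species x continuous-trait table aligned to tree tips on demand."""

    def __init__(self, species: Sequence[str], traits,
                 trait_names: Optional[Sequence[str]] = None):
        self.species = list(species)
        self.traits = np.atleast_2d(np.asarray(traits, dtype=float))
        if self.traits.shape[0] != len(self.species):
            raise ValueError("traits row count != number of species")
        if not np.all(np.isfinite(self.traits)):
            raise ValueError("missing or non-finite trait values")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        m = self.traits.shape[1]
        self.trait_names = (list(trait_names) if trait_names is not None
                            else [f"PC{i + 1}" for i in range(m)])
        if len(self.trait_names) != m:
            raise ValueError("trait_names length mismatch")

    @property
    def n_traits(self) -> int:
        return self.traits.shape[1]

    def row(self, species: str) -> np.ndarray:
        return self.traits[self.species.index(species)]

    def reorder(self, species_order: Sequence[str]) -> "TraitMatrix":
        idx = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species_order if s not in idx]
        if missing:
            raise KeyError(f"species not in trait table: {missing}")
        rows = [idx[s] for s in species_order]
        return TraitMatrix(list(species_order), self.traits[rows],
                           self.trait_names)

    def subset_traits(self, indices: Sequence[int]) -> "TraitMatrix":
        return TraitMatrix(self.species, self.traits[:, list(indices)],
                           [self.trait_names[i] for i in indices])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.traits, index=self.species,
                            columns=self.trait_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TraitMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float), list(df.columns))

    @classmethod
    def read_csv(cls, path) -> "TraitMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))

    def write_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "species"
        df.to_csv(path)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<TraitMatrix {len(self.species)} species x "
                f"{self.n_traits} traits>")


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------

def read_tps(path) -> list[LandmarkConfiguration]:
    """Read LM=/ID=/SCALE= records; SCALE multiplies coordinates."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]

    configs: list[LandmarkConfiguration] = []
    i, record_idx = 0, 0
    while i < len(lines):
        if not lines[i]:
            i += 1
            continue
        if not lines[i].upper().startswith("LM="):
            raise TPSFormatError(
                f"record {record_idx}: expected 'LM=' line, got {lines[i]!r}")
        try:
            n_lm = int(lines[i].split("=", 1)[1])
        except ValueError as exc:
            raise TPSFormatError(f"record {record_idx}: bad LM count") from exc
        if n_lm != N_LANDMARKS:
            raise TPSFormatError(
                f"record {record_idx}: LM={n_lm}, expected {N_LANDMARKS}")
        i += 1
        coords = []
        for k in range(n_lm):
            if i >= len(lines):
                raise TPSFormatError(f"record {record_idx}: truncated record")
            parts = lines[i].split()
            if len(parts) != 2:
                raise TPSFormatError(
                    f"record {record_idx}, landmark {k + 1}: expected "
                    f"'x y', got {lines[i]!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSFormatError(
                    f"record {record_idx}, landmark {k + 1}: "
                    f"non-numeric coordinate {lines[i]!r}") from exc
            i += 1
        specimen_id, species, scale = f"spec{record_idx}", "", 1.0
        while i < len(lines) and lines[i] and \
                not lines[i].upper().startswith("LM="):
            key, _, value = lines[i].partition("=")
            key = key.strip().upper()
            if key == "ID":
                specimen_id = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TPSFormatError(
                        f"record {record_idx}: bad SCALE {value!r}") from exc
            elif key == "SPECIES":
                species = value.strip()
            # IMAGE=, COMMENT= etc. ignored
            i += 1
        arr = np.asarray(coords) * scale
        if species == "":
            # convention: specimen ids like "Genus_species_03"
            species = "_".join(specimen_id.split("_")[:-1]) or specimen_id
        configs.append(LandmarkConfiguration(specimen_id, species, arr))
        record_idx += 1
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cfg in configs:
            fh.write(f"LM={N_LANDMARKS}\n")
            for x, y in cfg.coords:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={cfg.specimen_id}\n")
            if cfg.species:
                fh.write(f"SPECIES={cfg.species}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Procrustes machinery
# ---------------------------------------------------------------------------

def centroid_size(config) -> float:
    """sqrt of summed squared landmark distances to the centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) \
        else np.asarray(config, dtype=float)
    centred = coords - coords.mean(axis=0)
    size = float(np.sqrt((centred ** 2).sum()))
    if size <= 0.0:
        raise ShapeError("degenerate configuration: all landmarks coincide")
    return size


def _unitize(coords: np.ndarray) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    return centred / centroid_size(centred)


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||source @ R - target||_F."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def gpa(configs: Sequence[LandmarkConfiguration], tol: float = 1e-10,
        max_iter: int = 1000) -> AlignedShapes:
    """Generalized Procrustes superimposition of >= 2 configurations."""
    if len(configs) < 2:
        raise ShapeError("GPA needs at least 2 configurations")
    sizes = np.array([centroid_size(c) for c in configs])
    shapes = np.stack([_unitize(c.coords) for c in configs])
    consensus = shapes[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(shapes.shape[0]):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = _unitize(shapes.mean(axis=0))
        change = float(np.abs(new_consensus - consensus).max())
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise ShapeError(
            f"GPA did not converge after {max_iter} iterations "
            f"(last consensus change {change:.3e})")
    # final alignment onto the converged consensus
    for i in range(shapes.shape[0]):
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
    return AlignedShapes(
        consensus=consensus,
        aligned=shapes,
        centroid_sizes=sizes,
        specimen_ids=[c.specimen_id for c in configs],
        species=[c.species for c in configs],
        n_iterations=n_iter,
    )


def procrustes_distance(a, b) -> float:
    """Full Procrustes distance after optimal translation/scale/rotation.

    Zero iff the two shapes are identical up to a similarity transform
    (without reflection).
    """
    x = _unitize(a.coords if isinstance(a, LandmarkConfiguration) else a)
    y = _unitize(b.coords if isinstance(b, LandmarkConfiguration) else b)
    rot = _optimal_rotation(y, x)
    yr = y @ rot
    scale = float(np.sum(yr * x))  # optimal scaling of yr onto x
    return float(np.linalg.norm(scale * yr - x))


# ---------------------------------------------------------------------------
# PCA and species means
# ---------------------------------------------------------------------------

def pca(aligned: AlignedShapes) -> PCResult:
    """Covariance PCA of flattened deviations from the consensus."""
    n = aligned.aligned.shape[0]
    if n < 3:
        raise ShapeError("PCA needs at least 3 specimens")
    dev = (aligned.aligned - aligned.consensus).reshape(n, -1)
    dev = dev - dev.mean(axis=0)  # centre (consensus is mean up to tol)
    u, s, vt = np.linalg.svd(dev, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    keep = eigenvalues > max(1e-12 * eigenvalues[0], 0.0) if \
        eigenvalues.size and eigenvalues[0] > 0 else slice(0)
    eigenvalues = eigenvalues[keep]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    total = eigenvalues.sum()
    proportions = eigenvalues / total if total > 0 else eigenvalues
    return PCResult(eigenvalues=eigenvalues, proportions=proportions,
                    scores=scores, loadings=vt,
                    specimen_ids=list(aligned.specimen_ids),
                    species=list(aligned.species))


def species_mean_scores(pc: PCResult, species_of_specimen: Sequence[str],
                        n_components: int = 3) -> TraitMatrix:
    """Per-species arithmetic mean of the first ``n_components`` scores."""
    species_of_specimen = list(species_of_specimen)
    if len(species_of_specimen) != pc.scores.shape[0]:
        raise ValueError("one species label per specimen required")
    if n_components > pc.scores.shape[1]:
        raise ValueError(
            f"requested {n_components} components, only "
            f"{pc.scores.shape[1]} available")
    order: list[str] = []
    for sp in species_of_specimen:
        if sp not in order:
            order.append(sp)
    rows = []
    for sp in order:
        mask = np.array([s == sp for s in species_of_specimen])
        rows.append(pc.scores[mask, :n_components].mean(axis=0))
    return TraitMatrix(order, np.vstack(rows),
                       [f"PC{i + 1}" for i in range(n_components)])
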