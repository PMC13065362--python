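"""Activation threshold surfaces and their geometry.

The threshold surface of a cell is the set of amplitude combinations at
which it spikes with 50% probability. Its shape diagnoses the mode of
current summation: a single linear site yields a planar surface (a pair of
planes once both pulse polarities activate), whereas several reachable
spike-initiation sites bend the surface into curved or closed shapes.
Surfaces are extracted by linear interpolation along grid edges whose
endpoint probabilities straddle the level, and the planarity score
quantifies how far each connected sheet departs from its best-fit plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .linear_or import noisy_or_probability
from .stimulus import ResponseDataset, StimulusGrid, ValidationError

__all__ = [
    "ThresholdSurface",
    "intermediate_points",
    "level_set",
    "planarity_score",
]


def intermediate_points(dataset: ResponseDataset) -> list[tuple[np.ndarray, float]]:
    """Records with intermediate empirical probability 0 < P < 1.

    These are the stimuli that resolve the stochastic transition band of the
    threshold surface (deterministic 0s and 1s carry no shape information
    beyond which side they lie on).
    """
    p = dataset.probabilities
    keep = np.flatnonzero((p > 0) & (p < 1))
    return [(dataset.X[j], float(p[j])) for j in keep]


@dataclass
class ThresholdSurface:
    """Iso-probability crossing points on a stimulus grid."""

    points: np.ndarray           # (n_points, E) μA
    grid: StimulusGrid
    source: str = "linear_or"    # empirical | linear_or | gp
    level: float = 0.5
    linkage_factor: float = 1.5  # neighbour radius in units of the grid step

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    def __len__(self) -> int:
        return 0 if self.points.size == 0 else self.points.shape[0]

    def component_labels(self) -> np.ndarray:
        """Connected-component label per point (grid-neighbour linkage)."""
        n = len(self)
        if n == 0:
            return np.array([], dtype=int)
        radius = self.linkage_factor * self.grid.step
        tree = cKDTree(self.points)
        pairs = np.array(sorted(tree.query_pairs(radius)), dtype=int)
        if pairs.size == 0:
            return np.arange(n)
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(n, n))
        _, labels = connected_components(adj, directed=False)
        return labels

    @property
    def n_components(self) -> int:
        labels = self.component_labels()
        return int(labels.max()) + 1 if labels.size else 0

    def to_frame(self) -> pd.DataFrame:
        cols = {f"amp_uA_{k + 1}": self.points[:, k]
                for k in range(self.points.shape[1])}
        cols["component"] = self.component_labels()
        return pd.DataFrame(cols)


def _grid_probabilities(source, grid: StimulusGrid) -> np.ndarray:
    """Probability per grid vector from a model, dataset, or raw vector."""
    if hasattr(source, "biases") and hasattr(source, "weights"):
        return noisy_or_probability(source.biases, source.weights, grid.X)
    if isinstance(source, ResponseDataset):
        if len(source) != len(grid) or not np.allclose(source.X, grid.X):
            raise ValidationError(
                "empirical level sets need a dataset covering the full grid "
                "in grid order")
        return source.probabilities
    p = np.asarray(source, dtype=float).ravel()
    if p.size != len(grid):
        raise ValidationError("probability vector does not match the grid")
    return p


def level_set(source, grid: StimulusGrid, level: float = 0.5,
              source_tag: str | None = None) -> ThresholdSurface:
    """Extract the iso-probability surface by grid-edge interpolation.

    ``source`` may be a fitted model / synthetic neuron (anything with
    ``biases`` and ``weights``), a :class:`ResponseDataset` covering the
    grid, or a bare probability vector in grid order. For every grid edge
    whose endpoint probabilities straddle ``level``, the linearly
    interpolated crossing point is emitted. Deterministic; an empty surface
    (no crossing anywhere) is returned with a warning.
    """
    p = _grid_probabilities(source, grid)
    shape = grid.shape
    P = p.reshape(shape)
    A = grid.X.reshape(shape + (grid.n_electrodes,))
    points = []
    for axis in range(grid.n_electrodes):
        lo = tuple(slice(0, -1) if a == axis else slice(None)
                   for a in range(grid.n_electrodes))
        hi = tuple(slice(1, None) if a == axis else slice(None)
                   for a in range(grid.n_electrodes))
        p1, p2 = P[lo], P[hi]
        cross = ((p1 - level) * (p2 - level) < 0) | (p1 == level)
        if not cross.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p2 != p1, (level - p1) / (p2 - p1), 0.0)
        x1, x2 = A[lo][cross], A[hi][cross]
        points.append(x1 + t[cross, None] * (x2 - x1))
    if source_tag is None:
        source_tag = ("empirical" if isinstance(source, ResponseDataset)
                      or not hasattr(source, "biases") else "linear_or")
    if not points:
        warnings.warn(f"no grid edge crosses level {level}; empty surface",
                      stacklevel=2)
        pts = np.empty((0, grid.n_electrodes))
    else:
        pts = np.unique(np.concatenate(points).round(12), axis=0)
    return ThresholdSurface(points=pts, grid=grid, source=source_tag,
                            level=level)


def planarity_score(surface: ThresholdSurface, min_points: int = 4) -> float:
    """How non-planar the surface is: 0 means every sheet is a plane.

    Each connected component with ≥ ``min_points`` points gets a total
    least-squares plane (via SVD); the score is the maximum over components
    of the RMS orthogonal distance to that plane, normalised by the grid's
    amplitude span. A single-site (logistic) model scores ~0; multi-site
    neurons with curved surfaces score well above it.
    """
    if len(surface) < min_points:
        raise ValidationError(
            f"need at least {min_points} surface points, got {len(surface)}")
    labels = surface.component_labels()
    span = surface.grid.amp_max - surface.grid.amp_min
    scores = []
    for c in np.unique(labels):
        pts = surface.points[labels == c]
        if pts.shape[0] < min_points:
            continue
        centred = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centred, compute_uv=False)
        rms = sv[-1] / np.sqrt(pts.shape[0])
        scores.append(rms / span)
    if not scores:
        raise ValidationError(
            f"no connected component has ≥ {min_points} points")
    return float(max(scores))
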