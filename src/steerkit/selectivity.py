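"""Selectivity statistics for populations under multi-electrode stimulation.

The selectivity index of stimulus x for target cell i among cells c_1..c_K is

    S_{i,x} = p_{i,x} · (1 − max_{j≠i} p_{j,x})

— the probability the target fires times the probability the worst-case
non-target stays silent (under independence); 1 means perfect selectivity.
The aggregate index S_x treats the most activatable cell at x as the target,
giving the best selectivity any cell can achieve with that stimulus; its
landscape over the stimulus grid is the object the closed-loop calibration
searches. Landscapes are modelled in logit (log-odds) units, so empirical
values of exactly 0 or 1 are clipped by ε before the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimulus import StimulusGrid, ValidationError

__all__ = [
    "ProbabilityProfile",
    "SelectivityLandscape",
    "selectivity_index",
    "aggregate_selectivity",
    "logit",
    "inverse_logit",
    "landscape",
    "best_selectivity",
]


def selectivity_index(p_target: float, p_nontargets) -> float:
    """S = p_target · (1 − max non-target probability).

    An empty non-target collection gives S = p_target (the max over the
    empty set is taken as 0, the K=1 convention).
    """
    p_nontargets = np.asarray(p_nontargets, dtype=float).ravel()
    probs = np.concatenate([[p_target], p_nontargets])
    if np.any((probs < 0) | (probs > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    worst = p_nontargets.max() if p_nontargets.size else 0.0
    return float(p_target * (1.0 - worst))


def aggregate_selectivity(probs) -> tuple[float, int]:
    """Best achievable selectivity at one stimulus, over all target choices.

    The target is the most activatable cell, argmax_i p_i (ties broken
    toward the lowest index; the S value itself is tie-invariant). Returns
    ``(S, target_index)``; a single cell gives ``(p_1, 0)``.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    if probs.size < 1:
        raise ValidationError("need at least one cell")
    if np.any((probs < 0) | (probs > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    target = int(np.argmax(probs))
    others = np.delete(probs, target)
    worst = others.max() if others.size else 0.0
    return float(probs[target] * (1.0 - worst)), target


def logit(p, eps: float = 1e-3) -> np.ndarray | float:
    """log(p'/(1−p')) with p' = clip(p, ε, 1−ε); maps [0,1] onto the reals.

    ε guards empirical probabilities that are exactly 0 or 1 (inevitable
    with ~20 trials). A sensible default for trial data is 1/(2·T̄).
    """
    if not 0 < eps < 0.5:
        raise ValidationError("eps must lie in (0, 0.5)")
    p_arr = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    out = np.log(p_arr / (1.0 - p_arr))
    return float(out) if np.isscalar(p) else out


def inverse_logit(y) -> np.ndarray | float:
    """Sigmoid: inverse of :func:`logit` on [ε, 1−ε]."""
    y_arr = np.asarray(y, dtype=float)
    out = 1.0 / (1.0 + np.exp(-y_arr))
    return float(out) if np.isscalar(y) else out


@dataclass
class ProbabilityProfile:
    """Per-cell activation probabilities over one stimulus grid.

    ``probs`` maps cell_id → vector over ``grid`` rows; values may come from
    empirical trial fractions or from model predictions — ``source`` records
    which (e.g. ``"empirical"``, ``"linear_or"``, ``"gp"``).
    """

    grid: StimulusGrid
    probs: dict[str, np.ndarray]
    source: str = "empirical"

    def __post_init__(self) -> None:
        n = len(self.grid)
        clean = {}
        for cid, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (n,):
                raise ValidationError(
                    f"cell {cid!r}: probability vector length {p.shape} != grid {n}")
            if np.any((p < 0) | (p > 1)):
                raise ValidationError(f"cell {cid!r}: probabilities outside [0, 1]")
            clean[cid] = p
        self.probs = clean
        if not clean:
            raise ValidationError("profile needs at least one cell")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.probs)

    def matrix(self) -> np.ndarray:
        """(K, N) probability matrix in cell_id order."""
        return np.stack([self.probs[c] for c in self.cell_ids])


@dataclass
class SelectivityLandscape:
    """Aggregate selectivity over a grid, with per-stimulus best target."""

    grid: StimulusGrid
    s_values: np.ndarray
    best_cell: list[str]
    eps: float = 1e-3
    source: str = "empirical"
    logit_values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.s_values = np.asarray(self.s_values, dtype=float)
        if np.any((self.s_values < 0) | (self.s_values > 1)):
            raise ValidationError("selectivity values must lie in [0, 1]")
        self.logit_values = logit(self.s_values, eps=self.eps)

    def __len__(self) -> int:
        return len(self.s_values)

    @property
    def max(self) -> float:
        return float(self.s_values.max())

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.s_values))

    def to_frame(self) -> pd.DataFrame:
        cols = {f"amp_uA_{k + 1}": self.grid.X[:, k]
                for k in range(self.grid.X.shape[1])}
        cols["s_value"] = self.s_values
        cols["logit_s"] = self.logit_values
        cols["best_cell"] = self.best_cell
        return pd.DataFrame(cols)


def landscape(profile: ProbabilityProfile, eps: float = 1e-3) -> SelectivityLandscape:
    """Aggregate-selectivity landscape: S_x applied at every grid vector."""
    P = profile.matrix()  # (K, N)
    K, N = P.shape
    targets = np.argmax(P, axis=0)  # ties → lowest index, numpy convention
    p_t = P[targets, np.arange(N)]
    if K == 1:
        s = p_t.copy()
    else:
        masked = P.copy()
        masked[targets, np.arange(N)] = -np.inf
        worst = masked.max(axis=0)
        s = p_t * (1.0 - worst)
    ids = profile.cell_ids
    return SelectivityLandscape(grid=profile.grid, s_values=s,
                                best_cell=[ids[t] for t in targets],
                                eps=eps, source=profile.source)


def best_selectivity(profile: ProbabilityProfile, target: str,
                     restrict: StimulusGrid | None = None) -> tuple[float, np.ndarray]:
    """Maximum selectivity for one target cell, and the stimulus achieving it.

    ``restrict`` limits the search to a sub-grid (e.g. an axis subset for
    the single-electrode comparison); it must carry ``parent_indices`` into
    the profile's grid. Because axis subsets are subsets of the full grid,
    the full-grid (triplet) maximum is always ≥ any single-electrode maximum.
    """
    if target not in profile.probs:
        raise ValidationError(f"unknown target cell {target!r}")
    P = profile.matrix()
    ids = profile.cell_ids
    ti = ids.index(target)
    others = np.delete(P, ti, axis=0)
    worst = others.max(axis=0) if others.shape[0] else np.zeros(P.shape[1])
    s = P[ti] * (1.0 - worst)
    if restrict is not None:
        if restrict.parent_indices is None:
            raise ValidationError("restrict grid must carry parent_indices")
        idx = restrict.parent_indices
        j = idx[int(np.argmax(s[idx]))]
    else:
        j = int(np.argmax(s))
    return float(s[j]), profile.grid.X[j]
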