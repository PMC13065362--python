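"""Stimulus vectors, amplitude grids, and stimulation-response records.

A stimulus is a vector of signed second-phase current amplitudes (μA), one
per stimulating electrode: negative values are cathodic-peak pulses, positive
values anodic-peak. The triphasic pulse shape (relative phase amplitudes,
phase duration) is carried as metadata only — every model in this package
operates on the amplitude vector alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PulseShape",
    "StimulusGrid",
    "ResponseRecord",
    "ResponseDataset",
    "build_grid",
    "axis_subsets",
    "read_dataset",
    "write_dataset",
]

#: Default amplitude ceiling (μA) used for validation.
DEFAULT_MAX_AMPLITUDE_UA = 1.8


class ValidationError(ValueError):
    """Raised when a stimulus, grid, or dataset violates its invariants."""


@dataclass(frozen=True)
class PulseShape:
    """Charge-balanced triphasic pulse metadata.

    The default is the anodal/cathodal/anodal 2:−3:1 shape with 50 μs
    phases. Never enters any computation; recorded so files are
    self-describing.
    """

    relative_phase_amplitudes: tuple[float, ...] = (2.0, -3.0, 1.0)
    phase_duration_us: float = 50.0

    def __post_init__(self) -> None:
        charge = sum(self.relative_phase_amplitudes) * self.phase_duration_us
        if abs(charge) > 1e-9:
            raise ValidationError(
                f"pulse is not charge-balanced: net relative charge {charge}"
            )


def validate_current_vector(x, n_electrodes: int | None = None,
                            max_amplitude: float = DEFAULT_MAX_AMPLITUDE_UA) -> np.ndarray:
    """Coerce ``x`` to a 1-D float array of amplitudes (μA) and validate it."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValidationError("current vector must be 1-D with at least one electrode")
    if n_electrodes is not None and x.size != n_electrodes:
        raise ValidationError(
            f"current vector has {x.size} electrodes, expected {n_electrodes}"
        )
    if np.any(np.abs(x) > max_amplitude * (1 + 1e-12)):
        raise ValidationError(
            f"amplitude exceeds ±{max_amplitude} μA: {x}"
        )
    return x


@dataclass(frozen=True)
class StimulusGrid:
    """An ordered set of stimulus amplitude vectors.

    A *full* grid is the Cartesian product of ``n_levels`` linearly spaced
    amplitudes per electrode (endpoints included), ordered lexicographically
    by electrode index (electrode 0 varies slowest). ``axis_subsets``
    produces restricted grids that share the parent's metadata but hold only
    a subset of vectors; ``parent_indices`` maps those rows back into the
    parent ordering.
    """

    n_electrodes: int
    n_levels: int
    amp_min: float
    amp_max: float
    X: np.ndarray  # (n_stimuli, n_electrodes) signed amplitudes, μA
    pulse: PulseShape = field(default=PulseShape())
    full: bool = True
    parent_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.ndim != 2 or X.shape[1] != self.n_electrodes:
            raise ValidationError("grid X must be (n_stimuli, n_electrodes)")
        if self.full and X.shape[0] != self.n_levels ** self.n_electrodes:
            raise ValidationError(
                "full grid must contain n_levels**n_electrodes vectors"
            )

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def levels(self) -> np.ndarray:
        """The per-electrode amplitude levels (μA), ascending."""
        return np.linspace(self.amp_min, self.amp_max, self.n_levels)

    @property
    def step(self) -> float:
        """Spacing between adjacent levels (μA)."""
        return (self.amp_max - self.amp_min) / (self.n_levels - 1)

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.n_levels,) * self.n_electrodes

    def to_json(self, path) -> None:
        payload = {
            "n_electrodes": self.n_electrodes,
            "n_levels": self.n_levels,
            "amp_min_uA": self.amp_min,
            "amp_max_uA": self.amp_max,
            "pulse": {
                "ratios": list(self.pulse.relative_phase_amplitudes),
                "phase_us": self.pulse.phase_duration_us,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "StimulusGrid":
        payload = json.loads(Path(path).read_text())
        pulse = PulseShape(
            tuple(payload.get("pulse", {}).get("ratios", (2.0, -3.0, 1.0))),
            payload.get("pulse", {}).get("phase_us", 50.0),
        )
        return build_grid(
            payload["n_electrodes"],
            payload["n_levels"],
            payload["amp_min_uA"],
            payload["amp_max_uA"],
            pulse=pulse,
        )


def build_grid(n_electrodes: int, n_levels: int, amp_min: float, amp_max: float,
               pulse: PulseShape | None = None) -> StimulusGrid:
    """Build the full lattice of ``n_levels**n_electrodes`` stimulus vectors.

    Levels are linearly spaced inclusive of both endpoints; vectors are
    ordered lexicographically by electrode index, so electrode 0 varies
    slowest. The standard three-electrode protocol is
    ``build_grid(3, 20, -1.8, 1.8)`` — 8000 amplitude combinations.
    """
    if n_electrodes < 1:
        raise ValidationError("n_electrodes must be ≥ 1")
    if n_levels < 2:
        raise ValidationError("n_levels must be ≥ 2")
    if not amp_min < amp_max:
        raise ValidationError("amp_min must be < amp_max")
    levels = np.linspace(amp_min, amp_max, n_levels)
    mesh = np.meshgrid(*([levels] * n_electrodes), indexing="ij")
    X = np.stack([m.ravel() for m in mesh], axis=1)
    return StimulusGrid(
        n_electrodes=n_electrodes,
        n_levels=n_levels,
        amp_min=amp_min,
        amp_max=amp_max,
        X=X,
        pulse=pulse if pulse is not None else PulseShape(),
    )


def axis_subsets(grid: StimulusGrid, zero_tol: float | None = None) -> list[StimulusGrid]:
    """Single-electrode sub-grids: vectors that are "off" on all but one axis.

    With an odd number of levels the grid contains an exact 0 level and
    "off" means exactly zero. A symmetric grid with an even number of levels
    (the standard 20-level protocol) has no zero level; the off-electrode
    amplitude is then matched to the level nearest 0, with ties between ±
    broken toward the cathodic (negative) level. Passing ``zero_tol``
    overrides this with an explicit |amplitude| ≤ zero_tol test.

    Returns one restricted :class:`StimulusGrid` per electrode, each with
    ``parent_indices`` into ``grid.X``.
    """
    levels = grid.levels
    if zero_tol is None:
        # level nearest 0; tie toward the negative (cathodic) branch
        order = np.lexsort((levels, np.abs(levels)))
        off_value = levels[order[0]]
        off_mask = np.isclose(grid.X, off_value, rtol=0, atol=1e-12)
    else:
        off_mask = np.abs(grid.X) <= zero_tol
    subsets = []
    for k in range(grid.n_electrodes):
        others = [j for j in range(grid.n_electrodes) if j != k]
        sel = np.all(off_mask[:, others], axis=1) if others else np.ones(len(grid), bool)
        idx = np.flatnonzero(sel)
        subsets.append(
            StimulusGrid(
                n_electrodes=grid.n_electrodes,
                n_levels=grid.n_levels,
                amp_min=grid.amp_min,
                amp_max=grid.amp_max,
                X=grid.X[idx],
                pulse=grid.pulse,
                full=False,
                parent_indices=idx,
            )
        )
    return subsets


@dataclass(frozen=True)
class ResponseRecord:
    """One stimulus with its trial and spike counts."""

    stimulus: np.ndarray
    trials: int
    spikes: int

    def __post_init__(self) -> None:
        if not 0 <= self.spikes <= self.trials:
            raise ValidationError(
                f"spikes ({self.spikes}) must lie in [0, trials={self.trials}]"
            )

    @property
    def probability(self) -> float:
        return self.spikes / self.trials


@dataclass
class ResponseDataset:
    """Stimulation-response data for one cell over a stimulus grid.

    Holds parallel arrays: ``X`` (stimuli, μA), ``trials`` and ``spikes``
    (counts). ``probabilities`` is exactly spikes/trials. ``grid`` records
    the lattice the stimuli came from (the stimuli need not cover it).
    """

    cell_id: str
    grid: StimulusGrid
    X: np.ndarray
    trials: np.ndarray
    spikes: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.trials = np.asarray(self.trials, dtype=int)
        self.spikes = np.asarray(self.spikes, dtype=int)
        n = self.X.shape[0]
        if self.trials.shape != (n,) or self.spikes.shape != (n,):
            raise ValidationError("X, trials, spikes must have matching lengths")
        bad = np.flatnonzero((self.spikes < 0) | (self.spikes > self.trials)
                             | (self.trials < 1))
        if bad.size:
            raise ValidationError(
                f"row {bad[0]}: spikes must lie in [0, trials] with trials ≥ 1"
            )
        if n:
            uniq = np.unique(self.X.round(12), axis=0)
            if uniq.shape[0] != n:
                raise ValidationError("duplicate stimulus rows in dataset")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        return self.spikes / self.trials

    @property
    def total_stimulations(self) -> int:
        """Total number of individual stimulations Σⱼ Tⱼ."""
        return int(self.trials.sum())

    @property
    def records(self) -> list[ResponseRecord]:
        return [ResponseRecord(self.X[j], int(self.trials[j]), int(self.spikes[j]))
                for j in range(len(self))]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"amp_uA_{k + 1}": self.X[:, k] for k in range(self.X.shape[1])}
        cols["trials"] = self.trials
        cols["spikes"] = self.spikes
        return pd.DataFrame(cols)


def write_dataset(dataset: ResponseDataset, path) -> None:
    """Write a response dataset as CSV ('#'-comment header carries metadata)."""
    path = Path(path)
    g = dataset.grid
    meta = (f"# cell_id={dataset.cell_id}\n"
            f"# grid=n_electrodes:{g.n_electrodes},n_levels:{g.n_levels},"
            f"amp_min_uA:{g.amp_min!r},amp_max_uA:{g.amp_max!r}\n"
            f"# units=uA\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(meta)
        dataset.to_frame().to_csv(fh, index=False, float_format="%.12g")


def read_dataset(path) -> ResponseDataset:
    """Read a response dataset written by :func:`write_dataset`.

    Round-trips are lossless: integer columns exactly, amplitudes to 1e-12.
    Rejects files declaring units other than μA.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    if meta.get("units", "uA") not in ("uA", "μA"):
        raise ValidationError(f"unsupported units {meta.get('units')!r}; expected μA")
    amp_cols = [c for c in frame.columns if c.startswith("amp_uA_")]
    if not amp_cols:
        raise ValidationError("no amp_uA_* columns found")
    for col in amp_cols + ["trials", "spikes"]:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()][0]
            raise ValidationError(f"row {bad}: non-numeric value in column {col!r}")
    grid_meta = dict(item.split(":") for item in meta.get("grid", "").split(",")
                     if ":" in item)
    if grid_meta:
        grid = build_grid(int(grid_meta["n_electrodes"]), int(grid_meta["n_levels"]),
                          float(grid_meta["amp_min_uA"]), float(grid_meta["amp_max_uA"]))
    else:
        amps = frame[amp_cols].to_numpy(float)
        grid = StimulusGrid(len(amp_cols), 2, float(amps.min()), float(amps.max()),
                            X=np.zeros((2 ** len(amp_cols), len(amp_cols))), full=False)
    return ResponseDataset(
        cell_id=meta.get("cell_id", path.stem),
        grid=grid,
        X=frame[amp_cols].to_numpy(float),
        trials=frame["trials"].to_numpy(),
        spikes=frame["spikes"].to_numpy(),
    )
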