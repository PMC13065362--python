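"""Synthetic neurons with geometry-derived multi-site activation.

Ground truth for every downstream stage: each neuron carries m spike
initiation sites placed along its soma→axon polyline. Site i responds to a
stimulus x (signed second-phase amplitudes, μA) through a sigmoid of the
linear drive b_i + w_i·x, and the cell fires if any site fires:

    p(x) = 1 − Π_i (1 − σ(b_i + w_i·x))

Weights follow a point-source rule — magnitude inversely proportional to the
site-to-electrode distance — so that electrode/cell geometry, not hand-set
parameters, determines whether current summation looks linear (one reachable
site, planar 50% threshold surface) or nonlinear (several reachable sites
along the axon, curved surface). Cathodic (negative) currents drive the
anatomical sites; in the default dual-polarity mode each site is paired with
a mirrored anodic site with negated weights and its own threshold, giving the
paired cathodic/anodic threshold surfaces seen with charge-balanced pulses.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .stimulus import (DEFAULT_MAX_AMPLITUDE_UA, ResponseDataset,
                       StimulusGrid, ValidationError)

__all__ = [
    "ElectrodeArrayGeometry",
    "SyntheticNeuron",
    "Population",
    "make_neuron",
    "true_probability",
    "simulate_trials",
    "make_population",
    "make_selectivity_scenario",
]

#: Gain constant κ (μm · logit units per μA): |w| = κ / (distance · noise_scale).
#: At a typical 30 μm site-electrode distance this gives a sigmoid slope of
#: ~17 logit/μA, i.e. a 10–90% stochastic transition of ~0.26 μA around a
#: ~1 μA threshold — the steep activation curves characteristic of direct
#: single-cell stimulation.
DEFAULT_GAIN_UM = 500.0
#: z-offset of the electrode plane above the distal axon / soma centre (μm).
AXON_PLANE_DEPTH_UM = 12.0
SOMA_DEPTH_UM = 40.0
#: Joint resting activation cap: p(0) ≤ this for every generated neuron.
MAX_REST_PROB = 0.01


@dataclass(frozen=True)
class ElectrodeArrayGeometry:
    """Positions of the stimulating electrodes (μm), electrode plane at z=0."""

    positions: np.ndarray  # (E, 3)
    pitch: float = 30.0
    lattice: str = "triangular"

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        if pos.shape[1] != 3:
            raise ValidationError("electrode positions must be (E, 3) points in μm")
        if self.lattice != "custom" and pos.shape[0] > 1:
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            d = d[np.triu_indices(pos.shape[0], 1)]
            if np.any(d < self.pitch * (1 - 1e-6)):
                raise ValidationError("lattice electrodes closer than the pitch")

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def triangular_triplet(cls, pitch: float = 30.0) -> "ElectrodeArrayGeometry":
        """Three adjacent electrodes of a triangular lattice (standard triplet)."""
        h = pitch * np.sqrt(3) / 2
        pos = np.array([[0.0, 0.0, 0.0], [pitch, 0.0, 0.0], [pitch / 2, h, 0.0]])
        return cls(positions=pos, pitch=pitch, lattice="triangular")


@dataclass
class SyntheticNeuron:
    """Ground-truth neuron: geometry plus per-site biases and weights."""

    cell_id: str
    soma: np.ndarray  # (3,) μm
    axon_path: np.ndarray  # (k, 3) polyline, μm
    site_positions: np.ndarray  # (m, 3) μm (mirrored anodic sites repeat positions)
    biases: np.ndarray  # (m,)
    weights: np.ndarray  # (m, E) per μA

    def __post_init__(self) -> None:
        self.soma = np.asarray(self.soma, dtype=float)
        self.axon_path = np.atleast_2d(np.asarray(self.axon_path, dtype=float))
        self.site_positions = np.atleast_2d(np.asarray(self.site_positions, dtype=float))
        self.biases = np.atleast_1d(np.asarray(self.biases, dtype=float))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if not (len(self.biases) == self.weights.shape[0] >= 1):
            raise ValidationError("need ≥1 site with matching biases/weights")

    @property
    def m_true(self) -> int:
        return len(self.biases)

    @property
    def n_electrodes(self) -> int:
        return self.weights.shape[1]


def true_probability(neuron: SyntheticNeuron, x) -> np.ndarray | float:
    """Exact spike probability of the generative noisy-OR model at stimulus x.

    Accepts a single amplitude vector or an (N, E) batch.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != neuron.n_electrodes:
        raise ValidationError(
            f"stimulus has {X.shape[1]} electrodes, neuron expects {neuron.n_electrodes}"
        )
    z = neuron.biases[None, :] + X @ neuron.weights.T  # (N, m)
    # complement-of-product in log space: stable for extreme site drives
    log_q = -np.logaddexp(0.0, z)  # log(1 − σ(z))
    p = -np.expm1(log_q.sum(axis=1))
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if single else p


def _site_positions_along_axon(soma: np.ndarray, direction: np.ndarray, m: int,
                               site_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Polyline soma → bend into the axon plane → straight run; m sites on it."""
    direction = np.asarray(direction, dtype=float)
    dxy = direction[:2]
    norm = np.linalg.norm(dxy)
    dxy = np.array([1.0, 0.0]) if norm < 1e-12 else dxy / norm
    rise = SOMA_DEPTH_UM - AXON_PLANE_DEPTH_UM  # 28 μm climb toward the array
    bend_run = 30.0  # μm of horizontal travel while climbing
    p0 = soma
    p1 = soma + np.array([dxy[0] * bend_run, dxy[1] * bend_run, rise])
    far = max(200.0, m * site_spacing + bend_run)
    p2 = p1 + np.array([dxy[0] * far, dxy[1] * far, 0.0])
    path = np.stack([p0, p1, p2])
    # arc-length positions of the m sites, first site at the proximal axon
    seg_len = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(m) * site_spacing
    pts = np.empty((m, 3))
    for i, si in enumerate(s):
        si = min(si, cum[-1])
        k = int(np.searchsorted(cum, si, side="right") - 1)
        k = min(k, len(seg_len) - 1)
        t = (si - cum[k]) / seg_len[k] if seg_len[k] > 0 else 0.0
        pts[i] = path[k] + t * (path[k + 1] - path[k])
    return path, pts


def make_neuron(geometry: ElectrodeArrayGeometry, soma, axon_direction,
                m: int = 2, site_spacing: float = 20.0, noise_scale: float = 1.0,
                polarity_mode: str = "dual", seed: int = 0,
                cell_id: str = "cell0", gain: float = DEFAULT_GAIN_UM,
                distance_exponent: float = 1.0,
                threshold_range: tuple[float, float] = (0.5, 1.5),
                rest_logit: float | None = None,
                far_site_cutoff: float = 150.0) -> SyntheticNeuron:
    """Generate a ground-truth neuron from electrode/cell geometry.

    Parameters
    ----------
    m : number of anatomical activation sites along the soma→axon path.
        ``polarity_mode="dual"`` (default) mirrors each with an anodic site,
        so the model carries 2m sites in total.
    site_spacing : arc-length spacing of sites along the axon (μm).
    noise_scale : membrane-noise scale; divides every weight, so larger
        values flatten the sigmoids (wider stochastic transition).
    distance_exponent : power of the distance law (1 = point-source default).
    threshold_range : interval (μA) the per-site 50% thresholds are drawn
        from; shrinking or shifting it makes a cell more or less sensitive.
    rest_logit : optional ceiling on each site's resting logit. Sites whose
        distance-law slope would rest above it are sharpened (weights
        rescaled up) so the drawn threshold is preserved while the site
        rests at the ceiling; steeper sites are left untouched. Models
        maximally excitable cells pressed against the resting-probability
        cap; relative weights across electrodes still follow the distance
        law. Without it (default), an over-excitable site's threshold is
        pushed outward instead, keeping weight magnitudes strictly
        distance-monotone.

    Each site's weight on electrode k has magnitude
    ``gain / (d_ik**distance_exponent · noise_scale)`` and its bias is set so
    the site's 50% threshold, driven from its nearest electrode alone, falls
    inside the ±1.8 μA stimulation range; sites are then scaled, if needed,
    so the whole cell satisfies p(0) ≤ 0.01.
    """
    if m < 1:
        raise ValidationError("m must be ≥ 1")
    if noise_scale <= 0:
        raise ValidationError("noise_scale must be > 0")
    if polarity_mode not in ("cathodic_only", "dual"):
        raise ValidationError(f"unknown polarity_mode {polarity_mode!r}")
    soma = np.asarray(soma, dtype=float)
    if soma.size == 2:  # xy given: place at standard soma depth below the array
        soma = np.array([soma[0], soma[1], -SOMA_DEPTH_UM])
    rng = np.random.default_rng(_stream_seed(seed, cell_id, "make_neuron"))
    path, pts = _site_positions_along_axon(soma, np.asarray(axon_direction, float), m,
                                           site_spacing)
    d = np.linalg.norm(pts[:, None, :] - geometry.positions[None, :, :], axis=-1)
    d = np.maximum(d, 1.0)  # 1 μm floor: no singular weights
    if np.any(d.min(axis=1) > far_site_cutoff):
        warnings.warn("some activation sites are far from every electrode; "
                      "their weights will be small", stacklevel=2)
    mag = gain / (d ** distance_exponent * noise_scale)  # (m, E)

    n_total = 2 * m if polarity_mode == "dual" else m
    # per-site resting cap so the cell jointly satisfies p(0) ≤ 0.01
    b_cap = _per_site_bias_cap(n_total)
    a_max = 0.95 * DEFAULT_MAX_AMPLITUDE_UA
    biases, weights, positions = [], [], []
    for i in range(m):
        polarities = (-1.0, +1.0) if polarity_mode == "dual" else (-1.0,)
        for s in polarities:
            # cathodic site (s=−1): negative weights, driven by cathodic
            # currents; anodic mirror (s=+1): negated weights, own threshold
            w = s * mag[i].copy()
            a_star = rng.uniform(*threshold_range)  # 50% threshold, μA
            k_near = int(np.argmin(d[i]))
            if rest_logit is not None:
                ceiling = min(rest_logit, b_cap)
                b = -abs(w[k_near]) * a_star
                if b > ceiling:  # too excitable at rest: sharpen the site
                    w *= ceiling / b
                    b = ceiling
                biases.append(b)
                weights.append(w)
                positions.append(pts[i])
                continue
            b = -abs(w[k_near]) * a_star
            if b > b_cap:
                # sigmoid too shallow for both p(0) ≤ 0.01 and this
                # threshold: push the threshold out, and only if it would
                # leave the stimulation range, sharpen the site instead
                a_star = min(-b_cap / abs(w[k_near]), a_max)
                w *= -b_cap / (abs(w[k_near]) * a_star)
                b = b_cap
            biases.append(b)
            weights.append(w)
            positions.append(pts[i])
    biases = np.array(biases)
    weights = np.array(weights)
    return SyntheticNeuron(cell_id=cell_id, soma=soma, axon_path=path,
                           site_positions=np.array(positions),
                           biases=biases, weights=weights)


def _per_site_bias_cap(m_total: int, rest_prob: float = MAX_REST_PROB) -> float:
    """Bias bound so that m sites jointly give p(0) ≤ rest_prob."""
    per_site = 1.0 - (1.0 - rest_prob) ** (1.0 / m_total)
    return float(np.log(per_site / (1.0 - per_site)))


def _stream_seed(seed: int, cell_id: str, op: str) -> np.random.SeedSequence:
    """Independent, reproducible RNG stream per (root seed, cell, operation)."""
    return np.random.SeedSequence(
        [int(seed), zlib.crc32(cell_id.encode()), zlib.crc32(op.encode())]
    )


def simulate_trials(neuron: SyntheticNeuron, grid: StimulusGrid,
                    trials_per_stimulus: int = 20, seed: int = 0) -> ResponseDataset:
    """Binomial trial data for one neuron over a stimulus grid.

    Each stimulus receives ``trials_per_stimulus`` independent Bernoulli
    trials at the neuron's true activation probability. The full 20-level
    three-electrode grid at 20 trials therefore totals 160,000 stimulations.
    Deterministic given (seed, cell_id).
    """
    if trials_per_stimulus < 1:
        raise ValidationError("trials_per_stimulus must be ≥ 1")
    p = true_probability(neuron, grid.X)
    rng = np.random.default_rng(_stream_seed(seed, neuron.cell_id, "simulate_trials"))
    spikes = rng.binomial(trials_per_stimulus, p)
    trials = np.full(len(grid), trials_per_stimulus, dtype=int)
    return ResponseDataset(cell_id=neuron.cell_id, grid=grid, X=grid.X,
                           trials=trials, spikes=spikes)


@dataclass
class Population:
    """A collection of synthetic neurons over one electrode geometry."""

    neurons: list[SyntheticNeuron]
    geometry: ElectrodeArrayGeometry = field(
        default_factory=ElectrodeArrayGeometry.triangular_triplet)

    def __post_init__(self) -> None:
        ids = [n.cell_id for n in self.neurons]
        if len(set(ids)) != len(ids):
            raise ValidationError("cell_ids must be unique")

    def __len__(self) -> int:
        return len(self.neurons)

    @property
    def cell_ids(self) -> list[str]:
        return [n.cell_id for n in self.neurons]

    def true_probabilities(self, X) -> dict[str, np.ndarray]:
        """Exact activation probability of every cell at every stimulus."""
        return {n.cell_id: np.atleast_1d(true_probability(n, X))
                for n in self.neurons}

    def to_json(self, path) -> None:
        payload = {
            "geometry": {"positions": self.geometry.positions.tolist(),
                         "pitch": self.geometry.pitch,
                         "lattice": self.geometry.lattice},
            "neurons": [
                {"cell_id": n.cell_id, "soma_um": n.soma.tolist(),
                 "axon_path_um": n.axon_path.tolist(),
                 "site_positions_um": n.site_positions.tolist(),
                 "biases": n.biases.tolist(), "weights": n.weights.tolist()}
                for n in self.neurons
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "Population":
        payload = json.loads(Path(path).read_text())
        geom = ElectrodeArrayGeometry(
            positions=np.asarray(payload["geometry"]["positions"], float),
            pitch=payload["geometry"]["pitch"],
            lattice=payload["geometry"]["lattice"])
        neurons = [SyntheticNeuron(cell_id=n["cell_id"], soma=n["soma_um"],
                                   axon_path=n["axon_path_um"],
                                   site_positions=n["site_positions_um"],
                                   biases=n["biases"], weights=n["weights"])
                   for n in payload["neurons"]]
        return cls(neurons=neurons, geometry=geom)


def make_selectivity_scenario(geometry: ElectrodeArrayGeometry | None = None,
                              seed: int = 0, flanker_distance: float = 70.0,
                              target_thresholds: tuple[float, float] = (0.3, 0.5),
                              flanker_thresholds: tuple[float, float] = (1.4, 1.7),
                              ) -> Population:
    """Three-cell population with a genuinely selective stimulation target.

    One sensitive cell sits under the electrode triplet (50% thresholds
    drawn from ``target_thresholds`` μA) flanked by two less-sensitive
    cells ``flanker_distance`` μm to either side (``flanker_thresholds``).
    The gap between the target's and the flankers' threshold surfaces
    produces a contiguous region of stimuli that drive the target at high
    probability while sparing the others — the high-selectivity region a
    closed-loop calibration is supposed to find. All sites rest at the
    admissible excitability ceiling (``rest_logit`` at the p(0) cap), so a
    site's slope is |cap logit|/threshold: the sensitive target is steep,
    the high-threshold flankers shallow, and the resulting selectivity
    landscape varies over a few steps of the standard 20-level lattice —
    smooth enough for a surrogate model to exploit. Positions are jittered
    and axon directions drawn per seed.
    """
    geometry = geometry or ElectrodeArrayGeometry.triangular_triplet()
    rng = np.random.default_rng(_stream_seed(seed, "scenario", "make_scenario"))
    centre = geometry.positions[:, :2].mean(axis=0)
    offsets = np.array([[0.0, 0.0], [-flanker_distance, 0.0],
                        [flanker_distance, 0.0]])
    ranges = [target_thresholds, flanker_thresholds, flanker_thresholds]
    rest = _per_site_bias_cap(4)  # m=2 dual-polarity → 4 sites per cell
    neurons = []
    for c, (off, t_range) in enumerate(zip(offsets, ranges)):
        xy = centre + off + rng.uniform(-8.0, 8.0, size=2)
        theta = rng.uniform(0, 2 * np.pi)
        neurons.append(make_neuron(
            geometry, soma=xy,
            axon_direction=[np.cos(theta), np.sin(theta), 0.0],
            m=2, noise_scale=2.0, polarity_mode="dual",
            threshold_range=t_range, rest_logit=rest, seed=seed,
            cell_id=f"cell{c}"))
    return Population(neurons=neurons, geometry=geometry)


def make_population(geometry: ElectrodeArrayGeometry, n_cells: int,
                    spacing: float = 30.0, seed: int = 0, m: int = 2,
                    site_spacing: float = 20.0, noise_scale: float = 1.0,
                    polarity_mode: str = "dual") -> Population:
    """Population with somas jittered on a lattice and random axon directions.

    Somas sit on a square lattice of the given spacing centred under the
    electrode group, jittered by up to ±30% of the spacing; axon directions
    are uniform in the tissue (xy) plane. Reproducible given the seed.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be ≥ 1")
    rng = np.random.default_rng(_stream_seed(seed, "population", "make_population"))
    centre = geometry.positions[:, :2].mean(axis=0)
    side = int(np.ceil(np.sqrt(n_cells)))
    offsets = np.arange(side) - (side - 1) / 2
    lattice = np.array([[i, j] for i in offsets for j in offsets])[:n_cells] * spacing
    neurons = []
    for c, base in enumerate(lattice):
        xy = centre + base + rng.uniform(-0.3, 0.3, size=2) * spacing
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])
        cell_id = f"cell{c}"
        neurons.append(make_neuron(geometry, soma=xy, axon_direction=direction,
                                   m=m, site_spacing=site_spacing,
                                   noise_scale=noise_scale,
                                   polarity_mode=polarity_mode,
                                   seed=seed, cell_id=cell_id))
    return Population(neurons=neurons, geometry=geometry)
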