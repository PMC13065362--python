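"""Gaussian-process surrogate and closed-loop level-set calibration.

The aggregate-selectivity landscape (in logit units) is modelled with exact
GP regression: constant mean, RBF covariance, and a white-noise term whose
variance is fitted by marginal-likelihood maximisation alongside the kernel
hyperparameters. On top of the surrogate sits a GP-UCB / level-set sampler:
with confidence bounds UCB = μ + βσ and LCB = μ − βσ and a level L in logit
units, unmeasured stimuli with LCB > L are excluded (confidently selective —
no further measurement needed), and the next batch is drawn uniformly at
random among stimuli with UCB > L (possibly selective, still uncertain).
An empty eligible set terminates the search. Defaults β = 2, L = 3, and a
batch of 1000 stimulations per iteration (50 stimuli at 20 trials each).

The surrogate keeps to exact (dense) GP regression, whose cost grows
cubically with the number of training points; a guard refuses training sets
beyond ~10⁴ points, which is ample for desk-scale amplitude grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .neurons import Population
from .selectivity import (ProbabilityProfile, SelectivityLandscape,
                          aggregate_selectivity, inverse_logit, logit)
from .stimulus import StimulusGrid, ValidationError

__all__ = [
    "GPSurrogate",
    "LSEState",
    "fit_gp",
    "lse_step",
    "run_calibration",
    "CalibrationRun",
    "mae_high_selectivity",
    "ci95",
]

MAX_TRAIN_POINTS = 10_000


class GPSurrogate:
    """Exact GP with constant mean, RBF kernel, and fitted noise variance.

    The constant mean is realised by centring on the training-target mean
    (``mean_const``); far from all data the posterior reverts to it with
    predictive sd √(signal_var + noise_var) — the predictive convention
    includes the observation noise.
    """

    def __init__(self, length_scale: float = 1.0, seed: int = 0,
                 n_restarts: int = 2,
                 length_scale_bounds: tuple[float, float] = (0.2, 25.0)):
        # The default lower bound keeps the kernel from collapsing below the
        # resolution of the standard amplitude grids (~0.2 μA level spacing),
        # where the marginal likelihood would otherwise memorise near-binary
        # training targets instead of generalising.
        self.seed = int(seed)
        self.n_restarts = int(n_restarts)
        self._init_length_scale = length_scale
        self._length_scale_bounds = length_scale_bounds
        self._gpr: GaussianProcessRegressor | None = None
        self._const_y: float | None = None
        self.fitted = False
        self.train_X: np.ndarray | None = None
        self.train_y: np.ndarray | None = None

    def fit(self, X, y) -> "GPSurrogate":
        """Maximise the marginal likelihood over mean, scales, and noise."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size or X.shape[0] < 2:
            raise ValidationError("need ≥ 2 (x, y) pairs with matching lengths")
        if np.unique(X.round(12), axis=0).shape[0] < 2:
            raise ValidationError("need ≥ 2 distinct training inputs")
        if X.shape[0] > MAX_TRAIN_POINTS:
            raise ValidationError(
                f"exact GP limited to {MAX_TRAIN_POINTS} training points "
                f"(got {X.shape[0]}); subsample or coarsen the grid")
        self.train_X, self.train_y = X, y
        if np.ptp(y) == 0.0:
            warnings.warn("constant training targets: posterior mean is the "
                          "constant, noise variance at its lower bound",
                          stacklevel=2)
            self._const_y = float(y[0])
            self._gpr = None
            self.fitted = True
            return self
        ls0 = float(np.clip(self._init_length_scale,
                            *self._length_scale_bounds))
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(ls0, self._length_scale_bounds)
                  + WhiteKernel(1e-2, (1e-10, 1e2)))
        self._gpr = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True,
            n_restarts_optimizer=self.n_restarts, random_state=self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign bound-hit notices
            self._gpr.fit(X, y)
        self._const_y = None
        self.fitted = True
        return self

    # fitted hyperparameters, reported on the (unnormalised) target scale
    @property
    def mean_const(self) -> float:
        self._require_fit()
        return float(self.train_y.mean())

    @property
    def _y_scale2(self) -> float:
        s = float(self.train_y.std())
        return (s if s > 0 else 1.0) ** 2

    @property
    def length_scale(self) -> float:
        self._require_fit()
        if self._gpr is None:
            return float(self._init_length_scale)
        return float(self._gpr.kernel_.k1.k2.length_scale)

    @property
    def signal_var(self) -> float:
        self._require_fit()
        if self._gpr is None:
            return 0.0
        return float(self._gpr.kernel_.k1.k1.constant_value) * self._y_scale2

    @property
    def noise_var(self) -> float:
        self._require_fit()
        if self._gpr is None:
            return 1e-10
        return float(self._gpr.kernel_.k2.noise_level) * self._y_scale2

    def _require_fit(self) -> None:
        if not self.fitted:
            raise RuntimeError("GPSurrogate is not fitted")

    def posterior(self, X_query) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and predictive sd (includes noise) at queries."""
        self._require_fit()
        Xq = np.atleast_2d(np.asarray(X_query, dtype=float))
        if self._gpr is None:  # degenerate constant-target fit
            mu = np.full(Xq.shape[0], self._const_y)
            return mu, np.zeros(Xq.shape[0])
        mu, sd = self._gpr.predict(Xq, return_std=True)
        return mu, sd


def fit_gp(X, y, seed: int = 0, n_restarts: int = 2,
           length_scale: float = 1.0,
           length_scale_bounds: tuple[float, float] = (0.2, 25.0)) -> GPSurrogate:
    """Fit a :class:`GPSurrogate` to (stimulus, logit-value) pairs."""
    return GPSurrogate(length_scale=length_scale, seed=seed,
                       n_restarts=n_restarts,
                       length_scale_bounds=length_scale_bounds).fit(X, y)


@dataclass
class LSEState:
    """Bookkeeping for the closed-loop level-set search over one grid.

    ``batch_size`` and ``budget`` are counted in stimulations; each selected
    stimulus is measured with ``trials_per_measurement`` Bernoulli trials,
    so one iteration selects ``batch_size // trials_per_measurement``
    stimuli (fewer if the eligible set is smaller).
    """

    n_grid: int
    beta: float = 2.0
    level_L: float = 3.0
    batch_size: int = 1000
    trials_per_measurement: int = 20
    budget: int = 6000
    measured: set = field(default_factory=set)
    excluded: set = field(default_factory=set)
    spent: int = 0
    terminated: bool = False
    history: list = field(default_factory=list)

    @property
    def inputs_per_batch(self) -> int:
        return max(1, self.batch_size // self.trials_per_measurement)

    @property
    def candidates(self) -> np.ndarray:
        """Unmeasured, unexcluded grid indices."""
        blocked = self.measured | self.excluded
        return np.array([i for i in range(self.n_grid) if i not in blocked],
                        dtype=int)

    def _check_consistent(self) -> None:
        if self.measured & self.excluded:
            raise ValidationError("measured and excluded sets overlap")


def lse_step(state: LSEState, gp: GPSurrogate, grid: StimulusGrid,
             seed: int | np.random.Generator = 0) -> np.ndarray:
    """One acquisition step of the GP-UCB / level-set sampler.

    Evaluates UCB = μ + βσ and LCB = μ − βσ on the unmeasured inputs, moves
    those with LCB > L into the excluded set, and draws uniformly at random
    (seeded) up to one batch of indices from the eligible set {UCB > L}.
    An empty eligible set returns an empty batch — the termination signal.
    """
    state._check_consistent()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cand = state.candidates
    if cand.size == 0:
        state.terminated = True
        return np.array([], dtype=int)
    mu, sd = gp.posterior(grid.X[cand])
    ucb = mu + state.beta * sd
    lcb = mu - state.beta * sd
    newly_excluded = cand[lcb > state.level_L]
    state.excluded.update(int(i) for i in newly_excluded)
    eligible = cand[(ucb > state.level_L) & ~(lcb > state.level_L)]
    if eligible.size == 0:
        state.terminated = True
        return np.array([], dtype=int)
    k = min(state.inputs_per_batch, eligible.size)
    batch = rng.choice(eligible, size=k, replace=False)
    return np.sort(batch)


def _profile_oracle(oracle) -> tuple[np.ndarray, list[str]]:
    """(K, N) true-probability matrix from a Population or ProbabilityProfile."""
    if isinstance(oracle, ProbabilityProfile):
        return oracle.matrix(), oracle.cell_ids
    raise ValidationError("oracle must be a Population or ProbabilityProfile")


@dataclass
class CalibrationRun:
    """Outcome of one closed-loop calibration: estimate, state, history."""

    estimate: SelectivityLandscape
    state: LSEState
    gp: GPSurrogate
    measured_X: np.ndarray
    measured_y: np.ndarray


def run_calibration(oracle, grid: StimulusGrid, beta: float = 2.0,
                    L: float = 3.0, batch_size: int = 1000,
                    budget: int = 6000, mode: str = "lse",
                    trials_per_measurement: int = 20, seed: int = 0,
                    eps: float | None = None, hybrid_ratio: float = 0.5,
                    snapshot: bool = False) -> CalibrationRun:
    """Closed-loop estimation of the aggregate-selectivity landscape.

    Parameters
    ----------
    oracle : Population or ProbabilityProfile
        Ground truth: measuring a stimulus draws ``trials_per_measurement``
        Bernoulli trials per cell at its true activation probability, and
        the empirical aggregate selectivity (logit-transformed) becomes the
        GP training target.
    mode : {"lse", "random", "hybrid"}
        ``lse`` uses the UCB/LCB acquisition; ``random`` samples uniformly
        among unmeasured stimuli; ``hybrid`` splits each batch between the
        two (``hybrid_ratio`` = LSE fraction).
    budget, batch_size : int
        Stimulation counts; one warm-up batch of uniform random stimuli is
        taken before the first GP fit and counts against the budget.
    snapshot : bool
        If true, each history record carries the full posterior-mean
        landscape at that iteration (for error-vs-budget curves).

    The warm-up draw depends only on the seed, so runs in different modes
    share their initial batch. Deterministic given (oracle, seed).
    """
    if mode not in ("lse", "random", "hybrid"):
        raise ValidationError(f"unknown mode {mode!r}")
    if budget < batch_size:
        raise ValidationError("budget must be ≥ batch_size")
    if isinstance(oracle, Population):
        P_true = np.stack([np.atleast_1d(p) for p in
                           oracle.true_probabilities(grid.X).values()])
    else:
        P_true, _ = _profile_oracle(oracle)
    if P_true.shape[1] != len(grid):
        raise ValidationError("oracle does not cover the stimulus grid")
    eps = eps if eps is not None else 1.0 / (2.0 * trials_per_measurement)

    rng_select = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    rng_measure = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    state = LSEState(n_grid=len(grid), beta=beta, level_L=L,
                     batch_size=batch_size,
                     trials_per_measurement=trials_per_measurement,
                     budget=budget)

    X_meas: list[np.ndarray] = []
    y_meas: list[float] = []

    def measure(indices: np.ndarray) -> None:
        for i in indices:
            draws = rng_measure.binomial(trials_per_measurement, P_true[:, i])
            p_emp = draws / trials_per_measurement
            s, _ = aggregate_selectivity(p_emp)
            X_meas.append(grid.X[i])
            y_meas.append(logit(s, eps=eps))
            state.measured.add(int(i))
        state.spent += len(indices) * trials_per_measurement

    # warm-up: one uniform random batch, identical across modes
    k0 = min(state.inputs_per_batch, len(grid))
    warmup = np.sort(rng_select.choice(len(grid), size=k0, replace=False))
    measure(warmup)

    gp = fit_gp(np.array(X_meas), np.array(y_meas), seed=seed)
    it = 0
    while state.spent < budget and not state.terminated:
        it += 1
        k = state.inputs_per_batch
        if mode == "lse":
            batch = lse_step(state, gp, grid, seed=rng_select)
        elif mode == "random":
            cand = state.candidates
            if cand.size == 0:
                state.terminated = True
                batch = np.array([], dtype=int)
            else:
                batch = np.sort(rng_select.choice(
                    cand, size=min(k, cand.size), replace=False))
        else:  # hybrid: part LSE acquisition, part uniform exploration
            k_lse = int(round(k * hybrid_ratio))
            sub = LSEState(**{**state.__dict__, "history": []})
            sub.batch_size = k_lse * trials_per_measurement
            batch_lse = lse_step(sub, gp, grid, seed=rng_select)
            state.excluded = sub.excluded
            state.terminated = False
            cand = np.setdiff1d(state.candidates, batch_lse)
            k_rand = min(k - batch_lse.size, cand.size)
            batch_rand = (rng_select.choice(cand, size=k_rand, replace=False)
                          if k_rand > 0 else np.array([], dtype=int))
            batch = np.sort(np.concatenate([batch_lse, batch_rand]).astype(int))
            if batch.size == 0:
                state.terminated = True
        if batch.size == 0:
            break
        measure(batch)
        gp = fit_gp(np.array(X_meas), np.array(y_meas), seed=seed)
        record = {"iter": it, "n_measured": len(state.measured),
                  "n_excluded": len(state.excluded), "spent": state.spent}
        if snapshot:
            mu, _ = gp.posterior(grid.X)
            record["logit_estimate"] = mu
        state.history.append(record)

    mu, _ = gp.posterior(grid.X)
    estimate = SelectivityLandscape(
        grid=grid, s_values=inverse_logit(np.clip(mu, -30, 30)),
        best_cell=[""] * len(grid), eps=eps, source="gp")
    return CalibrationRun(estimate=estimate, state=state, gp=gp,
                          measured_X=np.array(X_meas),
                          measured_y=np.array(y_meas))


def mae_high_selectivity(estimate: SelectivityLandscape,
                         truth: SelectivityLandscape,
                         threshold: float = 0.9) -> float:
    """Mean |logit error| over the union of high-selectivity regions.

    The region is {stimuli where either landscape exceeds ``threshold``} —
    the part of the landscape that matters for finding selective stimuli.
    Returns NaN (with a warning) when neither landscape crosses the
    threshold anywhere: the error is undefined there, not zero.
    """
    if estimate.grid.X.shape != truth.grid.X.shape or \
            not np.allclose(estimate.grid.X, truth.grid.X):
        raise ValidationError("landscapes are on different grids")
    mask = (estimate.s_values > threshold) | (truth.s_values > threshold)
    if not mask.any():
        warnings.warn("no stimulus exceeds the selectivity threshold in "
                      "either landscape; MAE undefined", stacklevel=2)
        return float("nan")
    return float(np.mean(np.abs(estimate.logit_values[mask]
                                - truth.logit_values[mask])))


def mae_all(estimate: SelectivityLandscape, truth: SelectivityLandscape) -> float:
    """Mean |logit error| over the whole grid."""
    if not np.allclose(estimate.grid.X, truth.grid.X):
        raise ValidationError("landscapes are on different grids")
    return float(np.mean(np.abs(estimate.logit_values - truth.logit_values)))


def ci95(samples) -> tuple[float, float]:
    """Normal-approximation 95% interval: x̄ ± 1.96 · s/√n (sample sd, ddof=1)."""
    samples = np.asarray(samples, dtype=float).ravel()
    n = samples.size
    if n < 2:
        raise ValidationError("need at least two samples for a CI")
    return float(samples.mean()), float(1.96 * samples.std(ddof=1) / np.sqrt(n))
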