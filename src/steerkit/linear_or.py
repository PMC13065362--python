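"""The linear-OR (noisy-OR) activation model and its maximum-likelihood fit.

The model approximates a cell that can initiate a spike at any of m membrane
sites. Site i linearly sums the stimulating currents x (μA) and fires with
probability σ(w_{i,0} + w_i·x); the cell fires if any site fires:

    p(x) = 1 − Π_{i=1..m} (1 − σ(w_{i,0} + w_i·x))

For m = 1 this is logistic regression; larger m admits increasingly
nonlinear (curved, multi-sheet) 50% threshold surfaces. Fitting minimises
the grouped Bernoulli negative log-likelihood

    −l = −Σ_j T_j [ P_j log p(x_j) + (1 − P_j) log(1 − p(x_j)) ]

plus an L2 penalty λ‖W‖² on the weights, under box constraints: |w_{i,k}| ≤
100 and per-site bias bounds that force the resting probability p(0) ≤ 0.01.
The problem is non-convex, so the optimiser (L-BFGS-B) is restarted from
several random initialisations and the best optimum kept.

Usage follows the Model/Results pattern::

    model = LinearOR(dataset, m=8)
    res = model.fit(lambda_=0.5, n_restarts=20, seed=1)
    res.predict(grid.X)     # probabilities on any stimuli
    res.pseudo_r2           # McFadden goodness of fit
    print(res.summary())
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .stimulus import ResponseDataset, ValidationError

__all__ = [
    "LinearOR",
    "LinearORResults",
    "fit",
    "predict_prob",
    "neg_log_likelihood",
    "mcfadden_r2",
    "mean_absolute_error",
]

WEIGHT_BOUND = 100.0       # |w_{i,k}| ≤ 100 box constraint
MAX_REST_PROB = 0.01       # p(0) ≤ 0.01 via per-site bias caps
BIAS_FLOOR = -50.0
_LOG_FLOOR = 1e-300


def _per_site_bias_cap(m: int, rest_prob: float = MAX_REST_PROB) -> float:
    """Per-site bias bound whose joint effect guarantees p(0) ≤ rest_prob."""
    per_site = 1.0 - (1.0 - rest_prob) ** (1.0 / m)
    return float(np.log(per_site / (1.0 - per_site)))


def noisy_or_probability(biases, weights, X) -> np.ndarray:
    """p(x) = 1 − Π_i (1 − σ(b_i + w_i·x)), evaluated stably in log space."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    z = np.asarray(biases, float)[None, :] + X @ np.asarray(weights, float).T
    log_q = -np.logaddexp(0.0, z)          # log(1 − σ(z)), safe for |z| ~ 1e3
    return np.clip(-np.expm1(log_q.sum(axis=1)), 0.0, 1.0)


def predict_prob(model, x) -> np.ndarray | float:
    """Spike probability under any object exposing ``biases`` and ``weights``.

    Accepts a fitted :class:`LinearORResults`, a synthetic neuron, or any
    (biases, weights) carrier; a single stimulus vector or an (N, E) batch.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1 and x.size != np.shape(model.weights)[1]:
        raise ValidationError(
            f"stimulus has {x.size} electrodes, model expects "
            f"{np.shape(model.weights)[1]}")
    p = noisy_or_probability(model.biases, model.weights, x)
    return float(p[0]) if x.ndim == 1 else p


def _grouped_nll(p: np.ndarray, trials: np.ndarray, probs_emp: np.ndarray,
                 log_q: np.ndarray | None = None) -> float:
    """−Σ T[P log p + (1−P) log(1−p)] with floored logs."""
    log_p = np.log(np.maximum(p, _LOG_FLOOR))
    if log_q is None:
        log_q = np.log(np.maximum(1.0 - p, _LOG_FLOOR))
    return float(-np.sum(trials * (probs_emp * log_p + (1 - probs_emp) * log_q)))


def neg_log_likelihood(model, dataset: ResponseDataset) -> float:
    """Grouped Bernoulli negative log-likelihood of a model on a dataset."""
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")
    p = noisy_or_probability(model.biases, model.weights, dataset.X)
    return _grouped_nll(p, dataset.trials, dataset.probabilities)


def mean_absolute_error(model, dataset: ResponseDataset) -> float:
    """Mean |p_model(x_j) − P_j| over the dataset's records."""
    p = noisy_or_probability(model.biases, model.weights, dataset.X)
    return float(np.mean(np.abs(p - dataset.probabilities)))


def _null_log_likelihood(dataset: ResponseDataset) -> float:
    """Log-likelihood of the intercept-only model at its closed-form MLE."""
    p0 = dataset.spikes.sum() / dataset.trials.sum()
    return -_grouped_nll(np.full(len(dataset), p0), dataset.trials,
                         dataset.probabilities)


def mcfadden_r2(model, dataset: ResponseDataset) -> float:
    """McFadden pseudo-R²: 1 − l_model / l_null (unpenalised likelihoods).

    The null model is the intercept-only fit (constant probability at its
    closed-form MLE). Always ≤ 1; can be ≤ 0 when the model underperforms
    the null. A degenerate null (all outcomes identical, l₀ = 0) returns 0
    with a warning.
    """
    l_model = -neg_log_likelihood(model, dataset)
    l_null = _null_log_likelihood(dataset)
    if l_null == 0.0:
        warnings.warn("null model fits the data perfectly (l0 = 0); "
                      "pseudo-R² undefined, returning 0", stacklevel=2)
        return 0.0
    return 1.0 - l_model / l_null


class LinearOR:
    """Linear-OR activation model bound to one cell's stimulation data.

    Parameters
    ----------
    dataset : ResponseDataset
        Per-stimulus trial and spike counts for the cell.
    m : int, optional
        Number of activation sites. Defaults to 8 for three stimulating
        electrodes and 10 for four or more, which absorbs the strong
        nonlinearities seen with multi-electrode stimulation; m=1 is plain
        logistic regression.
    """

    def __init__(self, dataset: ResponseDataset, m: int | None = None):
        if len(dataset) == 0:
            raise ValidationError("dataset is empty")
        self.dataset = dataset
        n_elec = dataset.X.shape[1]
        self.m = int(m) if m is not None else (8 if n_elec <= 3 else 10)
        if self.m < 1:
            raise ValidationError("m must be ≥ 1")
        self.n_electrodes = n_elec

    # -- objective ---------------------------------------------------------

    def _objective(self, theta: np.ndarray, lambda_: float):
        m, E = self.m, self.n_electrodes
        b = theta[:m]
        W = theta[m:].reshape(m, E)
        X, T, P = self.dataset.X, self.dataset.trials, self.dataset.probabilities
        z = b[None, :] + X @ W.T                      # (J, m)
        sig = expit(z)
        log_q_site = -np.logaddexp(0.0, z)            # log(1 − σ)
        log_q = log_q_site.sum(axis=1)                # log(1 − p)
        p = np.clip(-np.expm1(log_q), 0.0, 1.0)
        nll = _grouped_nll(p, T, P, log_q=log_q)
        obj = nll + lambda_ * np.sum(W * W)
        # ∂p/∂z_i = σ_i (1−p); chain through the grouped likelihood
        q = np.exp(log_q)
        ratio = q / np.maximum(p, 1e-12)
        g = -(T * (P * ratio - (1 - P)))[:, None] * sig   # (J, m): ∂nll/∂z
        grad_b = g.sum(axis=0)
        grad_W = g.T @ X + 2.0 * lambda_ * W
        return obj, np.concatenate([grad_b, grad_W.ravel()])

    # -- fitting -----------------------------------------------------------

    def fit(self, lambda_: float = 0.5, n_restarts: int = 20, seed: int = 0,
            maxiter: int = 500) -> "LinearORResults":
        """Constrained MLE by L-BFGS-B with seeded random restarts.

        Returns the best optimum over ``n_restarts`` initialisations:
        biases start just inside their upper cap, weights at N(0, 1) draws.
        """
        m, E = self.m, self.n_electrodes
        b_cap = _per_site_bias_cap(m)
        bounds = ([(BIAS_FLOOR, b_cap)] * m
                  + [(-WEIGHT_BOUND, WEIGHT_BOUND)] * (m * E))
        rng = np.random.default_rng(seed)
        best = None
        any_converged = False
        for _ in range(max(1, n_restarts)):
            theta0 = np.concatenate([
                np.full(m, b_cap - np.log(2.0)),      # σ at half the cap odds
                rng.standard_normal(m * E),
            ])
            res = minimize(self._objective, theta0, args=(lambda_,),
                           method="L-BFGS-B", jac=True, bounds=bounds,
                           options={"maxiter": maxiter})
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        biases = theta[:m]
        weights = theta[m:].reshape(m, E)
        results = LinearORResults(
            model=self, biases=biases, weights=weights,
            fit_info={
                "lambda": lambda_,
                "converged": any_converged,
                "objective": float(best.fun),
                "nll": None,          # filled below (unpenalised)
                "pseudo_r2": None,
                "n_restarts": int(n_restarts),
                "seed": int(seed),
            })
        results.fit_info["nll"] = neg_log_likelihood(results, self.dataset)
        results.fit_info["pseudo_r2"] = mcfadden_r2(results, self.dataset)
        if not any_converged:
            warnings.warn("no L-BFGS-B restart reported convergence; "
                          "returning the best iterate", stacklevel=2)
        return results

    @classmethod
    def from_arrays(cls, X, trials, spikes, m: int | None = None,
                    cell_id: str = "cell", grid=None) -> "LinearOR":
        from .stimulus import StimulusGrid
        X = np.atleast_2d(np.asarray(X, float))
        if grid is None:
            grid = StimulusGrid(X.shape[1], 2, float(X.min()), float(X.max()),
                                X=X, full=False)
        ds = ResponseDataset(cell_id=cell_id, grid=grid, X=X,
                             trials=trials, spikes=spikes)
        return cls(ds, m=m)


class LinearORResults:
    """Fitted linear-OR parameters plus likelihood diagnostics."""

    def __init__(self, model: LinearOR, biases: np.ndarray, weights: np.ndarray,
                 fit_info: dict):
        self.model = model
        self.biases = np.asarray(biases, float)
        self.weights = np.asarray(weights, float)
        self.fit_info = fit_info

    @property
    def m(self) -> int:
        return len(self.biases)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.biases, self.weights.ravel()])

    @property
    def nll(self) -> float:
        return self.fit_info["nll"]

    @property
    def pseudo_r2(self) -> float:
        return self.fit_info["pseudo_r2"]

    @property
    def converged(self) -> bool:
        return self.fit_info["converged"]

    def predict(self, X) -> np.ndarray | float:
        """Spike probabilities at new stimuli."""
        return predict_prob(self, X)

    def resting_probability(self) -> float:
        """p(0): activation probability with zero current on every electrode."""
        return float(noisy_or_probability(
            self.biases, self.weights,
            np.zeros((1, self.weights.shape[1])))[0])

    def mean_absolute_error(self, dataset: ResponseDataset | None = None) -> float:
        return mean_absolute_error(self, dataset or self.model.dataset)

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Linear-OR activation model",
            "=" * 44,
            f"cell                 {ds.cell_id}",
            f"stimuli (J)          {len(ds)}",
            f"stimulations (N)     {ds.total_stimulations}",
            f"electrodes           {self.weights.shape[1]}",
            f"sites (m)            {self.m}",
            f"lambda (L2)          {self.fit_info['lambda']:g}",
            f"restarts             {self.fit_info['n_restarts']}",
            f"converged            {self.converged}",
            f"neg log-likelihood   {self.nll:.3f}",
            f"McFadden pseudo-R2   {self.pseudo_r2:.4f}",
            f"mean |p - P|         {self.mean_absolute_error():.4f}",
            f"p(0)                 {self.resting_probability():.4g}",
            "-" * 44,
            "site   bias      " + "  ".join(
                f"w_e{k + 1:<6d}" for k in range(self.weights.shape[1])),
        ]
        for i in range(self.m):
            ws = "  ".join(f"{w: 8.3f}" for w in self.weights[i])
            lines.append(f"{i + 1:>4d} {self.biases[i]: 9.3f} {ws}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {"schema": "steerkit.linear_or/1",
                   "m": self.m,
                   "biases": self.biases.tolist(),
                   "weights": self.weights.tolist(),
                   "fit_info": self.fit_info}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path, model: LinearOR | None = None) -> "LinearORResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != "steerkit.linear_or/1":
            raise ValidationError("unrecognised model file schema")
        return cls(model=model, biases=np.asarray(payload["biases"], float),
                   weights=np.asarray(payload["weights"], float),
                   fit_info=payload["fit_info"])


def fit(dataset: ResponseDataset, m: int | None = None, lambda_: float = 0.5,
        n_restarts: int = 20, seed: int = 0) -> LinearORResults:
    """Convenience wrapper: ``LinearOR(dataset, m).fit(...)``."""
    return LinearOR(dataset, m=m).fit(lambda_=lambda_, n_restarts=n_restarts,
                                      seed=seed)
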