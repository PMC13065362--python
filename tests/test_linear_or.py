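import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from steerkit.linear_or import (LinearOR, LinearORResults, fit, mcfadden_r2,
                                mean_absolute_error, neg_log_likelihood,
                                noisy_or_probability, predict_prob)
from steerkit.neurons import make_neuron, simulate_trials
from steerkit.stimulus import ResponseDataset, build_grid


def make_results(biases, weights):
    """Bare parameter carrier (no fit) for closed-form checks."""
    return LinearORResults(model=None, biases=np.asarray(biases, float),
                           weights=np.atleast_2d(np.asarray(weights, float)),
                           fit_info={})


def single_record_dataset(grid, trials, spikes):
    return ResponseDataset(cell_id="c", grid=grid, X=grid.X[:1],
                           trials=[trials], spikes=[spikes])


class TestPredictProb:
    def test_single_site_zero_drive_is_half(self):
        res = make_results([0.0], [[1.0, -2.0, 3.0]])
        assert predict_prob(res, np.zeros(3)) == pytest.approx(0.5)

    def test_two_sites_zero_drive(self):
        res = make_results([0.0, 0.0], [[1.0, 0, 0], [0, 1.0, 0]])
        assert predict_prob(res, np.zeros(3)) == pytest.approx(0.75)

    def test_matches_term_by_term_log_domain_recomputation(self):
        rng = np.random.default_rng(3)
        res = make_results(rng.normal(size=3), rng.normal(size=(3, 3)))
        for _ in range(20):
            x = rng.uniform(-1.8, 1.8, 3)
            z = res.biases + res.weights @ x
            expected = 1 - np.exp(np.sum(np.log1p(-expit(z))))
            assert predict_prob(res, x) == pytest.approx(expected, abs=1e-12)

    def test_numerically_stable_at_extreme_drives(self):
        res = make_results([1000.0], [[500.0, 0, 0]])
        assert predict_prob(res, np.array([1.0, 0, 0])) == 1.0
        res = make_results([-1000.0], [[500.0, 0, 0]])
        assert predict_prob(res, np.array([-1.0, 0, 0])) == 0.0

    def test_monotone_in_each_site_drive(self):
        rng = np.random.default_rng(5)
        b = rng.normal(size=4)
        W = rng.normal(size=(4, 3))
        x = rng.uniform(-1, 1, 3)
        base = noisy_or_probability(b, W, x)[0]
        for i in range(4):
            b_up = b.copy()
            b_up[i] += 0.5
            assert noisy_or_probability(b_up, W, x)[0] >= base - 1e-15

    def test_union_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            b = rng.normal(size=3)
            W = rng.normal(size=(3, 2))
            x = rng.uniform(-2, 2, 2)
            sig = expit(b + W @ x)
            p = noisy_or_probability(b, W, x)[0]
            assert p >= sig.max() - 1e-12
            assert p <= min(1.0, sig.sum()) + 1e-12


class TestLikelihood:
    def test_closed_form_twenty_log_two(self):
        grid = build_grid(3, 2, -1, 1)
        res = make_results([0.0], [[0.0, 0.0, 0.0]])  # p ≡ 0.5
        for spikes in (10, 20):  # P = 0.5 and P = 1 give the same value
            ds = single_record_dataset(grid, 20, spikes)
            assert neg_log_likelihood(res, ds) == pytest.approx(
                20 * np.log(2), abs=1e-9)

    def test_grouped_equals_per_trial_expansion(self):
        grid = build_grid(2, 4, -1.5, 1.5)
        rng = np.random.default_rng(1)
        trials = rng.integers(1, 30, len(grid))
        spikes = rng.integers(0, trials + 1)
        ds = ResponseDataset(cell_id="c", grid=grid, X=grid.X,
                             trials=trials, spikes=spikes)
        res = make_results(rng.normal(size=2), rng.normal(size=(2, 2)))
        p = res.predict(grid.X)
        per_trial = -np.sum(spikes * np.log(p) + (trials - spikes) * np.log(1 - p))
        assert neg_log_likelihood(res, ds) == pytest.approx(per_trial, abs=1e-9)

    def test_mae_closed_cases(self):
        grid = build_grid(1, 4, -1, 1)
        ds = ResponseDataset(cell_id="c", grid=grid, X=grid.X,
                             trials=[10] * 4, spikes=[0, 10, 0, 10])
        res = make_results([0.0], [[0.0]])  # p ≡ 0.5 everywhere
        assert mean_absolute_error(res, ds) == pytest.approx(0.5)


class TestMcFaddenR2:
    def _dataset(self):
        grid = build_grid(1, 6, -1, 1)
        return ResponseDataset(cell_id="c", grid=grid, X=grid.X,
                               trials=[10] * 6, spikes=[0, 1, 3, 7, 9, 10])

    def test_intercept_only_model_scores_zero(self):
        ds = self._dataset()
        p_hat = ds.spikes.sum() / ds.trials.sum()
        res = make_results([np.log(p_hat / (1 - p_hat))], [[0.0]])
        assert mcfadden_r2(res, ds) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_model_on_deterministic_data_scores_one(self):
        grid = build_grid(1, 4, -1, 1)
        ds = ResponseDataset(cell_id="c", grid=grid, X=grid.X,
                             trials=[10] * 4, spikes=[0, 0, 10, 10])
        res = make_results([0.0], [[1e4]])  # step function at 0
        assert mcfadden_r2(res, ds) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_null_warns_and_returns_zero(self):
        grid = build_grid(1, 3, -1, 1)
        ds = ResponseDataset(cell_id="c", grid=grid, X=grid.X,
                             trials=[5] * 3, spikes=[5] * 3)
        res = make_results([100.0], [[0.0]])
        with pytest.warns(UserWarning, match="null"):
            assert mcfadden_r2(res, ds) == 0.0


class TestFit:
    def test_matches_logistic_regression_oracle_for_single_site(
            self, triplet_geometry):
        grid = build_grid(3, 9, -1.8, 1.8)
        lam = 0.5
        for seed in (0, 1, 2):
            neuron = make_neuron(triplet_geometry, soma=[15, 8.66],
                                 axon_direction=[1, 0, 0], m=1,
                                 polarity_mode="cathodic_only", seed=seed,
                                 cell_id=f"s{seed}")
            ds = simulate_trials(neuron, grid, 20, seed=seed)
            res = LinearOR(ds, m=1).fit(lambda_=lam, n_restarts=5, seed=seed)
            # independent oracle: penalised logistic MLE, matching λ‖w‖²
            X2 = np.vstack([ds.X, ds.X])
            y2 = np.concatenate([np.ones(len(ds)), np.zeros(len(ds))])
            w2 = np.concatenate([ds.spikes, ds.trials - ds.spikes])
            clf = LogisticRegression(C=1.0 / (2 * lam), max_iter=2000,
                                     tol=1e-10)
            clf.fit(X2, y2, sample_weight=w2)
            p_oracle = clf.predict_proba(grid.X)[:, 1]
            assert np.max(np.abs(res.predict(grid.X) - p_oracle)) <= 0.02

    def test_all_silent_data_fits_near_zero_probability(self):
        grid = build_grid(3, 5, -1.8, 1.8)
        ds = ResponseDataset(cell_id="c", grid=grid, X=grid.X,
                             trials=np.full(len(grid), 20),
                             spikes=np.zeros(len(grid), int))
        res = LinearOR(ds, m=2).fit(n_restarts=3, seed=0)
        assert np.max(res.predict(grid.X)) <= 0.01 + 1e-6

    def test_fitted_model_satisfies_constraints(self, small_grid,
                                                dual_site_neuron):
        ds = simulate_trials(dual_site_neuron, small_grid, 20, seed=2)
        res = LinearOR(ds, m=2).fit(n_restarts=5, seed=0)
        assert np.all(np.abs(res.weights) <= 100.0 + 1e-9)
        assert res.resting_probability() <= 0.01 + 1e-9
        assert res.converged
        assert {"lambda", "nll", "pseudo_r2", "n_restarts",
                "seed"} <= res.fit_info.keys()

    def test_larger_m_never_fits_worse(self, small_grid, dual_site_neuron):
        ds = simulate_trials(dual_site_neuron, small_grid, 20, seed=6)
        nlls = {m: LinearOR(ds, m=m).fit(n_restarts=12, seed=1).nll
                for m in (1, 2, 3)}
        assert nlls[2] <= nlls[1] + 1e-6
        assert nlls[3] <= nlls[2] + 1e-6

    def test_more_sites_explain_curved_data_better(self, small_grid,
                                                   triplet_geometry):
        neuron = make_neuron(triplet_geometry, soma=[-20, -25],
                             axon_direction=[1, 0.3, 0], m=4,
                             site_spacing=25.0, polarity_mode="dual",
                             seed=13, cell_id="curved")
        ds = simulate_trials(neuron, small_grid, 20, seed=13)
        r1 = LinearOR(ds, m=1).fit(n_restarts=6, seed=0)
        r8 = LinearOR(ds, m=8).fit(n_restarts=6, seed=0)
        assert r8.pseudo_r2 > r1.pseudo_r2
        # linear-OR also beats the intercept-only null on mean error
        p_null = ds.spikes.sum() / ds.trials.sum()
        null_mae = np.mean(np.abs(p_null - ds.probabilities))
        assert r8.mean_absolute_error() < null_mae

    def test_summary_and_json_round_trip(self, tmp_path, small_grid,
                                         single_site_neuron):
        ds = simulate_trials(single_site_neuron, small_grid, 20, seed=0)
        res = fit(ds, m=1, n_restarts=3, seed=0)
        text = res.summary()
        assert "McFadden" in text and "sites (m)" in text
        path = tmp_path / "model.json"
        res.to_json(path)
        back = LinearORResults.from_json(path)
        assert np.allclose(back.weights, res.weights)
        assert np.allclose(back.biases, res.biases)
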