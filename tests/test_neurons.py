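import numpy as np
import pytest

from steerkit.linear_or import LinearOR
from steerkit.neurons import (ElectrodeArrayGeometry, Population,
                              make_neuron, make_population,
                              make_selectivity_scenario, simulate_trials,
                              true_probability)
from steerkit.selectivity import ProbabilityProfile, landscape
from steerkit.stimulus import ValidationError, build_grid


class TestTrueProbability:
    def test_all_sites_at_zero_drive(self, triplet_geometry):
        # every site at σ(0) = 0.5 → p = 1 − 0.5^m
        for m in (1, 2, 3):
            n = make_neuron(triplet_geometry, soma=[15, 8.66],
                            axon_direction=[1, 0, 0], m=m,
                            polarity_mode="cathodic_only", seed=0)
            n.biases[:] = 0.0
            n.weights[:] = 0.0
            assert true_probability(n, np.zeros(3)) == pytest.approx(
                1 - 0.5 ** m, abs=1e-12)

    def test_one_saturated_site_absorbs(self, triplet_geometry):
        n = make_neuron(triplet_geometry, soma=[15, 8.66],
                        axon_direction=[1, 0, 0], m=3,
                        polarity_mode="cathodic_only", seed=0)
        n.biases[1] = 1e3  # one site fires with certainty → OR absorbs
        assert true_probability(n, np.zeros(3)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_monte_carlo_per_site_bernoulli(self, triplet_geometry):
        n = make_neuron(triplet_geometry, soma=[10, 5], axon_direction=[1, 1, 0],
                        m=3, polarity_mode="cathodic_only", seed=4)
        rng = np.random.default_rng(99)
        x = rng.uniform(-1.8, 1.8, 3)
        p = true_probability(n, x)
        z = n.biases + n.weights @ x
        site_p = 1 / (1 + np.exp(-z))
        draws = rng.random((1_000_000, 3)) < site_p
        p_mc = draws.any(axis=1).mean()
        se = np.sqrt(p * (1 - p) / 1e6)
        assert abs(p - p_mc) <= 3 * se + 1e-9

    def test_dimension_mismatch_rejected(self, single_site_neuron):
        with pytest.raises(ValidationError):
            true_probability(single_site_neuron, np.zeros(4))


class TestGeometryDerivedWeights:
    def test_equidistant_electrodes_give_equal_weights(self, triplet_geometry):
        # soma under the centroid: all three electrodes equidistant
        n = make_neuron(triplet_geometry, soma=[15.0, 8.660254],
                        axon_direction=[1, 0, 0], m=1,
                        polarity_mode="cathodic_only", seed=0)
        w = np.abs(n.weights[0])
        assert np.allclose(w, w[0], rtol=1e-5)

    def test_inverse_distance_rule(self):
        # site at (0,0,-40); electrode 2 placed at twice the distance of 1
        geom = ElectrodeArrayGeometry(
            positions=np.array([[0.0, 0.0, 0.0],
                                [0.0, np.sqrt(80.0 ** 2 - 40.0 ** 2), 0.0]]),
            lattice="custom")
        n = make_neuron(geom, soma=[0.0, 0.0], axon_direction=[1, 0, 0],
                        m=1, polarity_mode="cathodic_only", seed=0)
        w = np.abs(n.weights[0])
        assert w[0] / w[1] == pytest.approx(2.0, rel=1e-6)

    def test_weights_shrink_when_all_distances_grow(self):
        near = ElectrodeArrayGeometry.triangular_triplet(pitch=30.0)
        # raising the electrode plane strictly increases every distance
        far = ElectrodeArrayGeometry(positions=near.positions + [0, 0, 40.0],
                                     pitch=30.0, lattice="custom")
        kw = dict(soma=[15.0, 8.66], axon_direction=[1, 0, 0], m=1,
                  polarity_mode="cathodic_only", seed=0)
        w_near = np.abs(make_neuron(near, **kw).weights)
        w_far = np.abs(make_neuron(far, **kw).weights)
        assert np.all(w_far < w_near)

    def test_resting_probability_capped(self, triplet_geometry):
        for seed in range(5):
            n = make_neuron(triplet_geometry, soma=[20, 0],
                            axon_direction=[0, 1, 0], m=3,
                            polarity_mode="dual", seed=seed)
            assert true_probability(n, np.zeros(3)) <= 0.01 + 1e-9

    def test_dual_polarity_doubles_sites_with_mirrored_weights(self, dual_site_neuron):
        n = dual_site_neuron
        assert n.m_true == 2
        assert np.allclose(n.weights[0], -n.weights[1])


class TestSimulateTrials:
    def test_full_protocol_stimulation_count(self, standard_grid,
                                             single_site_neuron):
        ds = simulate_trials(single_site_neuron, standard_grid, 20, seed=1)
        assert ds.total_stimulations == 160_000

    def test_silent_neuron_never_spikes(self, small_grid, triplet_geometry):
        n = make_neuron(triplet_geometry, soma=[15, 8.66],
                        axon_direction=[1, 0, 0], m=1,
                        polarity_mode="cathodic_only", seed=0)
        n.biases[:] = -1e4
        n.weights[:] = 0.0
        ds = simulate_trials(n, small_grid, 20, seed=3)
        assert ds.spikes.sum() == 0

    def test_same_seed_bit_identical(self, small_grid, single_site_neuron):
        a = simulate_trials(single_site_neuron, small_grid, 20, seed=7)
        b = simulate_trials(single_site_neuron, small_grid, 20, seed=7)
        c = simulate_trials(single_site_neuron, small_grid, 20, seed=8)
        assert np.array_equal(a.spikes, b.spikes)
        assert not np.array_equal(a.spikes, c.spikes)

    def test_empirical_probabilities_converge(self, single_site_neuron):
        grid = build_grid(3, 5, -1.8, 1.8)
        ds = simulate_trials(single_site_neuron, grid, 10_000, seed=5)
        p_true = true_probability(single_site_neuron, grid.X)
        assert np.max(np.abs(ds.probabilities - p_true)) <= 0.02


class TestPopulation:
    def test_cell_ids_unique_and_seeded_geometry_reproducible(self,
                                                              triplet_geometry):
        a = make_population(triplet_geometry, 3, seed=2)
        b = make_population(triplet_geometry, 3, seed=2)
        assert a.cell_ids == ["cell0", "cell1", "cell2"]
        for na, nb in zip(a.neurons, b.neurons):
            assert np.array_equal(na.weights, nb.weights)
            assert np.array_equal(na.biases, nb.biases)

    def test_seven_cell_population_has_selective_stimulus(self,
                                                          triplet_geometry,
                                                          small_grid):
        pop = make_population(triplet_geometry, 7, spacing=30.0, seed=0)
        profile = ProbabilityProfile(grid=small_grid,
                                     probs=pop.true_probabilities(small_grid.X))
        land = landscape(profile)
        assert land.max > 0

    def test_population_json_round_trip(self, tmp_path, triplet_geometry):
        pop = make_population(triplet_geometry, 2, seed=9)
        path = tmp_path / "pop.json"
        pop.to_json(path)
        back = Population.from_json(path)
        assert back.cell_ids == pop.cell_ids
        for na, nb in zip(pop.neurons, back.neurons):
            assert np.allclose(na.weights, nb.weights)
            assert np.allclose(na.soma, nb.soma)

    def test_selectivity_scenario_has_high_selectivity_region(self):
        grid = build_grid(3, 9, -1.8, 1.8)
        pop = make_selectivity_scenario(seed=0)
        land = landscape(ProbabilityProfile(
            grid=grid, probs=pop.true_probabilities(grid.X)))
        assert land.max > 0.95


def test_generative_fit_recovers_probability_surface(triplet_geometry):
    """Fitting with m = m_true on dense-trial data recovers p(x) closely."""
    neuron = make_neuron(triplet_geometry, soma=[15, 8.66],
                         axon_direction=[1, 0, 0], m=1, polarity_mode="dual",
                         seed=21, cell_id="gen")
    grid = build_grid(3, 20, -1.8, 1.8)
    ds = simulate_trials(neuron, grid, 100, seed=21)
    res = LinearOR(ds, m=neuron.m_true).fit(n_restarts=8, seed=0)
    p_fit = res.predict(grid.X)
    p_true = true_probability(neuron, grid.X)
    assert np.median(np.abs(p_fit - p_true)) <= 0.05
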