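import numpy as np
import pytest

from dlmra import (
    EstimationOptions,
    MarkovTransitionModel,
    add_noise,
    cellstate_design,
    dataset_from_csv,
    dataset_to_csv,
    drop_node,
    generate_design_data,
    sample_random_markov,
)
from dlmra.estimator import residual_vector
from dlmra.experiment import PerturbationSpec
from dlmra.models import ffl_model

from conftest import random_stable_nets


class TestDesignGeneration:
    def test_complete_inhibition_zeroes_perturbed_trace(self, activator_dataset):
        assert np.allclose(activator_dataset.perturbed[1].values[:, 0], 0.0)

    def test_design_has_n_plus_one_conditions(self, activator_dataset):
        assert len(activator_dataset.perturbed) == activator_dataset.n

    def test_supports_n_squared_residual_equations(self, activator_dataset, grid11):
        """The estimator consumes n vehicle + n(n−1) perturbation residual
        streams per time point: n² in total."""
        n, Nt = activator_dataset.n, grid11.size
        r = residual_vector(
            (np.zeros((n, n)), np.zeros(n)), activator_dataset, EstimationOptions()
        )
        assert r.size == Nt * n * n

    def test_p_one_reproduces_vehicle(self, single_activator, grid11):
        ds = generate_design_data(single_activator, grid11, p=1.0)
        for j, tr in ds.perturbed.items():
            assert np.allclose(tr.values, ds.vehicle.values, atol=1e-6)

    def test_vehicle_starts_at_basal_steady_state(self, grid11):
        for net in random_stable_nets(3, 5, seed=31):
            ds = generate_design_data(net, grid11, p=0.0)
            from dlmra import basal_steady_state

            assert np.allclose(ds.vehicle.values[0], basal_steady_state(net).x_ss)

    def test_invalid_strength_rejected(self, single_activator, grid11):
        with pytest.raises(ValueError):
            generate_design_data(single_activator, grid11, p=1.5)
        with pytest.raises(ValueError):
            PerturbationSpec(target=1, p=-0.1)


class TestFFLDesigns:
    def test_model1_node3_silent_under_complete_inhibition(self, grid11):
        """AND-gated circuit with both regulators required: complete
        inhibition leaves node 3 flat in every condition, hiding the direct
        1→3 edge."""
        ds = generate_design_data(ffl_model(1), grid11, p=0.0)
        for key in ("vehicle", 1, 2):
            pass  # vehicle node 3 responds; perturbed conditions are flat
        assert np.allclose(ds.perturbed[1].values[:, 2], 0.0, atol=1e-6)
        assert np.allclose(ds.perturbed[2].values[:, 2], 0.0, atol=1e-6)

    def test_model1_node3_informative_under_partial_inhibition(self, grid11):
        ds = generate_design_data(ffl_model(1), grid11, p=0.5)
        x3 = {k: ds.condition(k).values[:, 2] for k in ("vehicle", 1, 2)}
        assert np.max(np.abs(x3["vehicle"] - x3[1])) > 1e-3
        assert np.max(np.abs(x3["vehicle"] - x3[2])) > 1e-3
        assert np.max(np.abs(x3[1] - x3[2])) > 1e-3

    def test_unresponsive_perturbation_flagged(self, grid11):
        ds = generate_design_data(ffl_model(1), grid11, p=0.0)
        assert any("perturbation" in w for w in ds.warnings)


class TestNoise:
    def test_zero_level_is_identity(self, activator_dataset):
        assert add_noise(activator_dataset, 0.0, 1) is activator_dataset

    def test_zero_points_stay_zero(self, activator_dataset):
        noisy = add_noise(activator_dataset, 0.5, 3)
        # node-1 trace under complete node-1 inhibition is exactly zero
        assert np.all(noisy.perturbed[1].values[:, 0] == 0.0)

    def test_original_unmodified_and_seed_recorded(self, activator_dataset):
        before = activator_dataset.vehicle.values.copy()
        noisy = add_noise(activator_dataset, 0.1, 7)
        assert np.array_equal(activator_dataset.vehicle.values, before)
        assert noisy.seed == 7 and noisy.noise_d == 0.1

    def test_noise_scale_matches_specification(self):
        """sd of the added noise at x = 2, d = 0.5 is d·x = 1 (Monte Carlo)."""
        from dlmra.core import Trajectory
        from dlmra.experiment import PerturbationDataset

        n_rep = 100_000
        times = np.arange(n_rep, dtype=float)
        vals = np.full((n_rep, 1), 2.0)
        ds = PerturbationDataset(
            n=1, times=times, vehicle=Trajectory(times=times, values=vals),
            perturbed={1: Trajectory(times=times, values=vals)}, p=0.0,
        )
        noisy = add_noise(ds, 0.5, 123)
        sd = np.std(noisy.vehicle.values - 2.0)
        assert sd == pytest.approx(1.0, abs=0.01)

    def test_noise_is_unbiased(self):
        from dlmra.core import Trajectory
        from dlmra.experiment import PerturbationDataset

        n_rep = 10_000
        times = np.arange(n_rep, dtype=float)
        vals = np.full((n_rep, 1), 2.0)
        ds = PerturbationDataset(
            n=1, times=times, vehicle=Trajectory(times=times, values=vals),
            perturbed={1: Trajectory(times=times, values=vals)}, p=0.0,
        )
        noisy = add_noise(ds, 0.5, 5)
        se = 1.0 / np.sqrt(n_rep)
        assert abs(np.mean(noisy.vehicle.values) - 2.0) < 3 * se

    def test_negative_level_rejected(self, activator_dataset):
        with pytest.raises(ValueError):
            add_noise(activator_dataset, -0.1, 1)


class TestDropNode:
    def test_counts_after_drop(self, grid11):
        net = random_stable_nets(3, 1, seed=41)[0]
        ds = generate_design_data(net, grid11, p=0.0)
        reduced = drop_node(ds, 3)
        assert reduced.n == 2
        assert len(reduced.perturbed) == 2
        assert reduced.vehicle.values.shape == (grid11.size, 2)

    def test_retained_data_unchanged(self, grid11):
        net = random_stable_nets(3, 1, seed=43)[0]
        ds = generate_design_data(net, grid11, p=0.0)
        reduced = drop_node(ds, 2)
        assert np.array_equal(reduced.vehicle.values, ds.vehicle.values[:, [0, 2]])
        # old condition 3 becomes condition 2
        assert np.array_equal(reduced.perturbed[2].values, ds.perturbed[3].values[:, [0, 2]])

    def test_out_of_range_index(self, grid11):
        net = random_stable_nets(3, 1, seed=44)[0]
        ds = generate_design_data(net, grid11, p=0.0)
        reduced = drop_node(ds, 3)
        with pytest.raises(ValueError):
            drop_node(reduced, 3)


class TestCellStateDesign:
    def test_mass_conserved_in_every_condition(self):
        m = sample_random_markov(3, np.random.default_rng(8))
        ds = cellstate_design(m, np.linspace(0, 5, 11))
        for key in ["vehicle", 1, 2, 3]:
            tot = ds.condition(key).values.sum(axis=1)
            assert np.max(np.abs(tot - 1.0)) < 1e-8

    def test_identity_markov_gives_constant_trajectories(self):
        m = MarkovTransitionModel(M=np.eye(3))
        ds = cellstate_design(m, np.linspace(0, 5, 6))
        for key in ["vehicle", 1, 2, 3]:
            v = ds.condition(key).values
            assert np.allclose(v, v[0], atol=1e-9)

    def test_all_conditions_converge_to_stationary_distribution(self):
        m = sample_random_markov(3, np.random.default_rng(9))
        pi = m.stationary()
        long_times = np.linspace(0.0, 50.0 * m.step, 11)
        ds = cellstate_design(m, long_times)
        finals = [ds.condition(k).values[-1] for k in ["vehicle", 1, 2, 3]]
        for f in finals:
            assert np.max(np.abs(f - pi)) < 1e-3

    def test_perturbed_initial_conditions(self):
        m = sample_random_markov(3, np.random.default_rng(10))
        ds = cellstate_design(m, np.linspace(0, 5, 6))
        assert np.allclose(ds.vehicle.values[0], 1 / 3)
        assert ds.perturbed[2].values[0, 1] == 0.0
        assert np.allclose(ds.perturbed[2].values[0, [0, 2]], 0.5)


class TestSerialization:
    def test_csv_round_trip(self, tmp_path, activator_dataset):
        path = tmp_path / "ds.csv"
        dataset_to_csv(activator_dataset, path)
        back = dataset_from_csv(path)
        assert back.n == activator_dataset.n
        assert np.allclose(back.times, activator_dataset.times)
        assert np.allclose(back.vehicle.values, activator_dataset.vehicle.values)
        for j in back.perturbed:
            assert np.allclose(
                back.perturbed[j].values, activator_dataset.perturbed[j].values
            )
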