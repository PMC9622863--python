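import numpy as np
import pytest
from scipy.integrate import solve_ivp

import dlmra
from dlmra import (
    EstimationOptions,
    add_noise,
    cellstate_design,
    fit,
    fit_cellstate,
    fit_zero_basal,
    generate_design_data,
    negligible_mask,
    objective,
    perturbed_trace_interpolant,
    sample_random_markov,
)
from dlmra.estimator import PENALTY
from dlmra.models import markov_to_continuous

from conftest import random_stable_nets


class TestInterpolant:
    def test_constant_trace(self):
        f = perturbed_trace_interpolant(np.linspace(0, 10, 11), np.full(11, 3.0))
        assert np.allclose(f(np.linspace(-5, 15, 50)), 3.0)

    def test_polynomial_reproduced_exactly(self):
        t = np.linspace(0, 10, 11)
        f = perturbed_trace_interpolant(t, t**2, order=5)
        assert np.max(np.abs(f(t) - t**2)) < 1e-10

    def test_exponential_approximation_error(self):
        # closed-form oracle: the order-5 least-squares fit of e^{-t} on 11
        # evenly spaced points over [0, 10] has max dense-grid error 0.0225
        t = np.linspace(0, 10, 11)
        f = perturbed_trace_interpolant(t, np.exp(-t), order=5)
        dense = np.linspace(0, 10, 401)
        assert np.max(np.abs(f(dense) - np.exp(-dense))) < 0.023

    def test_clamps_outside_sampled_range(self):
        t = np.linspace(0, 10, 11)
        f = perturbed_trace_interpolant(t, t, order=2)
        assert f(-100.0) == pytest.approx(f(0.0))
        assert f(100.0) == pytest.approx(f(10.0))

    def test_order_reduced_with_warning_when_few_points(self):
        with pytest.warns(UserWarning, match="reduced"):
            f = perturbed_trace_interpolant(np.array([0.0, 1.0, 2.0]), np.ones(3), order=5)
        assert f.order == 2


class TestObjective:
    def test_generating_parameters_score_near_zero(self, activator_dataset, single_activator):
        phi = objective((single_activator.F, single_activator.S_ex), activator_dataset)
        assert phi < 1e-6

    def test_wrong_parameter_scores_positive(self, activator_dataset, single_activator):
        F = single_activator.F.copy()
        F[1, 0] += 1.0
        assert objective((F, single_activator.S_ex), activator_dataset) > 1e-3

    def test_agrees_with_independent_reimplementation(self, activator_dataset):
        """Straight-line recomputation of the objective — basal elimination,
        adaptive-solver integration with the interpolated forced trace, and
        the exclusion rule — agrees to 6 significant digits."""
        F = np.array([[-0.7, 0.2], [1.1, -1.2]])
        S_ex = np.array([0.8, 1.3])
        ds = activator_dataset
        x0 = ds.vehicle.values[0]
        S_b = -(F @ x0)
        s = S_b + S_ex
        phi = 0.0
        sol = solve_ivp(
            lambda t, x: s + F @ x, (ds.times[0], ds.times[-1]), x0,
            t_eval=ds.times, rtol=1e-10, atol=1e-12,
        )
        phi += np.sum((ds.vehicle.values - sol.y.T) ** 2)
        for j, tr in ds.perturbed.items():
            o = [i for i in range(2) if i != j - 1]
            g = perturbed_trace_interpolant(ds.times, tr.values[:, j - 1], 5)

            def rhs(t, xo, j=j, o=o, g=g):
                full = np.empty(2)
                full[o] = xo
                full[j - 1] = g(t)
                return (s + F @ full)[o]

            sol = solve_ivp(
                rhs, (ds.times[0], ds.times[-1]), tr.values[0, o],
                t_eval=ds.times, rtol=1e-10, atol=1e-12,
            )
            phi += np.sum((tr.values[:, o] - sol.y.T) ** 2)
        mine = objective((F, S_ex), ds)
        assert mine == pytest.approx(phi, rel=1e-6)

    def test_divergent_candidate_gets_finite_penalty(self, activator_dataset):
        # strongly unstable candidate driven by a stimulus: trajectories
        # overflow and the objective returns the finite penalty, not an error
        F = np.array([[10.0, 5.0], [5.0, 10.0]])
        assert objective((F, np.array([5.0, 5.0])), activator_dataset) == PENALTY

    def test_perturbed_node_samples_force_the_surrogate(self, activator_dataset):
        """Changing the sampled node-j trace under perturbation j changes the
        objective (it drives the forced equation), even though node j's own
        residuals in that condition are excluded."""
        import dataclasses

        from dlmra.core import Trajectory

        ds = activator_dataset
        tr2 = ds.perturbed[2]
        bumped = Trajectory(times=tr2.times, values=tr2.values + np.array([0.0, 0.5]))
        ds2 = dataclasses.replace(ds, perturbed={1: ds.perturbed[1], 2: bumped})
        # candidate with a non-zero 1<-2 coupling, so the forced node-2
        # trace actually enters node 1's surrogate equation
        F = np.array([[-1.0, 0.3], [1.5, -0.8]])
        S = np.array([1.0, 1.0])
        phi_ref = objective((F, S), ds)
        assert abs(objective((F, S), ds2) - phi_ref) > 1e-6 * max(phi_ref, 1e-6)

    def test_perturbed_node_residuals_are_excluded(self, activator_dataset):
        """Residuals never include node j under perturbation j: the residual
        vector has exactly n per time point for the vehicle plus n−1 per
        perturbation condition."""
        from dlmra.estimator import residual_vector

        r = residual_vector(
            (np.array([[-1.0, 0.0], [1.5, -0.8]]), np.array([1.0, 1.0])),
            activator_dataset,
        )
        n, Nt = 2, activator_dataset.n_timepoints
        assert r.size == Nt * (n + n * (n - 1))


class TestFit:
    def test_single_activator_recovery(self, activator_fit, single_activator):
        res = activator_fit
        assert np.max(np.abs(res.F_hat - single_activator.F)) < 0.05
        assert np.max(np.abs(res.S_ex_hat - single_activator.S_ex)) < 0.05

    def test_single_activator_noisy_sign_pattern(self, single_activator, grid11):
        ds = add_noise(generate_design_data(single_activator, grid11, p=0.0), 0.1, 17)
        res = fit(ds, EstimationOptions(n_starts=10, seed=18))
        est = np.concatenate([res.F_hat.ravel(), res.S_b_hat, res.S_ex_hat])
        truth = np.concatenate(
            [single_activator.F.ravel(), single_activator.S_b, single_activator.S_ex]
        )
        # signs match wherever the truth is non-zero
        nz = truth != 0
        assert np.all(np.sign(est[nz]) == np.sign(truth[nz]))

    def test_random_two_node_recovery(self, grid11):
        """Central zero-noise claim: parameters of random stable 2-node
        networks are recovered essentially exactly from clean 11-point data."""
        for k, net in enumerate(random_stable_nets(2, 20, seed=61)):
            ds = generate_design_data(net, grid11, p=0.0)
            res = fit(ds, EstimationOptions(n_starts=6, seed=500 + k))
            err = max(
                np.max(np.abs(res.F_hat - net.F)),
                np.max(np.abs(res.S_ex_hat - net.S_ex)),
                np.max(np.abs(res.S_b_hat - net.S_b)),
            )
            assert err < 0.05, f"net {k}: max parameter error {err}"

    def test_random_three_node_recovery(self, grid11):
        net = random_stable_nets(3, 1, seed=62)[0]
        ds = generate_design_data(net, grid11, p=0.0)
        res = fit(ds, EstimationOptions(n_starts=8, seed=63))
        assert np.max(np.abs(res.F_hat - net.F)) < 0.1

    def test_more_timepoints_never_hurt(self):
        """Median recovery error at 21 time points is no worse than at 3,
        for a fixed network and noise scheme."""
        errs = {}
        for n_t in (3, 21):
            per_net = []
            for k, net in enumerate(random_stable_nets(2, 5, seed=64)):
                ds = generate_design_data(net, np.linspace(0, 10, n_t), p=0.0)
                ds = add_noise(ds, 0.2, 700 + k)
                res = fit(
                    ds,
                    EstimationOptions(
                        n_starts=5, seed=800 + k, interp_order=min(5, n_t - 1)
                    ),
                )
                per_net.append(np.median(np.abs(res.F_hat - net.F)))
            errs[n_t] = np.median(per_net)
        assert errs[21] <= errs[3]

    def test_incomplete_dataset_rejected(self, activator_dataset):
        # a dataset missing a perturbation condition cannot even be built
        import dataclasses

        with pytest.raises(ValueError, match="one entry per node"):
            dataclasses.replace(
                activator_dataset, n=2, perturbed={1: activator_dataset.perturbed[1]}
            )

    def test_best_start_is_minimum_phi(self, activator_fit):
        phis = [st["phi"] for st in activator_fit.starts]
        assert activator_fit.sse == min(phis)


class TestCellStateFit:
    def test_recovers_transition_rates(self):
        m = sample_random_markov(3, np.random.default_rng(71))
        truth = markov_to_continuous(m)
        ds = cellstate_design(m, np.linspace(0, 5, 11))
        res = fit_cellstate(ds, EstimationOptions(n_starts=5, seed=72))
        off = ~np.eye(3, dtype=bool)
        # 5% relative, with a small absolute floor: the matrix logarithm can
        # produce marginally negative rates that the non-negativity
        # constraint legitimately clips to zero
        err = np.abs(res.F_hat[off] - truth.F[off])
        assert np.all(err <= np.maximum(0.05 * np.abs(truth.F[off]), 0.01))

    def test_column_sums_exactly_zero(self):
        m = sample_random_markov(3, np.random.default_rng(73))
        ds = cellstate_design(m, np.linspace(0, 5, 7))
        res = fit_cellstate(ds, EstimationOptions(n_starts=3, seed=74))
        assert np.allclose(res.F_hat.sum(axis=0), 0.0)
        assert np.all(res.S_b_hat == 0) and np.all(res.S_ex_hat == 0)

    def test_identity_markov_gives_null_rates(self):
        from dlmra import MarkovTransitionModel

        m = MarkovTransitionModel(M=np.eye(3))
        ds = cellstate_design(m, np.linspace(0, 5, 7))
        res = fit_cellstate(ds, EstimationOptions(n_starts=3, seed=75))
        assert np.max(np.abs(res.F_hat)) < 1e-4


class TestZeroBasalFit:
    def test_matches_standard_when_basal_truly_zero(self, activator_dataset, single_activator):
        res = fit_zero_basal(activator_dataset, EstimationOptions(n_starts=6, seed=81))
        assert np.max(np.abs(res.F_hat - single_activator.F)) < 0.05
        assert np.all(res.S_b_hat == 0)

    def test_negligible_threshold_arithmetic(self):
        mask = negligible_mask(np.array([2.0, 0.019, 0.021, -0.5]))
        assert mask.tolist() == [False, True, False, False]

    def test_cascade_null_edges_flagged_negligible(self, grid11):
        """3-node cascade (1→2→3, no 1→3 shortcut, zero basal): the absent
        F13 and F31 couplings fall below 1/100 of the dominant parameter."""
        from dlmra import LinearNetwork

        net = LinearNetwork(
            F=[[-1.0, 0.0, 0.0], [1.2, -1.0, 0.0], [0.0, 0.9, -1.0]],
            S_b=np.zeros(3),
            S_ex=[1.0, 0.0, 0.0],
        )
        ds = generate_design_data(net, grid11, p=0.0)
        res = fit_zero_basal(ds, EstimationOptions(n_starts=6, seed=82))
        params = np.concatenate([res.F_hat.ravel(), res.S_ex_hat])
        mask = negligible_mask(params)
        assert mask[2] and mask[6]  # F13 and F31


class TestMultistartDiagnostics:
    def test_cv_peaks_near_zero_on_clean_fit(self, activator_fit):
        from dlmra import multistart_cv

        cv = multistart_cv(activator_fit, mode="twice_min")
        assert cv.size > 0
        assert np.median(cv) < 0.05
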