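import numpy as np
import pandas as pd
import pytest

from softsense.kinetics import KineticParams, KineticState, simulate
from softsense.pso import (PENALTY, FitProblem, PSOConfig, criterion,
                           fit_kinetics, pso_minimize)
from softsense.synth import (concentration_frame, default_initial_state,
                             default_params, make_batch)


def sphere(x):
    return float(x @ x)


def rosenbrock(x):
    return float((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2)


class TestPSO:
    def test_sphere_minimum(self):
        res = pso_minimize(sphere, [(-5, 5)] * 5,
                           PSOConfig(n_particles=30, n_iterations=200, seed=1))
        assert res.best_value < 1e-4

    def test_rosenbrock_valley(self):
        res = pso_minimize(rosenbrock, [(-2, 2), (-1, 3)],
                           PSOConfig(n_particles=30, n_iterations=300, seed=2))
        assert np.max(np.abs(res.best_x - 1.0)) < 0.05

    def test_trace_non_increasing_and_best_is_min(self):
        res = pso_minimize(sphere, [(-5, 5)] * 3,
                           PSOConfig(n_particles=10, n_iterations=50, seed=3))
        assert np.all(np.diff(res.trace) <= 0)
        assert res.best_value == res.trace.min()

    def test_bit_reproducible(self):
        cfg = PSOConfig(n_particles=12, n_iterations=40, seed=7)
        a = pso_minimize(rosenbrock, [(-2, 2), (-1, 3)], cfg)
        b = pso_minimize(rosenbrock, [(-2, 2), (-1, 3)], cfg)
        np.testing.assert_array_equal(a.best_x, b.best_x)
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_degenerate_single_particle_pure_inertia(self):
        # no cognitive/social pull and vanishing inertia: the particle stays
        # at its start and the best point is the initial sample
        cfg = PSOConfig(n_particles=1, n_iterations=20, inertia=1e-12,
                        cognitive=0.0, social=0.0, seed=4)
        res = pso_minimize(sphere, [(-5, 5)] * 2, cfg)
        x0 = -5 + 10 * np.random.default_rng(4).random((1, 2))
        np.testing.assert_allclose(res.best_x, x0[0], atol=1e-6)

    def test_positions_stay_in_box(self):
        lo, hi = -1.0, 2.0
        seen = []

        def probe(x):
            seen.append(x.copy())
            return sphere(x)

        pso_minimize(probe, [(lo, hi)] * 3,
                     PSOConfig(n_particles=8, n_iterations=30, seed=5))
        arr = np.array(seen)
        assert arr.min() >= lo - 1e-12 and arr.max() <= hi + 1e-12

    def test_invalid_bounds_and_config(self):
        with pytest.raises(ValueError):
            pso_minimize(sphere, [(0, np.inf)], PSOConfig())
        with pytest.raises(ValueError):
            PSOConfig(n_particles=0)
        with pytest.raises(ValueError):
            PSOConfig(inertia=0.0)


class TestCriterion:
    @staticmethod
    def _decay_problem(noise_frac=0.0, seed=0):
        params = KineticParams(k_deg=0.0065, q_gln=0.0)
        state0 = KineticState(v=1.0, a_gln=5.0)
        traj = simulate(state0, params, None, t_end=100, grid_h=1.0)
        t = traj.times[::5]
        v = traj.column("a_gln")[::5]
        rng = np.random.default_rng(seed)
        noisy = v + rng.normal(0, noise_frac * v.std(), v.size)
        obs = pd.DataFrame({"variable": "glutamine", "time_h": t, "value": noisy})
        return params, state0, obs

    def test_truth_scores_near_zero(self):
        params, state0, obs = self._decay_problem()
        problem = FitProblem(free={"k_deg": (1e-4, 0.05)}, base_params=params,
                             state0=state0, observations=obs, t_end=100, grid_h=1.0)
        assert criterion(np.array([0.0065]), problem) < 1e-5

    def test_noise_expectation_after_normalisation(self):
        values = []
        for s in range(20):
            params, state0, obs = self._decay_problem(noise_frac=0.1, seed=s)
            problem = FitProblem(free={}, base_params=params, state0=state0,
                                 observations=obs, t_end=100, grid_h=1.0)
            values.append(criterion(np.array([]), problem))
        assert np.mean(values) == pytest.approx(0.1, rel=0.15)

    def test_unsimulable_parameters_return_penalty(self):
        params, state0, obs = self._decay_problem()
        problem = FitProblem(free={"q_gln": (0.0, 1.0)},
                             base_params=params.replace(
                                 k_deg=0.0065),
                             state0=KineticState(n_g1=1000.0, v=1.0, a_gln=0.01),
                             observations=obs, t_end=100, grid_h=1.0)
        assert criterion(np.array([0.5]), problem) == PENALTY


class TestFitKinetics:
    def test_k_deg_recovery_from_noiseless_decay(self):
        params, state0, obs = TestCriterion._decay_problem()
        for s in range(3):
            problem = FitProblem(free={"k_deg": (1e-4, 0.05)}, base_params=params,
                                 state0=state0, observations=obs, t_end=100,
                                 grid_h=1.0)
            res = fit_kinetics(problem, PSOConfig(n_particles=15,
                                                  n_iterations=40, seed=s))
            assert abs(res.best_x[0] - 0.0065) / 0.0065 < 0.01

    def test_empty_free_set_is_identity_fit(self):
        params, state0, obs = TestCriterion._decay_problem()
        problem = FitProblem(free={}, base_params=params, state0=state0,
                             observations=obs, t_end=100, grid_h=1.0)
        res = fit_kinetics(problem, PSOConfig(seed=0))
        assert res.trace.size == 1
        assert res.best_params is params
        assert "glutamine" in res.per_variable

    def test_three_parameter_recovery_from_fed_batch(self):
        # {Q_glc, Y_lac, K_deg} from a 14-day batch with 1% observation noise
        truth = default_params()
        traj, _, schedule = make_batch(seed=0)
        frame = concentration_frame(traj)
        t_obs = np.arange(6.0, 336.0, 12.0)
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            rows = []
            for var in ("glucose", "lactate", "glutamine", "ammonium"):
                v = np.interp(t_obs, frame["time_h"], frame[var])
                rows.append(pd.DataFrame({
                    "variable": var, "time_h": t_obs,
                    "value": v * (1 + rng.normal(0, 0.01, v.size))}))
            problem = FitProblem(
                free={"q_glc": (5e-6, 5e-5), "y_lac": (0.1, 1.0),
                      "k_deg": (0.001, 0.012)},
                base_params=truth, state0=default_initial_state(),
                observations=pd.concat(rows, ignore_index=True),
                schedule=schedule, t_end=336.0, grid_h=2.0)
            res = fit_kinetics(problem, PSOConfig(n_particles=16,
                                                  n_iterations=40, seed=s))
            target = np.array([truth.q_glc, truth.y_lac, truth.k_deg])
            hits += bool(np.all(np.abs(res.best_x - target) / target < 0.10))
        assert hits >= 8

    def test_problem_validation(self):
        params, state0, obs = TestCriterion._decay_problem()
        with pytest.raises(ValueError, match="bounds"):
            FitProblem(free={"k_deg": (0.1, 0.1)}, base_params=params,
                       state0=state0, observations=obs, t_end=100)
        with pytest.raises(ValueError, match="horizon"):
            FitProblem(free={}, base_params=params, state0=state0,
                       observations=obs, t_end=50)
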