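import numpy as np
import pytest

from softsense.kinetics import (Bolus, FeedSchedule, KineticParams,
                                KineticState, Sampling, derivatives,
                                growth_rate, simulate)


@pytest.fixture
def mixed_state():
    return KineticState(n_g1=100, n_s=50, n_g2m=30, n_g0=20, v=2.0,
                        a_gln=8.0, a_amn=1.0, a_glc=16.0, a_lac=2.0, a_mab=0.5)


class TestGrowthRate:
    def test_direct_evaluation(self):
        assert growth_rate(10, 5, 5) == pytest.approx(np.log(2) / 20)

    def test_homogeneity(self):
        assert growth_rate(20, 10, 10) == pytest.approx(growth_rate(10, 5, 5) / 2)

    def test_long_cycle_limit(self):
        assert 0 < growth_rate(1e9, 1e9, 1e9) < 1e-9

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            growth_rate(0, 5, 5)


class TestDerivatives:
    def test_equilibrium_when_all_rates_zero(self, mixed_state):
        params = KineticParams(k_g1s=0, k_sg2m=0, k_g2mg1=0, k_g1g0=0, k_d=0,
                               q_gln=0, k_deg=0, q_glc=0, m_glc=0,
                               q_g1g0=0, q_s=0, q_g2m=0)
        np.testing.assert_allclose(derivatives(mixed_state, params), 0.0)

    def test_mitosis_doubles_g2m_into_g1(self):
        k = 0.1
        params = KineticParams(k_g1s=0, k_sg2m=0, k_g2mg1=k, k_g1g0=0, k_d=0,
                               q_gln=0, k_deg=0, q_glc=0, m_glc=0,
                               q_g1g0=0, q_s=0, q_g2m=0)
        state = KineticState(n_g2m=10.0, v=1.0)
        d = derivatives(state, params)
        assert d[0] == pytest.approx(2 * k * 10)    # G1 gains two daughters
        assert d[2] == pytest.approx(-k * 10)       # G2/M loses the mother
        assert d[:4].sum() == pytest.approx(k * 10)  # net +1 cell per mitosis

    def test_glutamine_ammonia_cancel_with_unit_yield(self, mixed_state):
        params = KineticParams(y_amn=1.0)
        d = derivatives(mixed_state, params, feeds_at_t=(0.0, 0.0, 0.0))
        assert d[5] + d[6] == pytest.approx(0.0, abs=1e-14)

    def test_outflow_removes_at_concentration(self, mixed_state):
        params = KineticParams(k_g1s=0, k_sg2m=0, k_g2mg1=0, k_g1g0=0, k_d=0,
                               q_gln=0, k_deg=0, q_glc=0, m_glc=0,
                               q_g1g0=0, q_s=0, q_g2m=0)
        f_out = 0.5
        d = derivatives(mixed_state, params, feeds_at_t=(0.0, 0.0, f_out))
        assert d[7] == pytest.approx(-f_out * mixed_state.a_glc / mixed_state.v)
        assert d[4] == pytest.approx(-f_out)

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            derivatives(np.array([1, 1, 1, 1, 0.0, 1, 1, 1, 1, 0]), KineticParams())


class TestSimulate:
    def test_glutamine_decay_closed_form(self):
        params = KineticParams(k_deg=0.01, q_gln=0.0)
        traj = simulate(KineticState(v=1.0, a_gln=5.0), params, None,
                        t_end=100, grid_h=1.0)
        expected = 5.0 * np.exp(-0.01 * traj.times)
        assert np.max(np.abs(traj.column("a_gln") - expected)) / 5.0 < 1e-6

    def test_volume_quadrature_exact(self):
        schedule = FeedSchedule(rate_segments=[(0.0, 0.001, 0.0, 0.0)])
        traj = simulate(KineticState(v=1.0), KineticParams(), schedule,
                        t_end=100, grid_h=1.0)
        assert traj.column("v")[-1] == pytest.approx(1.1, rel=1e-9)

    def test_lactate_glucose_invariant(self, mixed_state):
        params = KineticParams(m_glc=0.0, y_lac=0.5)
        traj = simulate(mixed_state, params, None, t_end=200, grid_h=2.0)
        total = traj.column("a_lac") + 0.5 * traj.column("a_glc")
        assert (total.max() - total.min()) / total[0] < 1e-6

    def test_glutamine_ammonia_invariant(self, mixed_state):
        params = KineticParams(y_amn=1.0)
        traj = simulate(mixed_state, params, None, t_end=200, grid_h=2.0)
        total = traj.column("a_gln") + traj.column("a_amn")
        assert (total.max() - total.min()) / total[0] < 1e-6

    def test_total_cell_mitosis_balance(self, mixed_state):
        params = KineticParams(k_d=0.0)
        traj = simulate(mixed_state, params, None, t_end=50, grid_h=0.05)
        n_tot = traj.states[:, :4].sum(axis=1)
        dn = np.gradient(n_tot, traj.times)
        expected = params.k_g2mg1 * traj.column("n_g2m")
        assert np.max(np.abs(dn - expected)) / n_tot[0] < 1e-4

    def test_daily_boluses_make_sawtooth(self, mixed_state):
        boluses = [Bolus(24.0 * k, 0.05, "glc") for k in range(1, 15)]
        traj = simulate(mixed_state, KineticParams(), FeedSchedule(boluses=boluses),
                        t_end=360, grid_h=0.5)
        glc = traj.column("a_glc") / traj.column("v")
        up_jumps = np.sum(np.diff(glc) > 0.1)
        assert up_jumps == 14

    def test_sampling_preserves_concentrations(self, mixed_state):
        schedule = FeedSchedule(samplings=[Sampling(10.0, 0.2)])
        params = KineticParams(k_g1s=0, k_sg2m=0, k_g2mg1=0, k_g1g0=0, k_d=0,
                               q_gln=0, k_deg=0, q_glc=0, m_glc=0,
                               q_g1g0=0, q_s=0, q_g2m=0)
        traj = simulate(mixed_state, params, schedule, t_end=20, grid_h=1.0)
        glc_conc = traj.column("a_glc") / traj.column("v")
        np.testing.assert_allclose(glc_conc, glc_conc[0], rtol=1e-9)
        assert traj.column("v")[-1] == pytest.approx(1.8)

    def test_bolus_commutation(self, mixed_state):
        s1 = FeedSchedule(boluses=[Bolus(10.0, 0.05, "glc"), Bolus(10.0, 0.02, "gln")])
        s2 = FeedSchedule(boluses=[Bolus(10.0, 0.02, "gln"), Bolus(10.0, 0.05, "glc")])
        end1 = simulate(mixed_state, KineticParams(), s1, t_end=20, grid_h=1.0).states[-1]
        end2 = simulate(mixed_state, KineticParams(), s2, t_end=20, grid_h=1.0).states[-1]
        np.testing.assert_array_equal(end1, end2)

    def test_solver_tolerance_convergence(self, mixed_state):
        coarse = simulate(mixed_state, KineticParams(), None, t_end=100,
                          grid_h=10.0, rtol=1e-8, atol=1e-10)
        fine = simulate(mixed_state, KineticParams(), None, t_end=100,
                        grid_h=10.0, rtol=5e-9, atol=5e-11)
        rel = np.abs(coarse.states[-1] - fine.states[-1]) / np.maximum(
            np.abs(fine.states[-1]), 1e-12)
        assert rel.max() < 1e-6

    def test_negative_state_abort(self):
        # hungry cells, almost no glutamine, no uptake limitation
        params = KineticParams(q_gln=1e-2)
        state = KineticState(n_g1=1000.0, v=1.0, a_gln=0.01, a_glc=100.0)
        with pytest.raises(RuntimeError, match="negative"):
            simulate(state, params, None, t_end=50, grid_h=1.0)


class TestObservables:
    def test_equal_phases_quarter_g0(self):
        state = KineticState(n_g1=5, n_s=5, n_g2m=5, n_g0=5, v=1.0)
        traj = simulate(state, KineticParams(k_g1s=0, k_sg2m=0, k_g2mg1=0,
                                             k_g1g0=0, k_d=0, q_gln=0, k_deg=0,
                                             q_glc=0, m_glc=0, q_g1g0=0,
                                             q_s=0, q_g2m=0),
                        None, t_end=1, grid_h=1.0)
        obs = traj.observables()
        np.testing.assert_allclose(obs["f_g0"], 0.25)

    def test_concentration_amount_roundtrip(self, mixed_state):
        traj = simulate(mixed_state, KineticParams(), None, t_end=50, grid_h=5.0)
        obs = traj.observables()
        np.testing.assert_allclose(obs["glucose"] * obs["volume_l"],
                                   traj.column("a_glc"), rtol=1e-12)
        n_tot = traj.states[:, :4].sum(axis=1)
        np.testing.assert_allclose(obs["vcc"] * obs["volume_l"] * 1000.0,
                                   n_tot, rtol=1e-12)

    def test_tcc_at_least_vcc(self, mixed_state):
        traj = simulate(mixed_state, KineticParams(), None, t_end=100, grid_h=2.0)
        obs = traj.observables()
        assert np.all(obs["tcc"] >= obs["vcc"] - 1e-12)


class TestTypes:
    def test_state_validation(self):
        with pytest.raises(ValueError):
            KineticState(v=0.0)
        with pytest.raises(ValueError):
            KineticState(n_g1=-1.0)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            KineticParams(m_stress=1.5)
        with pytest.raises(ValueError):
            KineticParams(k_d=-0.1)

    def test_duration_constructor(self):
        p = KineticParams.from_durations(t_g1=10, t_s=5, t_g2m=5)
        assert p.k_g1s == pytest.approx(np.log(2) / 10)
        assert p.mu == pytest.approx(np.log(2) / 20)

    def test_state_vector_roundtrip(self, mixed_state):
        vec = mixed_state.to_vector()
        assert KineticState.from_vector(vec).to_vector().tolist() == vec.tolist()
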