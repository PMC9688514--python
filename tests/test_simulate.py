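"""Integration tests: closed-form oracles, convergence, reference integrator."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from carkin import (
    DoseSchedule,
    SimulationError,
    Trajectory,
    default_parameters,
    derivatives,
    per_capita_rate,
    simulate,
)
from carkin.synthetic import ARCHETYPES, SyntheticCohortConfig, sample_parameters
from carkin import KineticParameters


class TestClosedForms:
    def test_untreated_tumor_matches_logistic(self):
        kp = default_parameters()
        traj = simulate(kp, DoseSchedule.empty(), T0=1e7, t_end=50.0, dt=1e-3)
        K = 1.0 / kp.b
        e = np.exp(kp.r * traj.times)
        exact = K * 1e7 * e / (K + 1e7 * (e - 1.0))
        assert np.max(np.abs(traj.T / exact - 1.0)) < 1e-6
        assert np.all(traj.C == 0.0)

    def test_bolus_decay_matches_exponential(self):
        kp = default_parameters().replace(gamma=0.0, theta=0.0, alpha=0.0)
        traj = simulate(kp, DoseSchedule.single(1e8), T0=0.0,
                        t_end=20.0, dt=1e-3, grid=0.01)
        exact = 1e8 * np.exp(-(kp.beta + kp.eta) * traj.times)
        assert np.max(np.abs(traj.CD / exact - 1.0)) < 1e-6
        # half-life check
        t_half = np.log(2.0) / (kp.beta + kp.eta)
        cd_half = float(np.interp(t_half, traj.times, traj.CD))
        assert cd_half == pytest.approx(5e7, rel=1e-4)

    def test_split_dose_conserves_total(self):
        kp = default_parameters().replace(beta=0.0, eta=0.0, gamma=0.0)
        traj = simulate(kp, DoseSchedule.split(1e8), T0=0.0, t_end=5.0, dt=1e-3)
        assert traj.CD[-1] == pytest.approx(1e8, abs=1e-3)

    def test_split_fraction_warning(self):
        with pytest.warns(UserWarning, match="sum to"):
            sched = DoseSchedule.split(1e8, fractions=(0.1, 0.4, 0.6))
        # never silently normalised
        assert sched.total == pytest.approx(1.1e8)


class TestNumerics:
    def test_rk4_step_refinement(self, ref_kp):
        coarse = simulate(ref_kp, DoseSchedule.single(1e8), T0=1e7,
                          t_end=30.0, dt=2e-3, grid=0.5)
        fine = simulate(ref_kp, DoseSchedule.single(1e8), T0=1e7,
                        t_end=30.0, dt=1e-3, grid=0.5)
        scale = np.maximum(np.abs(fine.states), 1e-3)
        assert np.max(np.abs(coarse.states - fine.states) / scale) < 1e-6

    def test_against_adaptive_reference(self):
        """Fixed-step RK4 agrees with a tight-tolerance adaptive integrator."""
        cfg = SyntheticCohortConfig()
        rng = np.random.default_rng(3)
        draws = [sample_parameters(cfg, arch, rng)
                 for arch in ("CR", "PR", "SD") for _ in (0, 1)] + [
            sample_parameters(cfg, "CR", rng) for _ in range(4)]
        for kp in draws:
            traj = simulate(kp, DoseSchedule.single(1e8), T0=1e7,
                            t_end=365.0, dt=1e-3, grid=5.0)
            sol = solve_ivp(
                lambda t, y: np.array(derivatives(np.maximum(y, 0.0), t, kp)),
                (0.0, 365.0), [1e8, 0, 0, 0, 1e7],
                t_eval=traj.times, method="LSODA", rtol=1e-12, atol=1e-8)
            C_ref = sol.y[:4].sum(axis=0)
            T_ref = sol.y[4]
            # compare only above one cell: relative error on vanishingly
            # small continuum populations is meaningless
            mc = C_ref > 1.0
            mt = T_ref > 1.0
            assert np.max(np.abs(traj.C[mc] / C_ref[mc] - 1.0)) < 1e-5
            assert np.max(np.abs(traj.T[mt] / T_ref[mt] - 1.0)) < 1e-5

    def test_non_negativity_excursions_small(self, ref_traj):
        assert ref_traj.diagnostics["min_relative_excursion"] >= -1e-6
        assert np.all(ref_traj.states >= 0.0)

    def test_instability_reported_with_time(self):
        kp = default_parameters().replace(beta=5000.0)
        with pytest.raises(SimulationError, match="t = "):
            simulate(kp, DoseSchedule.single(1e8), T0=1e7, t_end=50.0, dt=0.1)

    def test_stop_when_tumor_escapes(self):
        kp = KineticParameters(**ARCHETYPES["SD"]["base"])
        traj = simulate(kp, DoseSchedule.single(1e8), T0=1e7, t_end=5000.0,
                        dt=1e-2, grid=1.0, stop_when_T_above=2e7)
        assert traj.times[-1] < 5000.0
        assert traj.T[-1] > 2e7


class TestPerCapitaRate:
    def test_pure_distribution_rate(self):
        kp = default_parameters().replace(eta=0.0, gamma=0.0)
        traj = simulate(kp, DoseSchedule.single(1e8), T0=0.0,
                        t_end=10.0, dt=1e-3, grid=0.1)
        rate = per_capita_rate(traj)
        assert np.max(np.abs(rate[1:-1] + kp.beta)) < 0.01 * kp.beta

    def test_constant_population_rate_zero(self):
        kp = default_parameters().replace(beta=0.0, eta=0.0, gamma=0.0)
        traj = simulate(kp, DoseSchedule.single(1e8), T0=0.0,
                        t_end=10.0, dt=1e-3, grid=0.1)
        assert np.max(np.abs(per_capita_rate(traj))) < 1e-9

    def test_memory_dominated_tail(self, ref_kp, ref_traj):
        rate = per_capita_rate(ref_traj)
        window = (ref_traj.times >= 60) & (ref_traj.times <= 120)
        assert np.mean(rate[window]) == pytest.approx(-ref_kp.mu, rel=0.05)

    def test_zero_population_rejected(self):
        traj = simulate(default_parameters(), DoseSchedule.empty(), T0=1e7,
                        t_end=5.0, dt=1e-3)
        with pytest.raises(ValueError):
            per_capita_rate(traj)


class TestMultiphasicShape:
    def test_four_phase_sign_pattern(self, ref_traj):
        """Decline, rise to a unique peak, fast decline, slow decline."""
        rate = per_capita_rate(ref_traj)
        t = ref_traj.times
        nadir = t[int(np.argmin(ref_traj.C[t < 10]))]
        peak = t[int(np.argmax(ref_traj.C))]
        assert 0 < nadir < peak < 20
        assert np.all(rate[(t > 0.2) & (t < nadir - 0.3)] < 0)       # distribution
        assert np.all(rate[(t > nadir + 0.3) & (t < peak - 0.3)] > 0)  # expansion
        fast = rate[(t > peak + 2) & (t < peak + 8)]
        slow = rate[(t > 60) & (t < 120)]
        assert np.all(fast < 0) and np.all(slow < 0)
        assert np.mean(np.abs(fast)) > 10 * np.mean(np.abs(slow))    # |mc| >> |mp|


class TestTrajectoryContainer:
    def test_csv_round_trip(self, ref_traj, tmp_path):
        path = tmp_path / "traj.csv"
        ref_traj.to_csv(path)
        back = Trajectory.from_csv(path)
        np.testing.assert_allclose(back.states, ref_traj.states, rtol=1e-12)
        np.testing.assert_allclose(back.times, ref_traj.times)

    def test_state_interpolation(self, ref_traj):
        sv = ref_traj.state_at(28.0)
        assert sv.C == pytest.approx(float(np.interp(28.0, ref_traj.times,
                                                     ref_traj.C)), rel=1e-9)
        assert sv.CF == sv.CD + sv.CT
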