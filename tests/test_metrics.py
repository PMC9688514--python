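"""Kinetic outcome metrics: AUCs, peak, relapse logic, outcome classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carkin import (
    DoseSchedule,
    KineticParameters,
    Trajectory,
    auc_by_phenotype,
    classify_outcome,
    default_parameters,
    non_exhausted_fraction,
    peak_summary,
    simulate,
    summarize_kinetics,
    theoretical_relapse,
)
from carkin.metrics import PHENOTYPES
from carkin.synthetic import ARCHETYPES


def make_traj(times, CD=0.0, CT=0.0, CM=0.0, CE=0.0, T=0.0):
    times = np.asarray(times, dtype=float)
    cols = []
    for comp in (CD, CT, CM, CE, T):
        cols.append(np.broadcast_to(np.asarray(comp, dtype=float),
                                    times.shape).copy())
    return Trajectory(times, np.column_stack(cols))


class TestAUC:
    def test_constant_level_rectangle(self):
        traj = make_traj(np.arange(0.0, 30.0, 0.1), CT=5e6)
        aucs = auc_by_phenotype(traj, 28.0)
        assert aucs["CT"] == pytest.approx(28 * 5e6, rel=1e-12)
        assert aucs["CD"] == aucs["CM"] == aucs["CE"] == 0.0

    def test_bolus_decay_closed_form(self):
        # trapezoid error for an exponential is ~(beta*h)^2/12 per unit area
        kp = default_parameters().replace(beta=0.3, eta=0.0, gamma=0.0)
        traj = simulate(kp, DoseSchedule.single(1e8), T0=0.0,
                        t_end=30.0, dt=1e-3, grid=0.05)
        aucs = auc_by_phenotype(traj, 28.0)
        exact = 1e8 * (1 - np.exp(-kp.beta * 28.0)) / kp.beta
        assert aucs["CD"] == pytest.approx(exact, rel=1e-4)

    def test_phenotype_sum_equals_total(self, ref_traj):
        aucs = auc_by_phenotype(ref_traj, 90.0)
        assert sum(aucs[p] for p in PHENOTYPES) == pytest.approx(
            aucs["total"], rel=1e-12)

    def test_horizon_additivity(self, ref_traj):
        a28 = auc_by_phenotype(ref_traj, 28.0)["total"]
        a60 = auc_by_phenotype(ref_traj, 60.0)["total"]
        t, C = ref_traj.times, ref_traj.C
        mask = (t > 28.0) & (t < 60.0)
        t_mid = np.concatenate([[28.0], t[mask], [60.0]])
        c_mid = np.concatenate([[np.interp(28.0, t, C)], C[mask],
                                [np.interp(60.0, t, C)]])
        a_28_60 = np.trapezoid(c_mid, t_mid)
        assert a60 == pytest.approx(a28 + a_28_60, rel=1e-12)

    def test_horizon_beyond_end_rejected(self, ref_traj):
        with pytest.raises(ValueError):
            auc_by_phenotype(ref_traj, 1e4)


class TestNonExhaustedFraction:
    @pytest.mark.parametrize("aucs, expected", [
        ({"CD": 1.0, "CT": 2.0, "CM": 1.0, "CE": 0.0, "total": 4.0}, 1.0),
        ({"CD": 0.0, "CT": 0.0, "CM": 0.0, "CE": 3.0, "total": 3.0}, 0.0),
        ({"CD": 1.0, "CT": 1.0, "CM": 1.0, "CE": 1.0, "total": 4.0}, 0.75),
    ])
    def test_values(self, aucs, expected):
        assert non_exhausted_fraction(aucs) == pytest.approx(expected)

    def test_empty_dynamics_rejected(self):
        with pytest.raises(ValueError):
            non_exhausted_fraction({p: 0.0 for p in (*PHENOTYPES, "total")})

    def test_archetype_separation(self):
        """CR exposure is less exhausted-dominated than SD exposure."""
        fractions = {}
        for arch in ("CR", "SD"):
            kp = KineticParameters(**ARCHETYPES[arch]["base"])
            traj = simulate(kp, DoseSchedule.single(1e8), T0=1e7,
                            t_end=30.0, dt=1e-2, grid=0.1)
            fractions[arch] = non_exhausted_fraction(
                auc_by_phenotype(traj, 28.0))
        assert fractions["CR"] > fractions["SD"]


class TestPeakSummary:
    def test_single_peak(self, ref_traj):
        peak = peak_summary(ref_traj, dose=1e8)
        i = int(np.argmax(ref_traj.C))
        assert peak.t_peak == ref_traj.times[i]
        assert peak.C_peak == ref_traj.C[i]
        assert sum(peak.composition.values()) == pytest.approx(peak.C_peak)

    def test_plateau_takes_earliest(self):
        times = np.arange(0.0, 10.0, 1.0)
        C = np.array([1, 2, 5, 5, 5, 4, 3, 2, 1, 1], dtype=float)
        traj = make_traj(times, CT=C)
        assert peak_summary(traj, dose=1.0).t_peak == 2.0

    def test_dose_ratio(self):
        traj = make_traj(np.arange(0.0, 5.0, 1.0),
                         CT=np.array([0, 1e9, 5e9, 1e9, 1e8]))
        assert peak_summary(traj, dose=1e8).dose_ratio == pytest.approx(50.0)


class TestTheoreticalRelapse:
    def test_constructed_crossing(self):
        times = np.arange(0.0, 400.0, 1.0)
        # below threshold from day 30, exponential regrowth crossing at 180
        T = np.where(times < 30, 1e7 * np.exp(-0.3 * times),
                     1e3 * np.exp(0.1 * (times - 30)))
        thr = 1e3 * np.exp(0.1 * 150.0)
        res = theoretical_relapse(times, T, threshold=thr, t_max=400.0)
        assert res.t_TR == pytest.approx(180.0, abs=1.0)

    def test_monotone_decay_no_recurrence(self):
        times = np.arange(0.0, 20000.0, 10.0)
        res = theoretical_relapse(times, 1e7 * np.exp(-0.01 * times),
                                  threshold=2.5e6)
        assert res.is_na and res.reason == "no_recurrence"

    def test_subthreshold_limit_cycle(self):
        times = np.arange(0.0, 20000.0, 10.0)
        T = 1e6 * (1.0 + 0.5 * np.sin(2 * np.pi * times / 500.0))
        T[times < 100] = 1e7 * np.exp(-0.1 * times[times < 100])
        res = theoretical_relapse(times, T, threshold=2.5e6)
        assert res.is_na and res.reason == "limit_cycle"

    def test_never_below_threshold(self):
        times = np.arange(0.0, 1000.0, 1.0)
        res = theoretical_relapse(times, np.full_like(times, 1e7),
                                  threshold=2.5e6)
        assert res.is_na and res.reason == "no_remission"

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            theoretical_relapse(np.arange(3.0), np.ones(3), threshold=0.0)


class TestClassifyOutcome:
    @pytest.mark.parametrize("T, expected", [
        (1e6, "CR"),      # below detection
        (4e6, "PR"),
        (1e7, "SD"),
        (2e7, "PD"),
    ])
    def test_examples(self, T, expected):
        assert classify_outcome(T, 1e7, 2.5e6) == expected

    def test_printed_class_limits(self):
        # half-open boundary convention at 0.5*T0 and 1.5*T0
        assert classify_outcome(5e6 - 1, 1e7, 2.5e6) == "PR"
        assert classify_outcome(5e6, 1e7, 2.5e6) == "SD"
        assert classify_outcome(1.5e7, 1e7, 2.5e6) == "SD"
        assert classify_outcome(1.5e7 + 1, 1e7, 2.5e6) == "PD"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(T=st.floats(1e-3, 1e13), T0=st.floats(1e5, 1e9),
           thr=st.floats(1e3, 1e7))
    def test_partition_of_positive_axis(self, T, T0, thr):
        assert classify_outcome(T, T0, thr) in {"CR", "PR", "SD", "PD"}


class TestKineticSummary:
    def test_reference_patient_summary(self, ref_kp, ref_traj):
        summary = summarize_kinetics(ref_traj, ref_kp, dose=1e8,
                                     threshold=2.5e6)
        assert set(summary.auc) == {28.0, 60.0, 90.0}
        for h in (28.0, 60.0, 90.0):
            assert 0.0 <= summary.non_exhausted[h] <= 1.0
        assert summary.EC == pytest.approx(
            ref_kp.eta / (ref_kp.beta + ref_kp.eta) * 1e8)
        # durable responder: tumor held below detection indefinitely
        assert summary.relapse.is_na
        assert summary.relapse.reason in ("limit_cycle", "no_recurrence")
        assert summary.peak_dose_ratio == summary.C_peak / 1e8
        payload = summary.to_dict()
        assert payload["t_TR"] is None
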