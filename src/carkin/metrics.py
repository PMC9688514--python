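"""Kinetic outcome metrics derived from a simulated trajectory.

Covers the standard exposure and response quantities used to stratify
CAR-T therapy outcomes: per-phenotype areas under the concentration-time
curve over 28/60/90-day horizons, the fraction of non-exhausted CAR-T cells
(CD + CT + CM) in the total exposure, the peak summary (time, height,
phenotype composition, expansion ratio relative to the dose), the expected
number of engrafted cells, the theoretical relapse time (first model
re-crossing of the tumor detection threshold), and the CR/PR/SD/PD response
classification from the tumor burden at follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import find_peaks

from .dynamics import engrafted_cells
from .parameters import KineticParameters
from .simulate import Trajectory, simulate

__all__ = [
    "PHENOTYPES",
    "auc_by_phenotype",
    "non_exhausted_fraction",
    "peak_summary",
    "PeakSummary",
    "RelapseResult",
    "theoretical_relapse",
    "classify_outcome",
    "KineticSummary",
    "summarize_kinetics",
]

PHENOTYPES = ("CD", "CT", "CM", "CE")


def auc_by_phenotype(traj: Trajectory, horizon: float) -> dict[str, float]:
    """Trapezoidal AUC of each phenotype and of the total over [0, horizon].

    Returns a mapping with keys ``CD``, ``CT``, ``CM``, ``CE`` and ``total``
    in cell*day.  The value at ``horizon`` is linearly interpolated when the
    horizon falls between grid points.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    times = traj.times
    if horizon > times[-1] + 1e-9:
        raise ValueError(
            f"horizon {horizon:g} d beyond trajectory end {times[-1]:g} d"
        )
    mask = times < horizon
    t_sub = np.append(times[mask], horizon)
    out: dict[str, float] = {}
    for name in PHENOTYPES:
        y = traj.series(name)
        y_sub = np.append(y[mask], np.interp(horizon, times, y))
        out[name] = float(np.trapezoid(y_sub, t_sub))
    out["total"] = float(sum(out[name] for name in PHENOTYPES))
    return out


def non_exhausted_fraction(aucs: Mapping[str, float]) -> float:
    """Fraction of the total CAR-T exposure carried by non-exhausted cells.

    ``(AUC_CD + AUC_CT + AUC_CM) / AUC_total``; values near 1 indicate an
    exposure dominated by functional and memory phenotypes.
    """
    total = aucs.get("total", sum(aucs[n] for n in PHENOTYPES))
    if total <= 0:
        raise ValueError("total AUC is zero: empty dynamics")
    return (aucs["CD"] + aucs["CT"] + aucs["CM"]) / total


@dataclass(frozen=True)
class PeakSummary:
    t_peak: float
    C_peak: float
    composition: dict
    dose_ratio: float


def peak_summary(traj: Trajectory, dose: float) -> PeakSummary:
    """Peak of the total CAR-T population on the output grid.

    The peak time is the argmax of C (earliest grid point on ties); the
    composition is the per-phenotype state at that time, and the dose ratio
    ``C_peak / dose`` measures how many-fold the infused product expanded.
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    if dose <= 0:
        raise ValueError("dose must be > 0")
    C = traj.C
    i = int(np.argmax(C))
    composition = {name: float(traj.series(name)[i]) for name in PHENOTYPES}
    return PeakSummary(
        t_peak=float(traj.times[i]),
        C_peak=float(C[i]),
        composition=composition,
        dose_ratio=float(C[i] / dose),
    )


@dataclass(frozen=True)
class RelapseResult:
    """Theoretical relapse time, or why none is reported.

    ``t_TR`` is the first time after the tumor drops below the detection
    threshold at which it crosses the threshold upward again (linearly
    interpolated between grid points).  ``reason`` is set instead when no
    relapse is reported: ``no_recurrence`` (never re-crosses within the
    horizon), ``limit_cycle`` (sustained sub-threshold oscillations), or
    ``no_remission`` (tumor never fell below the threshold; the bound is
    undefined in that regime).
    """

    t_TR: float | None
    reason: str | None = None

    @property
    def is_na(self) -> bool:
        return self.t_TR is None

    def to_dict(self) -> dict:
        return {"t_TR": self.t_TR, "reason": self.reason}


def theoretical_relapse(traj_or_times, T=None, *, threshold: float,
                        t_max: float = 20000.0) -> RelapseResult:
    """Locate the theoretical relapse of the tumor burden.

    Parameters
    ----------
    traj_or_times : Trajectory or array_like
        Either a trajectory or a time grid (paired with ``T``).
    T : array_like, optional
        Tumor series when the first argument is a time grid.
    threshold : cells
        Detection threshold; must be > 0.
    t_max : days
        Horizon within which a recurrence is searched (default 20,000 days).

    Notes
    -----
    The limit-cycle surrogate flags ``>= 3`` sub-threshold local maxima whose
    successive amplitude ratios lie within [0.8, 1.25] (non-decaying
    oscillation) over the last three maxima.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if isinstance(traj_or_times, Trajectory):
        times = traj_or_times.times
        tumor = traj_or_times.T
    else:
        times = np.asarray(traj_or_times, dtype=float)
        tumor = np.asarray(T, dtype=float)
    mask = times <= t_max + 1e-9
    times = times[mask]
    tumor = tumor[mask]

    below = tumor < threshold
    if not np.any(below):
        return RelapseResult(None, "no_remission")
    i0 = int(np.argmax(below))  # first sub-threshold sample

    after_t = tumor[i0:]
    after_d = times[i0:]
    up = (after_t[:-1] < threshold) & (after_t[1:] >= threshold)
    if np.any(up):
        k = int(np.argmax(up))
        t_lo, t_hi = after_d[k], after_d[k + 1]
        v_lo, v_hi = after_t[k], after_t[k + 1]
        frac = (threshold - v_lo) / (v_hi - v_lo) if v_hi > v_lo else 1.0
        return RelapseResult(float(t_lo + frac * (t_hi - t_lo)), None)

    # no up-crossing: distinguish a sustained sub-threshold cycle from decay
    peaks, _ = find_peaks(after_t)
    if peaks.size >= 3:
        amps = after_t[peaks[-3:]]
        ratios = amps[1:] / amps[:-1]
        if np.all((ratios >= 0.8) & (ratios <= 1.25)):
            return RelapseResult(None, "limit_cycle")
    return RelapseResult(None, "no_recurrence")


def classify_outcome(T_followup: float, T0: float, threshold: float) -> str:
    """Classify the therapy response from the tumor burden at follow-up.

    * ``CR`` (complete response): burden below the detection threshold.
    * ``PR`` (partial response): detectable but below 50% of the initial
      burden.
    * ``SD`` (stable disease): within +-50% of the initial burden.
    * ``PD`` (progressive disease): more than 150% of the initial burden.

    Boundary values follow a documented half-open convention: ``0.5 T0``
    and ``1.5 T0`` belong to SD.
    """
    if T_followup <= 0 or T0 <= 0 or threshold <= 0:
        raise ValueError("inputs must be positive")
    if T_followup < threshold:
        return "CR"
    if T_followup < 0.5 * T0:
        return "PR"
    if T_followup <= 1.5 * T0:
        return "SD"
    return "PD"


@dataclass
class KineticSummary:
    """Bundle of kinetic outcome metrics for one simulated patient."""

    auc: dict            # horizon -> {phenotype or "total": cell*day}
    non_exhausted: dict  # horizon -> fraction in [0, 1]
    t_peak: float
    C_peak: float
    peak_composition: dict
    peak_dose_ratio: float
    EC: float
    relapse: RelapseResult = field(default_factory=lambda: RelapseResult(None, None))
    relapse_composition: dict | None = None

    def to_dict(self) -> dict:
        return {
            "auc": {str(h): dict(v) for h, v in self.auc.items()},
            "non_exhausted_fraction": {str(h): v for h, v in self.non_exhausted.items()},
            "t_peak": self.t_peak,
            "C_peak": self.C_peak,
            "peak_composition": dict(self.peak_composition),
            "peak_dose_ratio": self.peak_dose_ratio,
            "EC": self.EC,
            "t_TR": self.relapse.t_TR,
            "t_TR_reason": self.relapse.reason,
            "relapse_composition": (
                dict(self.relapse_composition) if self.relapse_composition else None
            ),
        }


def summarize_kinetics(
    traj: Trajectory,
    kp: KineticParameters,
    dose: float,
    threshold: float,
    horizons: tuple[float, ...] = (28.0, 60.0, 90.0),
    relapse_t_max: float = 20000.0,
    relapse_grid: float = 0.5,
    dt_long: float = 1.0e-2,
) -> KineticSummary:
    """Compute the full kinetic summary for one patient trajectory.

    When the supplied trajectory is shorter than ``relapse_t_max`` the tumor
    dynamics are re-simulated out to that horizon (coarser output grid,
    internal step ``dt_long``) to locate the theoretical relapse.  The
    relapse search stops once the tumor has escaped well past its initial
    burden, where any up-crossing must already have happened.
    """
    aucs = {h: auc_by_phenotype(traj, h) for h in horizons}
    fractions = {h: non_exhausted_fraction(aucs[h]) for h in horizons}
    peak = peak_summary(traj, dose)

    T0 = float(traj.T[0])
    if traj.times[-1] >= relapse_t_max - 1e-9:
        long_traj = traj
    else:
        long_traj = simulate(
            kp, traj.schedule, T0=T0,
            t_end=relapse_t_max, dt=dt_long, grid=relapse_grid,
            stop_when_T_above=max(2.0 * T0, 2.0 * threshold),
        )
    relapse = theoretical_relapse(long_traj, threshold=threshold, t_max=relapse_t_max)
    relapse_comp = None
    if relapse.t_TR is not None:
        state = long_traj.state_at(relapse.t_TR)
        relapse_comp = {name: getattr(state, name) for name in PHENOTYPES}

    return KineticSummary(
        auc=aucs,
        non_exhausted=fractions,
        t_peak=peak.t_peak,
        C_peak=peak.C_peak,
        peak_composition=peak.composition,
        peak_dose_ratio=peak.dose_ratio,
        EC=engrafted_cells(kp, dose),
        relapse=relapse,
        relapse_composition=relapse_comp,
    )
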