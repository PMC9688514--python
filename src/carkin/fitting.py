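"""Patient-specific calibration of the CAR-T kinetics model.

The calibration loss is the sum of squared log10 residuals between the
simulated total CAR-T population C(t) and the detectable observations;
points at or below the detection threshold are censored and excluded.
Because the loss surface is multimodal and the full parameter set is not
uniquely identifiable from a single blood time course, fitting uses bounded
local least squares (scipy's trust-region reflective algorithm in log10
parameter space) with deterministic multi-start jitter, seeded by the
phase-slope analysis: ``beta`` comes from a dose-anchored regression of the
distribution decline (and stays fixed there), the expansion slope seeds
``p1 + r_min`` (given an assumed effector death rate ``xi``), the
contraction slope seeds ``delta`` and the persistence slope seeds
``mu``.  Only these slope-identified quantities should be trusted from a
fit; parameters such as ``theta``, ``alpha`` or ``epsilon`` trade off
against each other and are reported as a non-unique best-fitting set.

The statsmodels-style entry points are :class:`CARTKinetics` (the model,
built from a :class:`PatientRecord` or a data frame) and
:class:`CARTKineticsResults` (estimates, uncertainties, diagnostics,
``summary()``, and simulation/metrics hooks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import phases as phase_analysis
from .metrics import KineticSummary, classify_outcome, summarize_kinetics
from .parameters import DoseSchedule, KineticParameters, default_parameters
from .simulate import SimulationError, Trajectory, simulate

__all__ = [
    "Observation",
    "PatientRecord",
    "FitResult",
    "residual_loss",
    "fit_patient",
    "goodness_of_fit",
    "initial_parameters",
    "CARTKinetics",
    "CARTKineticsResults",
    "DEFAULT_FREE",
    "auto_free",
    "anchored_beta",
    "DEFAULT_BOUNDS",
]

#: Default free parameters: the slope-identified rates plus the expansion
#: shape and exhaustion parameters they trade off against.  ``"auto"``
#: restricts this set to the parameters the record's phase structure can
#: actually constrain (see :func:`auto_free`).
DEFAULT_FREE: tuple[str, ...] = (
    "beta", "p1", "p2", "delta", "mu", "lam",
)

#: Default box bounds (linear scale) for free parameters.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "beta": (0.02, 5.0),
    "eta": (1e-6, 1.0),
    "r_min": (1e-3, 1.0),
    "p1": (0.01, 5.0),
    "p2": (1e-3, 2.0),
    "p3": (0.5, 12.0),
    "A": (1e2, 1e8),
    "a": (1e2, 1e8),
    "xi": (0.05, 1.0),
    "epsilon": (1e-4, 0.5),
    "lam": (1e-3, 2.0),
    "theta": (1e-12, 1e-6),
    "alpha": (1e-16, 1e-6),
    "mu": (1e-4, 0.25),
    "delta": (0.02, 2.0),
    "r": (0.01, 1.0),
    "b": (1e-14, 1e-10),
    "gamma": (0.1, 10.0),
    "vartheta": (0.01, 100.0),
}

_CLASS_TARGET_MARGIN = 0.05  # dex margin pulled inside the class boundaries


class Observation(NamedTuple):
    day: float
    value: float
    censored: bool


@dataclass
class PatientRecord:
    """One patient's CAR-T time course plus dosing and outcome metadata.

    ``observations`` holds (day, value in cells, censored) triples sorted by
    day; censoring is equivalent to the value lying at or below the
    detection threshold, and censored points are excluded from calibration.
    ``provenance`` carries generator truth for synthetic patients (hidden
    from the fitting interface, used only for recovery scoring).
    """

    id: str
    schedule: DoseSchedule
    observations: tuple[Observation, ...]
    detection_threshold: float
    disease: str = "other"
    T0: float = 1.0e7
    followup_day: float | None = None
    outcome: str | None = None
    provenance: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        obs = tuple(Observation(float(d), float(v), bool(c))
                    for d, v, c in self.observations)
        if any(o.day < 0 for o in obs):
            raise ValueError("observation days must be non-negative")
        if any(b.day < a.day for a, b in zip(obs, obs[1:])):
            raise ValueError("observations must be sorted by day")
        for o in obs:
            if o.censored != (o.value <= self.detection_threshold):
                raise ValueError(
                    f"censor flag inconsistent with threshold at day {o.day:g}: "
                    f"value {o.value:g}, threshold {self.detection_threshold:g}"
                )
        object.__setattr__(self, "observations", obs)

    @classmethod
    def from_arrays(cls, id, days, values, *, detection_threshold,
                    schedule, censored=None, **meta) -> "PatientRecord":
        days = np.asarray(days, dtype=float)
        values = np.asarray(values, dtype=float)
        if censored is None:
            censored = values <= detection_threshold
        obs = tuple(Observation(float(d), float(v), bool(c))
                    for d, v, c in zip(days, values, censored))
        return cls(id=id, schedule=schedule, observations=obs,
                   detection_threshold=detection_threshold, **meta)

    @property
    def days(self) -> np.ndarray:
        return np.array([o.day for o in self.observations])

    @property
    def values(self) -> np.ndarray:
        return np.array([o.value for o in self.observations])

    @property
    def censored(self) -> np.ndarray:
        return np.array([o.censored for o in self.observations], dtype=bool)

    def uncensored(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.censored
        return self.days[keep], self.values[keep]

    @property
    def dose(self) -> float:
        return self.schedule.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.days, "value": self.values, "censored": self.censored}
        )


def _obs_grid(record: PatientRecord, t_end: float) -> np.ndarray:
    """Output grid containing every observation day exactly."""
    base = np.arange(0.0, t_end + 0.5, 1.0)
    return np.unique(np.concatenate([base, record.days, [t_end]]))


def _simulate_record(kp: KineticParameters, record: PatientRecord,
                     dt: float, t_end: float | None = None,
                     stop_when_T_above: float | None = None) -> Trajectory:
    if t_end is None:
        t_end = float(record.days.max()) + 1.0
    return simulate(kp, record.schedule, T0=record.T0, t_end=t_end,
                    dt=dt, grid=_obs_grid(record, t_end),
                    stop_when_T_above=stop_when_T_above)


def _log10_residuals(kp: KineticParameters, record: PatientRecord,
                     dt: float) -> np.ndarray:
    days, values = record.uncensored()
    traj = _simulate_record(kp, record, dt)
    c_model = np.interp(days, traj.times, traj.C)
    # zero model values at a detectable observation: large finite penalty
    c_model = np.maximum(c_model, 1e-12)
    return np.log10(c_model) - np.log10(values)


def residual_loss(kp: KineticParameters, record: PatientRecord,
                  dt: float = 1.0e-2) -> float:
    """Sum of squared log10 residuals of C(t) over detectable observations.

    Censored observations never contribute.  A model value of zero at a
    detectable observation incurs a large finite penalty rather than an
    infinite loss, so optimisers can recover.
    """
    days, _ = record.uncensored()
    if days.size == 0:
        raise ValueError("record has no detectable (uncensored) observations")
    res = _log10_residuals(kp, record, dt)
    return float(res @ res)


def goodness_of_fit(record: PatientRecord, traj: Trajectory) -> dict[str, float]:
    """Fit-quality diagnostics of a trajectory against a patient record.

    Reports the number of detectable points, the RMSE and maximum absolute
    residual in log10 space, and the fraction of censored observations whose
    model value also lies at or below the detection threshold.
    """
    days, values = record.uncensored()
    if days.size == 0:
        raise ValueError("record has no detectable (uncensored) observations")
    c_model = np.maximum(np.interp(days, traj.times, traj.C), 1e-12)
    res = np.log10(c_model) - np.log10(values)
    out = {
        "n_points": float(days.size),
        "rmse_log10": float(np.sqrt(np.mean(res ** 2))),
        "max_abs_log10": float(np.max(np.abs(res))),
    }
    cens = record.censored
    if np.any(cens):
        cd = record.days[cens]
        cm = np.interp(cd, traj.times, traj.C)
        out["censored_below_fraction"] = float(
            np.mean(cm <= record.detection_threshold)
        )
    else:
        out["censored_below_fraction"] = float("nan")
    return out


def initial_parameters(record: PatientRecord,
                       base: KineticParameters | None = None,
                       assumed_xi: float | None = None,
                       only: Sequence[str] | None = None,
                       ) -> tuple[KineticParameters, list[str]]:
    """Seed a parameter set from the phase-slope analysis of a record.

    Slope-identified estimates (beta, delta, mu, p1 + r_min) override the
    base values where available and within bounds; everything else stays at
    the base set.  ``only`` restricts which parameters may be overridden
    (used so that parameters held fixed during a fit keep their defaults
    rather than inheriting a noisy slope estimate).  Returns the seeded
    parameters and any constraint notes.
    """
    base = base if base is not None else default_parameters()
    xi = base.xi if assumed_xi is None else assumed_xi
    days, values = record.uncensored()
    notes: list[str] = []
    updates: dict[str, float] = {}
    try:
        seg = phase_analysis.segment_phases(days, values)
        slopes = phase_analysis.fit_phase_slopes(days, values, seg)
        estimates, notes = phase_analysis.slopes_to_estimates(slopes, assumed_xi=xi)
    except ValueError as exc:
        return base, [f"phase seeding unavailable: {exc}"]

    def _clip(name: str, value: float) -> float:
        lo, hi = DEFAULT_BOUNDS[name]
        return float(min(max(value, lo), hi))

    if "beta" in estimates and estimates["beta"] > 0:
        updates["beta"] = _clip("beta", estimates["beta"])
    beta_fix = anchored_beta(record)
    if beta_fix is not None:
        # dose-anchored estimate supersedes the plain slope and is applied
        # even when beta is not refined further (multi-step calibration)
        updates["beta"] = _clip("beta", beta_fix)
        if only is not None and "beta" not in only:
            only = tuple(only) + ("beta",)
    if "delta" in estimates and estimates["delta"] > 0:
        updates["delta"] = _clip("delta", estimates["delta"])
    if "mu" in estimates and estimates["mu"] > 0:
        updates["mu"] = _clip("mu", min(estimates["mu"], 0.9 * xi))
    if "p1_plus_r_min" in estimates and estimates["p1_plus_r_min"] > base.r_min:
        updates["p1"] = _clip("p1", estimates["p1_plus_r_min"] - base.r_min)
    if only is not None:
        updates = {k: v for k, v in updates.items() if k in only}
    return base.replace(xi=xi, **updates), notes


def anchored_beta(record: PatientRecord) -> float | None:
    """Distribution-phase loss rate from a dose-anchored regression.

    For a single day-0 infusion the initial condition ``C(0) = dose`` is
    known exactly, so the distribution decline can be regressed through that
    anchor: ``beta_hat = sum(t_i ln(dose/C_i)) / sum(t_i^2)`` over the
    pre-nadir detectable points (the nadir sample itself is excluded, since
    the curve flattens there).  This estimator is markedly more precise than
    an ordinary two-point slope and is the first step of the multi-step
    calibration; the refinement then keeps ``beta`` fixed at it.  Returns
    ``None`` when no usable pre-nadir point exists (split dosing, late first
    sample, or an absent distribution phase).
    """
    sched = record.schedule
    if len(sched) != 1 or sched.entries[0][0] != 0.0:
        return None
    dose = sched.total
    days, values = record.uncensored()
    if days.size == 0:
        return None
    if days.size >= 4:
        try:
            seg = phase_analysis.segment_phases(days, values)
        except ValueError:
            return None
        if seg.i_min is None or seg.i_min < 1:
            return None
        pre = np.zeros(days.size, dtype=bool)
        pre[np.arange(seg.i_min)] = True
        # keep the nadir sample when it is the only second point; with the
        # day-0 anchor the flattening bias there is modest
        if pre.sum() < 2:
            pre[seg.i_min] = True
    else:
        pre = (days <= 5.0) & (values < dose)
    t, c = days[pre], values[pre]
    if t.size == 0:
        return None
    den = float(np.sum(t * t))
    num = float(np.sum(t * np.log(dose / c)))
    if den <= 0 or num <= 0:
        return None
    return num / den


def auto_free(record: PatientRecord) -> tuple[str, ...]:
    """Free-parameter set adapted to the record's observable phase structure.

    A sparse, heavily censored time course cannot constrain rates whose
    phase it never samples: the distribution slope identifies ``beta``, the
    contraction ``delta``, the persistence ``mu``.  Parameters of absent
    phases stay fixed at their defaults rather than drifting to a bound;
    ``beta`` is excluded whenever the dose-anchored distribution estimate
    (:func:`anchored_beta`) is available, in which case the refinement keeps
    it fixed at that value.
    The expansion parameters (``p1``, ``p2``, ``lam``) are always freed.
    To keep the problem overdetermined, the free set is additionally capped
    at two fewer than the number of detectable points, dropping the least
    constrained parameters first (``mu``, then ``delta``, ``lam``, ``p2``).
    """
    free = ["p1", "p2", "lam"]
    days, values = record.uncensored()
    try:
        seg = phase_analysis.segment_phases(days, values)
        present = seg.present
    except ValueError:
        present = {}
    if anchored_beta(record) is None and present.get("distribution", True):
        free.insert(0, "beta")
    if present.get("contraction", True):
        free.append("delta")
    if present.get("persistence", True):
        free.append("mu")
    max_free = max(2, days.size - 2)
    for name in ("mu", "delta", "lam", "p2"):
        if len(free) <= max_free:
            break
        if name in free:
            free.remove(name)
    return tuple(free)


@dataclass
class FitResult:
    """Outcome of a patient-specific calibration."""

    params: KineticParameters
    loss: float
    free_names: tuple[str, ...]
    fixed_names: tuple[str, ...]
    gof: dict
    converged: bool
    stderr_log10: dict = field(default_factory=dict)
    n_starts: int = 1
    start_losses: tuple[float, ...] = ()
    seed: int | None = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loss": self.loss,
            "free": list(self.free_names),
            "fixed": list(self.fixed_names),
            "gof": dict(self.gof),
            "converged": self.converged,
            "stderr_log10": dict(self.stderr_log10),
            "n_starts": self.n_starts,
            "start_losses": list(self.start_losses),
            "seed": self.seed,
            "notes": list(self.notes),
        }


def _outcome_residual(record: PatientRecord, traj_tail_T: float,
                      weight: float) -> float:
    """Soft penalty pulling the follow-up tumor burden into the recorded class."""
    thr = record.detection_threshold
    T0 = record.T0
    lo, hi = {
        "CR": (1e-30, thr),
        "PR": (thr, 0.5 * T0),
        "SD": (0.5 * T0, 1.5 * T0),
        "PD": (1.5 * T0, 1e30),
    }[record.outcome]
    x = math.log10(max(traj_tail_T, 1e-30))
    lo_d = math.log10(lo) + _CLASS_TARGET_MARGIN if lo > 1e-29 else -math.inf
    hi_d = math.log10(hi) - _CLASS_TARGET_MARGIN if hi < 1e29 else math.inf
    if x < lo_d:
        return weight * (lo_d - x)
    if x > hi_d:
        return weight * (x - hi_d)
    return 0.0


def fit_patient(
    record: PatientRecord,
    init: KineticParameters | None = None,
    free: Sequence[str] | str = "auto",
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 5,
    dt: float = 1.0e-2,
    jitter: float = 0.3,
    outcome_weight: float = 0.0,
    max_nfev: int | None = None,
) -> FitResult:
    """Multi-start bounded least squares in log10 parameter space.

    Parameters
    ----------
    record : PatientRecord
    init : KineticParameters, optional
        Starting point; defaults to the phase-slope seeded set.
    free : sequence of parameter names, or ``"auto"``
        Parameters optimised; the rest stay fixed at ``init``.  ``"auto"``
        (default) frees only what the record's phases can constrain.
    bounds : mapping name -> (low, high), optional
        Linear-scale box bounds; defaults to :data:`DEFAULT_BOUNDS`.
    seed : int
        Seeds the multi-start jitter; identical record + seed reproduce the
        result exactly.
    n_starts : int
        Number of local searches; start 0 is ``init`` itself, the rest are
        jittered around it by N(0, ``jitter``) dex.
    outcome_weight : float
        When > 0 and the record carries an outcome label, adds a soft
        residual pulling the simulated follow-up tumor burden into the
        recorded response class (used when kinetic data cannot constrain the
        late dynamics).

    Notes
    -----
    The final loss never exceeds the loss of ``init`` (the seed is always a
    candidate).  ``converged`` is False when no local search reported
    success; the best-effort parameters are still returned.
    """
    days_u, _ = record.uncensored()
    if days_u.size == 0:
        raise ValueError("record has no detectable (uncensored) observations")
    use_outcome = outcome_weight > 0 and record.outcome is not None \
        and record.followup_day is not None
    auto = isinstance(free, str) and free == "auto"
    free = auto_free(record) if auto else tuple(free)
    if auto and use_outcome and record.outcome == "CR" \
            and "r_min" not in free:
        # durable response requires basal expansion exceeding effector
        # losses; only a free basal rate can express that regime
        free = free + ("r_min",)
    unknown = set(free) - set(DEFAULT_BOUNDS)
    if unknown:
        raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
    bounds_map = dict(DEFAULT_BOUNDS)
    if bounds:
        bounds_map.update(bounds)

    notes: list[str] = []
    if init is None:
        init, notes = initial_parameters(record, only=free)
        if use_outcome and record.outcome == "CR":
            # start inside the durable-response basin (see docs): the
            # optimiser cannot cross into it from relapse-type optima
            init = init.replace(r_min=0.9, lam=min(init.lam, 0.15))
            notes.append("seeded in the durable-response basin "
                         "(recorded CR with outcome penalty)")

    # keep mu strictly below a fixed xi so every candidate is a valid set
    if "mu" in free and "xi" not in free:
        lo, hi = bounds_map["mu"]
        bounds_map["mu"] = (lo, min(hi, 0.95 * init.xi))
    init_dict = {n: getattr(init, n) for n in free}
    for n in free:
        lo, hi = bounds_map[n]
        init_dict[n] = min(max(init_dict[n], lo), hi)
    init = init.replace(**init_dict)

    lo10 = np.array([math.log10(bounds_map[n][0]) for n in free])
    hi10 = np.array([math.log10(bounds_map[n][1]) for n in free])
    x_init = np.array([math.log10(getattr(init, n)) for n in free])

    def build(x: np.ndarray) -> KineticParameters:
        return init.replace(**{n: 10.0 ** v for n, v in zip(free, x)})

    n_res = int((~record.censored).sum()) + (1 if use_outcome else 0)

    def fun(x: np.ndarray) -> np.ndarray:
        kp = build(x)
        try:
            if use_outcome:
                t_end = max(float(record.days.max()) + 1.0, record.followup_day)
                # tumor escape past 2*T0 before follow-up counts as
                # progression, matching predicted_outcome
                traj = _simulate_record(kp, record, dt, t_end=t_end,
                                        stop_when_T_above=2.0 * record.T0)
                days, values = record.uncensored()
                c_model = np.maximum(np.interp(days, traj.times, traj.C), 1e-12)
                keep = days <= traj.times[-1]
                res = np.where(keep, np.log10(c_model) - np.log10(values), 3.0)
                if traj.times[-1] < record.followup_day - 0.5:
                    t_fu = 2.0 * record.T0
                else:
                    t_fu = float(np.interp(record.followup_day,
                                           traj.times, traj.T))
                return np.append(res,
                                 _outcome_residual(record, t_fu, outcome_weight))
            return _log10_residuals(kp, record, dt)
        except SimulationError:
            # unstable candidate (e.g. runaway tumor escape): large finite
            # penalty steers the search away without aborting it
            return np.full(n_res, 30.0)

    rng = np.random.default_rng(seed)
    starts = [x_init]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.clip(x_init + rng.normal(0.0, jitter, x_init.size),
                              lo10, hi10))

    best_x, best_loss, best_jac = x_init, float(fun(x_init) @ fun(x_init)), None
    start_losses: list[float] = []
    any_success = False
    for x0 in starts:
        try:
            sol = least_squares(
                fun, x0, bounds=(lo10, hi10), method="trf",
                ftol=1e-6, xtol=1e-6, gtol=1e-6,
                max_nfev=max_nfev if max_nfev else 40 * len(free),
            )
        except Exception as exc:  # pragma: no cover - defensive
            notes.append(f"local search failed: {exc}")
            start_losses.append(float("nan"))
            continue
        loss = float(sol.fun @ sol.fun)
        start_losses.append(loss)
        any_success = any_success or bool(sol.success)
        if loss < best_loss:
            best_x, best_loss, best_jac = sol.x, loss, sol.jac

    params = build(best_x)
    stderr: dict[str, float] = {}
    if best_jac is not None:
        n_res = best_jac.shape[0]
        dof = max(n_res - len(free), 1)
        try:
            cov = np.linalg.pinv(best_jac.T @ best_jac) * (best_loss / dof)
            stderr = {n: float(math.sqrt(max(cov[i, i], 0.0)))
                      for i, n in enumerate(free)}
        except np.linalg.LinAlgError:  # pragma: no cover
            stderr = {}

    traj = _simulate_record(params, record, dt)
    gof = goodness_of_fit(record, traj)
    data_loss = residual_loss(params, record, dt)
    return FitResult(
        params=params,
        loss=data_loss,
        free_names=free,
        fixed_names=tuple(n for n in KineticParameters.__dataclass_fields__
                          if n not in free),
        gof=gof,
        converged=any_success,
        stderr_log10=stderr,
        n_starts=len(starts),
        start_losses=tuple(start_losses),
        seed=seed,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------

class CARTKinetics:
    """Patient-level CAR-T kinetics model.

    Wraps a :class:`PatientRecord` and exposes ``fit`` returning a
    :class:`CARTKineticsResults`.

    Examples
    --------
    >>> model = CARTKinetics(record)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    """

    def __init__(self, record: PatientRecord, dt: float = 1.0e-2):
        self.record = record
        self.dt = dt

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, *, id: str = "patient",
                       dose: float | None = None,
                       schedule: DoseSchedule | None = None,
                       detection_threshold: float = 2.5e6,
                       dt: float = 1.0e-2, **meta) -> "CARTKinetics":
        """Build a model from a tidy frame with ``day`` and ``value`` columns."""
        if schedule is None:
            if dose is None:
                raise ValueError("provide dose or schedule")
            schedule = DoseSchedule.single(dose)
        censored = (frame["censored"].to_numpy(dtype=bool)
                    if "censored" in frame else None)
        record = PatientRecord.from_arrays(
            id, frame["day"].to_numpy(float), frame["value"].to_numpy(float),
            detection_threshold=detection_threshold, schedule=schedule,
            censored=censored, **meta,
        )
        return cls(record, dt=dt)

    def loss(self, kp: KineticParameters) -> float:
        return residual_loss(kp, self.record, self.dt)

    def phase_analysis(self, assumed_xi: float | None = None):
        """Segment the record and return (segmentation, slopes, estimates, notes)."""
        days, values = self.record.uncensored()
        seg = phase_analysis.segment_phases(days, values)
        slopes = phase_analysis.fit_phase_slopes(days, values, seg)
        xi = default_parameters().xi if assumed_xi is None else assumed_xi
        est, notes = phase_analysis.slopes_to_estimates(slopes, assumed_xi=xi)
        return seg, slopes, est, notes

    def fit(self, free: Sequence[str] | str = "auto", seed: int = 0,
            n_starts: int = 5, init: KineticParameters | None = None,
            **kwargs) -> "CARTKineticsResults":
        result = fit_patient(self.record, init=init, free=free, seed=seed,
                             n_starts=n_starts, dt=self.dt, **kwargs)
        return CARTKineticsResults(self, result)


class CARTKineticsResults:
    """Estimates, uncertainties and diagnostics for a fitted patient model."""

    def __init__(self, model: CARTKinetics, result: FitResult):
        self.model = model
        self.result = result

    @property
    def params(self) -> KineticParameters:
        return self.result.params

    @property
    def loss(self) -> float:
        return self.result.loss

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def bse_log10(self) -> dict[str, float]:
        """Approximate standard errors of the free parameters, in dex."""
        return dict(self.result.stderr_log10)

    def simulate(self, t_end: float | None = None, grid=0.1,
                 stop_when_T_above: float | None = None) -> Trajectory:
        record = self.model.record
        if t_end is None:
            t_end = float(record.days.max()) + 1.0
        return simulate(self.params, record.schedule, T0=record.T0,
                        t_end=t_end, dt=self.model.dt, grid=grid,
                        stop_when_T_above=stop_when_T_above)

    def kinetic_summary(self, horizons=(28.0, 60.0, 90.0),
                        relapse_t_max: float = 20000.0) -> KineticSummary:
        """Exposure, peak and relapse metrics of the fitted dynamics.

        The acute-phase simulation stops once the fitted tumor escapes past
        twice its initial burden: beyond that point the model has declared
        progression and its (possibly extreme) dynamics carry no clinical
        information.  An escape before the last AUC horizon raises, which
        the pipeline reports as a failed patient.
        """
        record = self.model.record
        t_end = max(float(record.days.max()) + 1.0, max(horizons) + 1.0)
        traj = self.simulate(t_end=t_end, stop_when_T_above=2.0 * record.T0)
        return summarize_kinetics(
            traj, self.params, record.dose, record.detection_threshold,
            horizons=horizons, relapse_t_max=relapse_t_max,
        )

    def predicted_outcome(self) -> str | None:
        """Response class of the fitted model at the recorded follow-up day.

        A fitted tumor that escapes past twice its initial burden before
        follow-up is classified as progressive disease.
        """
        record = self.model.record
        if record.followup_day is None:
            return None
        traj = self.simulate(t_end=record.followup_day, grid=0.5,
                             stop_when_T_above=2.0 * record.T0)
        if traj.times[-1] < record.followup_day - 0.5:
            return "PD"
        t_fu = float(traj.T[-1])
        return classify_outcome(max(t_fu, 1e-30), record.T0,
                                record.detection_threshold)

    def outcome_consistent(self) -> bool | None:
        """Whether the predicted class matches the recorded outcome (if any)."""
        record = self.model.record
        if record.outcome is None or record.followup_day is None:
            return None
        return self.predicted_outcome() == record.outcome

    def summary(self) -> str:
        rec = self.model.record
        res = self.result
        lines = [
            "CAR-T kinetics fit",
            "=" * 60,
            f"patient: {rec.id}    disease: {rec.disease}    "
            f"dose: {rec.dose:.3g} cells",
            f"observations: {len(rec.observations)} "
            f"({int((~rec.censored).sum())} detectable)    "
            f"threshold: {rec.detection_threshold:.3g} cells",
            f"loss (sum sq log10): {res.loss:.4g}    "
            f"rmse: {res.gof['rmse_log10']:.3f} dex    "
            f"converged: {res.converged}",
            "-" * 60,
            f"{'parameter':<10}{'estimate':>14}{'se (dex)':>12}  status",
        ]
        for name in KineticParameters.__dataclass_fields__:
            value = getattr(res.params, name)
            if name in res.free_names:
                se = res.stderr_log10.get(name)
                se_s = f"{se:>12.3f}" if se is not None else f"{'--':>12}"
                lines.append(f"{name:<10}{value:>14.4g}{se_s}  free")
            else:
                lines.append(f"{name:<10}{value:>14.4g}{'--':>12}  fixed")
        lines.append("-" * 60)
        if rec.outcome is not None:
            pred = self.predicted_outcome()
            lines.append(f"recorded outcome: {rec.outcome}    "
                         f"model at follow-up: {pred}")
        if res.notes:
            lines.append("notes: " + "; ".join(str(n) for n in res.notes))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observations (censored greyed) over the fitted trajectory."""
        import matplotlib.pyplot as plt

        record = self.model.record
        traj = self.simulate(t_end=float(record.days.max()) + 1.0)
        if ax is None:
            _, ax = plt.subplots()
        traj.plot(ax=ax)
        cens = record.censored
        ax.plot(record.days[~cens], record.values[~cens], "ko", label="data")
        if np.any(cens):
            ax.plot(record.days[cens], record.values[cens], "o",
                    color="0.7", label="censored")
        ax.axhline(record.detection_threshold, color="0.6", ls=":")
        ax.legend(fontsize=8)
        return ax
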