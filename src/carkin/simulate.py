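"""Fixed-step RK4 integration of the CAR-T/tumor system with impulsive dosing.

The integrator steps the five-compartment system with the classical explicit
fourth-order Runge-Kutta scheme at a dense internal step ``dt`` (default
1e-3 day) while recording states only on a sparse output grid (default
0.1 day), which keeps decade-long trajectories memory-light.  Doses are
instantaneous additions to the distributed compartment ``CD`` at their
scheduled day; the state reported at a dose time is the post-infusion state,
so ``CD(0)`` equals the day-0 dose.

The inner loop is JIT-compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .parameters import DoseSchedule, KineticParameters, StateVector

__all__ = ["Trajectory", "SimulationError", "simulate", "per_capita_rate"]

_COLUMNS = ("CD", "CT", "CM", "CE", "T")


class SimulationError(RuntimeError):
    """Raised when the integration produces a non-finite state."""


@njit(cache=False)
def _rhs(t, y, p, dy):
    beta = p[0]; eta = p[1]; r_min = p[2]; p1 = p[3]; p2 = p[4]; p3 = p[5]
    A = p[6]; a = p[7]; xi = p[8]; eps = p[9]; lam = p[10]; theta = p[11]
    alpha = p[12]; mu = p[13]; delta = p[14]; r = p[15]; b = p[16]
    gamma = p[17]; varth = p[18]

    CD = y[0]; CT = y[1]; CM = y[2]; CE = y[3]; T = y[4]
    kappa = r_min + p1 / (1.0 + (p2 * t) ** p3)
    F = T / (A + T) if T > 0.0 else 0.0
    CF = CD + CT
    denom = varth * T + a + CF
    f = CF / denom if denom > 0.0 else 0.0

    dy[0] = -(beta + eta) * CD
    dy[1] = (eta * CD + kappa * F * CT - (xi + eps + lam) * CT
             + theta * T * CM - alpha * T * CT)
    dy[2] = eps * CT - theta * T * CM - mu * CM
    dy[3] = lam * CT - delta * CE
    dy[4] = r * T * (1.0 - b * T) - gamma * f * T


@njit(cache=False)
def _advance(y, t0, t1, dt, p, k1, k2, k3, k4, yt):
    """Advance ``y`` in place from ``t0`` to ``t1`` with fixed RK4 steps."""
    span = t1 - t0
    if span <= 0.0:
        return
    nfull = int(np.floor(span / dt + 1e-9))
    for step in range(nfull + 1):
        t = t0 + step * dt
        h = dt if step < nfull else (t1 - t)
        if h <= 1e-12:
            break
        _rhs(t, y, p, k1)
        for i in range(5):
            yt[i] = y[i] + 0.5 * h * k1[i]
        _rhs(t + 0.5 * h, yt, p, k2)
        for i in range(5):
            yt[i] = y[i] + 0.5 * h * k2[i]
        _rhs(t + 0.5 * h, yt, p, k3)
        for i in range(5):
            yt[i] = y[i] + h * k3[i]
        _rhs(t + h, yt, p, k4)
        for i in range(5):
            y[i] += h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=False)
def _integrate_segment(y, t_cur, out_times, j_start, j_stop, dt, p, states,
                       run_max, stop_T):
    """Fill ``states`` for output indices [j_start, j_stop), no doses inside.

    Clips small negative excursions to zero at each output sample, tracking
    the most negative excursion relative to the running maximum.  Returns
    (last index filled + 1, min excursion, flag) where flag is 1 on a
    non-finite state, 2 when the tumor bound ``stop_T`` was exceeded.
    """
    k1 = np.empty(5); k2 = np.empty(5); k3 = np.empty(5); k4 = np.empty(5)
    yt = np.empty(5)
    min_exc = 0.0
    for j in range(j_start, j_stop):
        t_out = out_times[j]
        if t_out > t_cur:
            _advance(y, t_cur, t_out, dt, p, k1, k2, k3, k4, yt)
            t_cur = t_out
        for i in range(5):
            if not np.isfinite(y[i]):
                return j, min_exc, 1
            if y[i] < 0.0:
                rm = run_max[i] if run_max[i] > 1e-300 else 1e-300
                exc = y[i] / rm
                if exc < min_exc:
                    min_exc = exc
                y[i] = 0.0
            states[j, i] = y[i]
            if y[i] > run_max[i]:
                run_max[i] = y[i]
        if stop_T > 0.0 and y[4] > stop_T:
            return j + 1, min_exc, 2
    return j_stop, min_exc, 0


@dataclass
class Trajectory:
    """A simulated time course on an output grid.

    Attributes
    ----------
    times : ndarray, days
        Strictly increasing output grid starting at 0.
    states : ndarray, shape (n, 5)
        Columns ``(CD, CT, CM, CE, T)`` in cells, clipped to be >= 0.
    dt : float, days
        Internal integration step used to produce the trajectory.
    schedule : DoseSchedule
    diagnostics : dict
        ``min_relative_excursion``: most negative pre-clip component value
        relative to that component's running maximum (0 when none occurred).
    """

    times: np.ndarray
    states: np.ndarray
    dt: float = float("nan")
    schedule: DoseSchedule = field(default_factory=DoseSchedule.empty)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 5):
            raise ValueError("states must have shape (len(times), 5)")

    # -- derived series ---------------------------------------------------
    @property
    def CD(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def CT(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def CM(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def CE(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def CF(self) -> np.ndarray:
        """Functional CAR-T cells, CD + CT."""
        return self.states[:, 0] + self.states[:, 1]

    @property
    def C(self) -> np.ndarray:
        """Total CAR-T cells, CD + CT + CM + CE."""
        return self.states[:, :4].sum(axis=1)

    def state_at(self, t: float) -> StateVector:
        """Linearly interpolated state at time ``t``."""
        comps = [float(np.interp(t, self.times, self.states[:, j])) for j in range(5)]
        return StateVector(*comps)

    def series(self, name: str) -> np.ndarray:
        if name in _COLUMNS:
            return self.states[:, _COLUMNS.index(name)]
        if name == "C":
            return self.C
        if name == "CF":
            return self.CF
        raise KeyError(name)

    # -- IO ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states, columns=list(_COLUMNS))
        frame.insert(0, "time", self.times)
        frame["C"] = self.C
        frame["CF"] = self.CF
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        frame = pd.read_csv(path)
        states = frame[list(_COLUMNS)].to_numpy(dtype=float)
        return cls(frame["time"].to_numpy(dtype=float), states)

    def plot(self, ax=None, log=True):
        """Quick-look plot of the phenotype series and the tumor burden."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in ("CD", "CT", "CM", "CE"):
            ax.plot(self.times, self.series(name), label=name, lw=1)
        ax.plot(self.times, self.C, "k-", label="C (total CAR-T)", lw=1.5)
        ax.plot(self.times, self.T, "r--", label="T (tumor)", lw=1.5)
        if log:
            ax.set_yscale("log")
        ax.set_xlabel("time (days)")
        ax.set_ylabel("cells")
        ax.legend(fontsize=8)
        return ax


def _build_grid(t_end: float, grid) -> np.ndarray:
    if np.ndim(grid) > 0:
        out = np.asarray(grid, dtype=float)
        if out.size == 0 or out[0] != 0.0 or np.any(np.diff(out) <= 0):
            raise ValueError("an explicit output grid must start at 0 and increase")
        if out[-1] > t_end + 1e-9:
            raise ValueError("output grid extends beyond t_end")
        return out
    step = float(grid)
    if step <= 0:
        raise ValueError("output grid step must be > 0")
    out = np.arange(0.0, t_end + 0.5 * step, step)
    if out[-1] < t_end - 1e-9:
        out = np.append(out, t_end)
    else:
        out[-1] = min(out[-1], t_end)
    return out


def simulate(
    kp: KineticParameters,
    schedule: DoseSchedule,
    T0: float = 1.0e7,
    t_end: float = 365.0,
    dt: float = 1.0e-3,
    grid=0.1,
    stop_when_T_above: float | None = None,
) -> Trajectory:
    """Integrate the model from ``t = 0`` to ``t_end``.

    The initial state is ``(0, 0, 0, 0, T0)``; each scheduled dose is added
    impulsively to ``CD`` at its day (so a day-0 dose makes ``CD(0)`` the
    infused dose, and all other phenotypes start at zero).

    Parameters
    ----------
    kp : KineticParameters
    schedule : DoseSchedule
        May be empty for an untreated control run.
    T0 : cells
        Initial tumor burden (default 1e7 cells).
    t_end : days
    dt : days
        Internal RK4 step (default 1e-3).
    grid : float or array_like
        Output sampling: a step in days (default 0.1) or an explicit grid
        starting at 0.
    stop_when_T_above : cells, optional
        Truncate the trajectory at the first output sample where the tumor
        exceeds this bound (useful for relapse searches: once the tumor has
        escaped well past the detection threshold the remaining dynamics are
        irrelevant and can be arbitrarily stiff).

    Raises
    ------
    SimulationError
        If the state becomes non-finite, naming the first bad output time.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if T0 < 0:
        raise ValueError("T0 must be >= 0")

    out_times = _build_grid(t_end, grid)
    p = kp.as_array()
    y = np.array([0.0, 0.0, 0.0, 0.0, float(T0)])
    states = np.empty((out_times.size, 5))
    run_max = np.maximum(y, 0.0)
    stop_T = float(stop_when_T_above) if stop_when_T_above is not None else -1.0

    doses = [(d, c) for d, c in zip(schedule.days, schedule.amounts)
             if d <= t_end + 1e-9] if len(schedule) else []

    scratch = tuple(np.empty(5) for _ in range(5))
    t_cur = 0.0
    j = 0
    min_excursion = 0.0
    flag = 0
    # integrate dose-to-dose segments; each kernel call fills the output
    # samples strictly before the next dose event
    events = doses + [(t_end + 1.0, 0.0)]
    for d_day, d_cells in events:
        j_stop = int(np.searchsorted(out_times, d_day - 1e-12))
        j, exc, flag = _integrate_segment(
            y, t_cur, out_times, j, j_stop, dt, p, states, run_max, stop_T)
        min_excursion = min(min_excursion, exc)
        if flag:
            break
        t_cur = max(t_cur, out_times[j - 1]) if j > 0 else t_cur
        if d_day <= t_end + 1e-9 and d_cells > 0.0:
            if d_day > t_cur:
                _advance(y, t_cur, d_day, dt, p, *scratch)
                t_cur = d_day
            y[0] += d_cells

    if flag == 1:
        raise SimulationError(
            f"integration unstable: non-finite state first detected at "
            f"t = {out_times[min(j, out_times.size - 1)]:g} days "
            f"(dt = {dt:g}); consider reducing dt"
        )
    if j < out_times.size:  # truncated by the tumor bound
        out_times = out_times[:j]
        states = states[:j]

    return Trajectory(
        out_times,
        states,
        dt=dt,
        schedule=schedule,
        diagnostics={"min_relative_excursion": min_excursion},
    )


def per_capita_rate(traj: Trajectory) -> np.ndarray:
    """Per-capita growth rate of the total CAR-T population, (1/C) dC/dt.

    Computed with centered finite differences on the output grid (one-sided
    at the ends).  The series diagnoses the four kinetic phases: it is close
    to ``-beta`` during distribution, ``r_min + p1 - xi`` during expansion,
    ``-delta`` during contraction and ``-mu`` during persistence.
    """
    C = traj.C
    if np.any(C <= 0):
        raise ValueError("per-capita rate undefined where C = 0")
    return np.gradient(C, traj.times) / C
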