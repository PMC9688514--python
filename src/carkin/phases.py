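"""Piecewise log-linear decomposition of a CAR-T time course.

Clinical CAR-T kinetics in peripheral blood follow a multiphasic shape:
an initial decline while infused cells redistribute (distribution), an
antigen-driven exponential rise to a peak (expansion), a steep post-peak
decline as effector and exhausted cells die (contraction), and a shallow
long tail carried by memory cells (persistence).  Each phase is
approximately a straight line in a log plot, and the four slopes map onto
model parameters:

=============  =====================  =========================
phase          slope (natural log)    parameter identification
=============  =====================  =========================
distribution   ``md``                 ``md ~ -beta``
expansion      ``me``                 ``me ~ r_min + p1 - xi``
contraction    ``mc``                 ``mc ~ -delta``
persistence    ``mp``                 ``mp ~ -mu``
=============  =====================  =========================

Segmentation is automated and deterministic: the expansion/contraction
boundary is the global maximum of the log counts (earliest on ties), the
distribution/expansion boundary is the pre-peak minimum, and the
contraction/persistence boundary minimises the total squared error of a
two-segment log-linear fit over the post-peak points, accepted only when a
BIC comparison favours two segments over one.  Slopes are ordinary least
squares of ln(count) against time within each phase; the extremum samples
shared between phases (nadir, peak) are excluded from a phase's fit whenever
at least two other points remain, because the series flattens there and
would otherwise bias the slope toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhaseSegmentation",
    "PhaseSlopes",
    "segment_phases",
    "fit_phase_slopes",
    "slopes_to_estimates",
    "PHASES",
]

PHASES = ("distribution", "expansion", "contraction", "persistence")

_LN10 = math.log(10.0)


@dataclass
class PhaseSegmentation:
    """Index-based split of an observation series into up to four phases."""

    days: np.ndarray
    i_min: int | None
    i_peak: int
    i_split: int | None
    present: dict = field(default_factory=dict)

    @property
    def boundaries(self) -> tuple[float | None, float | None, float | None]:
        """Interior breakpoints in days: (nadir, peak, contraction end)."""
        b1 = float(self.days[self.i_min]) if self.i_min is not None else None
        b2 = float(self.days[self.i_peak])
        b3 = float(self.days[self.i_split]) if self.i_split is not None else None
        return (b1, b2, b3)

    def phase_indices(self, phase: str) -> np.ndarray:
        n = self.days.size
        i_min = self.i_min if self.i_min is not None else 0
        if phase == "distribution":
            lo, hi = 0, i_min
        elif phase == "expansion":
            lo, hi = i_min, self.i_peak
        elif phase == "contraction":
            lo = self.i_peak
            hi = self.i_split if self.i_split is not None else n - 1
        elif phase == "persistence":
            if self.i_split is None:
                return np.array([], dtype=int)
            lo, hi = self.i_split, n - 1
        else:
            raise KeyError(phase)
        return np.arange(lo, hi + 1)

    def to_dict(self) -> dict:
        b1, b2, b3 = self.boundaries
        return {
            "boundaries": {"nadir": b1, "peak": b2, "contraction_end": b3},
            "present": dict(self.present),
        }


@dataclass
class PhaseSlopes:
    """Natural-log slopes per phase; absent phases carry ``None``."""

    md: float | None = None
    me: float | None = None
    mc: float | None = None
    mp: float | None = None
    stderr: dict = field(default_factory=dict)
    n_points: dict = field(default_factory=dict)

    _BY_PHASE = {
        "distribution": "md",
        "expansion": "me",
        "contraction": "mc",
        "persistence": "mp",
    }

    def slope(self, phase: str) -> float | None:
        return getattr(self, self._BY_PHASE[phase])

    def confidence_interval(self, phase: str, level: float = 0.95):
        """t-based OLS confidence interval for one phase slope."""
        from scipy import stats

        name = self._BY_PHASE[phase]
        value = getattr(self, name)
        se = self.stderr.get(name)
        n = self.n_points.get(name, 0)
        if value is None or se is None or n < 3:
            return (-np.inf, np.inf) if value is not None else None
        tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 2)
        return (value - tcrit * se, value + tcrit * se)

    def to_dict(self) -> dict:
        return {
            "md": self.md,
            "me": self.me,
            "mc": self.mc,
            "mp": self.mp,
            "stderr": dict(self.stderr),
            "n_points": dict(self.n_points),
        }


def _check_series(days, values) -> tuple[np.ndarray, np.ndarray]:
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.shape != values.shape or days.ndim != 1:
        raise ValueError("days and values must be 1-D arrays of equal length")
    if days.size < 4:
        raise ValueError("need at least 4 observations to segment phases")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("values must be positive and finite (drop censored points)")
    return days, values


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Return (slope, sse, stderr_of_slope) of a degree-1 OLS fit."""
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate (vertical) phase fit: repeated time values")
    se = math.sqrt(sse / max(n - 2, 1) / sxx) if n > 2 else float("inf")
    return float(slope), sse, se


def segment_phases(days, values, peak_hint: float | None = None) -> PhaseSegmentation:
    """Split an observation series into distribution/expansion/contraction/persistence.

    Parameters
    ----------
    days, values : array_like
        Positive, uncensored observations sorted by day (at least 4).
    peak_hint : days, optional
        Restrict the peak search to points within +-30% of the series span
        around this time (manual override for multi-modal series).

    Notes
    -----
    * The expansion/contraction boundary is the global argmax of the log
      values (earliest sample on ties).
    * The distribution/expansion boundary is the argmin before the peak; the
      distribution phase is flagged absent when that argmin is the first
      sample.
    * The contraction/persistence boundary minimises the summed SSE of a
      two-segment log-linear fit over the post-peak points (segments share
      the boundary sample and need >= 2 points each); the split is accepted
      only when BIC favours two segments over one, so a post-peak series that
      is a single line yields contraction only.
    * Phases with fewer than 2 points are flagged absent.
    """
    days, values = _check_series(days, values)
    logv = np.log(values)
    n = days.size

    if peak_hint is not None:
        span = days[-1] - days[0]
        window = np.abs(days - peak_hint) <= 0.3 * span
        if np.any(window):
            cand = np.flatnonzero(window)
            i_peak = int(cand[np.argmax(logv[cand])])
        else:
            i_peak = int(np.argmax(logv))
    else:
        i_peak = int(np.argmax(logv))

    if i_peak >= 1:
        i_min: int | None = int(np.argmin(logv[: i_peak + 1]))
    else:
        i_min = None
    distribution_present = i_min is not None and i_min >= 1
    expansion_present = i_min is not None and (i_peak - i_min) >= 1
    if not distribution_present and i_min == 0:
        i_min = 0  # expansion starts at the first sample

    # post-peak two-segment scan
    post = np.arange(i_peak, n)
    m = post.size
    i_split: int | None = None
    if m >= 4:
        x, y = days[post], logv[post]
        _, sse1, _ = _ols(x, y)
        eps = 1e-12
        bic1 = m * math.log(max(sse1, eps) / m) + 2.0 * math.log(m)
        best = (math.inf, None)
        for j in range(1, m - 1):
            _, sse_l, _ = _ols(x[: j + 1], y[: j + 1])
            _, sse_r, _ = _ols(x[j:], y[j:])
            sse2 = sse_l + sse_r
            if sse2 < best[0]:
                best = (sse2, j)
        sse2, j_best = best
        bic2 = m * math.log(max(sse2, eps) / m) + 5.0 * math.log(m)
        if bic2 < bic1 and j_best is not None:
            i_split = int(post[j_best])

    contraction_present = m >= 2
    persistence_present = i_split is not None

    seg = PhaseSegmentation(
        days=days,
        i_min=i_min if (distribution_present or expansion_present) else None,
        i_peak=i_peak,
        i_split=i_split,
        present={
            "distribution": distribution_present,
            "expansion": expansion_present,
            "contraction": contraction_present,
            "persistence": persistence_present,
        },
    )
    return seg


def _best_linear_window(x: np.ndarray, y: np.ndarray,
                        min_frac: float = 0.6) -> np.ndarray:
    """Indices of the most log-linear contiguous sub-window of a phase.

    Each phase of the true dynamics is only asymptotically a straight line:
    near its boundaries the curve bends (effector influx at the start of
    expansion, the exhausted-cell shoulder after the peak, residual fast
    modes early in persistence).  For densely sampled phases (>= 6 points)
    the slope is therefore fitted on the contiguous window of at least
    ``min_frac`` of the points minimising the residual SSE per degree of
    freedom; exact lines are unaffected (every window fits exactly, and ties
    prefer the longest, earliest window).  Sparse phases are used whole.
    """
    n = x.size
    if n < 6:
        return np.arange(n)
    w_min = max(4, int(math.ceil(min_frac * n)))
    best = (math.inf, -10**9, 0, n)  # (sse/dof, -length, start, stop)
    for length in range(w_min, n + 1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            _, sse, _ = _ols(x[sl], y[sl])
            key = (sse / (length - 2) + 1e-15, -length, start, start + length)
            if key < best:
                best = key
    return np.arange(best[2], best[3])


def fit_phase_slopes(days, values, seg: PhaseSegmentation,
                     trim_extrema: bool = True) -> PhaseSlopes:
    """Ordinary least squares of ln(count) vs time within each present phase.

    With ``trim_extrema`` (default), the shared nadir/peak samples are
    dropped from a phase's point set whenever at least two points remain,
    since the series flattens at its extrema and the boundary samples bias
    the slope toward zero.  Densely sampled phases are additionally fitted
    on their most log-linear contiguous sub-window (see
    :func:`_best_linear_window`).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    logv = np.log(values)

    drop_by_phase = {
        "distribution": [seg.i_min],
        "expansion": [seg.i_peak, seg.i_min],
        "contraction": [seg.i_peak],
        "persistence": [],
    }

    slopes = PhaseSlopes()
    for phase in PHASES:
        if not seg.present.get(phase, False):
            continue
        idx = list(seg.phase_indices(phase))
        if trim_extrema:
            for d in drop_by_phase[phase]:
                if d is not None and d in idx and len(idx) - 1 >= 2:
                    idx.remove(d)
        if len(idx) < 2:
            continue
        idx_arr = np.asarray(idx, dtype=int)
        sub = _best_linear_window(days[idx_arr], logv[idx_arr])
        idx_arr = idx_arr[sub]
        slope, _, se = _ols(days[idx_arr], logv[idx_arr])
        name = PhaseSlopes._BY_PHASE[phase]
        setattr(slopes, name, slope)
        slopes.stderr[name] = se
        slopes.n_points[name] = len(idx_arr)
    return slopes


def slopes_to_estimates(slopes: PhaseSlopes, assumed_xi: float,
                        ) -> tuple[dict[str, float], list[str]]:
    """Map observed phase slopes to first-pass parameter estimates.

    Identifications: ``beta = -md``, ``p1 + r_min = me + assumed_xi``,
    ``delta = -mc``, ``mu = -mp``.  The effector death rate ``xi`` is not
    identifiable from the expansion slope alone and must be assumed (it is
    fixed during calibration refinement).

    Returns
    -------
    estimates : dict
        Keys among ``beta``, ``p1_plus_r_min``, ``delta``, ``mu``; slopes
        from absent phases yield no entry.
    warnings : list of str
        Non-fatal constraint violations (e.g. ``mu >= assumed_xi``); the
        estimates are reported as-is, never silently altered.
    """
    if all(s is None for s in (slopes.md, slopes.me, slopes.mc, slopes.mp)):
        raise ValueError("no phase slopes available")
    estimates: dict[str, float] = {}
    notes: list[str] = []
    if slopes.md is not None:
        estimates["beta"] = -slopes.md
        if slopes.md > 0:
            notes.append("distribution slope is positive; beta estimate is negative")
    if slopes.me is not None:
        estimates["p1_plus_r_min"] = slopes.me + assumed_xi
        if estimates["p1_plus_r_min"] <= 0:
            notes.append("expansion slope too negative for assumed xi")
    if slopes.mc is not None:
        estimates["delta"] = -slopes.mc
        if slopes.mc > 0:
            notes.append("contraction slope is positive; delta estimate is negative")
    if slopes.mp is not None:
        estimates["mu"] = -slopes.mp
        if slopes.mp > 0:
            notes.append("persistence slope is positive; mu estimate is negative")
        elif estimates["mu"] >= assumed_xi:
            notes.append(
                f"estimated mu={estimates['mu']:.4g} >= assumed xi={assumed_xi:.4g} "
                "(memory should outlive effectors)"
            )
    return estimates, notes
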