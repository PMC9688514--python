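"""Right-hand side of the phenotype-structured CAR-T/tumor ODE system.

The model couples five populations::

    dCD/dt = -(beta + eta) CD
    dCT/dt = eta CD + kappa(t) F(T) CT - (xi + epsilon + lam) CT
             + theta T CM - alpha T CT
    dCM/dt = epsilon CT - theta T CM - mu CM
    dCE/dt = lam CT - delta CE
    dT/dt  = r T (1 - b T) - gamma f(CF, T) T

with the time-dependent antigen-modulated expansion rate
``kappa(t) = r_min + p1 / (1 + (p2 t)^p3)``, the antigen saturation
``F(T) = T / (A + T)``, and the cytotoxicity saturation
``f(CF, T) = CF / (vartheta T + a + CF)`` where ``CF = CD + CT``.

The cytotoxicity function has the two standard limits: when the tumor
dwarfs the functional pool (``T >> CF``) the kill term reduces to
``gamma CF / vartheta`` (killing limited by the number of killers), and when
killers dwarf the tumor (``T << CF``) it saturates at ``gamma T`` (killing
limited by available targets).
"""

from __future__ import annotations

import numpy as np

from .parameters import KineticParameters, StateVector

__all__ = [
    "expansion_rate",
    "antigen_saturation",
    "kill_saturation",
    "derivatives",
    "engrafted_cells",
]


def _as_float_or_array(x, like):
    """Return a scalar float when the input was scalar, else an ndarray."""
    return float(x) if np.isscalar(like) or np.ndim(like) == 0 else x


def expansion_rate(t, kp: KineticParameters):
    """Antigen-independent part of the effector expansion rate, ``kappa(t)``.

    Decays from ``r_min + p1`` at infusion toward the basal rate ``r_min``;
    ``p2`` sets the plateau duration (the rate is half-way down at
    ``t = 1/p2``) and ``p3`` the sharpness of the decay.

    Parameters
    ----------
    t : float or array_like, days
        Time since the first infusion; must be >= 0.
    kp : KineticParameters
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("expansion_rate requires t >= 0")
    out = kp.r_min + kp.p1 / (1.0 + (kp.p2 * t_arr) ** kp.p3)
    return _as_float_or_array(out, t)


def antigen_saturation(T, A):
    """Antigen availability factor ``F(T) = T / (A + T)`` in [0, 1).

    Equals 0.5 when the tumor burden equals the half-saturation constant
    ``A``; effector expansion only proceeds in the presence of antigen.
    """
    if A <= 0:
        raise ValueError("antigen half-saturation A must be > 0")
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr < 0):
        raise ValueError("tumor burden must be >= 0")
    out = T_arr / (A + T_arr)
    return _as_float_or_array(out, T)


def kill_saturation(CF, T, vartheta, a):
    """Cytotoxicity saturation ``f(CF, T) = CF / (vartheta T + a + CF)``.

    Values lie in [0, 1]; the function is increasing in the functional pool
    ``CF`` and decreasing in the tumor burden ``T``.  ``f`` reaches one half
    when ``CF = vartheta T + a``.
    """
    if vartheta < 0 or a < 0:
        raise ValueError("vartheta and a must be >= 0")
    CF_arr = np.asarray(CF, dtype=float)
    T_arr = np.asarray(T, dtype=float)
    if np.any(CF_arr < 0) or np.any(T_arr < 0):
        raise ValueError("cell counts must be >= 0")
    denom = vartheta * T_arr + a + CF_arr
    if np.any(denom == 0):
        raise ValueError(
            "kill_saturation undefined: vartheta*T + a + CF = 0 "
            "(invalid parameters for an empty system)"
        )
    out = CF_arr / denom
    return _as_float_or_array(out, CF if np.ndim(CF) else T)


def derivatives(state, t: float, kp: KineticParameters) -> StateVector:
    """Time derivatives ``(dCD, dCT, dCM, dCE, dT)`` in cells/day.

    ``state`` may be a :class:`StateVector` or any length-5 sequence ordered
    ``(CD, CT, CM, CE, T)``.
    """
    arr = np.asarray(state, dtype=float)
    if arr.shape != (5,):
        raise ValueError("state must have five components (CD, CT, CM, CE, T)")
    if not np.all(np.isfinite(arr)) or not np.isfinite(t):
        raise ValueError("non-finite state or time")
    if t < 0:
        raise ValueError("t must be >= 0")
    CD, CT, CM, CE, T = arr

    kappa = expansion_rate(t, kp)
    F = antigen_saturation(T, kp.A) if T > 0 else 0.0
    CF = CD + CT
    f = kill_saturation(CF, T, kp.vartheta, kp.a)

    dCD = -(kp.beta + kp.eta) * CD
    dCT = (
        kp.eta * CD
        + kappa * F * CT
        - (kp.xi + kp.epsilon + kp.lam) * CT
        + kp.theta * T * CM
        - kp.alpha * T * CT
    )
    dCM = kp.epsilon * CT - kp.theta * T * CM - kp.mu * CM
    dCE = kp.lam * CT - kp.delta * CE
    dT = kp.r * T * (1.0 - kp.b * T) - kp.gamma * f * T
    return StateVector(dCD, dCT, dCM, dCE, dT)


def engrafted_cells(kp: KineticParameters, dose: float) -> float:
    """Expected total number of engrafted CAR-T cells for a given dose.

    With distributed cells decaying as ``CD(t) = dose * exp(-(beta+eta) t)``
    and engrafting at rate ``eta``, the engrafted total is the integral
    ``EC = integral eta CD(t) dt = eta / (beta + eta) * dose``.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    denom = kp.beta + kp.eta
    if denom == 0:
        raise ValueError("engrafted cells undefined when beta + eta = 0")
    return kp.eta / denom * dose
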