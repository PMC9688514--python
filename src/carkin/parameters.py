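"""Parameter, state, and dosing containers for the CAR-T kinetics model.

The model tracks five cell populations: distributed CAR-T cells (``CD``,
freshly infused cytotoxic cells redistributing through the body), effector
CAR-T cells (``CT``, engrafted functional cells), memory CAR-T cells (``CM``),
exhausted CAR-T cells (``CE``), and tumor cells (``T``).  All populations are
absolute cell numbers; times are in days and rates in day^-1.

:class:`KineticParameters` holds the 19 model constants.  Parameter sets are
serialisable to flat YAML/JSON mappings using the conventional symbol names
(``beta``, ``eta``, ``r_min``, ``p1``, ``p2``, ``p3``, ``A``, ``a``, ``xi``,
``epsilon``, ``lambda``, ``theta``, ``alpha``, ``mu``, ``delta``, ``r``,
``b``, ``gamma``, ``vartheta``); the Python attribute for the exhaustion rate
is ``lam`` because ``lambda`` is a keyword.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import yaml

__all__ = [
    "PARAM_NAMES",
    "KineticParameters",
    "StateVector",
    "DoseSchedule",
    "default_parameters",
    "reference_parameters",
]

#: Canonical parameter order, used for array round-trips and the ODE kernel.
PARAM_NAMES: tuple[str, ...] = (
    "beta", "eta", "r_min", "p1", "p2", "p3", "A", "a", "xi", "epsilon",
    "lam", "theta", "alpha", "mu", "delta", "r", "b", "gamma", "vartheta",
)

_TO_SERIAL = {"lam": "lambda"}
_FROM_SERIAL = {"lambda": "lam"}


@dataclass(frozen=True)
class KineticParameters:
    """The 19 constants of the phenotype-structured CAR-T/tumor model.

    Parameters
    ----------
    beta : day^-1
        Loss rate of distributed CAR-T cells that never engraft.
    eta : day^-1
        Engraftment rate of distributed cells into the effector pool.
    r_min : day^-1
        Basal (background) expansion rate of effector CAR-T cells.
    p1 : day^-1
        Initial (maximal extra) expansion rate; the peak expansion rate of the
        time-dependent schedule is ``r_min + p1``.
    p2 : day^-1
        Rate regulating the duration of the maximal-expansion plateau.
    p3 : dimensionless
        Exponent regulating how sharply the expansion rate decays.
    A : cells
        Tumor burden at which antigen-driven expansion is half-maximal.
    a : cells
        Half-saturation constant of the cytotoxicity function.
    xi : day^-1
        Natural death rate of effector CAR-T cells.
    epsilon : day^-1
        Conversion rate of effector into memory CAR-T cells.
    lam : day^-1
        Exhaustion rate of effector CAR-T cells.
    theta : (cell day)^-1
        Antigen-driven memory-to-effector reconversion coefficient.
    alpha : (cell day)^-1
        Tumor inhibition coefficient acting on effector CAR-T cells.
    mu : day^-1
        Death rate of memory CAR-T cells (must satisfy ``mu < xi``).
    delta : day^-1
        Death rate of exhausted CAR-T cells.
    r : day^-1
        Maximal tumor growth rate (logistic).
    b : cell^-1
        Inverse tumor carrying capacity.
    gamma : day^-1
        Maximal cytotoxic (kill) rate of functional CAR-T cells.
    vartheta : dimensionless
        Half-saturation coefficient of the cytotoxic effect.
    """

    beta: float = 0.7
    eta: float = 0.001
    r_min: float = 0.3
    p1: float = 0.8
    p2: float = 0.1
    p3: float = 10.0
    A: float = 1.0e4
    a: float = 1.0e5
    xi: float = 0.3
    epsilon: float = 0.02
    lam: float = 0.2
    theta: float = 1.0e-9
    alpha: float = 1.0e-12
    mu: float = 0.013
    delta: float = 0.35
    r: float = 0.1
    b: float = 1.0e-12
    gamma: float = 1.0
    vartheta: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value!r}")
        if self.b <= 0:
            raise ValueError("b must be > 0 (finite carrying capacity)")
        if self.p3 <= 0:
            raise ValueError("p3 must be > 0")
        if not self.mu < self.xi:
            raise ValueError(
                f"memory cells must outlive effectors: mu={self.mu} >= xi={self.xi}"
            )

    # -- conversions ------------------------------------------------------
    def as_array(self) -> np.ndarray:
        """Return the parameters as a float64 array in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "KineticParameters":
        values = np.asarray(list(values), dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def to_dict(self) -> dict[str, float]:
        """Flat mapping using serialised symbol names (``lambda`` not ``lam``)."""
        return {_TO_SERIAL.get(n, n): float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "KineticParameters":
        kwargs = {}
        for key, value in mapping.items():
            name = _FROM_SERIAL.get(key, key)
            if name not in PARAM_NAMES:
                raise KeyError(f"unknown parameter {key!r}")
            kwargs[name] = float(value)
        return cls(**kwargs)

    def replace(self, **changes: float) -> "KineticParameters":
        changes = {_FROM_SERIAL.get(k, k): v for k, v in changes.items()}
        return dataclasses.replace(self, **changes)

    # -- file round trips -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "KineticParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "KineticParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class StateVector(NamedTuple):
    """Instantaneous cell counts ``(CD, CT, CM, CE, T)``.

    ``CF = CD + CT`` is the functional (cytotoxically active) CAR-T pool and
    ``C = CD + CT + CM + CE`` the total CAR-T population observable in blood.
    """

    CD: float
    CT: float
    CM: float
    CE: float
    T: float

    @property
    def CF(self) -> float:
        return self.CD + self.CT

    @property
    def C(self) -> float:
        return self.CD + self.CT + self.CM + self.CE

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


@dataclass(frozen=True)
class DoseSchedule:
    """An ordered sequence of impulsive CAR-T infusions ``(day, cells)``."""

    entries: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        entries = tuple((float(d), float(c)) for d, c in self.entries)
        object.__setattr__(self, "entries", entries)
        days = [d for d, _ in entries]
        if any(d < 0 for d in days):
            raise ValueError("dose days must be non-negative")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("dose days must be strictly increasing")
        if any(c <= 0 for _, c in entries):
            raise ValueError("dose sizes must be positive")

    @property
    def days(self) -> np.ndarray:
        return np.array([d for d, _ in self.entries], dtype=float)

    @property
    def amounts(self) -> np.ndarray:
        return np.array([c for _, c in self.entries], dtype=float)

    @property
    def total(self) -> float:
        """Total infused dose in cells."""
        return float(sum(c for _, c in self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def single(cls, cells: float, day: float = 0.0) -> "DoseSchedule":
        return cls(((day, cells),))

    @classmethod
    def split(
        cls,
        total: float,
        fractions: tuple[float, ...] = (0.1, 0.3, 0.6),
        start_day: float = 0.0,
    ) -> "DoseSchedule":
        """Split-dose regimen: ``fractions`` of ``total`` on consecutive days.

        The default is the clinical 3-day 10%/30%/60% split.  Fractions that do
        not sum to 1 are used as given (never normalised silently) with a
        warning.
        """
        if abs(sum(fractions) - 1.0) > 1e-9:
            warnings.warn(
                f"split fractions sum to {sum(fractions):g}, not 1; "
                "using them as given",
                stacklevel=2,
            )
        entries = tuple(
            (start_day + i, f * total) for i, f in enumerate(fractions) if f > 0
        )
        return cls(entries)

    @classmethod
    def empty(cls) -> "DoseSchedule":
        """No infusion (untreated control run)."""
        return cls(())


def default_parameters() -> KineticParameters:
    """Package default parameter set.

    ``r``, ``b``, ``gamma`` and ``vartheta`` play the role of
    literature-fixed constants (tumor doubling ~7 days, carrying capacity
    1e12 cells, maximal kill rate 1/day, unit kill half-saturation); the
    remaining values are mid-range CAR-T kinetics defaults used to seed and
    fix parameters during calibration.
    """
    return KineticParameters()


def reference_parameters() -> KineticParameters:
    """Timescale-separated reference ("textbook") parameter set.

    Produces the canonical four-phase kinetic profile after a 1e8-cell dose
    into a 1e7-cell tumor burden: a fast distribution decline (beta much
    larger than the expansion slope), expansion to a peak near two weeks,
    a steep exhaustion-driven contraction (delta much larger than mu), and a
    shallow memory-dominated persistence tail.  Used throughout the test
    suite and documentation.
    """
    return KineticParameters(
        beta=1.0,
        eta=0.003,
        r_min=0.85,
        p1=0.8,
        p2=0.09,
        p3=10.0,
        A=1.0e4,
        a=1.0e5,
        xi=0.3,
        epsilon=0.003,
        lam=0.25,
        theta=1.0e-9,
        alpha=1.0e-12,
        mu=0.006,
        delta=0.35,
        r=0.1,
        b=1.0e-12,
        gamma=1.0,
        vartheta=1.0,
    )
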