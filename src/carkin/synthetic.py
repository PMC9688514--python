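"""Virtual-patient generator emulating clinical CAR-T kinetics datasets.

Real CAR-T time courses are sparse (roughly a dozen samples over a year,
denser during the first month), multiplicative in their measurement error
(qPCR-derived counts), and left-censored at an assay detection threshold of
a few million cells.  The generator reproduces that structure: it draws
model parameters from archetype-specific priors, simulates the full
phenotype dynamics, samples the total CAR-T population at a clinical
sampling scheme, applies lognormal (dex-scale) noise, and censors values at
the threshold.

Archetypes encode the qualitative response regimes:

* ``CR`` — low exhaustion, a high basal expansion rate (effector
  self-renewal exceeds losses) and memory-driven surveillance: the tumor is
  driven below the detection threshold and held (or cycles) there
  indefinitely.
* ``PR`` — intermediate exhaustion and a low basal rate: a strong initial
  response, but the effector pool cannot sustain itself and the tumor
  re-crosses the detection threshold months later.
* ``SD`` — heavy exhaustion: the initial expansion is substantial (as
  observed clinically for stable-disease patients) but the effector pool
  converts rapidly to short-lived exhausted cells, the exposure is
  exhausted-dominated, and the tumor returns to near its initial burden.

Within an archetype the identifiable kinetic rates (``beta``, ``p1``,
``p2``, ``delta``, ``mu``) vary log-uniformly between patients; each
record hides its true parameters in the ``provenance`` field for recovery
scoring only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import PatientRecord
from .metrics import classify_outcome
from .parameters import DoseSchedule, KineticParameters
from .simulate import simulate

__all__ = [
    "SyntheticCohortConfig",
    "ARCHETYPES",
    "sample_parameters",
    "generate_patient",
    "generate_cohort",
]

#: Sampling days mirroring the cadence of published trials: daily-ish over
#: the first two weeks, then months 1, 2, 3, 6 and 12.
CLINICAL_SPARSE_DAYS = (1.0, 3.0, 7.0, 10.0, 14.0, 21.0, 28.0,
                        60.0, 90.0, 180.0, 365.0)

_DENSE_DAYS = tuple(
    np.concatenate([
        np.arange(1.0, 28.0, 1.0),
        np.arange(28.0, 90.0, 3.0),
        np.arange(90.0, 366.0, 5.0),
    ]).tolist()
)

#: Archetype definitions: a base parameter set plus log-uniform prior ranges
#: for the patient-to-patient variable parameters.
#:
#: The CR regime has a basal expansion rate exceeding the total effector
#: loss rate (``r_min > xi + epsilon + lam``), which gives the system a
#: coexistence attractor deep below the detection threshold: the tumor is
#: held (or cycles) at undetectable levels indefinitely, as reported for
#: decade-long responders.  PR and SD regimes lack that reserve
#: (``r_min`` well below the loss rate), so after the contraction the tumor
#: relapses; the two differ in expansion strength and exhaustion, and in
#: when the clinical follow-up catches the regrowth (see
#: :func:`generate_patient`).
ARCHETYPES: dict[str, dict] = {
    "CR": {
        "base": dict(
            beta=0.8, eta=0.001, r_min=0.85, p1=1.35, p2=0.13, p3=10.0,
            A=1.0e4, a=1.0e5, xi=0.3, epsilon=0.005, lam=0.3,
            theta=1.0e-9, alpha=1.0e-12, mu=0.013, delta=0.35,
            r=0.1, b=1.0e-12, gamma=1.0, vartheta=1.0,
        ),
        "vary": {
            "beta": (0.6, 1.0),
            "p1": (1.2, 1.5),
            "p2": (0.10, 0.16),
            "delta": (0.28, 0.45),
            "mu": (0.009, 0.018),
        },
    },
    "PR": {
        "base": dict(
            beta=0.8, eta=0.001, r_min=0.25, p1=1.6, p2=0.11, p3=10.0,
            A=1.0e4, a=1.0e5, xi=0.3, epsilon=0.005, lam=0.25,
            theta=1.0e-11, alpha=1.0e-12, mu=0.013, delta=0.35,
            r=0.1, b=1.0e-12, gamma=1.0, vartheta=1.0,
        ),
        "vary": {
            "beta": (0.6, 1.05),
            "p1": (1.45, 1.8),
            "p2": (0.09, 0.14),
            "delta": (0.28, 0.45),
            "mu": (0.009, 0.018),
        },
    },
    "SD": {
        "base": dict(
            beta=0.6, eta=0.001, r_min=0.3, p1=1.95, p2=0.1, p3=10.0,
            A=1.0e4, a=1.0e5, xi=0.3, epsilon=0.002, lam=0.9,
            theta=1.0e-11, alpha=1.0e-12, mu=0.013, delta=0.35,
            r=0.1, b=1.0e-12, gamma=1.0, vartheta=1.0,
        ),
        "vary": {
            "beta": (0.4, 0.7),
            "p1": (1.8, 2.1),
            "p2": (0.085, 0.12),
            "delta": (0.28, 0.45),
            "mu": (0.009, 0.018),
        },
    },
}


@dataclass
class SyntheticCohortConfig:
    """Configuration of a virtual cohort.

    ``noise_sigma`` is the standard deviation of the multiplicative
    measurement noise in dex (log10 units); 0.2 dex corresponds to a ~60%
    one-sigma multiplicative spread, typical of qPCR transgene counts.
    """

    n_patients: int = 12
    archetype_mix: dict = field(
        default_factory=lambda: {"CR": 0.5, "PR": 0.25, "SD": 0.25}
    )
    parameter_priors: dict = field(default_factory=lambda: ARCHETYPES)
    sampling_scheme: str = "clinical_sparse"  # or "dense"
    noise_sigma: float = 0.2
    detection_threshold: float = 2.5e6
    dosing_mode: str = "single"  # or "split"
    dose: float = 1.0e8
    split_fractions: tuple = (0.1, 0.3, 0.6)
    T0: float = 1.0e7
    followup_day: float = 365.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype mix must sum to 1, got {total:g}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.sampling_scheme not in ("clinical_sparse", "dense"):
            raise ValueError(f"unknown sampling scheme {self.sampling_scheme!r}")
        if self.dosing_mode not in ("single", "split"):
            raise ValueError(f"unknown dosing mode {self.dosing_mode!r}")

    @property
    def scheme_days(self) -> np.ndarray:
        days = (CLINICAL_SPARSE_DAYS if self.sampling_scheme == "clinical_sparse"
                else _DENSE_DAYS)
        return np.asarray(days, dtype=float)

    def schedule(self) -> DoseSchedule:
        if self.dosing_mode == "single":
            return DoseSchedule.single(self.dose)
        return DoseSchedule.split(self.dose, self.split_fractions)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["parameter_priors"] = {
            k: {"base": dict(v["base"]), "vary": {p: list(r) for p, r in v["vary"].items()}}
            for k, v in self.parameter_priors.items()
        }
        return out


def sample_parameters(config: SyntheticCohortConfig, archetype: str,
                      rng: np.random.Generator) -> KineticParameters:
    """Draw one patient's parameter set from an archetype prior.

    Variable parameters are log-uniform between their prior bounds; draws
    violating the parameter invariants (notably ``mu < xi``) are rejected
    and redrawn, aborting after 1000 rejections.
    """
    if archetype not in config.parameter_priors:
        raise KeyError(f"unknown archetype {archetype!r}")
    spec = config.parameter_priors[archetype]
    base = dict(spec["base"])
    for _ in range(1000):
        draw = dict(base)
        for name, (lo, hi) in spec["vary"].items():
            draw[name] = float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))
        try:
            return KineticParameters(**draw)
        except ValueError:
            continue
    raise RuntimeError(
        f"could not draw valid parameters for archetype {archetype!r} "
        "after 1000 rejections; check the priors"
    )


def _followup_day(traj, archetype: str | None,
                  config: SyntheticCohortConfig) -> float:
    """Clinically motivated follow-up time for a simulated patient.

    Durable responders are assessed at the configured horizon.  Relapsing
    patients are assessed when the regrowth is caught: shortly after the
    tumor re-crosses the detection threshold (PR-like timing) or once it is
    back near its initial burden (SD-like timing) -- in the clinic the visit
    that detects progression is the last follow-up.
    """
    if archetype in (None, "CR"):
        return config.followup_day
    t, T = traj.times, traj.T
    i_nadir = int(np.argmin(T))
    after_t, after_T = t[i_nadir:], T[i_nadir:]
    target = (config.detection_threshold if archetype == "PR"
              else 0.9 * config.T0)
    lag = 5.0 if archetype == "PR" else 0.0
    above = after_T >= target
    if not np.any(above):
        return config.followup_day
    t_detect = float(after_t[int(np.argmax(above))])
    return min(t_detect + lag, float(t[-1]))


def generate_patient(kp: KineticParameters, config: SyntheticCohortConfig,
                     rng: np.random.Generator, patient_id: str = "S01",
                     archetype: str | None = None) -> PatientRecord:
    """Simulate one virtual patient and emit a noisy, censored record.

    The noise-free trajectory determines the follow-up day (see
    :func:`_followup_day`) and the recorded outcome label (response class of
    the true tumor burden at follow-up).  Kinetic sampling stops at the
    follow-up day, mirroring clinical practice.
    """
    schedule = config.schedule()
    days = config.scheme_days
    t_end = float(max(days.max(), config.followup_day)) + 235.0
    grid = np.unique(np.concatenate([
        np.arange(0.0, t_end + 0.5, 1.0), days, [config.followup_day, t_end]
    ]))
    traj = simulate(kp, schedule, T0=config.T0, t_end=t_end, dt=1e-2, grid=grid,
                    stop_when_T_above=2.0 * config.T0)

    followup = _followup_day(traj, archetype, config)
    days = days[days <= followup]
    c_true = np.interp(days, traj.times, traj.C)
    noise = rng.normal(0.0, config.noise_sigma, size=days.size)
    values = c_true * 10.0 ** noise
    t_followup = float(np.interp(followup, traj.times, traj.T))
    outcome = classify_outcome(max(t_followup, 1e-30), config.T0,
                               config.detection_threshold)
    return PatientRecord.from_arrays(
        patient_id, days, values,
        detection_threshold=config.detection_threshold,
        schedule=schedule,
        disease="synthetic",
        T0=config.T0,
        followup_day=followup,
        outcome=outcome,
        provenance={
            "params": kp.to_dict(),
            "archetype": archetype,
            "T_followup_true": t_followup,
            "C_true": c_true.tolist(),
        },
    )


def _allocate(n: int, mix: dict[str, float]) -> list[str]:
    """Largest-remainder allocation of archetype counts."""
    names = sorted(mix)
    quotas = {k: n * mix[k] for k in names}
    counts = {k: int(np.floor(quotas[k])) for k in names}
    remaining = n - sum(counts.values())
    by_frac = sorted(names, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_frac[:remaining]:
        counts[k] += 1
    out: list[str] = []
    for k in names:
        out.extend([k] * counts[k])
    return out


def generate_cohort(config: SyntheticCohortConfig
                    ) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a reproducible cohort plus its truth table.

    Returns the patient records and a data frame with one row per patient:
    archetype, recorded outcome, and the true parameter values (columns
    named by parameter).  Byte-identical for identical configurations.
    """
    labels = _allocate(config.n_patients, config.archetype_mix)
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(config.n_patients)
    records: list[PatientRecord] = []
    rows: list[dict] = []
    for i, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        kp = sample_parameters(config, label, rng)
        pid = f"S{i + 1:02d}"
        record = generate_patient(kp, config, rng, patient_id=pid,
                                  archetype=label)
        records.append(record)
        row = {"id": pid, "archetype": label, "outcome": record.outcome,
               "followup_day": config.followup_day}
        row.update({k: v for k, v in kp.to_dict().items()})
        rows.append(row)
    truth = pd.DataFrame(rows)
    return records, truth
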