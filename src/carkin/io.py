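"""Readers, writers, unit conversions and the batch pipeline.

Tabular data are CSV, configuration is YAML, results are JSON.  At every
interface times are days, counts are absolute cells, and rates are day^-1;
unit conversions (qPCR transgene copies per microgram of DNA, counts per
microlitre of blood, per-kilogram dosing) are confined to this module via
:class:`TableDialect`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import CARTKinetics, PatientRecord, fit_patient
from .parameters import DoseSchedule
from .synthetic import SyntheticCohortConfig, generate_cohort

__all__ = [
    "TableDialect",
    "DIALECTS",
    "read_patient_table",
    "write_patient_table",
    "write_cohort",
    "run_pipeline",
]

logger = logging.getLogger("carkin")

DEFAULT_ALL_DOSE = 1.0e8  # median CAR-positive viable T-cell dose, cells
DEFAULT_WEIGHT_KG = 60.0


@dataclass(frozen=True)
class TableDialect:
    """How to convert a table's abundance values to absolute cell numbers.

    ``conversion_factor`` is cells per table unit.  The qPCR dialect uses
    1e5 cells per (copy/ug DNA): a threshold of 25 copies/ug DNA corresponds
    to 2.5e6 CAR-T cells.  The per-microlitre dialect assumes ~5 L of blood
    (5e6 uL).  ``weight_kg`` converts per-kilogram doses; the default
    assumes a 60 kg patient.
    """

    value_unit: str = "cells"
    conversion_factor: float = 1.0
    weight_kg: float = DEFAULT_WEIGHT_KG

    def __post_init__(self) -> None:
        if self.conversion_factor <= 0:
            raise ValueError("conversion_factor must be > 0")
        if self.weight_kg <= 0:
            raise ValueError("weight_kg must be > 0")

    def to_cells(self, value):
        return np.asarray(value, dtype=float) * self.conversion_factor


DIALECTS: dict[str, TableDialect] = {
    "cells": TableDialect("cells", 1.0),
    "copies_per_ug_dna": TableDialect("copies_per_ug_dna", 1.0e5),
    "cells_per_uL": TableDialect("cells_per_uL", 5.0e6),
}


def _schedule_from_meta(meta: dict, dialect: TableDialect) -> DoseSchedule:
    if "schedule" in meta and meta["schedule"]:
        entries = tuple((float(e["day"]), float(e["cells"]))
                        for e in meta["schedule"])
        return DoseSchedule(entries)
    dose = meta.get("dose")
    if dose is None and meta.get("dose_per_kg") is not None:
        dose = float(meta["dose_per_kg"]) * dialect.weight_kg
    if dose is None:
        # missing dose: fall back to the standard ALL surrogate dose
        logger.info("no dose in metadata; using default %.2g cells",
                    DEFAULT_ALL_DOSE)
        dose = DEFAULT_ALL_DOSE
    dose = float(dose)
    fractions = meta.get("split_fractions")
    if fractions:
        return DoseSchedule.split(dose, tuple(float(f) for f in fractions))
    return DoseSchedule.single(dose)


def read_patient_table(path, dialect: TableDialect | str = "cells",
                       meta=None) -> PatientRecord:
    """Read a patient CSV (columns ``day``, ``value``[, ``censored``]).

    ``meta`` is a mapping or a YAML path carrying id, disease, dose (cells)
    or dose_per_kg, optional explicit schedule/split fractions, detection
    threshold (in table units), T0, follow-up day and outcome.  Values and
    the threshold are converted to absolute cells through the dialect.
    Unparseable rows are reported with their line numbers.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    if meta is None:
        meta = {}
    elif not isinstance(meta, dict):
        with open(meta) as fh:
            meta = yaml.safe_load(fh) or {}

    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("day", "value"):
        if col not in frame:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = frame.index[
        frame["day"].isna() | frame["value"].isna() | (frame["value"] < 0)
    ]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad)  # header is line 1
        raise ValueError(f"{path}: unparseable or negative rows at lines {lines}")
    if bool(meta.get("log10_values", False)):
        frame = frame.assign(value=10.0 ** frame["value"])

    values = dialect.to_cells(frame["value"].to_numpy())
    threshold = float(meta.get("detection_threshold", 2.5e6 / dialect.conversion_factor))
    threshold_cells = float(dialect.to_cells(threshold))
    schedule = _schedule_from_meta(meta, dialect)
    order = np.argsort(frame["day"].to_numpy())

    censored = None
    if "censored" in frame:
        censored = frame["censored"].to_numpy(dtype=bool)[order]
    return PatientRecord.from_arrays(
        str(meta.get("id", path.stem)),
        frame["day"].to_numpy(dtype=float)[order],
        values[order],
        detection_threshold=threshold_cells,
        schedule=schedule,
        censored=censored,
        disease=str(meta.get("disease", "other")),
        T0=float(meta.get("T0", 1.0e7)),
        followup_day=(float(meta["followup_day"])
                      if meta.get("followup_day") is not None else None),
        outcome=meta.get("outcome"),
    )


def write_patient_table(record: PatientRecord, csv_path, meta_path=None) -> None:
    """Write a record as CSV (+ optional YAML sidecar), in absolute cells."""
    record.to_frame().to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {
            "id": record.id,
            "disease": record.disease,
            "schedule": [{"day": d, "cells": c} for d, c in record.schedule.entries],
            "detection_threshold": record.detection_threshold,
            "T0": record.T0,
            "followup_day": record.followup_day,
            "outcome": record.outcome,
        }
        with open(meta_path, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)


def write_cohort(records, truth: pd.DataFrame, out_dir) -> None:
    """Emit per-patient CSV + YAML plus a cohort truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for record in records:
        write_patient_table(record, out_dir / f"{record.id}.csv",
                            out_dir / f"{record.id}.yaml")
    truth.to_csv(out_dir / "truth.csv", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(orient="records"), fh, indent=2, default=float)


def run_pipeline(records, out_dir=None, seed: int = 0,
                 free=None, n_starts: int = 3,
                 horizons=(28.0, 60.0, 90.0),
                 relapse_t_max: float = 20000.0,
                 fit_kwargs: dict | None = None):
    """Phase analysis, fit, simulation and metrics for every record.

    Per-patient failures are logged and skipped; the returned summary frame
    has one row per attempted patient with a ``success`` flag.  Outputs are
    deterministic for a given seed.

    Returns
    -------
    summary : pandas.DataFrame
    results : dict of id -> (FitResult, KineticSummary) for successes
    """
    fit_kwargs = dict(fit_kwargs or {})
    rows: list[dict] = []
    results: dict = {}
    for record in records:
        row: dict = {"id": record.id, "disease": record.disease,
                     "outcome": record.outcome, "success": False}
        try:
            model = CARTKinetics(record)
            fitres = model.fit(seed=seed, n_starts=n_starts,
                               **({"free": free} if free else {}),
                               **fit_kwargs)
            logger.info("fit %s: loss=%.4g free=%s fixed=%s", record.id,
                        fitres.loss, list(fitres.result.free_names),
                        list(fitres.result.fixed_names))
            summary = fitres.kinetic_summary(horizons=horizons,
                                             relapse_t_max=relapse_t_max)
            h0 = horizons[0]
            row.update({
                "loss": fitres.loss,
                "rmse_log10": fitres.result.gof["rmse_log10"],
                "converged": fitres.converged,
                f"auc_0_{int(h0)}": summary.auc[h0]["total"],
                f"non_exhausted_0_{int(h0)}": summary.non_exhausted[h0],
                "t_peak": summary.t_peak,
                "C_peak": summary.C_peak,
                "peak_dose_ratio": summary.peak_dose_ratio,
                "EC": summary.EC,
                "t_TR": summary.relapse.t_TR,
                "t_TR_reason": summary.relapse.reason,
                "predicted_outcome": fitres.predicted_outcome(),
                "success": True,
            })
            results[record.id] = (fitres.result, summary)
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                payload = {"fit": fitres.result.to_dict(),
                           "metrics": summary.to_dict()}
                with open(out_dir / f"{record.id}.json", "w") as fh:
                    json.dump(payload, fh, indent=2, default=float)
        except Exception as exc:
            logger.error("patient %s failed: %s", record.id, exc)
            row["error"] = str(exc)
        rows.append(row)
    summary_frame = pd.DataFrame(rows)
    if out_dir is not None and len(summary_frame):
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        summary_frame.to_csv(Path(out_dir) / "cohort_summary.csv", index=False)
    return summary_frame, results


def load_cohort_config(path) -> SyntheticCohortConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SyntheticCohortConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    if "split_fractions" in raw:
        raw["split_fractions"] = tuple(raw["split_fractions"])
    return SyntheticCohortConfig(**raw)


def synthesize_to_dir(config: SyntheticCohortConfig, out_dir):
    records, truth = generate_cohort(config)
    write_cohort(records, truth, out_dir)
    return records, truth
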