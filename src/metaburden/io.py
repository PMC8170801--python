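"""File I/O: measurement and schedule CSVs, configs, results, reports.

Formats
-------
measurements CSV: columns ``day, lesion_id, volume, unit`` with unit in
  {ml, mm3, cells}; one row per lesion per visit.  The row with
  ``lesion_id == "primary"`` on the first day anchors the primary size.
schedule CSV: columns ``day, modality, drug_id, dose_mg`` with modality in
  {chemo, immuno}; days are offsets from diagnosis (first measurement day).
Configs are YAML or JSON; results and truth records are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import CELLS_PER_ML, CELLS_PER_MM3, DEFAULT_ALPHA, DEFAULT_K
from .density import MetastaticState
from .fitting import FitResult, PatientDataset
from .growth import GompertzParams, cell_cycle_hours, tumor_age, tvdt

_UNIT_FACTORS = {"ml": CELLS_PER_ML, "mm3": CELLS_PER_MM3, "cells": 1.0}

PRIMARY_LESION_ID = "primary"


def volumes_to_cells(values, unit: str):
    """Convert lesion volumes to cell counts (``10^-3 ml = 1 mm^3 = 10^6 cells``)."""
    try:
        return np.asarray(values, dtype=float) * _UNIT_FACTORS[unit.lower()]
    except KeyError:
        raise ValueError(f"unknown volume unit {unit!r}; expected one of {sorted(_UNIT_FACTORS)}")


def read_measurements(path):
    """Read a per-lesion measurement CSV; returns a tidy frame in cells."""
    df = pd.read_csv(path)
    required = {"day", "lesion_id", "volume", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement file {path} lacks columns: {sorted(missing)}")
    df = df.copy()
    df["cells"] = [
        float(volumes_to_cells(v, u)) for v, u in zip(df["volume"], df["unit"])
    ]
    return df


def read_schedule(path):
    df = pd.read_csv(path)
    required = {"day", "modality", "drug_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule file {path} lacks columns: {sorted(missing)}")
    bad = set(df["modality"]) - {"chemo", "immuno"}
    if bad:
        raise ValueError(f"unknown modality values {sorted(bad)}; expected chemo/immuno")
    return df


def load_patient(
    measurements_path,
    schedule_path=None,
    patient_id: str | None = None,
    K: float = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
    s_vis: float | None = None,
) -> PatientDataset:
    """Assemble a :class:`PatientDataset` from measurement and schedule files.

    Lesion volumes are summed per visit into the total burden; days are
    re-anchored so the first visit (diagnosis) is day 0.
    """
    meas = read_measurements(measurements_path)
    day0 = meas["day"].min()
    totals = meas.groupby("day")["cells"].sum().sort_index()
    primary_rows = meas[(meas["day"] == day0) & (meas["lesion_id"] == PRIMARY_LESION_ID)]
    if primary_rows.empty:
        raise ValueError(
            f"measurement file {measurements_path} has no '{PRIMARY_LESION_ID}' lesion "
            "on the first visit; the primary size anchors the time axis"
        )
    primary = float(primary_rows["cells"].iloc[0])

    chemo_offsets, immuno_offsets = (), ()
    chemo_drug, immuno_drug, immuno_dose = "cisplatin-pemetrexed", None, None
    if schedule_path is not None:
        sched = read_schedule(schedule_path)
        chemo = sched[sched["modality"] == "chemo"]
        immuno = sched[sched["modality"] == "immuno"]
        if len(chemo):
            chemo_offsets = tuple(sorted(chemo["day"].astype(float) - day0))
            chemo_drug = str(chemo["drug_id"].iloc[0])
        if len(immuno):
            immuno_offsets = tuple(sorted(immuno["day"].astype(float) - day0))
            immuno_drug = str(immuno["drug_id"].iloc[0])
            if "dose_mg" in immuno.columns and immuno["dose_mg"].notna().any():
                immuno_dose = float(immuno["dose_mg"].iloc[0])
    return PatientDataset(
        patient_id=patient_id or Path(measurements_path).stem,
        days=tuple(totals.index.astype(float) - day0),
        burdens_cells=tuple(totals.values),
        primary_size_at_diagnosis=primary,
        chemo_offsets=chemo_offsets,
        chemo_drug=chemo_drug,
        immuno_offsets=immuno_offsets,
        immuno_drug=immuno_drug,
        immuno_dose_mg=immuno_dose,
        K=K,
        alpha=alpha,
        s_vis=s_vis,
    )


def write_state_csv(state: MetastaticState, path):
    state.to_frame().to_csv(path, index=False)


def write_history(history: pd.DataFrame, path):
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(history.to_json(orient="records", indent=2))
    else:
        history.to_csv(path, index=False)


def write_fit_result(result: FitResult, path):
    Path(path).write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True) + "\n")


def write_truth(truth: dict, path):
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def write_dataset_csv(dataset: PatientDataset, path):
    """Write a dataset back to the per-lesion measurement dialect.

    On the first visit the primary is written separately (it anchors the
    time axis) with the metastatic remainder as one aggregate lesion; later
    visits carry a single total row.  Per-day sums reproduce the burdens.
    """
    primary = dataset.primary_size_at_diagnosis
    rows = [
        {"day": dataset.days[0], "lesion_id": PRIMARY_LESION_ID,
         "volume": primary, "unit": "cells"},
        {"day": dataset.days[0], "lesion_id": "metastases",
         "volume": max(dataset.burdens_cells[0] - primary, 0.0), "unit": "cells"},
    ]
    for d, b in zip(dataset.days[1:], dataset.burdens_cells[1:]):
        rows.append({"day": d, "lesion_id": "total", "volume": b, "unit": "cells"})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_schedule_csv(dataset: PatientDataset, path):
    rows = [
        {"day": d, "modality": "chemo", "drug_id": dataset.chemo_drug, "dose_mg": ""}
        for d in dataset.chemo_offsets
    ] + [
        {"day": d, "modality": "immuno", "drug_id": dataset.immuno_drug,
         "dose_mg": dataset.immuno_dose_mg if dataset.immuno_dose_mg is not None else ""}
        for d in dataset.immuno_offsets
    ]
    pd.DataFrame(rows, columns=["day", "modality", "drug_id", "dose_mg"]).to_csv(path, index=False)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must define a mapping")
    return cfg


_REPORT_ROWS = [
    ("K", "Environmental carrying capacity [cells]", "fixed"),
    ("a", "Growth rate [1/day]", "fitted"),
    ("m", "Colonization coefficient [1/cell 1/day]", "fitted"),
    ("alpha", "Fractal dimension of cells able to metastasize [-]", "fixed"),
    ("mu0", "Initial chemotherapy efficiency [-]", "fitted"),
    ("mu_star", "Refractory effect under chemotherapy [-]", "fitted"),
    ("chi", "Immunotherapeutic effect under application [1/day]", "fitted"),
    ("c50", "Drug concentration for half-maximal response [molecules/volume]", "fitted"),
]


def fit_report(result: FitResult, dataset: PatientDataset) -> str:
    """Human-readable parameter report for one fitted patient (markdown)."""
    p = dict(result.params)
    se = result.standard_errors
    lines = [
        f"# Fit report: patient {dataset.patient_id}",
        "",
        "| Parameter | Explanation | Value | Std. error | Origin |",
        "|---|---|---|---|---|",
        f"| K | Environmental carrying capacity [cells] | {dataset.K:.3g} | - | fixed |",
    ]
    for name, expl, _ in _REPORT_ROWS[1:]:
        if name == "alpha":
            lines.append(f"| alpha | {expl} | {dataset.alpha:.4g} | - | fixed |")
            continue
        if name not in p:
            continue
        origin = "fitted" if name in result.free_names else "fixed"
        sev = f"{se[name]:.3g}" if name in se else "-"
        lines.append(f"| {name} | {expl} | {p[name]:.4g} | {sev} | {origin} |")
    if "a" in p:
        gp = GompertzParams(p["a"], dataset.K)
        age = tumor_age(gp, dataset.primary_size_at_diagnosis)
        dbl = tvdt(gp, dataset.primary_size_at_diagnosis)
        lines += [
            f"| T | Age of primary tumor at diagnosis [d] | {age:.1f} | - | estimated |",
            f"| TVDT | Tumor volume doubling time at diagnosis [d] | {dbl:.1f} | - | estimated |",
            f"| - | Tumor cell cycle length ln(2)/a [h] | {cell_cycle_hours(gp):.1f} | - | estimated |",
        ]
    lines += [
        "",
        f"Residual sum of squares: {result.sse:.6g} cells^2"
        + (" (objective on log burden)" if result.log_residuals else ""),
        f"Converged: {result.converged}; Hessian reliable: {result.hessian_reliable}",
    ]
    return "\n".join(lines) + "\n"


def dataclass_to_json(obj, path):
    Path(path).write_text(json.dumps(dataclasses.asdict(obj), indent=2, sort_keys=True) + "\n")
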