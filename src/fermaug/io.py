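"""CSV and manifest formats for experiment collections.

One CSV per experiment, one row per grid point, header
``time_h,pH,redox_mV,capacitance_pFcm,temperature_C,ethanol_gL,substrate_gL,cells_gL``;
missing measurements are empty fields.  A YAML manifest records each file's
id, provenance and faults so original and synthetic experiments can never
mix silently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CHANNELS, ExperimentCollection, ExperimentSeries

__all__ = [
    "CSV_COLUMNS",
    "read_experiment_csv",
    "write_experiment_csv",
    "write_collection",
    "read_collection",
]

CSV_COLUMNS = [
    "time_h",
    "pH",
    "redox_mV",
    "capacitance_pFcm",
    "temperature_C",
    "ethanol_gL",
    "substrate_gL",
    "cells_gL",
]


def write_experiment_csv(series: ExperimentSeries, path: str | Path) -> None:
    """Write one experiment; values carry 12 significant digits, missing
    entries are empty fields."""
    frame = pd.DataFrame(
        np.column_stack([series.time, series.values]), columns=CSV_COLUMNS
    )
    frame.to_csv(path, index=False, float_format="%.12g", na_rep="")


def read_experiment_csv(
    path: str | Path,
    id: str | None = None,
    provenance: str = "original",
) -> ExperimentSeries:
    """Read one experiment CSV; empty fields become missing values."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: unreadable CSV ({exc})") from exc
    if list(frame.columns) != CSV_COLUMNS:
        raise ValueError(
            f"{path}: header mismatch; expected {','.join(CSV_COLUMNS)}, "
            f"got {','.join(map(str, frame.columns))}"
        )
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()
                              & frame[col].notna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
    values = frame[CSV_COLUMNS[1:]].to_numpy(dtype=float)
    return ExperimentSeries(
        time=frame["time_h"].to_numpy(dtype=float),
        values=values,
        id=id or path.stem,
        provenance=provenance,
    )


def write_collection(
    collection: ExperimentCollection, directory: str | Path,
    manifest_name: str = "manifest.yaml",
) -> Path:
    """Write every experiment as CSV plus a manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in collection:
        fname = f"{s.id}.csv"
        write_experiment_csv(s, directory / fname)
        entries.append({
            "id": s.id,
            "file": fname,
            "provenance": s.provenance,
            "faults": list(s.meta.get("faults", [])),
        })
    manifest = directory / manifest_name
    manifest.write_text(yaml.safe_dump({"experiments": entries}, sort_keys=False))
    return manifest


def read_collection(manifest_path: str | Path) -> ExperimentCollection:
    """Load a collection from its manifest."""
    manifest_path = Path(manifest_path)
    spec = yaml.safe_load(manifest_path.read_text())
    if not isinstance(spec, dict) or "experiments" not in spec:
        raise ValueError(f"{manifest_path}: not a collection manifest")
    series = []
    for entry in spec["experiments"]:
        s = read_experiment_csv(
            manifest_path.parent / entry["file"],
            id=entry["id"],
            provenance=entry.get("provenance", "original"),
        )
        s.meta["faults"] = entry.get("faults", [])
        series.append(s)
    return ExperimentCollection(series)
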