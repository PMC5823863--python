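"""CSV + JSON-sidecar persistence for traces, ACFs and measurement tables.

Every data CSV travels with a ``<stem>.json`` sidecar holding the metadata
needed to reproduce it (bin width, duration, config echo, seed); reading
without the sidecar is an explicit error, not a silent default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .correlator import AutocorrelationCurve, IntensityTrace

__all__ = [
    "write_trace", "read_trace",
    "write_acf", "read_acf",
    "write_measurements", "read_measurements",
]

MEASUREMENT_COLUMNS = ["cell_id", "condition", "distance_um", "time_min",
                       "conc_nM", "diff_coeff_m2s"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sc}: cannot interpret {path} without it"
        )
    return json.loads(sc.read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_trace(trace: IntensityTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"bin_index": np.arange(trace.counts.size),
                  "counts": trace.counts}).to_csv(path, index=False)
    meta = {"bin_width_s": trace.bin_width,
            "duration_s": trace.duration,
            "metadata": _jsonable(dict(trace.metadata))}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path) -> IntensityTrace:
    path = Path(path)
    meta = _read_sidecar(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return IntensityTrace(df["counts"].to_numpy(), meta["bin_width_s"],
                          meta.get("metadata", {}))


def write_acf(acf: AutocorrelationCurve, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"lag_s": acf.lags, "g": acf.g_values})
    if acf.g_sd is not None:
        df["g_sd"] = acf.g_sd
    df.to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"source": _jsonable(dict(acf.source))},
                                         indent=1))
    return path


def read_acf(path: str | Path) -> AutocorrelationCurve:
    path = Path(path)
    meta = _read_sidecar(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return AutocorrelationCurve(
        df["lag_s"].to_numpy(), df["g"].to_numpy(),
        df["g_sd"].to_numpy() if "g_sd" in df else None,
        meta.get("source", {}),
    )


def write_measurements(table: pd.DataFrame, path: str | Path,
                       metadata: dict | None = None) -> Path:
    path = Path(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    table[MEASUREMENT_COLUMNS].to_csv(path, index=False)
    meta = {"columns": MEASUREMENT_COLUMNS,
            "distance_frame": "above membrane (cells) / above coverslip (no_cell)"}
    meta.update(_jsonable(metadata or {}))
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    _read_sidecar(path)  # required, validates provenance exists
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement file missing columns: {missing}")
    for col in MEASUREMENT_COLUMNS[2:]:  # numeric columns stay float64
        df[col] = df[col].astype(float)
    return df
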