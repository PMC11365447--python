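"""CSV/JSON readers and writers for the assay dialects.

Dialects (all plain CSV, comma-separated, header optional only where
noted):

* traces — ``time_s,fluorescence[,label]``; a headerless two-column file is
  accepted as a single unlabeled trace;
* capture — ``captured_cpm,total_cpm[,replicate_id]``;
* band tables — ``sample,glycans_4,glycans_3,glycans_2,glycans_1,glycans_0
  [,loading_control]``;
* growth curves — long format ``sample,time_min,a600``;
* calibration — ``amount_ng,intensity``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .cells import GLYCOFORM_COLUMNS, BandTable, GrowthCurve
from .errors import InputError
from .traces import CaptureAssayData, FluorescenceTrace


def _read_csv(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    """Read one or more fluorescence traces from CSV.

    With a header, columns ``time_s`` and ``fluorescence`` are required and
    an optional ``label`` column splits the file into multiple traces.
    A headerless two-column numeric file is treated as one unlabeled trace.
    """
    df = _read_csv(path)
    if "time_s" not in df.columns or "fluorescence" not in df.columns:
        df = _read_csv(path, header=None)
        if df.shape[1] != 2:
            raise InputError(
                f"{path}: expected columns time_s,fluorescence[,label] or a "
                "headerless two-column file"
            )
        df.columns = ["time_s", "fluorescence"]
    if "label" in df.columns:
        return [
            FluorescenceTrace(g["time_s"].to_numpy(), g["fluorescence"].to_numpy(), str(label))
            for label, g in df.groupby("label", sort=False)
        ]
    return [FluorescenceTrace(df["time_s"].to_numpy(), df["fluorescence"].to_numpy(), "")]


def write_traces(path: str | Path, traces: Iterable[FluorescenceTrace]) -> None:
    frames = [
        pd.DataFrame(
            {"time_s": tr.time_s, "fluorescence": tr.fluorescence, "label": tr.label}
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_capture_table(path: str | Path) -> list[CaptureAssayData]:
    df = _read_csv(path)
    required = {"captured_cpm", "total_cpm"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: expected columns captured_cpm,total_cpm[,replicate_id]")
    reps = []
    for i, row in df.iterrows():
        rid = str(row["replicate_id"]) if "replicate_id" in df.columns else f"rep{i + 1}"
        reps.append(
            CaptureAssayData(
                captured_signal=float(row["captured_cpm"]),
                total_signal=float(row["total_cpm"]),
                replicate_id=rid,
            )
        )
    return reps


def write_capture_table(path: str | Path, data: Iterable[CaptureAssayData]) -> None:
    pd.DataFrame(
        {
            "captured_cpm": [d.captured_signal for d in data],
            "total_cpm": [d.total_signal for d in data],
            "replicate_id": [d.replicate_id for d in data],
        }
    ).to_csv(path, index=False)


def read_band_table(path: str | Path) -> BandTable:
    df = _read_csv(path)
    return BandTable(df)


def write_band_table(path: str | Path, table: BandTable) -> None:
    cols = ["sample", *GLYCOFORM_COLUMNS]
    if "loading_control" in table.df.columns:
        cols.append("loading_control")
    table.df[cols].to_csv(path, index=False)


def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    df = _read_csv(path)
    required = {"sample", "time_min", "a600"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: expected columns sample,time_min,a600")
    return [
        GrowthCurve(
            g.sort_values("time_min")["time_min"].to_numpy(),
            g.sort_values("time_min")["a600"].to_numpy(),
            str(label),
        )
        for label, g in df.groupby("sample", sort=False)
    ]


def write_growth_curves(path: str | Path, curves: Iterable[GrowthCurve]) -> None:
    frames = [
        pd.DataFrame({"sample": c.label, "time_min": c.time_min, "a600": c.a600})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_calibration(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path)
    if not {"amount_ng", "intensity"} <= set(df.columns):
        raise InputError(f"{path}: expected columns amount_ng,intensity")
    return df["amount_ng"].to_numpy(dtype=float), df["intensity"].to_numpy(dtype=float)


def write_calibration(path: str | Path, amounts: np.ndarray, intensities: np.ndarray) -> None:
    pd.DataFrame({"amount_ng": amounts, "intensity": intensities}).to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses and numpy scalars/arrays to plain
    JSON-serializable Python types."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(path: str | Path, payload: Any) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
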