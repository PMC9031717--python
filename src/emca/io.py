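"""CSV readers/writers and run manifests.

All files are plain text.  Voltammogram series use a long-format CSV
(``electrode_id,temperature_C,potential_V,current``); closed-loop traces
use ``time_s,setpoint_C,plate_C,slide_C,actuation``.  Temperatures are
serialized with 2 decimals and currents with 6 significant digits, so a
given simulation always round-trips to byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .swv import Voltammogram
from .thermal import ClosedLoopTrace, StepResponse

__all__ = [
    "SchemaError",
    "read_voltammogram_series",
    "write_voltammogram_series",
    "read_height_table",
    "write_height_table",
    "read_fluorescence_curve",
    "read_closed_loop_trace",
    "write_closed_loop_trace",
    "read_step_response",
    "RunManifest",
    "file_digest",
]

VOLTAMMOGRAM_COLUMNS = ["electrode_id", "temperature_C", "potential_V", "current"]
HEIGHT_COLUMNS = ["electrode_id", "temperature_C", "height"]
FLUOR_COLUMNS = ["temperature_C", "intensity"]
TRACE_COLUMNS = ["time_s", "setpoint_C", "plate_C", "slide_C", "actuation"]


class SchemaError(ValueError):
    pass


def _read_csv_checked(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty file: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    numeric = [c for c in required if c != "electrode_id"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = df.loc[coerced.isna(), col].iloc[0]
            raise SchemaError(f"{path}: non-numeric value {bad!r} in column {col!r}")
        df[col] = coerced
    return df


def read_voltammogram_series(path) -> List[Voltammogram]:
    """Parse a long-format voltammogram CSV into per-(electrode, temperature)
    voltammograms, potentials sorted ascending."""
    df = _read_csv_checked(path, VOLTAMMOGRAM_COLUMNS)
    dup = df.duplicated(subset=["electrode_id", "temperature_C", "potential_V"])
    if dup.any():
        row = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate (electrode, temperature, potential) row: "
            f"({row.electrode_id}, {row.temperature_C}, {row.potential_V})"
        )
    out: List[Voltammogram] = []
    for (eid, temp), grp in df.groupby(["electrode_id", "temperature_C"], sort=True):
        grp = grp.sort_values("potential_V")
        out.append(
            Voltammogram(
                potentials=grp["potential_V"].to_numpy(float),
                currents=grp["current"].to_numpy(float),
                electrode_id=str(eid),
                temperature=float(temp),
            )
        )
    return out


def write_voltammogram_series(voltammograms: Sequence[Voltammogram], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(VOLTAMMOGRAM_COLUMNS) + "\n")
        for v in voltammograms:
            for E, i in zip(v.potentials, v.currents):
                fh.write(f"{v.electrode_id},{v.temperature:.2f},{E:.4f},{i:.6e}\n")


def read_height_table(path) -> pd.DataFrame:
    return _read_csv_checked(path, HEIGHT_COLUMNS)


def write_height_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_fluorescence_curve(path) -> pd.DataFrame:
    return _read_csv_checked(path, FLUOR_COLUMNS)


def write_closed_loop_trace(trace: ClosedLoopTrace, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        slide = trace.slide_temperatures
        for k in range(len(trace.times)):
            s = f"{slide[k]:.4f}" if slide is not None else ""
            fh.write(
                f"{trace.times[k]:.3f},{trace.setpoints[k]:.2f},"
                f"{trace.plate_temperatures[k]:.4f},{s},"
                f"{trace.controller_outputs[k]:.6g}\n"
            )


def read_closed_loop_trace(path) -> ClosedLoopTrace:
    df = _read_csv_checked(path, [c for c in TRACE_COLUMNS if c != "slide_C"])
    slide = None
    if "slide_C" in df.columns and df["slide_C"].notna().any():
        slide = df["slide_C"].to_numpy(float)
    return ClosedLoopTrace(
        times=df["time_s"].to_numpy(float),
        setpoints=df["setpoint_C"].to_numpy(float),
        plate_temperatures=df["plate_C"].to_numpy(float),
        controller_outputs=df["actuation"].to_numpy(float),
        slide_temperatures=slide,
    )


def read_step_response(path, step_magnitude: float, step_time: float = 0.0) -> StepResponse:
    """Read a step-response trace; uses the ``plate_C`` column of the
    standard trace schema (``time_s,...,plate_C,...``)."""
    df = _read_csv_checked(path, ["time_s", "plate_C"])
    return StepResponse(
        times=df["time_s"].to_numpy(float),
        temperatures=df["plate_C"].to_numpy(float),
        step_magnitude=step_magnitude,
        step_time=step_time,
    )


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    seed: Optional[int]
    config: Dict
    inputs: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    tool_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
    )

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
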