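"""Trace file I/O, run configuration and report writing.

Trace files are tab-delimited text with a ``# mitotherm-trace {json}``
metadata header line: columns ``time_s``, ``f_main`` (MTY) or
``f_sapphire``/``f_sirius`` (mito-gTEMP), ``setpoint_c``, ``event`` (empty
or semicolon-joined labels). Times are seconds, temperatures °C. Reports
are JSON; configurations are YAML validated through pydantic models.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .traces import FluorescenceTrace

METADATA_PREFIX = "# mitotherm-trace "


# ---------------------------------------------------------------------------
# trace files
# ---------------------------------------------------------------------------

def write_trace(trace: FluorescenceTrace, path) -> None:
    """Write a trace as tab-delimited text with a JSON metadata header."""
    path = Path(path)
    frame = trace.to_frame()
    meta = {k: v for k, v in trace.metadata.items() if _jsonable(v)}
    buf = _io.StringIO()
    buf.write(METADATA_PREFIX + json.dumps(meta, sort_keys=True) + "\n")
    frame.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    path.write_text(buf.getvalue())


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def load_trace_table(path) -> FluorescenceTrace:
    """Read a trace file back into a :class:`FluorescenceTrace`.

    Validates the column schema (naming any missing column), strict time
    monotonicity and intensity non-negativity.
    """
    path = Path(path)
    metadata: dict = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith(METADATA_PREFIX):
            metadata = json.loads(first[len(METADATA_PREFIX):])
    df = pd.read_csv(path, sep="\t", comment="#")
    if "time_s" not in df.columns:
        raise ValueError("trace file missing required column 'time_s'")
    if "setpoint_c" not in df.columns:
        raise ValueError("trace file missing required column 'setpoint_c'")
    if "f_main" in df.columns:
        channels = df[["f_main"]].to_numpy().T
    elif {"f_sapphire", "f_sirius"} <= set(df.columns):
        channels = df[["f_sapphire", "f_sirius"]].to_numpy().T
    else:
        raise ValueError(
            "trace file missing intensity columns: expected 'f_main' or "
            "'f_sapphire'+'f_sirius'")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("non-monotone time column")
    events: list[tuple[float, str]] = []
    if "event" in df.columns:
        ev = df["event"].fillna("")
        for t, labels in zip(times, ev):
            for lab in str(labels).split(";"):
                if lab:
                    events.append((float(t), lab))
    return FluorescenceTrace(times, channels, df["setpoint_c"].to_numpy(dtype=float),
                             events, metadata)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class ScenarioConfig(BaseModel):
    name: str
    params: dict = Field(default_factory=dict)


class SimulateConfig(BaseModel):
    """Configuration for the ``simulate`` command; the seed is mandatory."""

    scenario: ScenarioConfig
    probe: Literal["mty", "gtemp"] = "mty"
    probe_params: dict = Field(default_factory=dict)
    noise_sd: float = Field(default=0.005, ge=0)
    seed: int
    cell_line: str = "iMEF"


class AnalysisConfig(BaseModel):
    """Windows and tolerances for the analysis commands."""

    drug_event: str | None = None
    equilibration_discard: float = Field(default=120.0, gt=0)
    averaging_window: float = Field(default=60.0, gt=0)
    plateau_window: float = Field(default=300.0, gt=0)
    stability_min_span: float = Field(default=600.0, gt=0)
    smooth_window: float = Field(default=60.0, gt=0)
    intervals_min: list[tuple[float, float]] = Field(default_factory=list)


def load_config(path, model: type[BaseModel]) -> BaseModel:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return model.model_validate(raw)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(report: dict, path) -> None:
    """Deterministic JSON report (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(_sanitize(report), indent=2, sort_keys=True) + "\n")


def _sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj
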