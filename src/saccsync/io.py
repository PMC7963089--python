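"""CSV/JSON/YAML interchange for event tables, ISI tables and run configs.

The event-table CSV dialect is the package's ingestion boundary: any eye
tracker whose events are exported with this header can be analysed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InvalidParameterError
from .preprocess import SessionISITable

__all__ = [
    "EVENT_COLUMNS",
    "TRACE_COLUMNS",
    "write_events",
    "read_events",
    "write_trace",
    "read_trace",
    "write_isi_table",
    "load_config",
    "parameter_hash",
    "write_manifest",
]

#: Column contract of the event-table CSV (inducer_loc empty when absent).
EVENT_COLUMNS = [
    "trial_id",
    "step",
    "target_landmark",
    "direction",
    "soa_ms",
    "inducer_loc",
    "onset_ms",
    "landing_x_deg",
    "landing_y_deg",
    "latency_ms",
    "isi_ms",
]

#: Column contract of the gaze-trace CSV.
TRACE_COLUMNS = ["t_ms", "x_deg", "y_deg"]

PathLike = Union[str, Path]


def write_trace(trace, path: PathLike) -> None:
    """Write a gaze trace as CSV (t_ms, x_deg, y_deg)."""
    pd.DataFrame(
        {"t_ms": trace.t, "x_deg": trace.x, "y_deg": trace.y}
    ).to_csv(path, index=False, float_format="%.6f")


def read_trace(path: PathLike, sample_rate: float | None = None):
    """Read a gaze-trace CSV back into an :class:`~saccsync.EyeTrace`.

    The sample rate is inferred from the time column unless given.
    """
    from .simulate import EyeTrace

    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: trace CSV lacks columns {missing}")
    t = df["t_ms"].to_numpy(dtype=float)
    if sample_rate is None:
        if len(t) < 2:
            raise InvalidParameterError(f"{path}: cannot infer sample rate")
        sample_rate = 1000.0 / float(np.median(np.diff(t)))
    return EyeTrace(
        sample_rate=float(sample_rate),
        t=t,
        x=df["x_deg"].to_numpy(dtype=float),
        y=df["y_deg"].to_numpy(dtype=float),
    )


def write_events(events: pd.DataFrame, path: PathLike) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise InvalidParameterError(f"event table lacks columns {missing}")
    events[EVENT_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_events(path: PathLike) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise InvalidParameterError(f"{path}: event CSV lacks columns {missing}")
    return events


def write_isi_table(table: SessionISITable, path: PathLike) -> None:
    """Tidy per-category summary CSV: category, n, mean_ms, sd_ms."""
    table.category_stats.to_csv(path, index=False, float_format="%.6f")


def load_config(path: PathLike) -> dict:
    """Load a run configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            cfg = json.loads(text)
        else:
            cfg = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as err:
        raise ConfigurationError(f"cannot parse config {path}: {err}") from err
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return cfg


def parameter_hash(params: dict) -> str:
    """Stable hash of a parameter mapping (sorted-key JSON, sha256)."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: PathLike, params: dict, **extras) -> dict:
    """Write a reproducibility manifest (parameters, hash, extras)."""
    from . import __version__

    manifest = {
        "saccsync_version": __version__,
        "parameters": params,
        "parameter_hash": parameter_hash(params),
        **extras,
    }
    Path(path).write_text(json.dumps(manifest, sort_keys=True, indent=2, default=str))
    return manifest
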