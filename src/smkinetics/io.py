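"""Trace and table I/O.

Traces round-trip losslessly through HDF5 (dataset ``samples``; attributes
``schema_version``, ``sampling_rate`` and the metadata dict as JSON).  CSV
export (columns ``time_s, current`` at 17 significant digits) is provided
for interoperability but is lossy in metadata.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .signals import CurrentTrace

SCHEMA_VERSION = 1

DWELL_CSV_COLUMNS = [
    "trace_id", "state", "start_s", "duration_s", "censored",
    "temperature_K", "ligand", "conc_M",
]


def save_trace(trace: CurrentTrace, path) -> None:
    """Write a trace to HDF5 (lossless round trip of samples and metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=trace.samples)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sampling_rate"] = trace.sampling_rate
        f.attrs["metadata"] = json.dumps(trace.metadata, sort_keys=True, default=float)


def load_trace(path) -> CurrentTrace:
    """Read a trace written by :func:`save_trace`.

    Raises a clean error on corrupt files or schema-version mismatches; no
    partial object is returned.
    """
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("schema_version", -1))
            if version != SCHEMA_VERSION:
                raise ValueError(
                    f"trace file schema version {version} unsupported "
                    f"(this package reads version {SCHEMA_VERSION})"
                )
            samples = f["samples"][...]
            fs = float(f.attrs["sampling_rate"])
            metadata = json.loads(f.attrs["metadata"])
    except (OSError, KeyError) as exc:
        raise ValueError(f"cannot read trace file {path}: {exc}") from exc
    return CurrentTrace(samples=samples, sampling_rate=fs, metadata=metadata)


def trace_to_csv(trace: CurrentTrace, path) -> None:
    """CSV export (time_s, current).  Metadata is NOT preserved."""
    t = trace.times
    with open(path, "w") as f:
        f.write("time_s,current\n")
        for ti, xi in zip(t, trace.samples):
            f.write(f"{ti:.17g},{xi:.17g}\n")


def trace_from_csv(path) -> CurrentTrace:
    """Import a two-column CSV trace; sampling rate is inferred from the
    time column and metadata is empty (flagged lossy)."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("CSV trace needs >= 2 samples")
    fs = 1.0 / np.median(np.diff(t))
    warnings.warn("CSV trace import carries no metadata")
    return CurrentTrace(samples=df["current"].to_numpy(), sampling_rate=fs, metadata={})


def save_dwell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_dwell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "censored" in df:
        df["censored"] = df["censored"].astype(bool)
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if hasattr(o, "__dict__"):
        return o.__dict__
    return str(o)
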