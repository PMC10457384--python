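"""Dwell extraction: converting per-sample labels (or ground-truth paths)
into dwell tables.

A dwell table is a pandas DataFrame with the columns
``trace_id, state, start_s, duration_s, censored`` plus optional condition
metadata columns (``temperature_K, ligand, conc_M``).  Within a trace, rows
are contiguous; the first and last dwells are censored (their true length
is unknown because the recording window clips them).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmm import IdealizedTrace
from .simulate import StatePath

DWELL_COLUMNS = ["trace_id", "state", "start_s", "duration_s", "censored"]


def _run_length_encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [len(labels)]]))
    return labels[starts], lengths


def _merge_short_runs(states: np.ndarray, lengths: np.ndarray, dead_time: int, means: np.ndarray):
    """Absorb runs of <= dead_time samples into the neighbour whose state
    mean is nearest to the short run's own state mean."""
    states = list(states)
    lengths = list(lengths)
    while len(states) > 1:
        idx = None
        for i, ln in enumerate(lengths):
            if ln <= dead_time:
                idx = i
                break
        if idx is None:
            break
        neighbours = [i for i in (idx - 1, idx + 1) if 0 <= i < len(states)]
        tgt = min(
            neighbours,
            key=lambda i: (abs(means[states[i]] - means[states[idx]]), i),
        )
        lengths[tgt] += lengths[idx]
        del states[idx], lengths[idx]
        # coalesce newly adjacent equal states
        i = 1
        while i < len(states):
            if states[i] == states[i - 1]:
                lengths[i - 1] += lengths[i]
                del states[i], lengths[i]
            else:
                i += 1
    return np.array(states, dtype=np.int64), np.array(lengths, dtype=np.int64)


def segment_dwells(
    idealized: IdealizedTrace,
    dead_time: int = 2,
    trace_id: str = "trace",
    metadata: dict | None = None,
) -> pd.DataFrame:
    """Convert per-sample labels into a dwell table.

    Runs of at most ``dead_time`` samples are merged into the neighbouring
    dwell whose state has the nearer emission mean (blips below the event
    detection limit); the first and last dwells are flagged censored.
    """
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    labels = np.asarray(idealized.labels)
    if len(labels) == 0:
        return pd.DataFrame(columns=DWELL_COLUMNS)
    states, lengths = _run_length_encode(labels)
    if dead_time > 0:
        states, lengths = _merge_short_runs(states, lengths, dead_time, idealized.means)
    fs = idealized.sampling_rate
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    censored = np.zeros(len(states), dtype=bool)
    censored[0] = True
    censored[-1] = True
    df = pd.DataFrame(
        {
            "trace_id": trace_id,
            "state": states,
            "start_s": starts / fs,
            "duration_s": lengths / fs,
            "censored": censored,
        }
    )
    for key, val in (metadata or {}).items():
        df[key] = val
    return df


def dwells_from_path(
    path: StatePath,
    trace_id: str = "path",
    state_map=None,
    metadata: dict | None = None,
) -> pd.DataFrame:
    """Ground-truth dwell table from a simulated state path.

    ``state_map`` optionally maps simulation state indices to observed state
    indices (e.g. two scheme states sharing one current level); adjacent
    dwells that map to the same observed state are merged.
    """
    states = path.states.copy()
    durations = path.durations.copy()
    if state_map is not None:
        mapped = np.array([state_map[int(s)] for s in states])
        keep_states = []
        keep_durs = []
        for s, d in zip(mapped, durations):
            if keep_states and keep_states[-1] == s:
                keep_durs[-1] += d
            else:
                keep_states.append(int(s))
                keep_durs.append(float(d))
        states = np.array(keep_states)
        durations = np.array(keep_durs)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    censored = np.zeros(len(states), dtype=bool)
    if len(states):
        censored[0] = True
        censored[-1] = True
    df = pd.DataFrame(
        {
            "trace_id": trace_id,
            "state": states,
            "start_s": starts,
            "duration_s": durations,
            "censored": censored,
        }
    )
    for key, val in (metadata or {}).items():
        df[key] = val
    return df


def uncensored_durations(dwell_table: pd.DataFrame, state: int) -> np.ndarray:
    """Durations of uncensored dwells of one state, across traces."""
    sel = (dwell_table["state"] == state) & (~dwell_table["censored"])
    return dwell_table.loc[sel, "duration_s"].to_numpy()
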