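"""File formats and session manifests.

All on-disk formats are plain text: comma-separated CSV (header row
mandatory, '.' decimal, UTF-8) for event tables and traces, JSON or
YAML for session manifests.  Times are serialized in seconds with 6
decimal places; angles in degrees; eyelid traces are in raw units
before normalization.

Spike-event CSV: columns ``cell_id, time_s, type`` with type ``ss`` or
``cs`` (case-insensitive).  Trace CSV: column ``time_s`` plus either
``stimulus_deg, eye_deg`` (eye trial) or ``eyelid_raw`` (blink trial);
sampling must be uniform within 1 %.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .eyeblink import BlinkTrial
from .eyemovement import EyeTrial
from .spiketrain import SpikeTrain

__all__ = [
    "SessionManifest",
    "load_manifest",
    "read_spike_csv",
    "write_spike_csv",
    "read_trace_csv",
    "write_trace_csv",
]

_MODALITIES = ("spikes", "eye", "blink", "excitability")


@dataclass
class SessionManifest:
    """Session-level metadata tying files to stimulus/trial parameters."""

    session_id: str
    modality: str
    files: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.modality not in _MODALITIES:
            raise ParseError(f"unknown modality '{self.modality}'")


def load_manifest(path: str | Path) -> SessionManifest:
    """Load a JSON or YAML session manifest (identical schema)."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise ParseError(f"{path}: manifest must be a mapping")
    try:
        return SessionManifest(
            session_id=str(data["session_id"]),
            modality=str(data["modality"]),
            files=list(data.get("files", [])),
            params=dict(data.get("params", {})),
            units=dict(data.get("units", {})),
            seed=data.get("seed"))
    except KeyError as e:
        raise ParseError(f"{path}: missing manifest key {e}") from e


def read_spike_csv(path: str | Path, duration: float | None = None
                   ) -> list[SpikeTrain]:
    """Read a spike-event CSV into one SpikeTrain per cell.

    ``duration`` defaults to the maximum event time in the file (use the
    manifest value when available).  Unknown type tokens raise a
    ParseError carrying the offending line number.
    """
    df = pd.read_csv(path, dtype={"cell_id": str})
    required = {"cell_id", "time_s", "type"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: header must contain {sorted(required)}")
    types = df["type"].astype(str).str.strip().str.lower()
    bad = ~types.isin(("ss", "cs"))
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # header = line 1
        raise ParseError(f"{path}:{line}: unknown event type "
                         f"'{df['type'].iloc[line - 2]}'")
    if duration is None:
        duration = float(df["time_s"].max())
    trains = []
    for cell_id, g in df.assign(type=types).groupby("cell_id", sort=True):
        ss = np.sort(g.loc[g["type"] == "ss", "time_s"].to_numpy(dtype=float))
        cs = np.sort(g.loc[g["type"] == "cs", "time_s"].to_numpy(dtype=float))
        for name, t in (("ss", ss), ("cs", cs)):
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ParseError(f"{path}: duplicated {name} times for "
                                 f"cell '{cell_id}'")
        trains.append(SpikeTrain(simple_spike_times=ss, complex_spike_times=cs,
                                 duration=duration, cell_id=str(cell_id)))
    return trains


def write_spike_csv(path: str | Path, trains: list[SpikeTrain]) -> None:
    rows = []
    for tr in trains:
        cid = tr.cell_id or "cell"
        rows.extend((cid, t, "ss") for t in tr.simple_spike_times)
        rows.extend((cid, t, "cs") for t in tr.complex_spike_times)
    df = pd.DataFrame(rows, columns=["cell_id", "time_s", "type"])
    df = df.sort_values(["cell_id", "time_s"], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.6f")


def _check_uniform(time: np.ndarray, path, tol: float = 0.01) -> float:
    dt = np.diff(time)
    if dt.size == 0 or np.any(dt <= 0):
        raise ParseError(f"{path}: time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > tol * med:
        raise ParseError(f"{path}: non-uniform sampling beyond {tol:.0%}")
    return 1.0 / med


def read_trace_csv(path: str | Path, manifest: SessionManifest):
    """Read a trace CSV as an EyeTrial or BlinkTrial per the manifest.

    Eye manifests must declare ``stim_freq`` and ``stim_amplitude`` (and
    optionally ``condition``); blink manifests ``cs_onset`` (s) and
    optionally ``us_onset`` and ``trial_type``.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing 'time_s' column")
    time = df["time_s"].to_numpy(dtype=float)
    fs = _check_uniform(time, path)
    p = manifest.params
    if manifest.modality == "eye":
        for col in ("stimulus_deg", "eye_deg"):
            if col not in df.columns:
                raise ParseError(f"{path}: missing '{col}' column")
        return EyeTrial(time=time,
                        stimulus_position=df["stimulus_deg"].to_numpy(float),
                        eye_position=df["eye_deg"].to_numpy(float),
                        stim_freq=float(p["stim_freq"]),
                        stim_amplitude=float(p["stim_amplitude"]),
                        condition=str(p.get("condition", "OKR")))
    if manifest.modality == "blink":
        if "eyelid_raw" not in df.columns:
            raise ParseError(f"{path}: missing 'eyelid_raw' column")
        us = p.get("us_onset")
        return BlinkTrial(trace=df["eyelid_raw"].to_numpy(float),
                          sample_rate=fs,
                          cs_onset=float(p["cs_onset"]),
                          us_onset=None if us is None else float(us),
                          trial_type=str(p.get("trial_type", "paired")))
    raise ParseError(f"manifest modality '{manifest.modality}' is not a trace")


def write_trace_csv(path: str | Path, trial) -> None:
    if isinstance(trial, EyeTrial):
        df = pd.DataFrame({"time_s": trial.time,
                           "stimulus_deg": trial.stimulus_position,
                           "eye_deg": trial.eye_position})
    elif isinstance(trial, BlinkTrial):
        df = pd.DataFrame({"time_s": trial.time, "eyelid_raw": trial.trace})
    else:
        raise TypeError(f"cannot serialize {type(trial).__name__}")
    df.to_csv(path, index=False, float_format="%.6f")
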