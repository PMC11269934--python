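"""Readers and writers for the package's on-disk formats.

Spike tables and event schedules are plain CSV; sweep sets are HDF5 files
with a structured header (protocol, sample rate, junction correction) and
one group per sweep.  All readers round-trip the writers bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    Event,
    EventSchedule,
    FormatError,
    SchemaError,
    SpikeTrain,
    Sweep,
    SweepSet,
    sort_timestamps,
)

SPIKE_COLUMNS = ["unit_id", "animal_id", "pd", "region", "electrode_id", "t_s"]
EVENT_COLUMNS = ["onset_s", "duration_s", "kind", "label", "wavelength_nm", "intensity"]


def load_spike_table(path, format: str = "csv") -> list[SpikeTrain]:
    """Load a long-format spike table (one row per spike) into SpikeTrains.

    Trains are grouped by ``unit_id`` in order of first appearance; out of
    order timestamps are sorted with a warning.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    df = pd.read_csv(path)
    for col in SPIKE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"spike table missing column {col!r}")
    t = pd.to_numeric(df["t_s"], errors="coerce")
    if t.isna().any():
        row = int(t.index[t.isna()][0])
        raise SchemaError(f"non-numeric timestamp at row {row}")
    df = df.assign(t_s=t)
    trains = []
    for unit_id, g in df.groupby("unit_id", sort=False):
        meta = g.iloc[0]
        trains.append(
            SpikeTrain(
                unit_id=str(unit_id),
                animal_id=str(meta["animal_id"]),
                pd=int(meta["pd"]),
                region=str(meta["region"]),
                electrode_id=str(meta["electrode_id"]),
                timestamps=sort_timestamps(g["t_s"].to_numpy(), context=str(unit_id)),
            )
        )
    return trains


def write_spike_table(trains: list[SpikeTrain], path) -> None:
    rows = []
    for tr in trains:
        for t in tr.timestamps:
            rows.append((tr.unit_id, tr.animal_id, tr.pd, tr.region, tr.electrode_id, t))
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, index=False)


def load_events(path) -> EventSchedule:
    df = pd.read_csv(path)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"event table missing column {col!r}")
    events = []
    for _, r in df.iterrows():
        wl = None if pd.isna(r["wavelength_nm"]) else float(r["wavelength_nm"])
        inten = None if pd.isna(r["intensity"]) else float(r["intensity"])
        events.append(
            Event(
                onset=float(r["onset_s"]),
                duration=float(r["duration_s"]),
                kind=str(r["kind"]),
                label="" if pd.isna(r["label"]) else str(r["label"]),
                wavelength=wl,
                intensity=inten,
            )
        )
    return EventSchedule(events=events)


def write_events(schedule: EventSchedule, path) -> None:
    rows = [
        (e.onset, e.duration, e.kind, e.label, e.wavelength, e.intensity)
        for e in schedule.events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


_STEP_KEYS = ("start", "stop", "increment")


def _expected_step_count(stim: dict) -> int | None:
    """Sweep count implied by a step-family header, e.g. -150..150 pA by 10 -> 31."""
    if all(k in stim for k in _STEP_KEYS) and stim["increment"]:
        return int(round((stim["stop"] - stim["start"]) / stim["increment"])) + 1
    return None


def load_sweep_set(path) -> SweepSet:
    """Load a SweepSet from HDF5, validating the header against the contents."""
    with h5py.File(path, "r") as f:
        protocol = f.attrs["protocol"]
        sample_rate = float(f.attrs["sample_rate"])
        junction = float(f.attrs.get("junction_correction", 0.0))
        if sample_rate <= 0:
            raise FormatError("header sample_rate must be > 0")
        header = json.loads(f.attrs.get("protocol_header", "{}"))
        names = sorted(f["sweeps"].keys(), key=lambda s: int(s.split("_")[1]))
        sweeps = [
            Sweep(
                stimulus=json.loads(f["sweeps"][name].attrs["stimulus"]),
                trace=f["sweeps"][name][()],
            )
            for name in names
        ]
    expected = _expected_step_count(header)
    if expected is not None and expected != len(sweeps):
        raise FormatError(
            f"header implies {expected} sweeps but file contains {len(sweeps)}"
        )
    return SweepSet(
        protocol=str(protocol),
        sample_rate=sample_rate,
        sweeps=sweeps,
        junction_correction=junction,
    )


def write_sweep_set(sweep_set: SweepSet, path, protocol_header: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["protocol"] = sweep_set.protocol
        f.attrs["sample_rate"] = sweep_set.sample_rate
        f.attrs["junction_correction"] = sweep_set.junction_correction
        f.attrs["protocol_header"] = json.dumps(protocol_header or {})
        grp = f.create_group("sweeps")
        for i, sw in enumerate(sweep_set.sweeps):
            ds = grp.create_dataset(f"sweep_{i:04d}", data=sw.trace)
            ds.attrs["stimulus"] = json.dumps(sw.stimulus)


def write_fit_report(report: dict, path) -> None:
    """Write a fit report as JSON, converting numpy scalars/arrays."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default) + "\n")
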