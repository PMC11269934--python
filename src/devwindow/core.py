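"""Domain types shared by every analysis stage.

Units are fixed package-wide: time in seconds, firing rates in Hz, membrane
potentials in mV, injected/recorded currents in nA, capacitance in pF,
resistance in MOhm.  Bins are left-closed, right-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

REGIONS = ("DLG", "IGL", "MGN", "other")
EVENT_KINDS = ("drug_on", "stim_pulse", "light_pulse")
PROTOCOLS = ("ramp", "current_steps", "voltage_steps", "gap_free")


class SchemaError(ValueError):
    """A table is missing a required column or has an unparseable value."""


class FormatError(ValueError):
    """A sweep file header is inconsistent with its contents."""


class InsufficientBaselineError(ValueError):
    """Too little pre-onset data to estimate a baseline."""


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge from every starting point."""


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one single unit, with recording metadata.

    Parameters
    ----------
    unit_id, animal_id, electrode_id : str
        Identifiers; ``unit_id`` is unique within a session.
    pd : int
        Postnatal day of the animal at recording (>= 0).
    region : str
        One of ``DLG``, ``IGL``, ``MGN``, ``other``.
    timestamps : ndarray
        Spike times in seconds, ascending, all >= 0.
    """

    unit_id: str
    animal_id: str
    pd: int
    region: str
    electrode_id: str
    timestamps: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be a 1-D sequence")
        if self.timestamps.size and self.timestamps[0] < 0:
            raise ValueError("timestamps must be >= 0")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be ascending; sort before construction")
        if self.pd < 0:
            raise ValueError("postnatal day must be >= 0")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)


@dataclass
class Event:
    onset: float
    duration: float
    kind: str
    label: str = ""
    wavelength: Optional[float] = None  # nm, light pulses only
    intensity: Optional[float] = None  # photons cm^-2 s^-1, light pulses only

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("event duration must be >= 0")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}, got {self.kind!r}")
        if self.kind == "light_pulse":
            if self.wavelength is None and self.label != "white":
                raise ValueError("light_pulse events need a wavelength (or label 'white')")
            if self.intensity is None:
                raise ValueError("light_pulse events need an intensity")
        elif self.wavelength is not None or self.intensity is not None:
            raise ValueError("wavelength/intensity are only valid for light_pulse events")


@dataclass
class EventSchedule:
    """Time-ordered schedule of drug applications and stimulus pulses."""

    events: list[Event]

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be ascending")

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def onsets(self, kind: str) -> np.ndarray:
        return np.array([e.onset for e in self.events if e.kind == kind])


@dataclass
class BinnedSeries:
    """Firing rate per fixed-width bin; bins are left-closed, right-open."""

    t0: float
    bin_width: float
    rates: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(self.rates.size)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_bins) * self.bin_width


@dataclass
class Sweep:
    """One protocol sweep: a stimulus description and the recorded trace.

    ``trace`` is in mV for current-clamp protocols (ramp, current_steps,
    gap_free) and nA for voltage clamp (voltage_steps).
    """

    stimulus: dict
    trace: np.ndarray

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)


@dataclass
class SweepSet:
    """Ordered patch-clamp sweeps sharing one protocol and sample rate.

    ``junction_correction`` (mV) is recorded at load time but only applied
    when membrane potentials are reported.
    """

    protocol: str
    sample_rate: float
    sweeps: list[Sweep]
    junction_correction: float = 0.0

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be > 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def time(self, i: int = 0) -> np.ndarray:
        return np.arange(self.sweeps[i].trace.size) * self.dt


STUDY_COLUMNS = ("animal_id", "cell_id", "pd", "variable", "value")


def validate_study_table(df) -> None:
    """Check a tidy per-cell parameter table (one value per cell x variable)."""
    for col in STUDY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"study table missing column {col!r}")
    if df.duplicated(subset=["cell_id", "variable"]).any():
        raise ValueError("study table has more than one value per (cell, variable)")
    if df["pd"].isna().any():
        raise ValueError("pd must be present for every row")


def bin_spike_train(
    train: SpikeTrain | np.ndarray,
    t0: float,
    t1: float,
    bin_width: float,
) -> BinnedSeries:
    """Bin spikes into fixed-width rate bins over ``[t0, t1)``.

    The number of bins is ``floor((t1 - t0) / bin_width)``; a trailing
    partial bin is dropped.  Each rate is count / bin_width in Hz, so
    ``sum(rates) * bin_width`` equals the number of spikes inside the
    covered interval.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if t1 <= t0:
        raise ValueError("t1 must be > t0")
    ts = train.timestamps if isinstance(train, SpikeTrain) else np.asarray(train, float)
    n_bins = int(np.floor((t1 - t0) / bin_width))
    if n_bins == 0:
        raise ValueError("window shorter than one bin")
    edges = t0 + np.arange(n_bins + 1) * bin_width
    # np.histogram closes the last bin on the right; clip with searchsorted instead
    counts = np.diff(np.searchsorted(ts, edges, side="left"))
    return BinnedSeries(t0=t0, bin_width=bin_width, rates=counts / bin_width)


def sort_timestamps(ts: Sequence[float], context: str = "") -> np.ndarray:
    """Stable-sort timestamps, warning if they arrived out of order."""
    ts = np.asarray(ts, dtype=float)
    if np.any(np.diff(ts) < 0):
        warnings.warn(
            f"timestamps out of order{' for ' + context if context else ''}; sorting",
            stacklevel=2,
        )
        ts = np.sort(ts, kind="stable")
    return ts
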