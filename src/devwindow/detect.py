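"""Baseline-SD threshold response detection and responsiveness statistics.

The shared rule: a unit (or cell) is responsive when its activity during
the response window exceeds the baseline mean by ``sd_multiplier`` times
the baseline standard deviation.  A configurable SD floor guards silent
units whose baseline variance is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .core import BinnedSeries, InsufficientBaselineError, SpikeTrain, bin_spike_train


@dataclass
class DetectionConfig:
    """Windows and thresholds for drug-response detection on binned firing.

    Defaults follow the ex vivo convention: 30 s bins, a 3xSD threshold,
    a 10 min baseline window immediately before drug onset and a 10 min
    response window after it.  ``compressed`` rescales all time fields
    for time-compressed synthetic sessions, preserving bin counts.
    """

    bin_width: float = 30.0
    sd_multiplier: float = 3.0
    baseline_window: float = 600.0
    response_window: float = 600.0
    sd_floor: float = 0.1
    detect_decreases: bool = False
    min_baseline_bins: int = 5

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")

    def compressed(self, time_scale: float) -> "DetectionConfig":
        return replace(
            self,
            bin_width=self.bin_width / time_scale,
            baseline_window=self.baseline_window / time_scale,
            response_window=self.response_window / time_scale,
        )


@dataclass
class ResponseCall:
    """Detector output for one unit/cell and one application."""

    unit_id: str
    responsive: bool
    direction: str  # 'up', 'down' or 'none'
    amplitude: Optional[float]  # delta-Hz (or delta-nA in current mode); None if not responsive
    baseline_mean: float
    baseline_sd: float
    threshold_used: float
    current_density: Optional[float] = None  # pA/pF, current mode with capacitance

    def __post_init__(self) -> None:
        if not self.responsive:
            assert self.direction == "none" and self.amplitude is None


def _baseline_stats(values: np.ndarray, sd_floor: float) -> tuple[float, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return mean, sd, max(sd, sd_floor)


def detect_drug_response(
    binned: BinnedSeries,
    drug_onset: float,
    cfg: DetectionConfig | None = None,
    unit_id: str = "",
) -> ResponseCall:
    """Classify one unit's binned firing around an acute drug application.

    Baseline mean and SD are taken over the bins fully inside
    ``[onset - baseline_window, onset)``; the unit is responsive when any
    bin fully inside ``[onset, onset + response_window)`` strictly exceeds
    ``mean + sd_multiplier * max(SD, sd_floor)``.  The amplitude is the
    maximal response bin minus the baseline mean.
    """
    cfg = cfg or DetectionConfig()
    starts = binned.bin_starts
    ends = starts + binned.bin_width
    base_mask = (starts >= drug_onset - cfg.baseline_window) & (ends <= drug_onset)
    resp_mask = (starts >= drug_onset) & (ends <= drug_onset + cfg.response_window)
    base = binned.rates[base_mask]
    resp = binned.rates[resp_mask]
    if base.size < cfg.min_baseline_bins:
        raise InsufficientBaselineError(
            f"only {base.size} baseline bins before onset (need {cfg.min_baseline_bins})"
        )
    if resp.size == 0:
        raise ValueError("no response bins inside the response window")
    mean, sd, sd_eff = _baseline_stats(base, cfg.sd_floor)
    thr_up = mean + cfg.sd_multiplier * sd_eff
    up = bool(np.any(resp > thr_up))
    if up:
        return ResponseCall(unit_id, True, "up", float(resp.max() - mean), mean, sd, thr_up)
    if cfg.detect_decreases:
        thr_down = mean - cfg.sd_multiplier * sd_eff
        if np.any(resp < thr_down):
            return ResponseCall(unit_id, True, "down", float(resp.min() - mean), mean, sd, thr_down)
    return ResponseCall(unit_id, False, "none", None, mean, sd, thr_up)


@dataclass
class CurrentDetectionConfig:
    """Configuration for whole-cell current response detection (voltage clamp)."""

    bin_width: float = 5.0  # s, averaging window for 'averaged baseline values'
    sd_multiplier: float = 3.0
    baseline_window: float = 120.0
    response_window: float = 300.0
    sd_floor: float = 0.002  # nA
    min_baseline_bins: int = 5


def detect_current_response(
    current: np.ndarray,
    sample_rate: float,
    drug_onset: float,
    capacitance: Optional[float] = None,
    cfg: CurrentDetectionConfig | None = None,
    mask: Sequence[tuple[float, float]] | None = None,
    unit_id: str = "",
) -> ResponseCall:
    """Detect a drug-evoked whole-cell current shift (trace in nA).

    The trace is averaged in ``bin_width`` windows (test-pulse intervals
    given in ``mask`` excluded); the cell is responsive when any
    post-onset average deviates from the baseline mean by more than
    ``sd_multiplier`` baseline SDs in either direction.  The amplitude is
    the extreme deviation (inward currents negative); with ``capacitance``
    (pF) the current density amplitude / Cm is reported in pA/pF.
    """
    cfg = cfg or CurrentDetectionConfig()
    current = np.asarray(current, dtype=float)
    t = np.arange(current.size) / sample_rate
    valid = np.ones(current.size, dtype=bool)
    for a, b in mask or ():
        valid &= ~((t >= a) & (t < b))
    n_bins = int(np.floor(t[-1] / cfg.bin_width)) if current.size else 0
    means, starts = [], []
    for k in range(n_bins):
        sel = valid & (t >= k * cfg.bin_width) & (t < (k + 1) * cfg.bin_width)
        if sel.sum() > 0:
            means.append(float(current[sel].mean()))
            starts.append(k * cfg.bin_width)
    means = np.asarray(means)
    starts = np.asarray(starts)
    ends = starts + cfg.bin_width
    base_mask = (starts >= drug_onset - cfg.baseline_window) & (ends <= drug_onset)
    resp_mask = (starts >= drug_onset) & (ends <= drug_onset + cfg.response_window)
    base, resp = means[base_mask], means[resp_mask]
    if base.size < cfg.min_baseline_bins:
        raise InsufficientBaselineError(
            f"only {base.size} usable baseline bins before onset (need {cfg.min_baseline_bins})"
        )
    mean, sd, sd_eff = _baseline_stats(base, cfg.sd_floor)
    dev = resp - mean
    extreme = dev[np.argmax(np.abs(dev))] if dev.size else 0.0
    thr = cfg.sd_multiplier * sd_eff
    if np.abs(extreme) > thr:
        direction = "up" if extreme > 0 else "down"
        density = None if capacitance is None else float(extreme) / capacitance * 1000.0
        return ResponseCall(unit_id, True, direction, float(extreme), mean, sd, mean + np.sign(extreme) * thr,
                            current_density=density)
    return ResponseCall(unit_id, False, "none", None, mean, sd, mean + thr)


def responsiveness_ratio(
    calls: Sequence[ResponseCall],
    n_electrodes: int,
    mode: str = "responsive",
) -> float:
    """Responsive-unit (RR) or recorded-unit (activity) count per electrode.

    ``mode='responsive'``: count of responsive calls / n_electrodes.
    ``mode='activity'``: count of all units / n_electrodes.  Either ratio
    may exceed 1 when electrodes carry several sorted units.
    """
    if n_electrodes <= 0:
        raise ValueError("n_electrodes must be > 0")
    if mode == "responsive":
        num = sum(1 for c in calls if c.responsive)
    elif mode == "activity":
        num = len(calls)
    else:
        raise ValueError("mode must be 'responsive' or 'activity'")
    return num / n_electrodes


@dataclass
class StimDetectionConfig:
    """PSTH windows for electrically evoked response detection."""

    bin_width: float = 0.2
    pre_window: float = 2.0
    post_window: float = 0.6
    sd_multiplier: float = 3.0
    sd_floor: float = 0.1
    min_events: int = 10


def detect_stim_response(
    spikes: SpikeTrain | np.ndarray,
    stim_times: Sequence[float],
    cfg: StimDetectionConfig | None = None,
) -> tuple[bool, float]:
    """Stimulation-locked response detection from an event-averaged PSTH.

    Builds a PSTH at ``bin_width`` resolution over all stimulus events;
    the unit is responsive when any post-stimulus bin exceeds the
    pre-stimulus mean by ``sd_multiplier`` pre-stimulus SDs.  Returns
    ``(responsive, evoked rate change)`` where the change is the maximal
    post-stimulus bin minus the pre-stimulus mean (usable for before /
    during / after drug comparisons).
    """
    cfg = cfg or StimDetectionConfig()
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        raise ValueError("no stimulus events")
    if stim_times.size < cfg.min_events:
        raise ValueError(f"need >= {cfg.min_events} stimulus events, got {stim_times.size}")
    ts = spikes.timestamps if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    n_pre = int(round(cfg.pre_window / cfg.bin_width))
    n_post = int(round(cfg.post_window / cfg.bin_width))
    edges = (np.arange(n_pre + n_post + 1) - n_pre) * cfg.bin_width
    counts = np.zeros(n_pre + n_post)
    for t0 in stim_times:
        counts += np.diff(np.searchsorted(ts, t0 + edges, side="left"))
    rates = counts / (stim_times.size * cfg.bin_width)
    base, post = rates[:n_pre], rates[n_pre:]
    mean, sd, sd_eff = _baseline_stats(base, cfg.sd_floor)
    responsive = bool(np.any(post > mean + cfg.sd_multiplier * sd_eff))
    evoked_change = float(post.max() - mean)
    return responsive, evoked_change


def detect_session(
    trains: Sequence[SpikeTrain],
    drug_onset: float,
    cfg: DetectionConfig,
    t0: float = 0.0,
    t1: float | None = None,
) -> list[ResponseCall]:
    """Run drug-response detection over every unit of a session."""
    calls = []
    for tr in trains:
        end = t1 if t1 is not None else drug_onset + cfg.response_window
        binned = bin_spike_train(tr, t0, end, cfg.bin_width)
        calls.append(detect_drug_response(binned, drug_onset, cfg, unit_id=tr.unit_id))
    return calls
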