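"""Synthetic-data generators with ground-truth labels.

Every input the pipeline consumes can be produced here: multi-electrode
array (MEA) sessions with a developmental window of drug-responsive units,
in vivo light-stimulation sessions with three response types, patch-clamp
sweep families with known passive and active membrane properties, and tidy
developmental parameter tables with animal-level random intercepts.

Spiking is an inhomogeneous Poisson process generated by thinning.  With
``noise=0`` the generators switch to deterministic regular spiking (spike
times at half-integer crossings of the integrated rate) and fixed per-unit
parameters, so downstream detectors and classifiers can be checked for
exact agreement with the ground truth.

Per-unit random streams are keyed by ``(seed, unit index)`` so they do not
depend on how many units a session contains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Event, EventSchedule, SpikeTrain, Sweep, SweepSet

__all__ = [
    "RateProfile",
    "Segment",
    "simulate_poisson_train",
    "simulate_mea_session",
    "simulate_invivo_light_session",
    "simulate_patch_sweeps",
    "simulate_development_table",
    "simulate_rr_observations",
    "simulate_dose_response",
    "simulate_ct_table",
]


def _unit_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent per-unit generator keyed by (seed, unit index, ...)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# Rate profiles


@dataclass
class Segment:
    """One modulation of the baseline rate.

    ``amplitude`` adds spikes/s inside ``[start, end)``; alternatively
    ``factor`` multiplies the running rate (``factor=0`` silences it).
    ``shape='ramped_bump'`` replaces the rectangular envelope by a
    sigmoidal rise over ``rise`` seconds and an exponential washout with
    time constant ``decay`` after ``end``.
    """

    start: float
    end: float
    amplitude: float = 0.0
    factor: Optional[float] = None
    shape: str = "step"
    rise: float = 60.0
    decay: float = 300.0

    def envelope(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.shape == "step":
            return ((t >= self.start) & (t < self.end)).astype(float)
        if self.shape == "ramped_bump":
            env = np.zeros_like(t)
            inside = (t >= self.start) & (t < self.end)
            x = (t[inside] - self.start - self.rise / 2.0) / (self.rise / 10.0)
            env[inside] = 1.0 / (1.0 + np.exp(-x))
            after = t >= self.end
            x_end = (self.end - self.start - self.rise / 2.0) / (self.rise / 10.0)
            env_end = 1.0 / (1.0 + np.exp(-x_end))
            env[after] = env_end * np.exp(-(t[after] - self.end) / self.decay)
            return env
        raise ValueError(f"unknown segment shape {self.shape!r}")


@dataclass
class RateProfile:
    """Baseline firing rate plus a sequence of modulations."""

    baseline: float
    segments: list[Segment] = field(default_factory=list)

    def rate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if t.ndim == 1 and (t.size < 2 or np.all(np.diff(t) >= 0)):
            return self._rate_sorted(t)
        r = np.full(t.shape, float(self.baseline))
        for seg in self.segments:
            env = seg.envelope(t)
            if seg.factor is not None:
                r = r * (1.0 + (seg.factor - 1.0) * env)
            r = r + seg.amplitude * env
        return r

    def _rate_sorted(self, t: np.ndarray) -> np.ndarray:
        # fast path: each segment only touches the samples it covers
        r = np.full(t.shape, float(self.baseline))
        for seg in self.segments:
            if seg.shape == "step":
                i0, i1 = np.searchsorted(t, [seg.start, seg.end], side="left")
                if seg.factor is not None:
                    r[i0:i1] *= seg.factor
                r[i0:i1] += seg.amplitude
            else:  # ramped_bump decays to < 1e-5 of its height after ~12 tau
                i0 = np.searchsorted(t, seg.start, side="left")
                i1 = np.searchsorted(t, seg.end + 12.0 * seg.decay, side="left")
                env = seg.envelope(t[i0:i1])
                if seg.factor is not None:
                    r[i0:i1] *= 1.0 + (seg.factor - 1.0) * env
                r[i0:i1] += seg.amplitude * env
        return r

    def max_rate(self, duration: float) -> float:
        """Tight upper bound on the instantaneous rate (for thinning).

        Sweeps the breakpoint intervals and bounds each segment's
        envelope by its maximum on the interval, so non-overlapping
        response bumps do not accumulate into a loose bound.
        """
        pts = {0.0, duration}
        for s in self.segments:
            pts.update(x for x in (s.start, s.end) if 0.0 <= x <= duration)
        edges = sorted(pts)
        best = float(self.baseline)
        for t0, t1 in zip(edges, edges[1:]):
            ub = float(self.baseline)
            for s in self.segments:
                if t1 <= s.start:
                    env = 0.0
                elif t0 < s.end:  # interval overlaps the active window
                    env = 1.0
                elif s.shape == "ramped_bump":
                    env = float(s.envelope(np.array([t0]))[0])
                else:
                    env = 0.0
                if s.factor is not None and s.factor > 1:
                    ub *= 1.0 + (s.factor - 1.0) * env
                ub += max(s.amplitude, 0.0) * env
            best = max(best, ub)
        return best

    def check_nonnegative(self, duration: float, n: int = 4096) -> None:
        probe = np.linspace(0.0, duration, n)
        extra = [x for s in self.segments for x in (s.start, s.end, s.end - 1e-9) if 0 <= x <= duration]
        probe = np.sort(np.concatenate([probe, np.asarray(extra)]))
        if np.any(self.rate(probe) < -1e-12):
            raise ValueError("rate profile is negative somewhere in the window")


def _deterministic_times(profile: RateProfile, duration: float) -> np.ndarray:
    """Spike times at half-integer crossings of the integrated rate."""
    dt = min(0.005, duration / 1000.0)
    grid = np.arange(0.0, duration + dt, dt)
    rates = profile.rate(grid)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (rates[1:] + rates[:-1]) * np.diff(grid))])
    total = cum[-1]
    targets = np.arange(0.5, total, 1.0)
    return np.interp(targets, cum, grid)


def simulate_poisson_train(
    profile: RateProfile,
    duration: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
    **meta,
) -> SpikeTrain:
    """Inhomogeneous Poisson spike train by thinning against the peak rate.

    ``deterministic=True`` yields the regular (noise-free) train used by
    the noiseless session generators.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    profile.check_nonnegative(duration)
    meta.setdefault("unit_id", "u0")
    meta.setdefault("animal_id", "a0")
    meta.setdefault("pd", 0)
    meta.setdefault("region", "other")
    meta.setdefault("electrode_id", "e0")
    if deterministic:
        ts = _deterministic_times(profile, duration)
        return SpikeTrain(timestamps=ts, **meta)
    if rng is None:
        rng = np.random.default_rng(seed)
    upper = profile.max_rate(duration)
    if upper == 0:
        return SpikeTrain(timestamps=np.empty(0), **meta)
    n = rng.poisson(upper * duration)
    t = np.sort(rng.uniform(0.0, duration, n))
    keep = rng.uniform(0.0, upper, n) < profile.rate(t)
    return SpikeTrain(timestamps=t[keep], **meta)


def gaussian_window(pd_day, kappa: float, mu: float, sigma: float):
    """Responsive fraction as a Gaussian in postnatal day."""
    pd_day = np.asarray(pd_day, dtype=float)
    return kappa * np.exp(-((pd_day - mu) ** 2) / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# MEA drug sessions


def simulate_mea_session(
    pd_day: int,
    n_electrodes: int = 50,
    window: tuple[float, float, float] = (0.26, 12.99, 0.65),
    noise: float = 1.0,
    seed: int = 0,
    *,
    n_igl: int = 10,
    time_scale: float = 10.0,
    baseline_rate: float = 2.0,
    response_amp: float = 3.0,
    baseline_duration: float = 1800.0,
    response_duration: float = 600.0,
    washout_duration: float = 600.0,
    drug_duration: float = 180.0,
    rise: float = 60.0,
    washout_tau: float = 300.0,
) -> tuple[list[SpikeTrain], EventSchedule, pd.DataFrame]:
    """Simulate one slice recording: baseline, acute drug epoch, washout.

    The fraction of DLG units made truly responsive follows the Gaussian
    developmental window ``kappa * exp(-(pd - mu)^2 / (2 sigma^2))``; IGL
    units are always responsive.  All durations are real-time seconds and
    are divided by ``time_scale`` (default 10x compression); detector
    configurations scale their bin widths in tandem so bin counts match
    the uncompressed design.

    Returns (spike trains, event schedule, ground-truth table).
    """
    kappa, mu, sigma = window
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("window peak kappa must lie in [0, 1]")
    if n_electrodes <= 0:
        raise ValueError("n_electrodes must be > 0")
    ts = float(time_scale)
    t_drug = baseline_duration / ts
    duration = (baseline_duration + response_duration + washout_duration) / ts
    p_responsive = float(gaussian_window(pd_day, kappa, mu, sigma))

    master = _unit_rng(seed, 0)
    n_dlg = n_electrodes
    responsive = master.random(n_dlg) < p_responsive
    animal = f"rat_pd{pd_day}_s{seed}"

    trains: list[SpikeTrain] = []
    records = []
    for i in range(n_dlg + n_igl):
        is_igl = i >= n_dlg
        region = "IGL" if is_igl else "DLG"
        resp = True if is_igl else bool(responsive[i])
        rng = _unit_rng(seed, i + 1)
        if noise == 0:
            base = baseline_rate
            amp = response_amp
        else:
            base = baseline_rate * rng.lognormal(0.0, 0.4 * noise)
            amp = response_amp * rng.lognormal(0.0, 0.3 * noise)
        segments = []
        if resp:
            segments.append(
                Segment(
                    start=t_drug,
                    end=t_drug + response_duration / ts,
                    amplitude=amp,
                    shape="ramped_bump",
                    rise=rise / ts,
                    decay=washout_tau / ts,
                )
            )
        profile = RateProfile(baseline=base, segments=segments)
        unit_id = f"u{i:03d}"
        electrode = f"e{i % n_electrodes:02d}"
        trains.append(
            simulate_poisson_train(
                profile,
                duration,
                rng=rng,
                deterministic=(noise == 0),
                unit_id=unit_id,
                animal_id=animal,
                pd=pd_day,
                region=region,
                electrode_id=electrode,
            )
        )
        records.append(
            dict(
                unit_id=unit_id,
                region=region,
                electrode_id=electrode,
                responsive=resp,
                amplitude=amp if resp else 0.0,
                baseline_rate=base,
                pd=pd_day,
                seed=seed,
            )
        )
    schedule = EventSchedule(
        events=[Event(onset=t_drug, duration=drug_duration / ts, kind="drug_on", label="drug")]
    )
    return trains, schedule, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# In vivo light sessions


DEFAULT_MIX = {"transient_on": 0.22, "sustained": 0.23, "suppressed": 0.18, "none": 0.37}
WAVELENGTH_NM = {"blue": 470.0, "green": 525.0, "UV": 365.0}


def _hill_saturation(intensity, ec50: float, n: float):
    intensity = np.asarray(intensity, dtype=float)
    return intensity**n / (ec50**n + intensity**n)


def simulate_invivo_light_session(
    mix: dict[str, float] | None = None,
    hill: tuple[float, float, float] = (10.0, 1e11, 1.0),
    wavelengths: Sequence[str] = ("white", "blue", "green", "UV"),
    intensities: Sequence[float] | None = None,
    seed: int = 0,
    *,
    n_units: int = 30,
    noise: float = 1.0,
    pulse_duration: float = 15.0,
    isi: float = 15.0,
    n_pulses: int = 6,
    inter_intensity: float = 300.0,
    mono_intensity: float = 1e14,
    baseline_rate: float = 10.0,
    suppression_depth: float = 1.0,
    wavelength_sensitivity: float = 0.85,
    animal_id: str = "rat_invivo",
) -> tuple[list[SpikeTrain], EventSchedule, pd.DataFrame]:
    """Simulate an in vivo light-stimulation session in the visual thalamus.

    White light is presented at each intensity for ``n_pulses`` pulses
    (15 s on / 15 s off), then single-intensity blue, green and UV blocks.
    Unit response classes are drawn from ``mix``; white-light response
    amplitudes follow the Hill law ``I^n / (EC50^n + I^n)`` scaled by the
    unit's maximal amplitude.  Transient-ON units get a 0.5 s onset (and
    offset) bump, sustained units are elevated throughout the pulse, and
    suppressed units are silenced with a 1 s post-offset rebound.
    """
    mix = dict(DEFAULT_MIX if mix is None else mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mix proportions must sum to 1")
    if intensities is None:
        intensities = np.logspace(8, 15, 8)
    intensities = np.asarray(list(intensities), dtype=float)
    if intensities.size == 0:
        raise ValueError("intensity list must not be empty")
    rmax0, ec50, hill_n = hill

    # --- stimulus schedule
    events: list[Event] = []
    t = 30.0
    for inten in intensities:
        for _ in range(n_pulses):
            events.append(
                Event(onset=t, duration=pulse_duration, kind="light_pulse",
                      label="white", wavelength=None, intensity=float(inten))
            )
            t += pulse_duration + isi
        t += inter_intensity
    for wl in ("blue", "green", "UV"):
        if wl not in wavelengths:
            continue
        for _ in range(n_pulses):
            events.append(
                Event(onset=t, duration=pulse_duration, kind="light_pulse",
                      label=wl, wavelength=WAVELENGTH_NM[wl], intensity=mono_intensity)
            )
            t += pulse_duration + isi
        t += inter_intensity
    schedule = EventSchedule(events=events)
    duration = t + 30.0

    classes = list(mix)
    master = _unit_rng(seed, 0)
    unit_classes = master.choice(classes, size=n_units, p=[mix[c] for c in classes])

    trains: list[SpikeTrain] = []
    records = []
    for i in range(n_units):
        cls = str(unit_classes[i])
        rng = _unit_rng(seed, i + 1)
        if noise == 0:
            base = baseline_rate
            rmax = rmax0
        else:
            base = baseline_rate * rng.lognormal(0.0, 0.2 * noise)
            rmax = rmax0 * rng.lognormal(0.0, 0.2 * noise)
        sens = {wl: bool(rng.random() < wavelength_sensitivity) for wl in ("blue", "green", "UV")}
        if cls == "none":
            sens = {wl: False for wl in sens}
        segments: list[Segment] = []
        for ev in events:
            if cls == "none":
                continue
            if ev.label == "white":
                s = float(_hill_saturation(ev.intensity, ec50, hill_n))
            elif sens.get(ev.label, False):
                s = 1.0
            else:
                continue
            on, off = ev.onset, ev.onset + ev.duration
            if cls == "transient_on":
                segments.append(Segment(start=on, end=on + 0.5, amplitude=2.0 * rmax * s))
                segments.append(Segment(start=off, end=off + 0.5, amplitude=2.0 * rmax * s))
            elif cls == "sustained":
                segments.append(Segment(start=on, end=off, amplitude=rmax * s))
            elif cls == "suppressed":
                segments.append(Segment(start=on, end=off, factor=1.0 - suppression_depth * s))
                segments.append(Segment(start=off, end=off + 1.0, amplitude=rmax * s))
        profile = RateProfile(baseline=base, segments=segments)
        unit_id = f"u{i:03d}"
        trains.append(
            simulate_poisson_train(
                profile,
                duration,
                rng=rng,
                deterministic=(noise == 0),
                unit_id=unit_id,
                animal_id=animal_id,
                pd=70,
                region="DLG",
                electrode_id=f"e{i:02d}",
            )
        )
        records.append(
            dict(
                unit_id=unit_id,
                cls=cls,
                rmax=rmax,
                ec50=ec50,
                hill_n=hill_n,
                baseline_rate=base,
                blue=sens["blue"],
                green=sens["green"],
                uv=sens["UV"],
                seed=seed,
            )
        )
    return trains, schedule, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Patch-clamp sweeps


def _noise_levels(noise) -> tuple[float, float]:
    if isinstance(noise, dict):
        return float(noise.get("v_mV", 0.0)), float(noise.get("i_nA", 0.0))
    return float(noise), float(noise) * 0.01


def _simulate_current_clamp(
    current: np.ndarray,
    vrest: float,
    rm: float,
    cm: float,
    threshold: float,
    dt: float,
) -> tuple[np.ndarray, list[float]]:
    """Leaky RC membrane with threshold spiking and a stereotyped waveform.

    ``current`` in nA, potentials in mV, rm in MOhm, cm in pF.  Returns the
    voltage trace and spike times (threshold crossings).
    """
    tau = rm * cm * 1e-6  # seconds
    n = current.size
    v = np.empty(n)
    v[0] = vrest + current[0] * rm
    spikes: list[float] = []
    peak, reset = 30.0, threshold - 15.0
    n_rise = max(int(round(0.0005 / dt)), 2)
    n_fall = max(int(round(0.001 / dt)), 2)
    n_ref = max(int(round(0.001 / dt)), 1)
    i = 0
    while i < n - 1:
        dv = ((vrest - v[i]) + current[i] * rm) / tau
        v[i + 1] = v[i] + dt * dv
        if v[i + 1] >= threshold:
            spikes.append((i + 1) * dt)
            j = i + 1
            up = np.linspace(threshold, peak, n_rise, endpoint=False)
            down = np.linspace(peak, reset, n_fall, endpoint=False)
            wave = np.concatenate([up, down, np.full(n_ref, reset)])
            k = min(wave.size, n - j)
            v[j : j + k] = wave[:k]
            i = j + k - 1
        else:
            i += 1
    return v, spikes


def simulate_patch_sweeps(
    truth: dict,
    noise=0.0,
    seed: int = 0,
    *,
    sample_rate: float = 20000.0,
    cell_id: str = "cell0",
) -> tuple[dict[str, SweepSet], pd.DataFrame]:
    """Generate the whole patch-clamp protocol family for one model cell.

    ``truth`` carries the generating membrane parameters: ``vrest`` (mV,
    uncorrected), ``rm`` (MOhm), ``cm`` (pF), ``threshold`` (mV) and
    ``it`` (nA, peak T-type transient).  Families produced: a 10 s
    zero-current gap-free segment, a 1 s / 1 nA current ramp, current
    steps -150..+150 pA in 10 pA increments (0.5 s), and voltage steps
    -95..-38 mV in 3 mV increments (200 ms) carrying a transient inward
    deflection whose maximum over steps equals ``it`` exactly.

    Returns a dict of SweepSets keyed by protocol plus a one-row
    ground-truth table including the realized rheobase, threshold, spike
    count on the ramp and f-I gain of the noiseless model cell.
    """
    vrest = float(truth["vrest"])
    rm = float(truth["rm"])
    cm = float(truth["cm"])
    thr = float(truth["threshold"])
    it_amp = float(truth["it"])
    if rm <= 0 or cm <= 0:
        raise ValueError("rm and cm must be > 0")
    if not (vrest < thr <= 0):
        raise ValueError("need vrest < threshold <= 0 mV")
    noise_v, noise_i = _noise_levels(noise)
    dt = 1.0 / sample_rate
    rng = _unit_rng(seed, 7)
    junction = -15.0

    out: dict[str, SweepSet] = {}

    # gap-free resting potential segment
    n_gap = int(round(10.0 * sample_rate))
    v_gap = np.full(n_gap, vrest) + noise_v * rng.standard_normal(n_gap)
    out["gap_free"] = SweepSet(
        protocol="gap_free",
        sample_rate=sample_rate,
        sweeps=[Sweep(stimulus={"kind": "gap_free", "current_nA": 0.0, "duration_s": 10.0}, trace=v_gap)],
        junction_correction=junction,
    )

    # current ramp: 1 nA over 1 s
    t_pre, ramp_dur, ramp_amp = 0.1, 1.0, 1.0
    n_ramp = int(round((t_pre + ramp_dur + 0.1) * sample_rate))
    t_axis = np.arange(n_ramp) * dt
    i_ramp = np.where(
        (t_axis >= t_pre) & (t_axis < t_pre + ramp_dur),
        ramp_amp * (t_axis - t_pre) / ramp_dur,
        0.0,
    )
    v_ramp, ramp_spikes = _simulate_current_clamp(i_ramp, vrest, rm, cm, thr, dt)
    first = ramp_spikes[0] if ramp_spikes else None
    rheobase = ramp_amp * (first - t_pre) / ramp_dur if first is not None else np.nan
    out["ramp"] = SweepSet(
        protocol="ramp",
        sample_rate=sample_rate,
        sweeps=[
            Sweep(
                stimulus={"kind": "ramp", "amplitude_nA": ramp_amp, "duration_s": ramp_dur, "t_start_s": t_pre},
                trace=v_ramp + noise_v * rng.standard_normal(n_ramp),
            )
        ],
        junction_correction=junction,
    )

    # current steps -150..+150 pA by 10 pA, 0.5 s
    step_levels = np.round(np.arange(-0.15, 0.1501, 0.01), 4)
    step_dur, step_pre = 0.5, 0.1
    n_step = int(round((step_pre + step_dur + 0.1) * sample_rate))
    t_axis = np.arange(n_step) * dt
    sweeps = []
    counts = []
    for lev in step_levels:
        i_inj = np.where((t_axis >= step_pre) & (t_axis < step_pre + step_dur), lev, 0.0)
        v, spk = _simulate_current_clamp(i_inj, vrest, rm, cm, thr, dt)
        counts.append(len(spk))
        sweeps.append(
            Sweep(
                stimulus={"kind": "step", "current_nA": float(lev), "t_start_s": step_pre, "duration_s": step_dur},
                trace=v + noise_v * rng.standard_normal(n_step),
            )
        )
    out["current_steps"] = SweepSet(
        protocol="current_steps", sample_rate=sample_rate, sweeps=sweeps, junction_correction=junction
    )
    counts = np.asarray(counts, dtype=float)
    spiking = counts > 0
    if spiking.sum() >= 2:
        gain_slope = np.polyfit(step_levels[spiking] * 1000.0, counts[spiking], 1)[0]  # spikes/pA
    else:
        gain_slope = np.nan

    # voltage steps -95..-38 mV by 3 mV, 200 ms; T-type transient
    v_levels = np.arange(-95.0, -37.9, 3.0)
    hold = -75.0
    vs_pre, vs_dur, vs_post = 0.05, 0.2, 0.05
    n_vs = int(round((vs_pre + vs_dur + vs_post) * sample_rate))
    t_axis = np.arange(n_vs) * dt
    tau_r, tau_d = 0.003, 0.015

    def act(v):
        return 1.0 / (1.0 + np.exp(-(v + 58.0) / 5.0))

    act_norm = act(v_levels[-1])
    kernel_t = t_axis - vs_pre
    h = np.where(kernel_t >= 0, np.exp(-np.maximum(kernel_t, 0) / tau_d) - np.exp(-np.maximum(kernel_t, 0) / tau_r), 0.0)
    h_peak = h.max()
    sweeps = []
    for v_cmd in v_levels:
        leak_hold = (hold - vrest) / rm
        leak_step = (v_cmd - vrest) / rm
        i_tr = np.full(n_vs, leak_hold)
        step_mask = (t_axis >= vs_pre) & (t_axis < vs_pre + vs_dur)
        i_tr[step_mask] = leak_step
        i_tr -= it_amp * (act(v_cmd) / act_norm) * (h / h_peak) * step_mask
        sweeps.append(
            Sweep(
                stimulus={"kind": "voltage_step", "v_mV": float(v_cmd), "t_start_s": vs_pre,
                          "duration_s": vs_dur, "holding_mV": hold},
                trace=i_tr + noise_i * rng.standard_normal(n_vs),
            )
        )
    out["voltage_steps"] = SweepSet(
        protocol="voltage_steps", sample_rate=sample_rate, sweeps=sweeps, junction_correction=0.0
    )

    truth_row = pd.DataFrame(
        [
            dict(
                cell_id=cell_id,
                vrest=vrest,
                vm=vrest + junction,
                rm=rm,
                cm=cm,
                threshold=thr,
                rheobase=rheobase,
                ap_count=len(ramp_spikes),
                gain=gain_slope,
                it=it_amp,
                seed=seed,
            )
        ]
    )
    return out, truth_row


# ---------------------------------------------------------------------------
# Developmental parameter tables and small statistical fixtures


def _mean_function(model: dict):
    if "jp" in model:
        a, b, jp = model["a"], model["b"], model["jp"]
        return lambda x: a + b * np.minimum(np.asarray(x, float), jp)
    if "c" in model:
        a, b, c = model["a"], model["b"], model["c"]
        return lambda x: a + b * np.asarray(x, float) + c * np.asarray(x, float) ** 2
    a, b = model["a"], model["b"]
    return lambda x: a + b * np.asarray(x, float)


def simulate_development_table(
    model: dict,
    sd_animal: float,
    sd_resid: float,
    n_per_group: int,
    pds: Sequence[int],
    seed: int = 0,
    *,
    n_animals_per_pd: int = 4,
    variable: str = "y",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-cell table following a linear-plateau, quadratic or linear mean.

    ``model`` is ``{a, b, jp}`` (plateau), ``{a, b, c}`` (quadratic) or
    ``{a, b}`` (linear).  Each animal gets an intercept drawn with SD
    ``sd_animal``; each cell adds residual noise ``sd_resid``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    pds = list(pds)
    if "jp" in model and not (min(pds) <= model["jp"] <= max(pds)):
        warnings.warn("junction point lies outside the sampled PD range", stacklevel=2)
    mean_fn = _mean_function(model)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    intercepts = []
    cell_counter = 0
    for pd_day in pds:
        for a_i in range(n_animals_per_pd):
            animal = f"rat_pd{pd_day}_{a_i}"
            u = rng.normal(0.0, sd_animal) if sd_animal > 0 else 0.0
            intercepts.append(dict(animal_id=animal, pd=pd_day, intercept=u))
            for _ in range(n_per_group):
                eps = rng.normal(0.0, sd_resid) if sd_resid > 0 else 0.0
                rows.append(
                    dict(
                        animal_id=animal,
                        cell_id=f"c{cell_counter:04d}",
                        pd=pd_day,
                        variable=variable,
                        value=float(mean_fn(pd_day)) + u + eps,
                    )
                )
                cell_counter += 1
    return pd.DataFrame(rows), pd.DataFrame(intercepts)


def simulate_rr_observations(
    window: tuple[float, float, float] = (0.26, 12.99, 0.65),
    pds: Sequence[int] = tuple(range(7, 26)),
    slices_per_pd: tuple[int, int] = (3, 5),
    n_electrodes: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Responsiveness-ratio observations with binomial slice noise.

    For each slice the responsive-unit count is Binomial(n_electrodes, p)
    with p given by the Gaussian window; RR = count / n_electrodes.
    """
    kappa, mu, sigma = window
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for pd_day in pds:
        p = float(gaussian_window(pd_day, kappa, mu, sigma))
        k_slices = int(rng.integers(slices_per_pd[0], slices_per_pd[1] + 1))
        for s in range(k_slices):
            count = rng.binomial(n_electrodes, p)
            rows.append(dict(pd=pd_day, slice=s, rr=count / n_electrodes))
    return pd.DataFrame(rows)


def simulate_dose_response(
    hill: tuple[float, float, float] = (10.0, 1e11, 1.0),
    intensities: Sequence[float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy dose-response amplitudes from the Hill law (one unit)."""
    rmax, ec50, n = hill
    if intensities is None:
        intensities = np.logspace(8, 15, 8)
    intensities = np.asarray(list(intensities), dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    amps = rmax * _hill_saturation(intensities, ec50, n)
    if noise_sd > 0:
        amps = amps + rng.normal(0.0, noise_sd, size=amps.shape)
    return intensities, amps


def simulate_ct_table(
    groups: Sequence[int] = (4, 7, 10, 13, 16, 19, 22, 25),
    n_per_group: int = 5,
    model: dict | None = None,
    ct_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired target/reference Ct values whose Delta-Ct rises with age.

    The default mean Delta-Ct follows a rising linear-plateau (expression
    declining to a floor), mirroring a transcript switched off over
    development.  Returns columns sample_id, group, ct_target, ct_ref.
    """
    if model is None:
        model = {"a": 6.0, "b": 0.3, "jp": 19.0}
    mean_fn = _mean_function(model)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    k = 0
    for g in groups:
        for _ in range(n_per_group):
            ct_ref = rng.normal(18.0, ct_sd)
            dct = float(mean_fn(g)) + rng.normal(0.0, ct_sd)
            rows.append(dict(sample_id=f"s{k:03d}", group=g, ct_target=ct_ref + dct, ct_ref=ct_ref))
            k += 1
    return pd.DataFrame(rows)
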