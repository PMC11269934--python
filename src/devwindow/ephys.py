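"""Membrane-parameter extraction from patch-clamp sweep families.

Covers the standard panel: resting potential (junction-corrected), action
potential threshold / rheobase / spike count from a current ramp, input
resistance, capacitance and firing gain from a current-step family,
T-type current amplitude from voltage steps, and a PCA over the
per-cell parameter table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .core import SweepSet

logger = logging.getLogger(__name__)


@dataclass
class EphysParams:
    """Per-cell membrane parameter panel (missing values are None)."""

    vm: Optional[float] = None  # mV, junction-corrected
    threshold: Optional[float] = None  # mV
    rheobase: Optional[float] = None  # nA
    ap_count: Optional[int] = None
    cm: Optional[float] = None  # pF
    rm: Optional[float] = None  # MOhm
    gain: Optional[float] = None  # spikes/pA
    it_amp: Optional[float] = None  # nA


def detect_spikes(
    trace: np.ndarray,
    sample_rate: float,
    dvdt_threshold: float = 10.0,  # V/s
    peak_min: float = 0.0,  # mV
    peak_within: float = 0.002,  # s
    refractory: float = 0.002,  # s
) -> tuple[np.ndarray, np.ndarray]:
    """Find action potentials by a dV/dt criterion.

    A spike is an upward crossing of dV/dt >= 10 V/s followed by a peak
    above 0 mV within 2 ms; the per-spike threshold is the membrane
    potential at the crossing.  Crossings within the refractory period of
    a previous spike are merged.  Returns (spike times, thresholds).
    """
    if sample_rate < 10000:
        raise ValueError("sample_rate must be >= 10 kHz for spike detection")
    trace = np.asarray(trace, dtype=float)
    dt = 1.0 / sample_rate
    dvdt = np.gradient(trace) / dt / 1000.0  # V/s
    above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    n_peak = max(int(round(peak_within * sample_rate)), 1)
    times, thresholds = [], []
    last = -np.inf
    for idx in crossings:
        t = idx * dt
        if t - last < refractory:
            continue
        if trace[idx : idx + n_peak + 1].max() <= peak_min:
            continue
        times.append(t)
        thresholds.append(trace[idx])
        last = t
    return np.asarray(times), np.asarray(thresholds)


def measure_resting(gap_free: SweepSet) -> float:
    """Mean membrane potential over the zero-current segment, junction-corrected."""
    v = gap_free.sweeps[0].trace
    return float(v.mean()) + gap_free.junction_correction


@dataclass
class RampResult:
    threshold: Optional[float]
    rheobase: Optional[float]
    ap_count: int


def analyze_ramp(ramp: SweepSet) -> RampResult:
    """Threshold, rheobase and spike count from a current-ramp sweep.

    Rheobase is the injected current at the first spike,
    ``amplitude * (t - t_start) / duration``; threshold is the first
    spike's dV/dt-crossing voltage.  Without spikes all three degrade
    gracefully (count 0, threshold/rheobase missing).
    """
    sw = ramp.sweeps[0]
    stim = sw.stimulus
    if stim.get("kind") != "ramp":
        raise ValueError("sweep is not a ramp")
    t_start, dur, amp = stim["t_start_s"], stim["duration_s"], stim["amplitude_nA"]
    times, thresholds = detect_spikes(sw.trace, ramp.sample_rate)
    in_ramp = (times >= t_start) & (times < t_start + dur)
    times, thresholds = times[in_ramp], thresholds[in_ramp]
    if times.size == 0:
        return RampResult(threshold=None, rheobase=None, ap_count=0)
    return RampResult(
        threshold=float(thresholds[0]),
        rheobase=float(amp * (times[0] - t_start) / dur),
        ap_count=int(times.size),
    )


@dataclass
class StepsResult:
    rm: Optional[float]  # MOhm
    cm: Optional[float]  # pF
    gain: Optional[float]  # spikes/pA
    fi_table: pd.DataFrame  # current_nA, spike_count
    tau: Optional[float] = None  # s


def analyze_steps(steps: SweepSet, min_hyperpolarizing: int = 3) -> StepsResult:
    """Input resistance, capacitance and f-I gain from a current-step family.

    rm is the least-squares slope of steady-state voltage deflection
    against injected current over hyperpolarizing steps (mV/nA = MOhm);
    the membrane time constant comes from a single-exponential fit to the
    averaged, normalized hyperpolarizing onset, and cm = tau / rm.  Gain
    is the slope of spike count against injected current over steps with
    at least one spike, in spikes/pA.
    """
    dt = steps.dt
    levels, deltas, counts = [], [], []
    onsets = []  # normalized onset transients of hyperpolarizing steps
    for sw in steps.sweeps:
        stim = sw.stimulus
        if stim.get("kind") != "step":
            raise ValueError("sweep is not a current step")
        lev = stim["current_nA"]
        i0 = int(round(stim["t_start_s"] / dt))
        i1 = int(round((stim["t_start_s"] + stim["duration_s"]) / dt))
        pre = sw.trace[: i0].mean()
        steady = sw.trace[i1 - int(0.2 * (i1 - i0)) : i1].mean()
        levels.append(lev)
        deltas.append(steady - pre)
        t_spk, _ = detect_spikes(sw.trace, steps.sample_rate)
        counts.append(int(((t_spk >= stim["t_start_s"]) & (t_spk < stim["t_start_s"] + stim["duration_s"])).sum()))
        if lev < 0:
            seg = sw.trace[i0:i1] - pre
            if abs(steady - pre) > 1e-12:
                onsets.append(seg / (steady - pre))
    levels = np.asarray(levels)
    deltas = np.asarray(deltas)
    counts = np.asarray(counts)
    hyper = levels < 0
    if hyper.sum() < min_hyperpolarizing:
        raise ValueError(f"need >= {min_hyperpolarizing} hyperpolarizing steps")
    rm = float(np.polyfit(levels[hyper], deltas[hyper], 1)[0])  # mV/nA = MOhm

    cm = tau = None
    if onsets:
        avg = np.mean(onsets, axis=0)
        t = np.arange(avg.size) * dt
        try:
            (tau_fit,), _ = optimize.curve_fit(
                lambda tt, tau: 1.0 - np.exp(-tt / tau), t, avg, p0=[0.02], maxfev=2000
            )
            tau = float(tau_fit)
            cm = tau / rm * 1e6  # s / MOhm -> pF
        except RuntimeError:
            logger.warning("membrane time-constant fit did not converge; cm missing")

    spiking = counts > 0
    gain = None
    if spiking.sum() >= 2:
        gain = float(np.polyfit(levels[spiking] * 1000.0, counts[spiking], 1)[0])
    fi = pd.DataFrame({"current_nA": levels, "spike_count": counts})
    return StepsResult(rm=rm, cm=cm, gain=gain, fi_table=fi, tau=tau)


@dataclass
class ItResult:
    it_amp: float  # nA, magnitude of the peak transient inward current
    flagged: bool  # True when no transient rose above the noise floor


def measure_t_current(
    voltage_steps: SweepSet,
    n_leak_steps: int = 5,
    transient_window: float = 0.05,
    blank: float = 0.002,
) -> ItResult:
    """Low-threshold transient (T-type) current amplitude from voltage steps.

    Leak is a linear fit of steady-state current against command voltage
    over the most hyperpolarized ``n_leak_steps`` steps; the amplitude is
    the largest leak-subtracted inward deflection within 50 ms of step
    onset over all steps (first 2 ms blanked against onset artifacts).
    """
    dt = voltage_steps.dt
    sweeps = sorted(voltage_steps.sweeps, key=lambda s: s.stimulus["v_mV"])
    v_cmd, steady = [], []
    for sw in sweeps[:n_leak_steps]:
        stim = sw.stimulus
        i1 = int(round((stim["t_start_s"] + stim["duration_s"]) / dt))
        n_tail = int(round(0.05 / dt))
        v_cmd.append(stim["v_mV"])
        steady.append(sw.trace[i1 - n_tail : i1].mean())
    slope, intercept = np.polyfit(v_cmd, steady, 1)
    leak_resid = np.std(np.asarray(steady) - (slope * np.asarray(v_cmd) + intercept))
    noise_floor = max(3.0 * leak_resid, 1e-4)

    best = 0.0
    for sw in sweeps:
        stim = sw.stimulus
        i0 = int(round(stim["t_start_s"] / dt))
        w0 = i0 + int(round(blank / dt))
        w1 = i0 + int(round(transient_window / dt))
        leak_pred = slope * stim["v_mV"] + intercept
        deflection = sw.trace[w0:w1] - leak_pred
        inward_peak = -float(deflection.min())  # inward currents are negative
        best = max(best, inward_peak)
    if best <= noise_floor:
        return ItResult(it_amp=0.0, flagged=True)
    return ItResult(it_amp=best, flagged=False)


def extract_ephys_params(sweep_sets: dict[str, SweepSet]) -> EphysParams:
    """Run the full panel over a cell's sweep families (missing ones skipped)."""
    params = EphysParams()
    if "gap_free" in sweep_sets:
        params.vm = measure_resting(sweep_sets["gap_free"])
    if "ramp" in sweep_sets:
        r = analyze_ramp(sweep_sets["ramp"])
        params.threshold, params.rheobase, params.ap_count = r.threshold, r.rheobase, r.ap_count
    if "current_steps" in sweep_sets:
        s = analyze_steps(sweep_sets["current_steps"])
        params.rm, params.cm, params.gain = s.rm, s.cm, s.gain
    if "voltage_steps" in sweep_sets:
        params.it_amp = measure_t_current(sweep_sets["voltage_steps"]).it_amp
    return params


@dataclass
class PCAResult:
    scores: pd.DataFrame  # cells x components
    loadings: pd.DataFrame  # variables x components, orthonormal columns
    explained_variance_ratio: np.ndarray
    n_dropped: int


def pca_parameters(wide: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the per-cell membrane-parameter table (complete cases only).

    Columns are standardized to zero mean and unit variance before the
    decomposition; cells missing any parameter are dropped with a log
    message.  Variance-explained fractions sum to 1 over all components.
    """
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.info("dropping %d cells with missing parameters", n_dropped)
    if len(complete) < 2:
        raise ValueError("need at least 2 complete cases for PCA")
    X = StandardScaler().fit_transform(complete.to_numpy(dtype=float))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=complete.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=complete.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_dropped=n_dropped,
    )
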