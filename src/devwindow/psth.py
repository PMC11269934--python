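"""In vivo light-response analysis: PSTHs, response typing, Hill coding.

A peristimulus time histogram (PSTH) is built per unit and light
condition at 0.1 s resolution over a 5 s baseline / 15 s stimulus / 5 s
post window.  Responses are typed by two baseline-SD criteria: a 3xSD
"peak window" rule for transient ON responses in the first 0.5 s, and a
1xSD rule on the remainder of the stimulus for sustained and suppressed
responses.  Intensity coding is scored by a Hill fit whose goodness of
fit must reach R^2 >= 0.5.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .core import SpikeTrain

logger = logging.getLogger(__name__)

LIGHT_TYPES = ("transient_on", "sustained", "suppressed", "none")


@dataclass
class PSTHConfig:
    bin_width: float = 0.1
    baseline: float = 5.0
    stimulus: float = 15.0
    post: float = 5.0
    peak_window: float = 0.5
    sd_multiplier_peak: float = 3.0
    sd_multiplier_sustained: float = 1.0
    sd_floor: float = 0.1
    peak_stat: str = "mean"  # or "max": statistic over the peak window


@dataclass
class PSTH:
    """Event-averaged firing rate around light pulses (Hz per bin)."""

    bin_width: float
    baseline: float
    stimulus: float
    post: float
    rates: np.ndarray
    n_pulses: int

    @property
    def n_bins(self) -> int:
        return int(self.rates.size)

    @property
    def times(self) -> np.ndarray:
        """Bin start times relative to pulse onset."""
        return -self.baseline + np.arange(self.n_bins) * self.bin_width

    def _slice(self, t_from: float, t_to: float) -> np.ndarray:
        t = self.times
        return self.rates[(t >= t_from - 1e-9) & (t < t_to - 1e-9)]

    def baseline_rates(self) -> np.ndarray:
        return self._slice(-self.baseline, 0.0)

    def peak_window_rates(self, peak_window: float = 0.5) -> np.ndarray:
        return self._slice(0.0, peak_window)

    def sustained_rates(self, peak_window: float = 0.5) -> np.ndarray:
        return self._slice(peak_window, self.stimulus)


def build_psth(
    spikes: SpikeTrain | np.ndarray,
    pulse_onsets: Sequence[float],
    cfg: PSTHConfig | None = None,
) -> PSTH:
    """Average spike counts across pulses into a fixed-window PSTH.

    The default window (-5 s ... +20 s at 0.1 s bins) yields 250 bins.
    If consecutive pulse windows overlap, a warning is raised and each
    pulse's window is truncated at the start of the next pulse's baseline
    so no spike is double-counted within one PSTH.
    """
    cfg = cfg or PSTHConfig()
    onsets = np.asarray(pulse_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one pulse")
    ts = spikes.timestamps if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    window = cfg.baseline + cfg.stimulus + cfg.post
    n_bins = int(round(window / cfg.bin_width))
    edges = -cfg.baseline + np.arange(n_bins + 1) * cfg.bin_width
    gaps = np.diff(onsets)
    truncate_at = np.full(onsets.size, window - cfg.baseline)  # end relative to onset
    if gaps.size and np.any(gaps < window):
        warnings.warn("consecutive pulse windows overlap; truncating", stacklevel=2)
        truncate_at[:-1] = np.minimum(truncate_at[:-1], gaps - cfg.baseline)
    counts = np.zeros(n_bins)
    exposure = np.zeros(n_bins)
    for onset, t_end in zip(onsets, truncate_at):
        c = np.diff(np.searchsorted(ts, onset + edges, side="left"))
        valid = edges[1:] <= t_end + 1e-9
        counts[valid] += c[valid]
        exposure[valid] += 1
    exposure[exposure == 0] = np.nan
    with np.errstate(invalid="ignore"):
        rates = counts / (exposure * cfg.bin_width)
    return PSTH(
        bin_width=cfg.bin_width,
        baseline=cfg.baseline,
        stimulus=cfg.stimulus,
        post=cfg.post,
        rates=np.nan_to_num(rates),
        n_pulses=int(onsets.size),
    )


@dataclass
class LightResponse:
    """Typed light response of one unit to one wavelength/intensity."""

    unit_id: str
    wavelength: str  # 'white', 'blue', 'green', 'UV'
    type: str
    peak_window_rate: float
    sustained_rate: float
    baseline_mean: float
    baseline_sd: float
    rel_change_peak: float  # (peak - baseline) / baseline
    rel_change_sustained: float
    delta_peak: float  # absolute Hz
    delta_sustained: float
    multiple_criteria: bool = False

    @property
    def responsive(self) -> bool:
        return self.type != "none"


def classify_light_response(
    psth: PSTH,
    cfg: PSTHConfig | None = None,
    unit_id: str = "",
    wavelength: str = "",
) -> LightResponse:
    """Assign one of transient_on / sustained / suppressed / none.

    Peak criterion: activity in the 0.5 s peak window after light onset
    must exceed baseline mean + 3 x SD.  Sustained (suppressed): mean
    activity from the end of the peak window to the end of the stimulus
    at least 1 x SD above (below) baseline.  Precedence when criteria
    co-fire: sustained, then suppressed, then transient ON.
    """
    cfg = cfg or PSTHConfig()
    base = psth.baseline_rates()
    if base.size == 0:
        raise ValueError("no baseline bins available")
    mean = float(base.mean())
    sd = float(base.std(ddof=1)) if base.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn("zero baseline SD; applying sd_floor", stacklevel=2)
    sd_eff = max(sd, cfg.sd_floor)
    peak_rates = psth.peak_window_rates(cfg.peak_window)
    peak = float(peak_rates.max() if cfg.peak_stat == "max" else peak_rates.mean())
    sus = float(psth.sustained_rates(cfg.peak_window).mean())
    is_peak = peak > mean + cfg.sd_multiplier_peak * sd_eff
    is_sustained = sus >= mean + cfg.sd_multiplier_sustained * sd_eff
    is_suppressed = sus <= mean - cfg.sd_multiplier_sustained * sd_eff
    if is_sustained:
        rtype = "sustained"
    elif is_suppressed:
        rtype = "suppressed"
    elif is_peak:
        rtype = "transient_on"
    else:
        rtype = "none"
    multi = sum([is_peak, is_sustained, is_suppressed]) > 1
    if multi:
        logger.info("unit %s satisfies multiple criteria; precedence applied -> %s", unit_id, rtype)
    rel = lambda x: (x - mean) / mean if mean > 0 else np.nan
    return LightResponse(
        unit_id=unit_id,
        wavelength=wavelength,
        type=rtype,
        peak_window_rate=peak,
        sustained_rate=sus,
        baseline_mean=mean,
        baseline_sd=sd,
        rel_change_peak=rel(peak),
        rel_change_sustained=rel(sus),
        delta_peak=peak - mean,
        delta_sustained=sus - mean,
        multiple_criteria=multi,
    )


# ---------------------------------------------------------------------------
# Hill intensity coding


@dataclass
class HillFit:
    rmax: float
    ec50: float
    n: float
    r2: float
    coding: bool
    converged: bool


def _hill(log_i: np.ndarray, rmax: float, log_ec50: float, n: float) -> np.ndarray:
    return rmax / (1.0 + 10.0 ** (n * (log_ec50 - log_i)))


class HillRegressor(BaseEstimator, RegressorMixin):
    """Saturating Hill dose-response fit on log10 intensity.

    Fits ``R(I) = Rmax * I^n / (EC50^n + I^n)`` by least squares with
    multi-start initialization (an EC50 grid across the tested intensity
    decades and Hill coefficients {0.5, 1, 2}); a unit is scored as
    intensity-coding when R^2 >= ``coding_r2`` (default 0.5).
    """

    def __init__(self, coding_r2: float = 0.5, n_ec50_starts: int = 5):
        self.coding_r2 = coding_r2
        self.n_ec50_starts = n_ec50_starts

    def fit(self, X, y):
        intensities = np.asarray(X, dtype=float).ravel()
        amplitudes = np.asarray(y, dtype=float).ravel()
        if np.any(intensities <= 0):
            raise ValueError("intensities must be positive")
        if intensities.size < 4:
            raise ValueError("need at least 4 intensity levels")
        log_i = np.log10(intensities)
        lo, hi = log_i.min(), log_i.max()
        amax = max(amplitudes.max(), 1e-6)
        best, best_sse = None, np.inf
        for log_ec in np.linspace(lo, hi, self.n_ec50_starts):
            for n0 in (0.5, 1.0, 2.0):
                try:
                    popt, _ = optimize.curve_fit(
                        _hill,
                        log_i,
                        amplitudes,
                        p0=[amax, log_ec, n0],
                        bounds=([1e-9, lo - 3, 0.05], [10 * amax + 1, hi + 3, 10.0]),
                        maxfev=5000,
                    )
                except RuntimeError:
                    continue
                sse = float(np.sum((amplitudes - _hill(log_i, *popt)) ** 2))
                if sse < best_sse:
                    best, best_sse = popt, sse
        if best is None:
            self.rmax_, self.ec50_, self.n_ = np.nan, np.nan, np.nan
            self.r2_, self.coding_, self.converged_ = 0.0, False, False
            return self
        sst = float(np.sum((amplitudes - amplitudes.mean()) ** 2))
        self.rmax_, self.n_ = float(best[0]), float(best[2])
        self.ec50_ = float(10.0 ** best[1])
        self.r2_ = 1.0 - best_sse / sst if sst > 0 else 0.0
        self.converged_ = True
        self.coding_ = bool(self.r2_ >= self.coding_r2)
        return self

    def predict(self, X):
        check_is_fitted(self, "rmax_")
        return _hill(np.log10(np.asarray(X, float).ravel()), self.rmax_, np.log10(self.ec50_), self.n_)

    def result_(self) -> HillFit:
        check_is_fitted(self, "rmax_")
        return HillFit(self.rmax_, self.ec50_, self.n_, self.r2_, self.coding_, self.converged_)


def fit_hill(intensities, amplitudes) -> HillFit:
    """Fit the Hill intensity-coding curve; see :class:`HillRegressor`."""
    return HillRegressor().fit(intensities, amplitudes).result_()


# ---------------------------------------------------------------------------
# Cross-wavelength profiling and frequency comparisons

VENN_CATEGORIES = ("B", "G", "U", "BG", "BU", "GU", "BGU")
_WL_LETTER = {"blue": "B", "green": "G", "UV": "U"}


def crosswavelength_profile(
    responses: Sequence[LightResponse],
) -> tuple[dict[str, str], Counter]:
    """Assign each unit to its set of effective monochromatic wavelengths.

    Units must carry a response for all of blue/green/UV; units missing a
    wavelength are excluded (logged), units responsive to none are
    excluded from the category counts.  Returns (unit -> category,
    counts per category).
    """
    per_unit: dict[str, dict[str, LightResponse]] = {}
    for r in responses:
        if r.wavelength in _WL_LETTER:
            per_unit.setdefault(r.unit_id, {})[r.wavelength] = r
    categories: dict[str, str] = {}
    counts: Counter = Counter({c: 0 for c in VENN_CATEGORIES})
    for unit, by_wl in per_unit.items():
        if set(by_wl) != set(_WL_LETTER):
            logger.info("unit %s missing a wavelength; excluded from profile", unit)
            continue
        letters = "".join(
            _WL_LETTER[wl] for wl in ("blue", "green", "UV") if by_wl[wl].responsive
        )
        if not letters:
            continue
        categories[unit] = letters
        counts[letters] += 1
    return categories, counts


def chisq_frequencies(table) -> tuple[float, int, float]:
    """Pearson chi-squared test on an r x c count table (no Yates correction)."""
    table = np.asarray(table, dtype=float)
    expected = stats.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError("a cell has zero expected count; merge sparse categories first")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
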