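"""PSTH construction, light-response typing, Hill coding, frequency tests."""

import numpy as np
import pytest

from devwindow import (
    PSTH,
    PSTHConfig,
    build_psth,
    chisq_frequencies,
    classify_light_response,
    crosswavelength_profile,
    fit_hill,
)
from devwindow.psth import HillRegressor, LightResponse
from devwindow.simulate import simulate_dose_response, simulate_invivo_light_session

CFG = PSTHConfig()


def psth_from_rates(rates):
    return PSTH(bin_width=0.1, baseline=5.0, stimulus=15.0, post=5.0,
                rates=np.asarray(rates, float), n_pulses=6)


def template(baseline, peak, sustained, post=None):
    """250-bin PSTH: 50 baseline, 5 peak, 145 stimulus-remainder, 50 post bins."""
    post = baseline if post is None else post
    rates = np.concatenate([
        np.resize(baseline, 50), np.resize(peak, 5),
        np.resize(sustained, 145), np.resize(post, 50)])
    return psth_from_rates(rates)


class TestBuildPSTH:
    def test_empty_train_gives_zero_250_bins(self):
        p = build_psth(np.array([]), [100.0], CFG)
        assert p.n_bins == 250 and np.all(p.rates == 0)

    def test_one_spike_per_pulse_first_bin_rate(self):
        onsets = np.arange(100.0, 280.0, 30.0)  # 6 pulses
        spikes = onsets + 0.05
        p = build_psth(np.sort(spikes), onsets, CFG)
        first_stim_bin = int(5.0 / 0.1)
        assert p.rates[first_stim_bin] == pytest.approx(10.0)  # 1 spike / 0.1 s
        assert p.rates.sum() == pytest.approx(10.0)

    def test_overlapping_windows_warn_and_truncate(self):
        onsets = [10.0, 20.0]  # 10 s apart < 25 s window
        with pytest.warns(UserWarning, match="overlap"):
            p = build_psth(np.array([]), onsets, CFG)
        assert p.n_bins == 250


class TestClassifier:
    def test_transient_on(self):
        # baseline ~2 Hz (SD ~0.5), peak window 20 Hz, remainder at baseline
        base = np.tile([1.5, 2.5], 25)
        p = psth_from_rates(np.concatenate([base, [20.0] * 5, [2.0] * 145, [2.0] * 50]))
        assert classify_light_response(p, CFG).type == "transient_on"

    def test_sustained(self):
        base = np.tile([1.5, 2.5], 25)
        p = psth_from_rates(np.concatenate([base, [8.0] * 150, [2.0] * 50]))
        assert classify_light_response(p, CFG).type == "sustained"

    def test_suppressed(self):
        base = np.tile([9.0, 11.0], 25)
        p = psth_from_rates(np.concatenate([base, [4.0] * 150, [15.0] * 50]))
        assert classify_light_response(p, CFG).type == "suppressed"

    def test_none_when_flat(self):
        base = np.tile([4.0, 6.0], 25)
        p = psth_from_rates(np.concatenate([base, [5.0] * 150, [5.0] * 50]))
        assert classify_light_response(p, CFG).type == "none"

    def test_sustained_precedence_over_transient(self):
        # both peak and sustained criteria fire -> sustained wins
        base = np.tile([1.5, 2.5], 25)
        p = psth_from_rates(np.concatenate([base, [20.0] * 5, [8.0] * 145, [2.0] * 50]))
        r = classify_light_response(p, CFG)
        assert r.type == "sustained" and r.multiple_criteria

    def test_zero_baseline_sd_warns_and_uses_floor(self):
        p = psth_from_rates(np.concatenate([[2.0] * 50, [20.0] * 5, [2.0] * 145, [2.0] * 50]))
        with pytest.warns(UserWarning, match="sd_floor"):
            r = classify_light_response(p, CFG)
        assert r.type == "transient_on"

    def test_relative_changes_reported(self):
        p = template(2.0, 6.0, 2.0)
        with pytest.warns(UserWarning):  # constant baseline -> sd_floor
            r = classify_light_response(p, CFG)
        assert r.rel_change_peak == pytest.approx((6.0 - 2.0) / 2.0)
        assert r.delta_peak == pytest.approx(4.0)

    def test_time_shift_invariance(self):
        # classifying a uniformly shifted session gives identical results
        trains, schedule, _ = simulate_invivo_light_session(n_units=3, seed=6, noise=1.0)
        onsets = np.array([e.onset for e in schedule.events if e.label == "blue"])
        for tr in trains:
            a = classify_light_response(build_psth(tr.timestamps, onsets, CFG), CFG)
            b = classify_light_response(build_psth(tr.timestamps + 123.4, onsets + 123.4, CFG), CFG)
            assert a.type == b.type and a.peak_window_rate == pytest.approx(b.peak_window_rate)


class TestHill:
    def test_noiseless_recovery(self):
        I, amps = simulate_dose_response(hill=(10.0, 1e11, 1.0), noise_sd=0.0)
        fit = fit_hill(I, amps)
        assert fit.rmax == pytest.approx(10.0, rel=1e-3)
        assert np.log10(fit.ec50) == pytest.approx(11.0, abs=0.01)
        assert fit.n == pytest.approx(1.0, abs=0.01)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9) and fit.coding

    def test_midpoint_prediction(self):
        I, amps = simulate_dose_response(hill=(8.0, 1e12, 1.5), noise_sd=0.0)
        reg = HillRegressor().fit(I, amps)
        assert reg.predict([1e12])[0] == pytest.approx(4.0, rel=1e-3)

    def test_flat_amplitudes_not_coding(self):
        I = np.logspace(8, 15, 8)
        fit = fit_hill(I, np.full(8, 3.0) + np.linspace(-1e-3, 1e-3, 8))
        assert not fit.coding and fit.r2 < 0.5

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([0.0, 1e9, 1e10, 1e11], [0, 1, 2, 3])

    def test_ec50_recovery_under_noise(self):
        errs = []
        for s in range(50):
            I, amps = simulate_dose_response(hill=(10.0, 1e11, 1.0), noise_sd=1.0, seed=s)
            fit = fit_hill(I, amps)
            errs.append(abs(np.log10(fit.ec50) - 11.0))
        assert np.median(errs) < 0.15


class TestVennAndChisq:
    def make_resp(self, unit, wl, rtype):
        return LightResponse(unit, wl, rtype, 0, 0, 0, 0, 0, 0, 0, 0)

    def test_all_three_is_bgu(self):
        rs = [self.make_resp("u0", wl, "sustained") for wl in ("blue", "green", "UV")]
        cats, counts = crosswavelength_profile(rs)
        assert cats["u0"] == "BGU" and counts["BGU"] == 1

    def test_nonresponsive_unit_excluded(self):
        rs = [self.make_resp("u0", wl, "none") for wl in ("blue", "green", "UV")]
        cats, counts = crosswavelength_profile(rs)
        assert "u0" not in cats and sum(counts.values()) == 0

    def test_missing_wavelength_excluded(self):
        rs = [self.make_resp("u0", wl, "sustained") for wl in ("blue", "green")]
        cats, _ = crosswavelength_profile(rs)
        assert "u0" not in cats

    def test_blue_only_bookkeeping(self):
        rs = []
        for i in range(10):
            rs.append(self.make_resp(f"u{i}", "blue", "transient_on"))
            rs.append(self.make_resp(f"u{i}", "green", "none"))
            rs.append(self.make_resp(f"u{i}", "UV", "none"))
        _, counts = crosswavelength_profile(rs)
        assert counts["B"] == 10 and sum(counts.values()) == 10

    def test_chisq_homogeneous_zero(self):
        chi2, df, p = chisq_frequencies([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0) and df == 1

    def test_chisq_hand_computed(self):
        chi2, df, _ = chisq_frequencies([[30, 10], [10, 30]])
        assert chi2 == pytest.approx(20.0) and df == 1

    def test_chisq_2x7_df(self):
        table = np.ones((2, 7)) * 5
        _, df, _ = chisq_frequencies(table)
        assert df == 6

    def test_zero_expected_cell_advises_merge(self):
        with pytest.raises(ValueError, match="merge"):
            chisq_frequencies([[5, 0], [3, 0]])
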