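"""Generators: Poisson statistics, session structure, ground truth."""

import numpy as np
import pytest
from scipy import stats

from devwindow.simulate import (
    RateProfile,
    Segment,
    gaussian_window,
    simulate_development_table,
    simulate_invivo_light_session,
    simulate_mea_session,
    simulate_patch_sweeps,
    simulate_poisson_train,
)


class TestPoissonTrain:
    def test_zero_rate_gives_empty_train(self):
        train = simulate_poisson_train(RateProfile(baseline=0.0), 100.0, seed=0)
        assert train.n_spikes == 0

    def test_constant_rate_mean_count(self):
        # Poisson mean/variance oracle: 10 Hz x 100 s -> mean 1000
        counts = [
            simulate_poisson_train(RateProfile(baseline=10.0), 100.0, seed=s).n_spikes
            for s in range(20)
        ]
        assert abs(np.mean(counts) - 1000.0) < 3.0 * np.sqrt(1000.0 / 20)

    def test_same_seed_identical(self):
        prof = RateProfile(baseline=5.0, segments=[Segment(10, 20, amplitude=5.0)])
        a = simulate_poisson_train(prof, 50.0, seed=42)
        b = simulate_poisson_train(prof, 50.0, seed=42)
        assert np.array_equal(a.timestamps, b.timestamps)

    def test_negative_rate_rejected(self):
        prof = RateProfile(baseline=1.0, segments=[Segment(0, 10, amplitude=-5.0)])
        with pytest.raises(ValueError, match="negative"):
            simulate_poisson_train(prof, 20.0, seed=0)

    def test_thinning_matches_profile_chisq(self):
        # goodness of fit of segment counts on a large fixture
        prof = RateProfile(baseline=4.0, segments=[Segment(100, 200, amplitude=8.0),
                                                   Segment(250, 300, factor=0.5)])
        train = simulate_poisson_train(prof, 400.0, seed=7)
        edges = np.array([0, 100, 200, 250, 300, 400], dtype=float)
        observed = np.diff(np.searchsorted(train.timestamps, edges))
        expected = np.array([400, 1200, 200, 100, 400], dtype=float)
        chi2 = np.sum((observed - expected) ** 2 / expected)
        assert stats.chi2.sf(chi2, df=4) > 1e-3

    def test_deterministic_mode_counts_exact(self):
        train = simulate_poisson_train(RateProfile(baseline=2.0), 30.0, deterministic=True)
        assert train.n_spikes == 60


class TestMEASession:
    def test_fraction_at_peak_matches_kappa(self):
        kappa, mu, sigma = 0.26, 12.99, 0.65
        _, _, truth = simulate_mea_session(13, n_electrodes=800, seed=1, noise=0,
                                           window=(kappa, mu, sigma))
        frac = truth[truth.region == "DLG"].responsive.mean()
        p = gaussian_window(13, kappa, mu, sigma)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 800)

    def test_fraction_one_sigma_away(self):
        kappa, mu, sigma = 0.4, 13.0, 2.0
        _, _, truth = simulate_mea_session(15, n_electrodes=800, seed=2, noise=0,
                                           window=(kappa, mu, sigma))
        frac = truth[truth.region == "DLG"].responsive.mean()
        p = kappa * np.exp(-0.5)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 800)

    def test_degenerate_window_dlg_null_igl_responsive(self):
        _, _, truth = simulate_mea_session(13, n_electrodes=30, seed=0, window=(0.0, 13, 1))
        assert not truth[truth.region == "DLG"].responsive.any()
        assert truth[truth.region == "IGL"].responsive.all()

    def test_kappa_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_mea_session(13, window=(1.5, 13, 1))

    def test_ground_truth_one_record_per_unit(self):
        trains, _, truth = simulate_mea_session(10, n_electrodes=20, seed=5)
        assert sorted(truth.unit_id) == sorted(t.unit_id for t in trains)
        assert not truth.unit_id.duplicated().any()


class TestInvivoSession:
    def test_white_pulse_count(self):
        # 8 intensities x 6 pulses -> 48 white pulses in the schedule
        _, schedule, _ = simulate_invivo_light_session(n_units=1, seed=0, noise=0)
        white = [e for e in schedule.events if e.label == "white"]
        assert len(white) == 48
        assert all(e.duration == 15.0 for e in white)

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simulate_invivo_light_session(mix={"none": 0.5, "sustained": 0.2}, n_units=2)

    def test_empty_intensities_rejected(self):
        with pytest.raises(ValueError):
            simulate_invivo_light_session(intensities=[], n_units=2)

    def test_hill_midpoint_amplitude(self):
        # a sustained unit stimulated at EC50 is elevated by Rmax/2
        rmax, ec50 = 10.0, 1e11
        trains, schedule, truth = simulate_invivo_light_session(
            mix={"sustained": 1.0}, hill=(rmax, ec50, 1.0), intensities=[ec50],
            n_units=1, noise=0, seed=0)
        ev = [e for e in schedule.events if e.label == "white"]
        ts = trains[0].timestamps
        during = np.mean([np.sum((ts >= e.onset) & (ts < e.onset + 15.0)) / 15.0 for e in ev])
        base = truth.baseline_rate.iloc[0]
        assert during - base == pytest.approx(rmax / 2.0, abs=0.2)

    def test_all_none_units_stay_at_baseline(self):
        trains, schedule, truth = simulate_invivo_light_session(
            mix={"none": 1.0, "sustained": 0.0, "suppressed": 0.0, "transient_on": 0.0},
            n_units=3, noise=0, seed=1)
        for tr in trains:
            isi = np.diff(tr.timestamps)
            assert np.allclose(isi, isi[0])  # perfectly regular: no modulation anywhere


class TestPatchSweeps:
    def test_steady_state_ohms_law(self, patch_noiseless):
        # -50 pA on 500 MOhm -> steady-state deflection -25 mV
        ss = patch_noiseless[0]["current_steps"]
        sweep = next(s for s in ss.sweeps if abs(s.stimulus["current_nA"] + 0.05) < 1e-9)
        dt = ss.dt
        stim = sweep.stimulus
        i1 = int((stim["t_start_s"] + stim["duration_s"]) / dt)
        pre = sweep.trace[: int(stim["t_start_s"] / dt)].mean()
        steady = sweep.trace[i1 - 200 : i1].mean()
        assert steady - pre == pytest.approx(-25.0, abs=0.1)

    def test_step_family_has_31_sweeps(self, patch_noiseless):
        assert len(patch_noiseless[0]["current_steps"].sweeps) == 31

    def test_t_current_peak_equals_truth(self, patch_noiseless):
        ss = patch_noiseless[0]["voltage_steps"]
        top = max(ss.sweeps, key=lambda s: s.stimulus["v_mV"])
        leak = (top.stimulus["v_mV"] - (-60.0)) / 500.0
        assert leak - top.trace.min() == pytest.approx(1.5, abs=1e-6)

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_patch_sweeps({"vrest": -60, "rm": -5, "cm": 100, "threshold": -45, "it": 1})


class TestDevelopmentTable:
    MODEL = {"a": -52.84, "b": -1.12, "jp": 19.62}

    def test_noiseless_values_on_mean_function(self):
        table, _ = simulate_development_table(self.MODEL, 0.0, 0.0, 3, [4, 10, 19, 25], seed=0)
        expected = self.MODEL["a"] + self.MODEL["b"] * np.minimum(table["pd"], self.MODEL["jp"])
        assert np.allclose(table["value"], expected)

    def test_quadratic_noiseless_minimum_at_vertex(self):
        model = {"a": 0.24, "b": -0.021, "c": 0.00081}
        table, _ = simulate_development_table(model, 0.0, 0.0, 2, list(range(4, 26)), seed=0)
        grouped = table.groupby("pd")["value"].mean()
        assert abs(grouped.idxmin() - (-model["b"] / (2 * model["c"]))) <= 1.0

    def test_animal_sd_monotone(self):
        def spread(sd_animal, seed):
            table, _ = simulate_development_table({"a": 0.0, "b": 0.0}, sd_animal, 0.1, 10,
                                                  [10], seed=seed, n_animals_per_pd=30)
            return table.groupby("animal_id")["value"].mean().std()

        small = np.median([spread(0.5, s) for s in range(5)])
        large = np.median([spread(5.0, s) for s in range(5)])
        assert large > small

    def test_jp_outside_range_warns(self):
        with pytest.warns(UserWarning, match="junction"):
            simulate_development_table(self.MODEL, 0, 0, 1, [4, 7, 10], seed=0)
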