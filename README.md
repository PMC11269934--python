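# devwindow

Analysis toolkit for a developmental question in visual-thalamus
electrophysiology: for how long, and how strongly, are neurons of the
dorsolateral geniculate nucleus (DLG) — the primary visual relay of the
rodent thalamus — excited by the arousal neuropeptide orexin A during
postnatal development?

The package re-implements the full analysis chain as a tested, reusable
library for electrophysiologists and computational neuroscientists:

- **Drug-response detection** on multi-electrode-array (MEA) spike
  trains: a unit is *responsive* when its firing in 30 s bins rises more
  than 3 baseline standard deviations above the baseline mean; the
  per-slice **responsiveness ratio** RR = responsive units / DLG
  electrodes summarizes each recording.
- **Developmental window fitting**: RR against postnatal day (PD) is fit
  with a Gaussian, RR(PD) = κ·exp(−(PD−μ)²/2σ²), giving the peak day μ,
  peak ratio κ and window half-width σ.
- **Patch-clamp feature extraction**: resting potential (liquid-junction
  corrected), spike threshold / rheobase / spike count from a 1 s, 1 nA
  current ramp, input resistance Rm and capacitance Cm from current
  steps (−150…+150 pA by 10 pA), firing gain from the f–I slope, and the
  T-type calcium current I_t from voltage steps (−95…−38 mV by 3 mV),
  plus a PCA over the per-cell parameter panel.
- **Developmental statistics**: linear-plateau regression
  y = a + b·min(PD, jp) with a profiled junction point jp, quadratic
  trajectories with vertex −b/2c, and a Gaussian linear mixed model with
  one random intercept per animal (profiled variance-ratio maximum
  likelihood), plus relative gene expression by the 2^−ΔΔCt method.
- **In vivo light-response analysis**: peristimulus time histograms
  (0.1 s bins; 5 s baseline, 15 s stimulus, 5 s post) typed into
  *transient ON* (3×SD peak-window rule), *sustained* and *suppressed*
  (±1×SD stimulus-long rule) classes; Hill-curve intensity coding
  R(I) = Rmax·Iⁿ/(EC50ⁿ+Iⁿ) scored by R² ≥ 0.5; cross-wavelength
  (blue/green/UV) response profiles and χ² frequency comparisons.
- **A synthetic-data generator** for every input above — inhomogeneous
  Poisson spike trains by thinning, model-cell patch sweeps, light
  sessions with known response classes — so the whole pipeline is
  testable against ground truth without any recordings.

The statistical estimators follow the scikit-learn protocol
(`fit`/`predict`, fitted attributes with trailing underscores) and
compose with sklearn tooling.

## Worked example

Simulate one noise-free MEA slice at the eye-opening day (PD13), detect
drug responses, and fit the developmental window to simulated per-slice
RR data:

```python
import devwindow as dw

trains, schedule, truth = dw.simulate_mea_session(13, n_electrodes=50, noise=0.0, seed=1)
cfg = dw.DetectionConfig().compressed(10.0)        # 10x time-compressed session
onset = float(schedule.onsets("drug_on")[0])
calls = dw.detect_session([t for t in trains if t.region == "DLG"], onset, cfg)
rr = dw.responsiveness_ratio(calls, n_electrodes=50)
print(f"responsive DLG units: {sum(c.responsive for c in calls)}/50  RR = {rr:.2f}")

df = dw.simulate_rr_observations(window=(0.26, 12.99, 0.65), seed=1)
fit = dw.fit_gaussian_window(df["pd"], df["rr"])
print(f"kappa = {fit.kappa:.3f} +/- {fit.se['kappa']:.3f}")
print(f"mu    = {fit.mu:.2f} +/- {fit.se['mu']:.2f} days")
print(f"sigma = {fit.sigma:.2f} +/- {fit.se['sigma']:.2f} days")
```

prints

```
responsive DLG units: 10/50  RR = 0.20
kappa = 0.233 +/- 0.008
mu    = 12.89 +/- 0.03 days
sigma = 0.80 +/- 0.03 days
```

The detector recovered exactly the 10 truly responsive units the
generator planted (RR 0.20, a binomial draw around κ = 0.26), and the
window fit places the responsiveness peak at PD ≈ 13 — the day of eye
opening — with a half-width under a day.

The same stages run from the shell:

```bash
devwindow run --config examples/pipeline.yaml --out scratch/demo
```

which writes per-stage CSVs, the fitted window parameters
(`window_fit.json`) and a `summary.json` with the detector-vs-truth
confusion counts.

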