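# Methods

This note documents the models implemented in `devwindow`, the
conventions of its synthetic-data generators, and the numerical choices
made where the underlying analysis conventions were genuinely open.

## Units and data model

Time is in seconds, firing rates in Hz, membrane potentials in mV,
currents in nA, capacitance in pF, resistance in MΩ. All bins are
left-closed, right-open; a trailing partial bin is dropped, so
`sum(rates) · bin_width` always equals the spike count in the covered
interval. Spike tables arriving with unsorted timestamps are sorted
with a warning rather than rejected (exported sorting artifacts are
common); duplicate timestamps are preserved.

## Drug-response detection (MEA)

A unit's firing is binned at 30 s. Baseline mean and SD are computed
over the 10 min immediately preceding drug onset (the full baseline
epoch is longer, but the window nearest the application is the most
stationary); the unit is responsive when any bin in the 10 min after
onset strictly exceeds `mean + 3·max(SD, sd_floor)`. The SD is the
sample SD (ddof = 1) of the baseline bins; `sd_floor` (default 0.1 Hz)
guards silent units whose baseline variance is exactly zero. The
response amplitude is the maximal response bin minus the baseline mean,
which makes it invariant to adding a constant rate to every bin.
Decrease detection (`mean − 3·SD`) is implemented but disabled by
default, since the ex vivo rule is stated for increases. The
responsiveness ratio of a slice is responsive units / DLG electrode
count; in *activity* mode the numerator is all recorded units. Either
ratio may exceed 1 when electrodes carry several sorted units.

Voltage-clamp drug responses use the same 3×SD logic on whole-cell
current averaged in 5 s windows (test-pulse intervals masked out), in
either direction, with the amplitude signed (inward negative) and, when
capacitance is supplied, also expressed as current density in pA/pF.
Stimulation-locked responses are detected on an event-averaged PSTH at
0.2 s bins: responsive when any post-stimulus bin exceeds the
pre-stimulus mean + 3×SD; the evoked rate change (max post bin −
pre-stimulus mean) supports before/during/after drug comparisons.

## Gaussian developmental window

Per-slice RR against postnatal day is fit with
`RR(PD) = κ·exp(−(PD−μ)²/(2σ²))` by nonlinear least squares.
Multi-start initialization (μ₀ at the empirical argmax and ±2 days,
σ₀ ∈ {1, 3} days) guards against the narrow-peak local minima that a
half-width under one day produces on an integer PD grid. Standard
errors come from the Jacobian at the optimum; t = estimate/SE.

## Linear-plateau and quadratic fits; the mixed-model engine

The linear-plateau mean is `a + b·x` for `x < jp` and `a + b·jp` above —
continuous at the junction, constant on the plateau. `jp` is profiled:
a coarse grid pass (0.25-day steps between the third-smallest and
second-largest distinct PD) followed by 0.05-day refinement; at each
candidate the conditional two-parameter model is fit by the
random-intercept engine and `jp` minimizes the deviance. Its SE is
taken from the numerical second difference of the profile deviance
(var ≈ 2/deviance″). Flat data leave the junction unidentifiable; the
fit falls back to a plain linear model and flags it. Quadratic
trajectories report the vertex −b/(2c) and vertex value a − b²/(4c),
undefined when c ≈ 0.

The engine itself is a Gaussian linear mixed model with a single random
intercept per animal, estimated by profiling the variance ratio
λ = σ²_animal/σ²_resid: fixed effects are closed-form GLS at each λ
(group-wise Woodbury identity, so each evaluation costs O(groups ×
parameters)), and λ is found by bounded 1-D optimization on log λ
(xatol 1e−10) with an explicit λ = 0 boundary check, which makes the
degenerate case reduce exactly to OLS. ML is the default so deviances
are comparable across fixed-effect structures (as the jp profiling
requires); REML is available via a flag. Wald t statistics use residual
degrees of freedom; replicating any specific nested-model denominator-df
convention is out of scope. Random slopes and crossed random effects
are deliberately not implemented: analyses stated with richer random
structures are approximated by the intercept-only engine.

The engine's log-likelihood is verified in the tests against a direct
dense-covariance evaluation of the marginal Gaussian density and
against an independent general-purpose mixed-model implementation.

## Patch-clamp feature extraction

Action potentials are upward crossings of dV/dt ≥ 10 V/s followed by a
peak above 0 mV within 2 ms, with a 2 ms refractory merge — a standard
convention, since no spike criterion is dictated by the analysis being
reproduced. The per-spike threshold is the voltage at the dV/dt
crossing. From the 1 s / 1 nA ramp: threshold = first spike's crossing
voltage, rheobase = injected current at the first spike (amplitude ·
t/duration), spike count over the ramp. From the current steps: Rm is
the least-squares slope of steady-state deflection vs injected current
over hyperpolarizing steps; τ comes from a single-exponential fit to
the averaged normalized hyperpolarizing onset and Cm = τ/Rm. Gain is
defined as the f–I slope in spikes/pA over steps with ≥ 1 spike — the
natural reading that makes gain magnitudes of ~0.1 dimensionally
sensible. T-type current amplitude is measured after leak subtraction
(linear fit of steady-state current vs command voltage on the five most
hyperpolarized steps) as the largest inward transient within 50 ms of
step onset, with the first 2 ms blanked against onset artifacts; the
resting potential is the mean of a 10 s zero-current segment plus the
−15 mV liquid-junction correction. The correction is applied to
reported resting potentials only; thresholds are reported as measured.
PCA standardizes each parameter to zero mean and unit variance and
drops incomplete cells with a log message.

## In vivo light-response typing and intensity coding

PSTHs use 0.1 s bins over 5 s baseline / 15 s stimulus / 5 s post (250
bins); overlapping pulse windows are truncated at the next pulse's
baseline so no spike is double-counted. A response is *transient ON*
when the mean rate in the 0.5 s peak window after light onset exceeds
baseline mean + 3×SD; *sustained*/*suppressed* when the mean rate from
the end of the peak window to stimulus end is at least 1×SD
above/below baseline. When criteria co-fire the precedence is
sustained > suppressed > transient ON (a transient ON response is
defined by the *absence* of elevated firing through the stimulus), and
the co-firing is logged. The peak-window statistic is the mean by
default (max is available as config). Reported amplitudes are both the
relative change (window − baseline)/baseline and the absolute ΔHz.

Intensity coding fits `R(I) = Rmax·Iⁿ/(EC50ⁿ+Iⁿ)` on log10 intensity
with multi-start initialization (EC50 grid across the tested decades,
n ∈ {0.5, 1, 2}) — necessary because the tested white-light intensities
span eight decades. A unit codes intensity when the fit's R² ≥ 0.5.
Cross-wavelength profiles assign each unit to the subset of
{blue, green, UV} with a non-*none* response at the tested
monochromatic intensity; frequency tables are compared by Pearson χ²
without continuity correction.

## Synthetic-data generators

The generators produce every input the pipeline consumes, with one
ground-truth record per simulated unit or cell, and are bit-reproducible
under a fixed seed; per-unit random streams are keyed by (seed, unit
index) so they do not depend on unit count.

Spiking is an inhomogeneous Poisson process by thinning against a tight
per-interval upper bound of the rate profile. With `noise=0` the
generators switch to deterministic regular trains (spike times at
half-integer crossings of the integrated rate) and fixed per-unit
parameters, so detectors and classifiers can be held to *exact*
agreement with ground truth.

**MEA sessions** place one DLG unit per electrode (50 by default, with
10 always-responsive IGL control units); the truly responsive DLG
fraction is a binomial draw from the Gaussian window (defaults
κ = 0.26, μ = 12.99, σ = 0.65 days — the study conditions being
emulated). The drug response is a sigmoidal rise over 60 s, a plateau,
and an exponential washout with τ = 300 s; these kinetics are a
generator convention (qualitatively matched to published time courses,
which do not state constants). Baseline rates default to 2 Hz
(log-normal across units under noise), response amplitudes to 3 Hz.
Sessions are 10× time-compressed by default; detector configs scale
bin widths in tandem so bin counts match the uncompressed design. One
consequence worth knowing: compressing 30 s bins to 3 s lowers the
expected count per bin (≈6 at 2 Hz), which raises the 3×SD rule's null
false-positive rate (≈15% here vs ≈9% at uncompressed counts). The
detector-vs-oracle equivalence is unaffected — both implementations see
the same conditions — but compressed-session RR values carry a higher
false-positive floor than real 30 s-bin recordings.

**In vivo light sessions** follow the recorded protocol: white light at
8 intensities from 10⁸ to 10¹⁵ photons·cm⁻²·s⁻¹, 6 pulses per
intensity (15 s on / 15 s off, 5 min between intensities), then
single-intensity blue (470 nm), green (525 nm) and UV (365 nm) blocks.
Unit classes are drawn from a mixture (defaults ≈22% transient ON, 23%
sustained, 18% suppressed, 37% unresponsive, mirroring the observed
proportions); transient units get 0.5 s onset and offset bumps of
2·Rmax, sustained units +Rmax throughout the pulse, suppressed units
are silenced with a 1 s rebound. White-light amplitudes scale with the
Hill saturation Iⁿ/(EC50ⁿ+Iⁿ) (defaults Rmax 10 Hz, EC50 10¹¹, n = 1);
baseline is 10 Hz. Monochromatic sensitivity is independent per
wavelength (p = 0.85) for responsive units.

**Patch sweeps** integrate a leaky RC membrane (τ = Rm·Cm) with
threshold spiking and a stereotyped 1.5 ms waveform at 20 kHz, and
generate the full protocol family. Ground truth records the *realized*
rheobase, threshold-crossing, ramp spike count and f–I gain of the
noiseless model cell, since quantities like ramp rheobase depend on the
membrane time constant, not only on the static parameters. The T-type
transient is a double-exponential (rise 3 ms, decay 15 ms) scaled by a
sigmoidal activation normalized so the top step's peak equals the
ground-truth amplitude exactly; capacitive transients are not
synthesized (the voltage clamp is treated as ideally compensated).

**Development tables** draw one intercept per animal (SD `sd_animal`)
and per-cell residual noise around a plateau/quadratic/linear mean.
For recovery studies at realistic noise we use the published
between-animal SD for membrane potential (2.66 mV) and a residual SD of
5 mV — roughly twice the animal-level spread, a typical within-animal
cell-to-cell variability; the residual magnitude is not published.

What the generators deliberately do not emulate: biophysically detailed
conductances, network interactions between units, spike waveforms and
sorting artifacts, electrode drift, or brain-state covariates. Passing
tests therefore demonstrate correctness of the analysis chain under
clean Poisson/RC assumptions, not robustness to those real-data
failure modes.

## Relative expression

ΔCt = Ct(target) − Ct(reference gene) per sample; ΔΔCt subtracts the
reference group's mean ΔCt; RQ = 2^−ΔΔCt. Because ΔΔCt is centred on
the reference-group mean on the Ct (log₂) scale, the *geometric* mean
RQ of the reference group is exactly 1; group-level summaries therefore
report geometric means, the standard convention for fold-changes.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations for
desk-scale runs: 3000 null units for the detector/oracle comparison,
200 replicates for Gaussian-window recovery, 100 noisy replicates (12
PDs × 4 animals × 5 cells) for plateau-junction recovery, 30–60 units
per light session, and one model cell per patch protocol family. All
fits are seeded-deterministic: multi-start orders are fixed and
optimizer tolerances are 1e−10.

## Known limitations

- The mixed-model layer supports exactly one random intercept; richer
  random structures are approximated, so variance components reported
  for those analyses are not comparable to a full nested fit.
- The junction-point SE from profile curvature is a local quadratic
  approximation; for strongly asymmetric profiles a likelihood-ratio
  interval would be preferable.
- Whether the baseline SD should use the full 30 min baseline or a
  sub-window is not settled; it is exposed as configuration
  (`baseline_window`), defaulting to the 10 min before onset.
- Hill fits on fewer than ~5 informative intensities can trade Rmax
  against EC50; the multi-start reduces but does not eliminate this.
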