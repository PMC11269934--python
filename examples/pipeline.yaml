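# Demo pipeline: simulate MEA slices across development, detect drug
# responses, fit the Gaussian responsiveness window.
# noise 0 gives exact detection; with Poisson noise (1.0) the compressed
# sessions carry the false-positive floor documented in docs/methods.md.
scenario: mea
seed: 7
time_scale: 10.0
mea:
  pds: [7, 10, 11, 12, 13, 14, 15, 16, 19, 22, 25]
  n_electrodes: 50
  noise: 0.0
  window: [0.26, 12.99, 0.65]
detection: {}
fits:
  - model: gaussian
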