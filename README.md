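# tuvi — transcranial super-resolution ultrasound vascular imaging

`tuvi` simulates and reconstructs super-resolved microvascular maps from
compounded low-frequency chirp plane-wave ultrasound, the acquisition
scheme used to image vessels through the skull, where attenuation makes
conventional pulse-echo imaging too insensitive to localize contrast
microbubbles. It is aimed at people developing or teaching ultrasound
localization microscopy (ULM) processing chains who need a fully synthetic,
seed-reproducible test bench: every stage from raw multi-channel RF to the
final 10 µm density/velocity maps is implemented and testable without
hardware or external data.

The pipeline:

1. **Vessel-phantom RF simulation** — tube phantoms with flowing point
   scatterers, a 128-element linear array, five steered linear-FM chirp
   transmits (1.3–2.7 MHz over 6 µs) per compounded frame at PRF 1500 Hz,
   with spreading, attenuation, optional skull loss, and receiver noise.
2. **Beamforming** — matched-filter pulse compression (gain ≈ 10 log₁₀ TB
   ≈ 9.2 dB at time-bandwidth 8.4), delay-and-sum on the analytic signal
   with f-number-controlled Hann apodization, coherent compounding of the
   five angles. An eigenspace-based minimum-variance mode is included.
3. **Spatiotemporal filtering** — SVD of the Casorati (pixels × frames)
   matrix; leading singular components (static tissue/skull clutter) are
   removed, with automatic elbow selection.
4. **Localization** — robust-thresholded regional maxima refined to
   sub-pixel precision by windowed centroid or Gaussian fit.
5. **Tracking** — Markov chain Monte Carlo data association (MCMCDA): a
   Metropolis–Hastings chain over partitions of detections into tracks and
   clutter, scored by constant-velocity Kalman likelihoods with
   birth/missed-detection/clutter priors; a nearest-neighbor baseline is
   provided.
6. **Reconstruction & metrics** — tracks accumulate into density and
   velocity maps on a 10 × 10 µm grid; evaluation computes normalized MSE
   against the designed vessel map, vessel FWHM diameters, image SNR,
   localization resolution gain, and depth coverage.

## Worked example

Compare the compounded-chirp image of a single bubble at 40 mm depth
against a conventional single-angle, single-cycle pulse at the same
transmit amplitude and noise:

```python
from tuvi.pipeline import snr_gain_experiment

r = snr_gain_experiment(seed=1, n_seeds=8)
print({k: round(v, 2) for k, v in r.items()})
```

```
{'gain_db': 18.98, 'snr_ccw_db': 29.14, 'snr_short_db': 10.16, 'n_seeds': 8}
```

The matched-filtered, 5-angle compounded chirp image carries ≈ 19 dB more
SNR than the short-pulse image — the ~9 dB compression gain plus ~7 dB of
angle compounding and the chirp's longer integration — which is what makes
bubbles at depth detectable through the skull's attenuation.

A full phantom run from a YAML config:

```bash
tuvi run --config examples/desk.yaml     # simulate -> ... -> evaluate
tuvi presets                             # list phantom / pipeline presets
```

or stage by stage (`tuvi simulate / beamform / stf / localize / track /
reconstruct / evaluate`), each reading and writing open formats
(HDF5/NPZ, CSV, JSON). From Python, `tuvi.pipeline.run_pipeline(config)`
returns a metrics report (reconstruction MSE, lumen mean speed, FWHM
diameters, maximum tracked depth, per-stage runtimes) and persists every
intermediate artifact.

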