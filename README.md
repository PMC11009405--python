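# spiralbeta

Analysis pipeline for subthalamic beta bursts during spiral drawing, built
around a synthetic cohort generator with known injected ground truth.

The package covers the full chain:

* **`spiralbeta.synthetic`** — cohort generator: bursty beta-band LFP on a
  1/f background (line noise, optional 130 Hz stimulation artifact),
  Archimedean-spiral pen traces with radius-dependent velocity growth, and a
  burst-locked deceleration injected only in the free-drawing condition.
  Everything the generator injects is returned as ground truth for recovery
  oracles. Light-weight generators for calibration studies (warped map pairs,
  velocity tables, velocity-noise profiles) live here too.
* **`spiralbeta.kinematics`** — 10 Hz low-pass of pen positions, tangential
  velocity with Gaussian smoothing, radius–angle transform, spiral OLS fit
  (RMSE/slope, first revolution excluded), and polyline self-intersection
  (inaccurate-trial flagging).
* **`spiralbeta.lfp`** — LFP conditioning: 4 Hz high-pass, polyphase
  resampling to 200 Hz, demean/detrend, DFT notches (50/100 Hz, plus the
  stimulation frequency), and threshold-based artifact segment repair with
  linear interpolation.
* **`spiralbeta.spectral`** — 7-cycle Morlet time–frequency maps (4–100 Hz,
  20 ms centers), time-warping of rest/draw onto fixed 50 + 100 samples,
  baseline-relative power change, DPSS multitaper band power, and a paired
  sign-flip cluster permutation test (exact enumeration for small n).
* **`spiralbeta.bursts`** — individual beta-peak selection, envelope
  extraction (peak ± 2 Hz band-pass, rectify, 200 ms smoothing), pooled
  75th-percentile rest thresholds, burst detection (≥ 100 ms), and
  per-interval burst metrics.
* **`spiralbeta.periburst`** — burst-triggered kinematics: mean acceleration
  in ±0.25 s windows around burst onsets, 50 ms linear-grid and shuffled-onset
  control constructions, and spiral-residual deviation around onsets.
* **`spiralbeta.stats`** — mixed-effects models (REML, subject random
  intercepts, optional random slopes) with Bonferroni post hocs, Spearman
  correlations, pooled-SD effect sizes, and trial/subject exclusion filters.
* **`spiralbeta.io` / `spiralbeta.pipeline` / `spiralbeta.cli`** — dataset
  layout (TSV kinematics, float32 + JSON-sidecar LFP, JSON manifest), a staged
  pipeline driver with content-hash caching, and the command-line interface.

## Command-line usage

```bash
# run everything on a synthetic cohort
spiralbeta all --config config.yaml --seed 1 --root run1

# or stage by stage (later stages reuse cached upstream outputs)
spiralbeta simulate --seed 1 --root run1
spiralbeta preprocess --root run1
spiralbeta stats --root run1 --drop-inaccurate
spiralbeta report --root run1
```

The YAML config has one section per stage; unspecified keys keep their
defaults (see `spiralbeta.pipeline.DEFAULT_CONFIG`). Example:

```yaml
seed: 1
simulate:
  n_subjects: 19
  trials_per_condition: 12
bursts:
  percentile: 75.0
stats:
  n_perm: 5000
```

A stage whose config (or any upstream config) changed is recomputed; all
others are served from cache. All randomness descends from the single seed;
two runs with the same config are byte-identical.

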