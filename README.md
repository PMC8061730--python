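# ocumotor

Oculomotor event analysis for bistable plaid perception.

When observers view an ambiguous moving plaid — two superimposed drifting
gratings — perception alternates spontaneously between a single coherently
moving pattern (*coherent* percept) and two gratings sliding across each
other (*component* percept, at ±67.5° to the coherent direction). Blinks
and microsaccades are modulated around these purely internal perceptual
switches, and disentangling whether the eye movements cause the switches
or follow them requires a time-resolved event-rate analysis with careful
baselines and nonparametric statistics.

`ocumotor` implements that analysis end to end for researchers in visual
psychophysics and oculomotor control:

- **Blink detection** from binocular pupil-diameter traces: per-eye
  z-transform, binocular sub-threshold/missing candidate runs at `-k·SD`
  (default k = 2.5), boundary extension to half threshold, concatenation of
  blinks < 100 ms apart, and a 50–1000 ms duration filter.
- **Microsaccade detection** in two-dimensional velocity space: 5-point
  moving-window velocities, median-based thresholds
  η = λ·σ with σ² = median(v²) − median(v)² (default λ = 6), an elliptic
  threshold test, a 4-sample minimum duration, binocular coincidence,
  a 1° amplitude ceiling, and a 20-ms exclusion zone around blinks, with
  the amplitude/peak-velocity main sequence as a diagnostic.
- **Peri-event time courses**: event-onset counts in 100-ms bins within
  ±2 s of each button lift (the first indicator of a switch), events shared
  between overlapping windows weighted 1/m, averaged over anchors,
  normalized by the trial's event total, and z-transformed per trial before
  averaging — compared against matched *no-switch* baselines (all
  non-overlapping 4-s periods free of perceptual change starting 2 s after
  a switch, alternately assigned to the two switch-type comparisons).
  An event-locked mode uses 50-ms bins around blink/blank/microshift
  onsets and offsets.
- **Cluster-based permutation statistics** for paired comparisons:
  adjacent bins with paired t beyond the 97.5% t-quantile are clustered,
  cluster mass = Σt is referred to the Monte-Carlo null of the maximum
  |mass| under per-participant sign flips (1,000 partitions, or full
  enumeration for small n), controlling family-wise error at α = 0.05.
- **Summaries and QC**: per-percept rates honouring percept durations,
  paired t with Cohen's d = mean(D)/sd(D), 10°-bin direction histograms and
  opposition shares in stimulus-aligned coordinates, and the participant
  screens (blink rate < 5/min or > 35/min, > 39% missing data).
- **A synthetic session generator** with ground truth: gamma-distributed
  percept durations (coherent 14.77 ± 6.65 s, component 7.57 ± 4.41 s),
  uniform 0.5–0.7 s report latencies, blinks at 12.09/min and
  microsaccades at 1.39/s as inhomogeneous Poisson processes with
  switch-locked multiplicative hazard kernels sampled by thinning,
  blank (116–167 ms every 3–6 s) and microshift (±0.2°, capped at ±0.8°)
  schedules, and fully rendered binocular gaze/pupil traces.

All I/O is plain tab-delimited text with documented columns.

## Worked example

```python
import numpy as np
import ocumotor as om

cfg = om.SimConfig(seed=42)                    # one 3-min synthetic trial
gt  = om.simulate_trial(cfg, participant=0, trial_index=0)
rec = om.render_recording(gt, cfg)             # binocular gaze + pupil at 500 Hz

blinks = om.detect_blinks(rec, om.BlinkConfig(k_sd=2.5))
ms     = om.detect_microsaccades(rec, om.MsConfig(lambda_sd=6.0), blinks)
print(f"true blinks: {len(gt.blinks)}, detected: {len(blinks)}")
print(f"true microsaccades: {len(gt.microsaccades)}, detected: {len(ms)}")
slope, intercept, r = om.main_sequence(ms)
print(f"main sequence: slope={slope:.2f}, r={r:.3f}")
```

prints

```
true blinks: 43, detected: 43
true microsaccades: 209, detected: 213
main sequence: slope=0.77, r=0.952
```

— every rendered blink is recovered, and the detected microsaccades obey
the lawful log–log amplitude/peak-velocity relation (r > 0.9) expected of
genuine saccades. Continuing with a 19-participant cohort and the
switch-locked analysis:

```python
from ocumotor.peri import TrialEvents, condition_timecourses, PeriEventConfig
from ocumotor.cluster import ClusterConfig, cluster_permutation_test

cohort = {p: [TrialEvents.from_ground_truth(g) for g in om.simulate_session(cfg, p)]
          for p in range(19)}
a, b, kept = condition_timecourses(cohort, "blink", "switch_to_coherent")
res = cluster_permutation_test(a, b, ClusterConfig(seed=42))
centers = PeriEventConfig().bin_centers_s
for c in res.significant:
    print(f"significant cluster: {centers[c.first_bin]-0.05:+.2f} to "
          f"{centers[c.last_bin]+0.05:+.2f} s, sign={c.sign:+d}, p={c.p_value:.4f}")
```

```
significant cluster: -0.80 to -0.60 s, sign=-1, p=0.0090
significant cluster: -0.50 to -0.30 s, sign=-1, p=0.0150
significant cluster: +0.10 to +0.40 s, sign=+1, p=0.0010
significant cluster: +0.70 to +0.90 s, sign=-1, p=0.0420
```

The generator's default hazard kernels suppress blinks before a reported
switch (×0.4 over −0.8 to −0.2 s) and boost them after a switch to
coherent (×2.0 over 0.1 to 0.6 s); the pipeline recovers exactly that
structure — negative pre-switch clusters and a positive post-switch
cluster at the injected latencies.

The same workflow is available from the shell:

```bash
ocumotor simulate --seed 42 --participants 1 out/
ocumotor detect-blinks out/p00_t00_test.recording.tsv -o blinks.tsv
ocumotor detect-microsaccades out/p00_t00_test.recording.tsv --blinks blinks.tsv -o ms.tsv
ocumotor full-pipeline --seed 42 --participants 5 report/
```

## Layout

- `src/ocumotor/core.py` — shared types, conventions, TSV I/O
- `src/ocumotor/synth.py` — synthetic session generator with ground truth
- `src/ocumotor/blinks.py` — pupil-based blink detection
- `src/ocumotor/microsaccades.py` — velocity-space microsaccade detection
- `src/ocumotor/peri.py` — peri-event time courses and no-switch baselines
- `src/ocumotor/cluster.py` — cluster-based permutation test
- `src/ocumotor/summary.py` — rates, effect sizes, directions, QC
- `src/ocumotor/calibration.py` — cohort-level simulation studies
- `src/ocumotor/cli.py` — `ocumotor` command-line interface
- `docs/methods.md` — models, parameters, and design notes
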