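# Methods

This note documents the models and procedures `ocumotor` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Task and conventions

The package analyses continuous-report sessions with an ambiguous moving
plaid. Observers hold one of two buttons for the currently dominant
percept — *coherent* (one pattern, one direction) or *component* (two
gratings sliding at ±67.5° to the coherent direction). The button **lift**
is the first behavioural sign of a switch and anchors all switch-locked
analyses; the percept being switched *to* is only known at the next press.

Conventions: time in seconds from trial start; intervals half-open
`[onset, offset)`; sample indices 0-based; gaze in visual degrees with
screen-right = 0°, counter-clockwise positive; a stimulus rotated by `r`
has its coherent motion at `(270 − r) mod 360` degrees (rotation 0 moves
straight down, rotation 90 leftward, rotation 180 up).

## Blink detection

Video-based trackers lose the pupil while the lid is closed and see a
rapidly shrinking pupil while it closes. Each eye's pupil trace is
z-transformed over its non-missing samples (population SD — the choice is
irrelevant at trace length but fixed for reproducibility). A sample is in
blink-state when its z-value is below `−k_sd` or missing; candidate
blinks are maximal runs where **both** eyes are in blink-state. Candidates
grow outward until both eyes are back above half the threshold
(`−k_sd/2`; missing counts as not-above), then blinks less than 100 ms
apart are concatenated — merging strictly precedes the duration filter,
so two 40-ms fragments 80 ms apart survive as one blink — and durations
outside 50–1000 ms are discarded.

`k_sd` defaults to 2.5, inside the 1.9–4 range practitioners set by
visual inspection; it is exposed in `BlinkConfig` together with the merge
gap and duration bounds. The threshold scope is per trial and per eye.

## Microsaccade detection

Gaze is transformed to velocity with the 5-point moving-window derivative
`v_n = (p_{n+2} + p_{n+1} − p_{n−1} − p_{n−2}) / (6Δt)` per component
(exact for linear signals; first/last two samples and any sample whose
window touches missing gaze are undefined). Per component, a
median-based spread estimate `σ² = median(v²) − median(v)²` — insensitive
to the rare fast events being detected — yields the threshold
`η = λ·σ`, floored at a small epsilon (with a warning) on degenerate
traces. Samples with `(v_x/η_x)² + (v_y/η_y)² > 1` form monocular
candidate runs of at least `min_samples` (4 samples; kept in samples, not
milliseconds, and configurable). Only binocularly coincident candidates
(≥1 sample overlap; greedy by onset; union span) are retained.

Event properties: amplitude is the start-to-end Euclidean displacement
(not maximum excursion), direction `atan2(Δy, Δx)` mapped to [0, 360),
peak velocity the maximum speed inside the event. Filters: amplitude
≤ 1° (compared with a 1e-9 epsilon, since a rendered 1.0° saccade
measures 1.0 plus float round-off through `hypot`), peak velocity below a
configurable 300°/s ceiling (a stand-in for a stricter velocity
criterion whose exact published form is unavailable), and no blink within
20 ms of the event. `λ` defaults to 6, the cited method's common choice;
it is not fixed by the source analysis and is exposed in `MsConfig`.
The log–log main-sequence fit (slope, intercept, r) is provided as the
standard detector diagnostic; r > 0.9 on default synthetic sessions.

## Peri-event time courses

Event **onsets** are counted in 100-ms bins tiling a ±2-s window around
each anchor (half-open bins; an event exactly at the anchor falls in the
bin starting at 0). The window half-width is an inferred default: the
no-switch baseline periods are 4 s, and the anchor-centered window is
chosen to equal one period. An event inside the windows of m anchors
contributes 1/m to each, so its total contribution is exactly 1. Per
trial: the count matrix is averaged over anchors, divided by the trial's
total event count, and z-transformed across bins (mean 0, SD 1); the
z-transform precedes averaging over trials. Zero-variance series are
flagged and excluded from participant averages; trials with zero usable
anchors or zero events are likewise excluded.

No-switch baselines: within each percept interval, 4-s periods are tiled
forward from 2 s after the switch into the percept, non-overlapping and
fully free of perceptual change, anchored at their centers. All possible
periods are tiled (the literal reading of the procedure), and they are
assigned alternately in time order across the trial — first, third, … to
the coherent-switch comparison; second, fourth, … to the component-switch
comparison. Participant averages weight trials equally (not by anchor
count).

Anchors whose window would extend beyond the trial span are excluded in
**both** conditions. Switch anchors can occur near trial edges while
no-switch periods are interior by construction; without the exclusion the
switch condition acquires structural zeros in its outer bins that the
baseline can never match, biasing the comparison even under a
homogeneous event process.

Blink and microsaccade analyses use test-condition trials only (trials
with blanks or microshifts excluded), pooled across stimulus rotations.
The event-locked mode applies the same machinery with 50-ms bins around
blink/blank onsets or offsets and around microshifts (whose onset and
offset coincide).

## Cluster-based permutation test

Per bin, the paired t statistic `t = mean(D)/(sd(D)/√n)` (sample SD;
zero-variance bins with nonzero mean map to ±∞, which is always
supra-threshold). Bins with t beyond the 97.5% quantile of the
t-distribution with n−1 df are clustered by adjacency and common sign;
cluster mass is the sum of member t-values. The null distribution flips
each participant's difference series independently (the paired-design
partition) — full enumeration of all 2ⁿ sign patterns when
2ⁿ ≤ n_permutations, otherwise 1,000 seeded Monte-Carlo partitions — and
records the maximum |cluster mass| over both signs per partition (0 when
nothing is supra-threshold), giving two-sided family-wise control.
Cluster p-values use the +1-corrected estimate
`(1 + #{null ≥ |mass|})/(n_partitions + 1)`, so p is never 0; a cluster
is significant at p ≤ 0.05. Permutation is at the participant level, the
standard choice for this paired design. Under sign flips only the mean
depends on the signs (squares are invariant), so the whole null t-matrix
is a single matrix product.

Measured behaviour (computed by the validation suite and the reproduction
script, not asserted from theory): the family-wise rejection rate over
200 simulated null cohorts of n = 19 sits within the binomial 95% band
around the nominal 0.05 (slight conservatism is inherent to the
discreteness of the max-statistic); an injected 1-SD, 6-bin dip at n = 19
is detected in well over 80% of cohorts.

## Summaries, directions, QC

Per-percept rates divide event counts inside a percept's intervals by
that percept's total duration; an unreported percept yields a missing
rate, not zero. Cohen's d for paired samples is `mean(D)/sd(D)` (sample
SD), with `t = d·√n`; p-values are reported uncorrected, as is usual for
these summary tests alongside the cluster-corrected time courses.

Directions are pooled across rotations by rotating each trial's
directions so the coherent motion is at 0°; "opposite to coherent" is the
180° ± 10° sector and "opposite to the components" the union of
112.5° ± 10° and 247.5° ± 10°. Sectors are closed on the lower edge and
open on the upper, making ±10° boundary cases deterministic. Shares are
computed per trial and averaged per participant. Histograms use 10° bins
and sum to 100% for non-empty input.

QC excludes a participant when the blink rate on test trials is below
5/min or above 35/min, or when more than 39% of samples are missing.

## Synthetic generator

The generator emulates the 500-Hz experiment's study conditions. Defaults:
19 participants; eight 180-s test trials plus four blank and four
microshift trials (the layout after concatenating the two recording
blocks); gamma percept durations with mean/SD 14.77/6.65 s (coherent) and
7.57/4.41 s (component); report latency uniform 0.5–0.7 s; blinks at
12.09/min with uniform 100–300 ms durations; microsaccades at 1.39/s;
blanks of 116–167 ms after gaps drawn from {3.0, 3.5, …, 6.0} s;
microshifts of ±0.2° after the same gaps, with the running offset capped
at ±0.8° by forcing the next shift back toward center (the cap is stated;
the resolution rule is this package's choice).

Event streams are inhomogeneous Poisson processes sampled by thinning
against `λ(t) = base_rate · Π g_k(t − t_k)` with piecewise-constant
multiplicative kernels; the exact maximum of the piecewise-constant rate
is used as the thinning bound, so the sample is exact. Default
switch-locked kernels: blink rate ×0.4 over [−0.8, −0.2] s before any
reported switch, ×2.0 over [0.1, 0.6] s after a switch to coherent, and a
×0.4 dip over [−0.3, 0] s before a switch to component; microsaccade rate
×0.5 over [−0.3, 0] s before a component switch, with additional
event-locked kernels (suppression around blinks/blanks/microshifts, an
anticipatory component only for blinks, a rebound only after blanks).
Setting `switch_kernels={}` (or using `null_config`) gives homogeneous
processes for calibration studies.

Microsaccade directions are drawn, per event, from a per-percept mixture
of a narrow lobe (wrapped normal, SD 7°) opposite the coherent motion, two
narrow lobes opposite the component motions, and a uniform floor, with
weights chosen to land sector shares near those of real observers
(roughly 22% vs 16% opposite-coherent during coherent vs component
percept). Amplitudes are gamma (mean 0.32°, SD 0.16°) truncated to
[0.05°, 1.2°] — the tail above 1° exercises the amplitude filter.
Durations follow 12 ms + 24 ms/° of amplitude, placing peak velocity
2A/d on a realistic main sequence.

Rendering: gaze (conjugate in both eyes) is a random walk (step SD
0.001°/sample) plus slow 0.1°/s pursuit toward the perceived motion
direction, with each microsaccade a raised-cosine velocity profile
(`v(t) = (A/d)(1 − cos 2πt/d)`, integrating exactly to A). Pupil is a
1000 a.u. baseline with 10 a.u. Gaussian noise per eye; each blink is a
20-ms linear ramp down by 150 a.u., a missing core, and a ramp up — the
ramps give the detector's half-threshold extension something real to
extend into. Gaze is missing wherever the pupil is.

Generator-internal regularities that keep ground truth scoreable:
consecutive blinks are at least 200 ms apart (so detector merging cannot
collapse two true blinks); percept durations are resampled above a small
floor derived from the latency and press-gap ranges (so reports stay
strictly ordered and every reported lift trails its internal switch by a
latency inside the configured range); microsaccades within 50 ms of a
blink are removed at generation (the eye is closed); the lift-to-press
gap is uniform 0.1–0.3 s. One random stream is derived per
(seed, participant, trial, stage), so any trial regenerates
independently and identical seeds give byte-identical outputs.

**What the generator does not emulate:** saccadic suppression, OKN slow
phases as a physiological process, pupil light reflex, tracker-specific
noise spectra, head motion, or calibration drift. Passing tests therefore
demonstrate that the pipeline's logic and statistics behave correctly
under the assumed event statistics — not that the detectors' default
thresholds are optimal for any particular hardware.

## Problem sizes and limitations

The cohort studies use 200 null cohorts (false-positive calibration) and
100 modulated cohorts (dip recovery) of 19 participants with eight 180-s
test trials each — sizes chosen so the binomial error of the measured
rates is small relative to the quantities being checked. Truncated
percepts at trial boundaries are dropped with a warning (their duration
is unknown); the final lift of a trial, lacking a subsequent press, is
excluded from switch-type-classed analyses. Native tracker formats
(EyeLink EDF/ASC, SMI IDF) are out of scope; recordings enter as TSV.
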