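# Methods

## Problem setting

The package reimplements, at desk scale, the software of an ambulatory
asthma-symptom monitor: a wearable device that listens continuously,
counts coughs automatically, tracks activity with an accelerometer,
records medication use, and presents an hourly symptom report. The
detection approach is classical keyword spotting: the target sound
(cough) and everything else (fillers) are modelled by hidden Markov
models, and a Viterbi decoder over a loop grammar labels each stretch
of audio with the best-scoring model sequence. Wheeze detection is
deliberately out of scope: wheezes are too variable across individuals
for this modelling approach, and the package does not attempt it.

## Acoustic front end

Audio is processed at 16 kHz mono. Frames are 25 ms with a 10 ms hop
(trailing partial frames dropped); processing blocks ("segments") are
6 s, tiling the recording with the final partial segment kept. Each
frame yields a 39-dimensional vector: 13 mel-frequency cepstral
coefficients (26 triangular mel filters, orthonormal DCT-II, c0
replaced by log frame energy), plus delta and delta-delta dynamics
(regression window ±2 frames, edges replicated). Pre-emphasis is 0.97,
applied per frame with the first sample attenuated by (1 − 0.97) so
the operation is self-contained. All logs are floored at 1e-10, so
digital silence produces finite features sitting at the floor.

Cepstral mean normalization (CMN) is computed per 6-second segment and
applied to the cepstral coefficients only. Log-energy is deliberately
left un-normalized: the level of an impulsive cough relative to the
background bed is itself discriminative, and normalizing energy per
segment would remove it. Training sequences are sliced out of 6-second
segments *after* segment-level CMN (see Corpus below), so training and
deployment features go through an identical normalization path.

These front-end choices are the standard speech-recognition defaults;
nothing in the detector depends on their exact values, and all are
exposed in `FeatureConfig` / the YAML config.

## Models and training

Each class (cough; background; door slam) is a left-to-right HMM with
self-loops, non-emitting entry/exit states, and diagonal-covariance
Gaussian-mixture emissions. Defaults: 5 emitting states for cough
(an impulsive event with attack/body/decay structure), 3 per filler,
2 mixture components per state. Training is Baum–Welch over the
labelled corpus:

- initialization: uniform segmentation of every training sequence
  across states, pooled per state, k-means splitting into mixture
  components (seeded, one restart);
- all probability arithmetic in the log domain; the left-to-right
  topology makes the forward/backward recursions tridiagonal, which is
  how they are implemented;
- variances floored at 1e-3 after every M-step — no fitted variance
  can fall below the floor;
- termination when the total log-likelihood improves by less than the
  tolerance (default 1e-3 absolute) or after 25 iterations. The
  likelihood history is recorded on the model; EM guarantees it is
  non-decreasing, and the test suite asserts it to 1e-6 slack.

Training is deterministic for a fixed seed: the seed only enters the
k-means initialization.

## Decoding

The recognition network joins all models in a closed loop: any model
may follow any model, with a configurable log-domain `loop_penalty`
charged per inter-model transition (default 0). Decoding is token
passing — per frame, tokens propagate through each model's states
(self/advance), and the best exiting token re-enters the loop — which
with no beam is an exact Viterbi search over the composed network. The
test suite verifies exact equivalence (scores to 1e-9, identical
segmentations) against brute-force enumeration of every (model
sequence, state path) pair on small instances.

Numerical conventions: exact score ties are broken toward staying in
the current model (self > advance > re-entry) and toward the lowest
state index, so decoding is deterministic and ties do not fragment a
span into spurious insertions. An input shorter than every model's
state chain has no admissible path and raises a configuration error;
segment-level callers treat that as "no events".

Events are maximal cough-labelled spans, timestamped by span start:
spans shorter than 60 ms are dropped (shorter than any cough phase),
spans separated by less than 200 ms are merged (intra-bout pauses).
Both thresholds are configurable. Because segments are decoded in
isolation — mirroring the device's 6-second block pipeline — an event
crossing a segment boundary cannot be detected as one event; the scene
generator therefore places coughs inside single segments by default,
with a flag (`allow_boundary_straddle`) to probe exactly this
limitation.

## Audit retention

Every segment containing a detected event is retained ("positive");
event-free segments are retained with probability 0.05 ("random"),
drawn from a seeded generator. This mirrors the audit protocol that
lets sensitivity *and* specificity be estimated from archived audio
alone. The empirical retention rate over many empty segments is
asserted to lie within three standard errors of its parameter.

## Synthetic data

The generators are pure functions of (parameters, seed).

**Coughs** are band-filtered Gaussian noise bursts (default band
300–3000 Hz, duration 0.08–0.30 s) with a sharp attack (4–12 ms),
exponential decay (12–25 s⁻¹), and an optional short voiced tail
(180–260 Hz, 30% of events) — a literature-typical parametric cough
shape. **Babble** is three formant-band noise channels with syllabic
(2.5–5 Hz) amplitude modulation; **hum** is a 60 Hz fundamental with
two weak harmonics; **door slams** are a low-frequency damped thump
plus a fast broadband edge, included specifically because impulsive
non-cough sounds are the natural confuser for an impulsive-event
detector. In a scene, each cough's power over its labelled interval is
normalized to a common reference and the background bed is scaled so
the event-to-background power ratio equals the requested SNR; the
benchmark operates at 10 dB. Scene labels are the exact placement
intervals.

**Activity traces** are per-minute scores: a sedentary baseline (zero
most minutes, occasional gamma-distributed bouts, marginal mean ≈ 0.8
and SD ≈ 2.9 on the 0–24 scale) plus `coupling` points per cough in
the minute, capped at 24. **Survey tables** follow a parallel-items
model — latent respondent score plus item noise, discretized to 1..5
at normal quantile cutpoints. The latent inter-item correlation is
inflated by the analytic attenuation factor of the discretization
(computed from the categorized-normal covariance identity) so the
*observed* items hit the requested ρ; Cronbach's α then matches the
closed form kρ/(1+(k−1)ρ) and the suite asserts recovery within ±0.03
at n = 5000.

What the generators do **not** emulate: real cough variability across
speakers and illnesses, reverberation and microphone channel effects,
overlapping speech, non-stationary noise, or device artifacts. Passing
the synthetic benchmark therefore demonstrates the pipeline is
implemented correctly and behaves sensibly under controlled
conditions; it says nothing about field performance on real
recordings, which for this class of detector is known to be much
harder than 10 dB synthetic scenes.

## Activity scoring

The monitor's 0–24 activity score is not publicly specified, so the
package defines it as a capped, calibrated mean absolute deviation:
score = min(24, 12π · MAD(|a|)) over each complete minute, where |a|
is the acceleration magnitude in g. The 12π calibration maps a
sustained 1 g sinusoidal oscillation (MAD = 2/π) to the top of the
scale; a perfectly still trace scores 0; incomplete trailing minutes
are dropped. The statistic is monotone in movement intensity and
bounded, matching the scale's observed range. Cough–activity
correlation is ordinary Pearson r with the two-sided t-transform p,
paired per minute by default (the activity granularity), hourly via a
flag.

## Validation metrics

Detected and truth events are matched one-to-one when midpoints lie
within ±0.5 s (configurable). Detections are processed in time order
and claim the earliest unmatched compatible truth event; because all
compatibility windows share one width, this greedy rule attains the
maximum-cardinality matching (convex bipartite argument), which the
tests verify against an assignment-problem oracle. Sensitivity is
tp/(tp+fn); false alarms are fp per monitored hour; rater agreement is
plain percent agreement. Event-level granularity is used throughout.

Survey statistics: totals (range 7–35) with the predetermined ≥ 28
satisfaction cutoff; per-item "agree" proportions pooling responses of
4 and 5, with pairwise deletion of missing values (denominators are
reported per item); Cronbach's α on listwise-complete rows with
unbiased variances; item–companion Pearson correlations on complete
pairs. Percentages are kept at full precision with display rounding
left to the caller.

## Benchmark design

The default network is trained on 200 cough clips and 200
background-allotment clips (3/5 babble+hum beds, 1/5 door slams, 1/10
quiet/silence), all sliced from CMN-normalized 6-second segments at
the benchmark SNR so training is matched to deployment. The benchmark
sizes — ten 600 s scenes with 30 coughs each for sensitivity, ten
720 s cough-free distractor scenes for false alarms — keep a full run
(training, synthesis, decoding) at a few minutes on one CPU while
giving 300 truth events and 2 h of negative audio, enough for stable
rates. All seeds derive from one base seed.

## Known limitations

- Segment-boundary events are undetectable by construction (6-second
  block processing); quantified nowhere, but the generator can place
  straddling events to measure it.
- The decoder's per-span log scores are cumulative-score increments,
  informational rather than calibrated posteriors.
- The filler repertoire is three procedural classes; a richer
  distractor library would make the false-alarm benchmark harder.
- Fixed-dimension (7-item) survey handling: the instrument size is a
  package constant, not a parameter.
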