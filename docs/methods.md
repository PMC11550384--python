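# Methods

This note documents the models, conventions and parameter choices behind
`soc_calcium`, in the order data flows through the pipeline.

## Paradigm and synthetic data

The generator (`soc_calcium.synthetic`) emulates a four-phase second-order
conditioning (SOC) experiment, one session per phase:

| phase       | schedule                                                        |
|-------------|-----------------------------------------------------------------|
| habituation | 10 light (CS1) + 10 tone (CS2) cues, 10 s each, random order    |
| CS1–US      | 10 CS1 cues co-terminating with a 0.5-s foot shock (US onset = cue onset + 9.5 s) |
| CS2–CS1     | 4 pairings: 10-s CS2, 0.5-s gap, 10-s CS1                       |
| test        | 3 CS2 presentations                                             |

Inter-trial interval is 2 min (randomized 1–2 min during habituation), with
a 5-min pre-session baseline used both as the z/correlation baseline state
and as lead-in. Sampling is 10 Hz, the effective rate of miniscope data
after 2× temporal downsampling. Cue intensity metadata (lux, dB, mA) is
not modeled — only timing matters to the analysis.

**Fluorescence model.** Each neuron's raw trace is
`F = F_base · (1 + drift + signal + noise)` with `F_base = 100` a.u., so
`signal` is calibrated directly in ΔF/F units:

- *Evoked transients*: impulses at the onsets of the neuron's driving
  events, convolved with a double-exponential kernel
  `h(t) ∝ exp(−t/τ_decay) − exp(−t/τ_rise)`, τ_rise = 0.2 s,
  τ_decay = 1.2 s (typical published GCaMP6m kinetics; configurable, not a
  fitted claim), peak amplitude 0.5 ΔF/F scaled by a per-neuron lognormal
  gain (σ = 0.2) and shifted by a per-neuron latency (0–0.2 s).
- *Response classes* planted per phase: US-, CS1- or CS2-driven transient
  responders; a *sustained* class driven by a boxcar extending 10 s past
  cue offset (the sustained post-cue activity seen after a learned tone);
  an *inhibited* class (negative half-amplitude boxcar); and unresponsive.
  Default per-phase fractions: mostly unresponsive during habituation
  (15 % weak tone responders, 5 % inhibited), 80 % US-driven during
  CS1–US, 45 % CS1 + 25 % CS2 during pairing, and 30 % CS2 + 10 %
  sustained + 6 % inhibited at test — the qualitative progression a SOC
  cohort shows.
- *Identity fingerprint*: every neuron also carries a stable, weak
  (0.15 ΔF/F) cue-locked temporal motif — a fixed per-neuron mixture of
  sine harmonics with whole periods per 10-s analysis window. It stands in
  for the stable idiosyncratic response dynamics that let real neurons be
  recognized across days. Because each harmonic integrates to zero over
  the −10…0, 0…+10 and +10…+20 s windows (exactly, under the trapezoid
  rule), the motif is invisible to AUC classification while making
  same-neuron reference traces correlate across sessions.
- *Drift*: slow sinusoid (period 600 s, the time scale of bleaching-like
  baseline wander) plus a linear trend, total amplitude 10 % of baseline,
  random phase per neuron.
- *Noise*: i.i.d. Gaussian, SD 0.1 ΔF/F, giving transient SNR 5 at the
  default amplitude.

Session dropout (20 % of neurons per session, the day-to-day variability
of neuron yield) and per-session centroid jitter (SD 0.5 on a 100×100
field of view) perturb longitudinal structure. A `replicate` index
re-records a phase with identical planted identity but fresh noise,
dropout and jitter — the ground-truth correspondence for registration
tests. Behavior is an alternating freeze/move renewal process with
exponential bouts (mean freeze bout 4 s); each constant-probability
segment is simulated from its stationary state (exponential bouts are
memoryless, so planted freeze fractions are recovered without boundary
bias). Frozen frames have exactly zero motion.

**What the generator does not emulate:** shared network co-fluctuations,
photobleaching decay, motion artifacts, neuropil contamination, spike
trains (activity is modeled directly at the transient level), or
cross-modal response correlations. Tests passing on this generator
validate the analysis logic and its calibration against known ground
truth — not performance on artifact-laden real recordings.

## Normalization

ΔF/F uses the whole-session mean per neuron; rows with non-positive mean
are rejected by name. Z-scoring is per neuron *per trial* against that
trial's −10…0 s baseline (a per-session pooled-baseline variant is
available behind a flag); the SD is the population SD (divisor N) — the
convention is fixed and tests use the same estimator. Onset maps to the
first sample with t ≥ onset; the baseline is the half-open window
[−pre, 0). Trials whose window does not fit in the session are excluded
and counted, never padded; neuron-trials with zero baseline SD are flagged
degenerate, set to NaN and excluded from averages rather than producing
infinities.

## AUC and classification

AUC is the trapezoidal integral of the trial-averaged ΔF/F trace over the
closed windows [−10, 0], [0, +10] and [+10, +20] s (boundary samples act
only as shared integration endpoints, so a constant trace c over a 10-s
window integrates to exactly 10 c). The late window quantifies sustained
post-cue activity; per-trial AUCs are exposed for trial-course analyses.

Classification: increased iff post/pre ratio > 1.5, decreased iff < 0.5,
strict at both boundaries. ΔF/F integrals can be non-positive, where the
ratio is meaningless, so when `auc_pre ≤ ε` (ε = 0.01 × window length =
0.1) the decision uses the difference `auc_post − auc_pre` thresholded at
half the robust SD (1.4826·MAD) of pre-AUCs across the population, with
an absolute floor of 1e-9 so float residue cannot flip a category on
noiseless data. A record classified without population context and a
non-positive pre-AUC is labelled `degenerate` (a fourth category, never an
error). Percentages are reported with one decimal, rounded half up, the
convention of printed population splits.

*Known limitation*: the fallback threshold scales with the population
spread of pre-AUCs. When many trials are averaged (e.g. a 10-trial
habituation session) that spread becomes noise-dominated and the threshold
under-rejects: false increased/decreased calls inflate at low signal. At
the 3-trial test-day conditions the classifier recovers planted fractions
within a few percentage points and agrees 100 % with the plant at zero
noise; before-learning sessions should be read knowing the baseline
false-positive rate is higher (as it also is in manually thresholded real
data).

## Clustering

Per-neuron trial-averaged z-scored traces over −10…+20 s are clustered
with K-means (Euclidean distance on the raw 301-sample vectors, 50
restarts, fixed seed; deterministic given seed). The working group number
is 5; `select_k` scans k = 2…8 and takes the maximum mean silhouette,
smallest k on ties. A scan whose best silhouette is ≤ 0.2 warns that the
data show no cluster structure. Clusters are renumbered by decreasing
size for stable presentation.

## Longitudinal tracking

The match score between neurons of two sessions is
`0.5 · max(0, 1 − d/d_scale) + 0.5 · r`, with d the centroid distance
(d_scale = 10 units) and r the Pearson correlation of the session's
trial-averaged peri-event reference traces; with traces only, the score is
r alone. Matching is greedy best-score one-to-one (deterministic, ties
broken by neuron id; Hungarian assignment available behind a flag), and
pairs below 0.5 — the standard minimum-correlation acceptance for
longitudinal registration — are rejected. The score is a documented,
testable stand-in for proprietary image-based registration, validated
against planted correspondences (≥95 % recovery under 20 % dropout and
jitter). Tracking follows matched neurons across habituation → CS2–CS1 →
test; the shock day is excluded because foot-shock motion artifacts
corrupt registration in practice. Outputs are per-neuron category
trajectories, a first-phase × last-phase transition matrix whose marginals
equal the per-phase category counts restricted to tracked neurons, and
mean AUC per phase for each habituation-defined group.

## State correlations

A behavioral state is a set of non-overlapping intervals; samples are
concatenated across a state's intervals before correlating (zero-lag
Pearson only — "maximum pairwise" is read as the max over *partners*, not
lags; a lagged variant is out of scope). Each neuron's statistic is its
maximum correlation against any other neuron; zero-variance neurons are
excluded with a count. Two states are compared by Cohen's d with pooled
N−1-weighted SD. The default baseline state is the 5 min before the
session starts. Note that max-partner statistics are strongly dependent
across neurons, so a single baseline-vs-baseline split has non-negligible
|d| even on exchangeable data; exchangeability shows as the signed d
averaging to ~0 over many splits, which is how the property is tested.

## Behavior

A frame is frozen when it lies in a contiguous sub-threshold run of at
least `min_bout_s` (default 1.0 s; 0 reproduces pure frame thresholding —
the floor exists to suppress single-frame noise in measured motion, at the
cost of discarding genuinely short bouts). Freezing percent is the share
of frozen frames in each 10-s cue window; the 10-s post-cue window is also
reported. Memory strength per mouse is 100 × (mean test-day CS2 freezing) /
(mean CS1 freezing during the CS2–CS1 pairing session), undefined and
excluded when the reference is zero. Extinction over repeated trials is
summarized by trial-ordered group means plus an exponential decay rate
from least squares of log(mean freezing, floored at 1 %) on trial index —
the per-trial means are the primary output, the rate a convenience
summary.

## Pipeline, determinism and problem sizes

`soc_calcium.pipeline.run` drives all stages from one flat YAML config
whose defaults pin the analysis constants (ratio boundaries 1.5/0.5, k = 5
with a 2–8 scan, registration threshold 0.5, −10/+20 s windows); every run
writes a resolved config copy, per-stage CSVs and a JSON report with
counts and a SHA-256 manifest. All randomness flows from explicit seeds
through `numpy.random.default_rng`, so identical config + seed gives
byte-identical outputs.

The test suite and `scripts/acceptance.py` use simulations sized like the
study itself — ~100–200 pooled neurons per session, 3 test trials, a
15-mouse behavioral cohort, 20-seed averages for stochastic recovery
checks — which keeps the full suite in the tens of seconds while leaving
Monte-Carlo error well inside the asserted tolerances.
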