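# Methods

## The measurement model

A measurement is the joint response of `n_sensors = 32` MOS gas sensors over
`n_time = 6000` samples at `dt = 0.1 s`. Each sensor's mean curve follows
first-order adsorption/desorption kinetics:

    mu_s(t) = baseline_s + drift_s * t + eff * A_s * r_s(t)

    r_s(t) = 0                                   for t < t0
           = 1 - exp(-(t - t0)/tau_rise_s)       for t0 <= t <= t_end
           = r_s(t_end) * exp(-(t - t_end)/tau_recover_s)  afterwards

with exposure onset `t0 = 30 s` and exposure end `t_end = 300 s` (the first
five minutes cover baseline and VOC detection; the sample is then removed and
the sensors recover). The multiplicative effect `eff` is the product of a
log-normal per-sample random effect (sd 0.15 on the log scale, drawn **once
per sample** and shared across all of its repeated measurements) and a
log-normal per-measurement, per-sensor jitter (sd 0.05). Additive Gaussian
observation noise has sd 0.01 V. Amplitudes are drawn in 0.3–1.5 V over
baselines of 0.1–0.5 V, time constants in 15–60 s (rise) and 30–120 s
(recovery), linear drift within ±2e-5 V/s. These defaults are plausible for
TGS2X-class sensors at these acquisition times; no published raw-amplitude or
noise figures existed to copy, so they are declared package defaults, chosen
once.

Class structure enters only through the per-sensor profiles. A
*discriminability scenario* builds a profile pair in which a designated set
of "dead" sensors (taken in a fixed preference order, the weakly informative
ids 17, 25, 4, 12, 20, 28 first) is exactly identical across classes, while
the remaining sensors differ in amplitude and in both time constants by an
`effect_size`-scaled random factor; every third live sensor responds with
opposite sign in the second class, mimicking cross-reactive sensors whose
conductance moves the other way. Because the Pearson similarity statistic is
scale-invariant, class contrast is carried by curve *shape* (time constants,
sign), not merely amplitude — amplitude contrast matters to the raw-signal
features instead.

The PMI scenario makes the profile a function of postmortem day: "late
rising" sensors scale with `1 - exp(-day/6)` (putrefaction volatiles
accumulating over weeks), every third sensor is "early peaking" with a
Gaussian bump centred on day 2 (esters/aldehydes of early decomposition), and
rise time constants lengthen by 3 % per day. A `day_effect` factor scales all
day-dependent terms; the PMI analyses use `day_effect = 2` (strong day
effects), the regime in which cascade-grade discrimination between adjacent
days is attainable at these noise levels.

Study designs: 98 + 98 single measurements (postmortem/antemortem), 70 + 70
(animal/human), and 488 measurements of 50 pig samples — each sample measured
7–8 times across days 1–3 (377 total) plus 111 late measurements dealt
round-robin over days 4–11 and 18–32 (days 12–17 are unmeasured, matching the
two late decision bins). All randomness flows from one master seed through a
counter-based `SeedSequence` fan-out, so generation is reproducible and
order-independent.

What the generator does **not** emulate: sensor aging/drift beyond a linear
term, temperature-modulation physics, humidity, cross-measurement carry-over,
and real biological heterogeneity beyond a single multiplicative sample
effect. Passing tests therefore demonstrate that the *pipeline* recovers
structure it is pointed at under controlled conditions — not that real
biosamples are separable.

## Preprocessing

Savitzky–Golay smoothing (default window 51 samples = 5.1 s, order 3; both
configurable and recorded in run metadata) followed by range normalization
`(x - min)/(max - min)`. Edges use scipy's `mode="interp"`: the boundary
polynomial is fitted to the first/last window and evaluated over the edge.
The raw trace is always retained. A constant (dead-sensor) trace maps to all
zeros in both normalized views, with a `degenerate` flag; constancy is judged
on the *range* being exactly zero, because the floating-point sd of a flat
array can be a nonzero rounding residual that normalization would amplify.

## The 85-feature representation

A frozen, versioned 42-descriptor catalog (`enosekit-42-v1`) is applied to
the raw signal (`_raw`) and the smoothed-normalized signal (`_sn`), plus one
SNR feature: `10*log10(var(smoothed)/var(normalized - smoothed))`, capped at
±120 dB. The catalog covers: 16 statistical descriptors (moments, quantiles,
RMS, energy, trapezoidal AUC, 16-bin histogram entropy), 18 time-domain
descriptors (times of extrema, 10→90 % rise time, baseline slope, response
amplitude, crest factor, line length, forward-difference first/second
derivative extrema, derivative zero crossings, lag-1 autocorrelation, Hjorth
activity/mobility/complexity, prominence-thresholded peak count at 5 % of the
signal range) and 8 frequency-domain descriptors of the mean-removed power
spectrum (dominant frequency, centroid, bandwidth, normalized spectral
entropy, 85 % rolloff, relative band powers below 0.1 Hz, 0.1–1 Hz, ≥ 1 Hz).
All derivatives use forward differences divided by `dt`, everywhere.
Degenerate inputs map to defined sentinels (0, or ±120 dB for SNR), never
NaN, so tree ensembles always see complete matrices. Feature matrices hold
one row per (measurement, sensor) with the sample id attached as the group
key for leakage-safe splitting.

## Sensor utility and ablation

For two classes A and B, sensor s's similarity coefficient is the mean
Pearson correlation over all |A|×|B| inter-class signal pairs of that sensor
(computed on smoothed-normalized signals by default). Since correlation is a
dot product of z-scored signals, the pair-grid mean collapses to
`dot(mean_z_A, mean_z_B)/n_time` — an O(n) identity that the tests verify
against brute-force pair enumeration at 1e-12. Constant signals contribute 0
to the average. Ablation removes the highest-coefficient sensor per step
(ties: the lower sensor id is removed last), producing 32 nested subsets;
removing a sensor removes its observation rows. The inter-sensor
mean-absolute-correlation ranking (which finds *independent* sensors rather
than *discriminative* ones) is provided for comparison only.

## Ensembles

GentleBoost: `F0 = 0`; each cycle fits a weighted least-squares regression
tree to the ±1 targets, `F += learn_rate * h_m`, and reweights
`w_i *= exp(-y_i * learn_rate * h_m(x_i))` (renormalized). AdaBoostM1:
weighted classification trees, learner weight
`alpha_m = learn_rate * 0.5 * ln((1-eps)/eps)`, weight update on errors,
early stop at `eps = 0` (the perfect learner is kept with a floored-epsilon
weight) or `eps >= 0.5` (if the first learner is no better than chance the
ensemble is returned empty and scores 0, predicting the first class).
Individual trees are scikit-learn CART trees grown best-first to at most
`max_splits` internal nodes (`max_leaf_nodes = max_splits + 1`) with
`min_samples_leaf = min_leaf`; the boosting loops, additive model, gain
bookkeeping and JSON persistence are implemented here, and prediction always
goes through the package's own array-backed trees so a serialized model
predicts identically after a round trip. Predictor importance attributes each
split's weighted impurity reduction to its feature, scales by learner weight
and normalizes to percentages summing to 100.

The hyperparameter search is a seeded quasi-random exploration of
{method, n_cycles 10–500, learn_rate 1e-3–1, max_splits 1–64, min_leaf 1–32}
(log-uniform), spending the last third of the budget jittering the incumbent,
scored by stratified 5-fold CV loss; the full evaluation log is returned. It
fulfils a 30-evaluation budget without claiming to replicate any particular
Bayesian optimizer.

Default operating point: GentleBoost, 100 cycles, learn rate 0.1, 8 splits,
min leaf 1 — enough capacity to saturate the synthetic two-class designs at a
fraction of the cost of the 400–500-cycle configurations the search space
admits. The PMI cascade classifiers use 16 splits and 100 cycles: the
observation rows mix 32 heterogeneous sensor populations per class, which
needs deeper trees.

## Evaluation protocol

Stratified 90–10 train/test splits at observation level (rows) or sample
level (all rows of a sample move together; verified disjoint on every call).
Per-stratum test counts use largest-remainder rounding toward a total of
`ceil(test_frac * n_units)`. K-fold CV shuffles units per class and deals
them round-robin, so fold sizes differ by at most the number of classes and
no sample spans folds at sample level. Metrics are accuracy, sensitivity and
specificity in percent (reported to 1 decimal), consistent with the 2×2
confusion matrix by construction; ROC curves come from a threshold sweep with
trapezoidal AUC, mean ROC by vertical averaging on a 101-point FPR grid.
Robustness repeats the split/fit/evaluate cycle (default 15×) with derived
seeds and reports means with Student-t 95 % CIs (df = repeats − 1).
Leakage-disciplined runs recompute the sensor ranking from training
measurements only and record exactly which measurement ids informed it, so
the discipline is auditable.

For the PMI classifiers the split is at observation level by design: a single
pig contributes measurements to *both* classes of a node (day 1 and day 3,
say), so sample-level stratification is ill-defined there.

## Voting and the cascade

A sample's class requires `ceil(0.90 * n_sensors)` agreeing sensor votes
("at least 90 %"); below that the outcome is the explicit first-class value
INCONCLUSIVE, which any consumer must handle. With 32 sensors the bar is 29
votes; with 6 retained sensors, 6. The cascade routes A1-early to A2, A2
"2–3 days" to A3, and A1-late to A4; an INCONCLUSIVE vote at any node
terminates with the partial path recorded. All four node models are validated
(present, trained on the expected label pairs) before any classification.
Node-specific retained-sensor subsets are supported (A2 excludes sensor 4;
A3 excludes 4, 12 and 17). Models persist as portable JSON stamped with the
feature-catalog version; loading with a mismatched catalog fails loudly.

## Run manifest

The full protocol enumerates 796 model trainings: for each two-class case,
43 model-selection slots + 3 × 32 ablation series (random-split, sample-split,
training-only ranking) + 15 robustness repeats = 154; the PMI case's 488 are
split evenly over its four classifiers as 4 × (11 selection + 96 ablation +
15 robustness). The model-selection slots execute against a configurable
roster of ensemble presets; re-implementing dozens of unrelated learner
families is out of scope, but the manifest preserves the slot counts.
`run_case` executes a reduced protocol (fewer slots/steps/repeats, optionally
shorter records) with every artifact stamped with the config hash and master
seed, so a run can be replayed exactly.

## Problem sizes and numerical choices

The test suite runs the full design *sizes* (98 + 98, 70 + 70, 488/50)
throughout, using full-length records (6000 points) for the headline
strong-effect recovery run and 600-point records elsewhere — record length
does not enter the quantities checked there (row counts, ranking order,
null-calibration accuracy). The acceptance script uses full-length records
for all three case pipelines and 600-point records only for the
null-calibration and ranking-replicate runs. Other fixed choices: ±1e-12
tolerance for the oracle equivalences; SNR cap ±120 dB; peak prominence
fraction 0.05; histogram entropy over 16 bins; spectral features exclude the
DC bin; split tie-breaks by feature index then midpoint threshold inside
trees (delegated to CART with a fixed random state), and by sensor id in the
ablation order.

## Known limitations

Feature-level equivalence with any particular published 42-descriptor list is
not claimed; the catalog is a documented, versioned stand-in covering the
same descriptor families with the same count, and is config-replaceable. The
synthetic generator's realism limits are listed above; in particular,
held-out accuracies on synthetic data say nothing quantitative about real
forensic samples. The 90 %-agreement rule makes small retained-sensor sets
brittle (8 sensors require unanimity), which is visible in the cascade when
few sensors are kept. Days 12–17 of the PMI design belong to no late bin; a
real sample from that window can only resolve to INCONCLUSIVE or be
mis-binned, mirroring the bin structure itself.
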