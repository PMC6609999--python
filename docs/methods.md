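# Methods

## Overview

`kcdetect` detects k-complexes — the biphasic, > ±75 µV, 0.5–1.5 s
transients of stage-2 sleep — in single-channel EEG by classifying
overlapping 0.5 s windows with features derived from the *texture* of
their time-frequency images. The chain per window is

```
samples → STFT spectrogram → binary T-F image → 10 per-scale box-counting
fractal dimensions → undirected graph → (P(k), mean CC, mean Jaccard) →
LS-SVM
```

followed by merging runs of positively classified windows into events.
This note records the model, the parameters that matter, the numerical
conventions, and what the synthetic benchmark does and does not show.

## Segmentation and labels

Windows are 0.5 s with 0.4 s overlap (step 0.1 s); a trailing partial
window is dropped. All times are seconds, sample indices 0-based, and
annotation intervals half-open `[onset, onset + duration)`.

For *evaluation*, a window is positive when its centre lies inside an
annotated event (`label_rule: center`) — a parameter-free, symmetric rule.

For *training*, the pools are stricter: a training positive must have at
least 80 % of the window inside an event (`train_pos_overlap: 0.8`), so it
actually contains the k-complex waveform, and a training negative must not
intersect any event. Windows straddling an event boundary are excluded
from training (they are neither a k-complex waveform nor clean background;
with a 0.1 s step, a window shifted one step across a boundary has a
nearly identical image but the opposite centre-rule label, and such label
noise caps any classifier's cross-validated accuracy). Detection still
classifies every window.

## Time-frequency image

* STFT: Hann taper of 64 samples (0.32 s at 200 Hz), hop 1 sample,
  256-point FFT (`scipy.signal.spectrogram`, no detrending; power =
  squared magnitude). The taper length sets the spectral mainlobe to
  ~3 Hz, narrow enough to resolve structure *within* the delta band where
  the k-complex lives; a 0.16 s taper (~6 Hz mainlobe) smears the
  k-complex ridge and the low-frequency background into the same blob and
  measurably degrades class separation.
* Display: the power is limited to 0–32 Hz (`image_freq_max`; the
  conventional sleep-EEG display band — the upper bands of a 0–100 Hz axis
  are empty for both classes and would waste most of the image), converted
  to decibels relative to the window's peak with a −40 dB floor
  (`image_floor_db`; the standard spectrogram display scale), min-max
  normalised, bilinearly resampled to 1024 × 1024 and binarised with
  Otsu's threshold. 1024 = 2^10 makes every power-of-two box size divide
  the image side exactly.
* Because the dB scale is peak-relative, the binary image is *exactly*
  invariant to the window's amplitude gain: classification uses
  time-frequency shape only, never absolute amplitude. Constant images
  (all-zero power) map to all-background.

## Box-counting fractal dimensions

For an `L × L` binary image the boxes are grid-aligned at the origin and
`r` runs over powers of two. Two readings of
`Dim = lim log N(r) / log(1/r)` are computed, both base-10:

* **per-scale**: `FD_r = log10 N(r) / log10 (L/r)` for the 10 scales
  `r = 1 … L/2`. `r = L` is excluded — its denominator is zero (and
  `N(L) = 1` for any nonempty image carries no information. The grid
  bound `N(r) ≤ (L/r)²` forces every value into [0, 2]; an empty image
  yields the zero vector.
* **slope**: the negated least-squares slope of `log10 N(r)` vs `log10 r`
  over scales with positive counts (2.0 for an exact plane-filling law).

A reference count series for one 0.5 s window
(277925, 70406, 17805, 6418, 1232, 360, 105, 34, 12, 4, 1 over
r = 1 … 1024) is used as a desk-check fixture: base-10 logs of the counts
must reproduce the associated log-log regression ordinates to 4 decimals.
Two cells of that series (r = 8 and r = 32) are internally inconsistent —
log10(6418) = 3.8074 and log10(360) = 2.5563, not the associated 3.6645
and 2.4857 — and are excluded from the check.

## Fractal graph and its features

Each window's 10 FD values become graph nodes; the distance between two
nodes is `|FD_i − FD_j|`. Three edge schemes (`graph_scheme`):

* **arbitrary** (default): connect pairs with distance ≤ `graph_thr`
  (default 0.15). The default was chosen by training-phase
  cross-validation over a coarse grid, the same empirical calibration any
  user should repeat when the upstream settings change; accuracy is flat
  over roughly 0.1–0.2.
* **mean_degree**: the smallest threshold among the sorted unique
  distances whose graph reaches a target mean degree (default 6). The
  definition is circular (the mean degree depends on the adjacency the
  threshold produces), resolved by an exact scan over candidate
  thresholds. Note that fixing every window's mean degree *removes* the
  between-window density differences that carry most of the class signal,
  so this scheme is a comparison baseline, not the recommended default.
* **mst**: Kruskal's minimum spanning tree with ties broken by
  lexicographic node-pair order (deterministic).

Features from the 0/1 adjacency `B` (zero diagonal, symmetric):

* degree distribution `P(k) = |{v : deg v = k}|/n`, `k = 0 … n−1`;
* clustering coefficient per node — the fraction of its neighbour pairs
  that are connected; nodes of degree < 2 get 0; the mean is reported;
* Jaccard coefficient `|Γ(i)∩Γ(j)|/|Γ(i)∪Γ(j)|` over all unordered pairs
  with **open** neighbourhoods; empty-union pairs count 0; the mean is
  reported. (Under open neighbourhoods a complete graph has mean Jaccard
  `(n−2)/n`, not 1.)

Default feature vector (`feature_mode: scalar`): `[P(0…9), CC̄, J̄]`,
length 12. `full` mode appends the 45 pairwise Jaccard values.

## Classifiers

* **LS-SVM** (primary): training solves the KKT system
  `[[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y]` with
  `K(x, z) = exp(−‖x−z‖²/2σ²)`, γ = 10, σ = 1, labels in {−1, +1}; the
  solve is rejected if its relative residual exceeds 1e−8 (no silent
  re-regularisation). Scores are `Σ αᵢK(x, xᵢ) + b`; a zero score maps
  to +1. Features are z-scored with training-set statistics
  (`standardize: true`).
* **k-means baseline**: Lloyd iteration, seeded kmeans++ initialisation,
  stop at centroid shift < 1e−8 or 300 sweeps; empty clusters keep their
  centre; clusters map to classes by majority vote against training
  truth. The within-cluster SSE is recorded per sweep (non-increasing).

Training balances classes by seeded undersampling of the majority pool.
Performance is the arithmetic mean of six per-fold accuracies under a
seeded stratified 6-fold split (per-class shuffle, round-robin deal).
Undefined evaluation metrics (zero denominators) are reported as NaN,
never coerced to 0.

## Detection and event assembly

Every window is classified; consecutive positive windows (starts one step
apart) merge into one event spanning first start → last start + window.
A gap of ≥ `merge_gap_s` (default 0.1 s, i.e. one step) splits events.
Event-level scoring matches detections to references greedily by
descending overlap, one-to-one; unmatched detections are false positives,
unmatched references false negatives.

## Synthetic benchmark

The generator emulates the statistics a detector must cope with, not the
physiology it cannot access:

* background: seeded spectrally shaped noise with power ∝ `f^−1.5`
  (between pink and brown; sleep EEG is steeper than pink, and > 99 % of
  the power lies below 30 Hz), scaled to 10 µV SD;
* sleep spindles: ~1 s Hann-enveloped 12–14 Hz bursts, 3/min;
* k-complexes: biphasic templates (two opposed raised-cosine lobes,
  negative first), peak-to-peak ≥ 100 µV, durations uniform in
  [0.5, 1.5] s, non-overlapping with 0.2 s clearance, amplitude tapering
  exactly to zero at both ends. Annotations are exactly the injected
  events.

The standard benchmark is 120 s at 200 Hz with 20 events (~1196 windows,
~276 balanced training windows). On it the detector reaches ≈ 0.93 6-fold
CV accuracy and event-level recall 1.0 with the defaults; k-means on the
same features performs substantially worse.

**What passing does not show**: real stage-2 EEG has artifacts (EMG, eye
movements, electrode pops), non-stationary background, K-alpha complexes
and spindle-superimposed k-complexes, and expert annotations with their
own onset jitter and disagreement. The synthetic benchmark demonstrates
that the pipeline's stages compose correctly, are deterministic, and can
learn the texture signature of a biphasic delta transient over realistic
coloured noise — not clinical-grade performance. Accuracy claims on
expert-scored polysomnography require those recordings, which this
repository does not ship. Detection precision on the
benchmark is low (many short false events); no operating-point tuning
(score thresholding, minimum event duration) is applied.

## Problem sizes and runtime

Feature extraction costs ~60 ms per window (dominated by the 1024×1024
resampling), so the 120 s benchmark takes ~1–2 min per pass on one core.
Unit tests use 20–30 s recordings; the acceptance script and the
acceptance tests run the full 120 s benchmark once and share it.

## Known limitations

* Node count is fixed at 10 (one per FD scale); the graph is unweighted.
* No artifact rejection or amplitude criterion: the features are
  deliberately gain-invariant, so a gain-scaled background fluctuation
  with k-complex-like morphology is a false positive by construction.
* `calibrate_threshold` assumes the target mean degree is reachable;
  duplicate FD values can make an empty graph unreachable (threshold 0
  still joins identical values).
* EDF reading requires channel labels to match exactly; no montage
  arithmetic is performed.
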