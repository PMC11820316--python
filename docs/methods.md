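# Methods

## The problem and the model

`fedhar` implements a federated-learning pipeline for human activity
recognition (HAR) from two body-worn tri-axial accelerometers (thigh and
lower back, 50 Hz). M simulated clients each hold a private shard of
labeled windows; every communication round the server broadcasts the
global parameters Θ, each client j runs local SGD on its shard D_j, and
the server aggregates the returned parameters

    Θ_global = Σ_j (D_j / D_total) · θ_j        (FedAvg)

with the plain arithmetic mean Θ = (1/M) Σ_j θ_j available as the
equal-sizes special case (`aggregation: mean`). Raw windows never leave
their shard object; only parameters and sample/class counts reach the
aggregation path, and a test enforces this structurally.

To counter class imbalance, weighted FedAvg rescales each client's
aggregation weight by the inverse frequency of the classes it holds:
with w_c = D_total / (C · count_c) computed from pooled training counts,

    ω_j ∝ Σ_c count_{j,c} · w_c,   Σ_j ω_j = 1,   Θ = Σ_j ω_j · θ_j.

Clients rich in rare classes therefore contribute more. With balanced
classes all w_c coincide and the rule collapses exactly to FedAvg.
Where the weighting acts is genuinely open — the alternative reading
(class-weighted local loss) is available independently through
`TrainConfig.class_weights`, so both mechanisms can be compared.

## Signal path

1. **Synchronization.** Streams are linearly interpolated onto a common
   50 Hz grid over their overlapping interval and stacked; labels come
   from the reference stream.
2. **Segmentation.** Sliding windows of 5 s (250 samples) with 50%
   overlap, both config keys. Windows are half-open `[t1, t2)` index
   intervals, labeled by per-sample majority vote with ties broken by
   the center sample. 5 s at these sensor placements spans at least two
   gait cycles; no standard value exists for this choice.
3. **Gravity/movement decomposition.** A fourth-order low-pass
   Butterworth filter with 1 Hz cutoff, applied forward and backward
   (zero phase, so gravity stays time-aligned with the labels; the
   effective amplitude response is the squared magnitude response of
   the digital filter). Gravity is the filtered signal; movement is the
   residual, so the two reconstruct the input exactly by construction.
4. **Features.** 161 per window, from a fixed manifest stored as
   versioned package data (`data/feature_manifest.json`):
   6 axes × (8 gravity + 8 movement statistics) = 96;
   2 per-sensor vector magnitudes × 16 = 32; 28 pairwise Pearson
   correlations among the 8 movement signals; 3 per-axis cross-sensor
   gravity means; 2 whole-window magnitude means.
5. **Scaling.** Min–max to [0, 1], fitted on the training split only;
   test-time values clip; constant features map to 0.

Numerical conventions (fixed so tests can be exact): population
(n-denominator) standard deviation; skewness and kurtosis as plain
standardized third/fourth moments (no Fisher correction, 0 for constant
windows); linear-interpolation quantiles; coefficient of variation
defined as 0 when |mean| < 1e-12; spectra are one-sided unnormalized DFT
magnitudes with the DC bin excluded (DC is gravity leakage by
construction); all-zero spectra yield 0 for every frequency feature;
correlation with a constant series is 0. The exact composition summing
to 161 is a documented reconstruction — the feature families are
standard for this sensor placement, but no canonical list exists — and
the manifest file makes alternatives pluggable.

## Models

**Hybrid LSTM-GRU classifier.** An LSTM layer (128 units) feeding a GRU
layer (64 units), then a dense softmax head. The cells follow the
standard gate equations over the concatenation [q_{k−1}, y_k]; the LSTM
candidate cell state is tanh(U_c[q, y] + b_c), the only consistent
completion of the gate set. Training is plain SGD without momentum
(learning rate 0.001, batch 32, 30 local epochs by default), Glorot
uniform initialization, optional gradient-norm clipping (off by
default). The classifier consumes either raw `[L × 6]` windows or the
engineered 161-vector as a length-1 sequence (`input_mode`).

**Perceptive extraction network (PEN).** A dual-branch extractor over
raw windows: three convolutional blocks (1-D convolution with same
padding → batch normalization → leaky ReLU, default widths 32/64/64,
kernel 5) with temporal mean pooling, in parallel with a relation
branch (LSTM → GRU → dot-product self-attention → mean pooling). The
attention is O = softmax(Q Kᵀ) V **without** 1/√d score scaling, as a
deliberate fidelity choice; `scale_attention=True` enables the scaling.
Q, K, V are three learned linear projections of the GRU output
sequence — self-attention is the only self-consistent way to form them
from a single input stream. The two representations are concatenated
(optionally with the engineered features, `use_engineered_features`)
into a dense softmax head. Loss is mean cross-entropy with predictions
clamped at 1e-12.

All models run on a small reverse-mode automatic-differentiation engine
(`fedhar.autodiff`) over float64 numpy arrays. This keeps every training
run single-threaded and bit-reproducible from its seed, which the
federated equivalence tests rely on. Batch-normalization running
statistics are state, not weights: they are updated in place during
training-mode forward passes and excluded from gradient steps.

## Reproducibility

A master seed fans out to one child seed per (round, client) through
`numpy.random.SeedSequence([master, round, client])`, so any client's
round can be replayed in isolation and results do not depend on client
execution order. Identical configs produce bit-identical streams,
partitions, parameters and metrics.

## What the synthetic generator emulates — and what it does not

Each subject is a continuous 50 Hz two-sensor recording built from
alternating activity bouts (exponential lengths, mean 30 s, truncated
at 2 s, drawn from the class mix without immediate repeats — free-living
recordings have no published bout statistics, so this schedule is an
assumption, not a reconstruction). Within a bout, each channel is

    g_c + A · sin(2π f t + φ_bout + ψ_c) + ε,   ε ~ N(0, σ²),

with the sensor's unit gravity orientation g (the lower-back sensor uses
a fixed 90° rotation of the thigh orientation, with attenuated, phase-
lagged oscillation, so cross-sensor correlations are non-degenerate),
gait frequency f (0 for static postures; 2.0 Hz walking, 2.8 Hz running,
1.5 Hz cycling), and fixed per-axis phase offsets ψ decorrelating the
axes. The default six-class mix is strongly imbalanced (35% walking,
25% sitting, 18% standing, 12% lying, 5% running, 5% cycling), mirroring
the rarity of dynamic activities in free-living data.

The generator captures posture-dependent orientation, gait-band
periodicity, class imbalance and subject-level structure. It does not
capture biomechanical waveform shape, amplitude drift, sensor
miscalibration, walking-aid artifacts, or transitions inside a bout.
Passing tests therefore demonstrate the correctness of the pipeline's
mechanics and the direction of the federated effects — not real-world
recognition accuracy, which depends on external datasets that are out
of scope here.

## Desk-scale study conditions

The full-scale protocol (50 clients, 128/64-unit model, lr 0.001 with 30
local epochs over 25–200 rounds on tens of thousands of windows) implies
millions of SGD steps. The desk-scale experiments in
`fedhar.experiments` — shared verbatim by the test suite and
`scripts/acceptance.py` — scale this to: 10 subjects × 90 s (≈350
windows), 8 clients, a 16/8-unit model on the engineered features,
30 local epochs per round, 20 rounds, batch 32, learning rate 0.1. The
raised learning rate compensates the ~1000× smaller step budget; with
the full-scale 0.001 the desk-scale runs never leave the majority-class
plateau. Subject-stratified 70/15/15 splits throughout.

Three experiments:

* **Federated vs centralized** — homogeneous shards, centralized
  baseline trained with matched total epochs from the same
  initialization; the two validation accuracies agree within a few
  points.
* **Imbalance** — three classes mixed 10:5:1 (minority: running),
  heterogeneous shards, identical seeds in both arms; weighted FedAvg's
  minority-class F1 is compared with plain FedAvg's.
* **Client distributions** — homogeneous vs heterogeneous (skew 0.8)
  partitions of the same cohort; heterogeneous accuracy trails early
  (round 5) and the gap closes by the final round; the smoothed
  (5-round moving average) homogeneous curve is non-decreasing within
  a 0.025 tolerance.

Because the comparative effects are stochastic at this scale, the
test suite asserts them over ten fixed seeds with a ≥ 7/10 majority,
mirroring how stability is reported per communication round (mean,
sample SD, min/max, linear-interpolation IQR).

## Known limitations

* Recognition accuracies on synthetic cohorts say nothing quantitative
  about HARTH/HAR70+/UCI-HAR performance; loaders for those datasets
  exist behind the same `SensorStream` interface but nothing depends on
  them.
* The autodiff engine implements exactly the primitives these models
  need; it is not a general-purpose framework and has no GPU path.
* Client sampling, transport, stragglers, secure aggregation and
  differential privacy are out of scope; the engine simulates full
  participation in-process.
* The heterogeneous partitioner guarantees disjointness, pool coverage
  and a dominant class per client, but the exact dominant fraction
  degrades when a class's supply cannot cover its holders' demand.
* With only ten subjects, the subject-stratified validation split can
  contain no minority-class window at all for some seeds; the imbalance
  comparison then records a 0–0 tie, which is why the acceptance script
  reports each minority F1 together with its validation support.
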