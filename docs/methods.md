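# Methods

This note documents the models, defaults and design choices behind
`herdsense`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Data model

The raw unit is a labelled triaxial accelerometer stream: 25 Hz samples of
acceleration in g on X/Y/Z (16-bit sensor, ±2 g full scale), each carrying
a behaviour annotation. Cleaning removes unannotated samples (blank or
whitespace-only labels) and the catch-all `other` category
(case-insensitive), leaving the 13 well-defined behaviours; rows whose
numeric fields do not parse are dropped and counted, never imputed.
Behaviour names are integer-encoded lexicographically so codes are stable
across runs and platforms. Real data outside ±2 g is passed through with a
warning rather than clipped — the range check is a sensor contract, not a
physical bound.

## Windowing

Streams are segmented independently (a window never spans two source
files) into non-overlapping blocks of T consecutive samples starting at
0, T, 2T, …, discarding the trailing remainder. Only
behaviour-homogeneous blocks — all T labels identical — become windows;
mixed blocks are dropped and counted, not majority-voted. Two presets
coexist:

* **T = 10** (default): windows are exactly the model input, 0.4 s at
  25 Hz.
* **5-second preset**: 125-sample windows subsampled to 10 equally spaced
  timesteps (indices `round(i·124/9)`, i = 0…9), so a 5-second semantic
  window still feeds the fixed (10, 3) model input. The rule is
  deterministic and keeps the first and last sample.

## Whole-window SMOTE

Classical SMOTE is implemented from scratch and applied to flattened
windows (time-major 3T-vectors) in the standardised space. For each class
below the majority count, synthetic vectors are generated as
`x + λ(x′ − x)` with the base window `x` drawn uniformly from the class,
`x′` drawn uniformly among its `k_eff = min(k, n−1)` nearest same-class
neighbours (Euclidean; exact distance ties broken toward the lower index),
and `λ ~ U(0, 1)`. Defaults: k = 5 (the classical choice), match-majority
targets. Degenerate cases: a single-window class is replicated verbatim
(nothing to interpolate); the majority class is untouched; originals are
preserved unchanged and precede all synthetics in the output. One seeded
generator drives base, neighbour and λ draws in that fixed order per class
(classes in ascending code order), so balancing is bit-reproducible.
Neighbour search is a chunked brute-force scan (argpartition plus an exact
deterministic reordering of the candidate block), which handles the
~1.8-million-window balancing experiment in well under its time budget
without approximate-search dependencies.

Interpolating whole windows, not samples, is the point: each synthetic
window inherits the temporal shape of two real windows of the same
behaviour, so the oversampled training set remains sequence-consistent.

## Classifier

A stacked LSTM implemented in NumPy (forward pass, backpropagation through
time, Adam), matching the layer contract exactly:

| layer | output shape |
|---|---|
| input | (B, 10, 3) |
| LSTM 128, full sequence | (B, 10, 128) |
| LSTM 64, full sequence | (B, 10, 64) |
| LSTM 32, final state | (B, 32) |
| Dropout 0.5 | (B, 32) |
| Dense 64, ReLU | (B, 64) |
| Dense C, softmax | (B, C) |

Trainable parameters follow the closed form
`4((3+128+1)·128) + 4((128+64+1)·64) + 4((64+32+1)·32) + (32+1)·64 +
(64+1)·C` = 132,365 for C = 13, asserted in the tests. Cell conventions:
gate order input/forget/cell/output, Glorot-uniform input kernels,
orthogonal recurrent kernels, forget-gate bias 1. Weights and batched
activations are float32; softmax/cross-entropy and the Adam moments are
accumulated in float64 for stability.

Training: Adam at learning rate 1e-3 (β₁ 0.9, β₂ 0.999, ε 1e-7), batch 64,
sparse categorical cross-entropy, at most 10 epochs. A stratified 30%
validation split is held out of the training partition (size-1 classes stay
in training with a warning; `val_fraction = 0` disables the split for
capacity experiments). Early stopping monitors validation loss with
patience 3 and restores the best epoch's weights; it can be disabled for a
fixed schedule. The batch size follows the dedicated hyperparameter list
(64) where the architecture prose says 128; patience is unstated upstream
and defaults to 3. All stochastic elements — initialisation, shuffling,
the validation split, dropout masks — come from one seeded generator, so
training is bit-reproducible in this single-threaded implementation.
Inference never applies dropout and is deterministic; argmax ties resolve
to the lower class index.

## Metrics

All metrics derive from the C×C confusion matrix (rows true, columns
predicted): precision `diag/colsum`, recall `diag/rowsum`, F1 the harmonic
mean, with empty rows/columns reported as 0 (warned); macro averages are
unweighted class means, weighted averages support-weighted (hence weighted
recall ≡ accuracy, asserted as an identity test). Multiclass MCC uses
Gorodkin's generalisation
`(N·tr − Σ r_k c_k) / √((N² − Σ r_k²)(N² − Σ c_k²))` with the zero-denominator
convention MCC = 0. The test suite cross-checks every formula against
scikit-learn and against a literal per-class brute-force computation.

## Simulator

The generator emulates what the pipeline assumes about field recordings,
not cow biomechanics. A stream is a sequence of behaviour bouts; within a
bout, `acc(t) = base + amp ⊙ sin(2πft + φ) + ε`, with a per-bout random
phase per axis, Gaussian noise, then 16-bit quantisation over ±2 g and
clipping. The 13-behaviour catalogue uses time shares proportional to the
six-cow reference counts (RES 150,130 … BMN 54; the RES:BMN ratio is exact
by construction) with hand-chosen, well-separated signatures: distinct
posture vectors (base), oscillation frequencies 0.3–5 Hz and amplitudes
0.02–0.6 g, noise 0.02–0.06 g, each respecting `|base| + amp + 4σ ≤ 2 g`
per axis. Dwell times are lognormal with behaviour-specific means (90 s
resting bouts down to 4–5 s escape/mount events, SD = mean/2).

Bout scheduling is i.i.d. by default: each bout's behaviour is drawn with
probability proportional to `proportion / dwell_mean`, which makes the
expected *time* share equal the catalogue proportion (renewal–reward);
reference counts are sample counts, i.e. time, so this is the faithful
reading. At desk-scale durations the literal shares leave the rarest
behaviours with an expected time below a single window (BMN would get
~0.3 s in 30 minutes), so short experiments use two switches chosen once
from this bout arithmetic: a `min_share` floor of 0.004 on the time shares
(floor then renormalise; the majority:minority ratio stays ≈ 125:1), and a
`scheduled` mode that lays out `round(share·duration/dwell)` bouts per
behaviour (at least one, with the dwell shrunk to the behaviour's share
when that share is below one typical dwell) in seeded random order.
Scheduled mode emits every planned bout, so coverage of all 13 behaviours
is guaranteed by construction and the realised duration is only
approximately the requested one.

**What passing tests show**: that the pipeline's mechanics are correct and
that balancing rescues minority classes *when the behaviours are separable
in the signal*. The default signatures are deliberately separable; real
accelerometer classes overlap (RES vs RUS differ subtly), annotations are
noisy, and bout structure is autocorrelated within days. End-to-end scores
on simulated data therefore validate the machinery, not field performance.

## Pipeline order and leakage

Default stage order: read → clean → window → encode → **split** (stratified
on whole windows, per-class test counts `round(n_c·0.2)` within ±1;
singleton classes go to training) → **scale** (fitted on training windows
only) → **balance** (training partition only) → train → evaluate. This
deviates from the literal upstream description, which scales before
partitioning and depicts whole-dataset balancing; both introduce leakage —
test statistics into the scaler, synthetic windows interpolated from test
neighbours into training. The `paper_order` flag reproduces the literal
order for comparison. Splitting operates on windows rather than raw rows
because windows are the model's atomic unit; splitting rows would sever
windows across the partition boundary. One master seed derives the
simulate/split/SMOTE/model stage seeds through `SeedSequence`, so a single
integer reproduces an entire experiment.

## Problem sizes

The balancing experiment runs at the published scale (280,428 input
windows → 13 × 141,717 ≈ 1.8 M, ~2 minutes, ~1.5 GB). End-to-end
experiments use 30 simulated minutes (~45,000 samples, ~4,400 windows,
~31,000 after balancing), three seeds with and without balancing; one
balanced training run takes roughly a minute on a single CPU. The
long-run share check simulates 4 hours at the literal proportions, with
tolerances from the compound bout-count variance (3 SE plus one dwell of
slack per behaviour).

## Known limitations

* The simulator has no behaviour-transition grammar (bouts are exchangeable)
  and no inter-animal variability; a transition-matrix extension would be
  straightforward but is not needed to exercise the pipeline.
* The NumPy LSTM is single-threaded and unoptimised for large batches; it
  targets correctness and reproducibility over throughput.
* Whole-window SMOTE interpolates linearly in flattened space; for long
  windows or phase-shifted periodic signals, linear interpolation can
  average out oscillations. At T = 10 this is mild, and it is inherent to
  the classical method implemented here.
* Reported simulated-data scores should not be read as expected field
  accuracy (see the simulator section).
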