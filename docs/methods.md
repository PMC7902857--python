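# Methods

`targetproj` trains multi-layer networks without automatic differentiation,
implementing six credit-assignment strategies that differ only in how each
hidden layer obtains its *modulatory signal* — the quantity standing in for
the loss gradient with respect to the layer's pre-activations. This note
records the model, the conventions the implementation fixes where the
problem statement is open, and what the included experiments do and do not
demonstrate.

## Model and update rules

A network is an ordered stack of layers k = 1..K with forward weights
`W_k`, biases `b_k` and activations `f_k` (tanh, sigmoid, softmax or
linear):

    z_k = W_k y_{k-1} + b_k,     y_k = f_k(z_k),     y_0 = x.

For classification the output activation is sigmoid (with binary
cross-entropy) or softmax (with categorical cross-entropy); both keep the
outputs strictly inside (0, 1). Both losses carry a 1/C prefactor over the
C output units, so the exact negative gradient of the loss with respect to
`z_K` is

    dz_K = (y* - y_K) / C,

with `y*` the one-hot target. For regression (MSE, tanh or linear output)
the analogous exact form is `dz_K = (2/C)(y* - y_K) ⊙ f'(z_K)`.

Hidden layers receive `dz_k = dy_k ⊙ f'_k(z_k)`, where `dy_k` is
strategy-specific:

| strategy | `dy_k` | reads deeper weights? | needs full forward pass? |
|---|---|---|---|
| `bp` | `W_{k+1}^T dz_{k+1}` | yes | yes |
| `fa` | `B_k dz_{k+1}` (fixed random, shape of `W_{k+1}`) | no | yes |
| `dfa` | `B_k^T e`, `e = y* - y_K` | no | yes (needs `y_K`) |
| `sdfa` | `B_k^T sign(e)` | no | no (sign(e) is known from the label) |
| `drtp` | `B_k^T y*` | no | no |
| `shallow` | 0 (hidden layers frozen) | — | — |

Because `y*` is one-hot, the DRTP signal is a row lookup of `B_k` — no
matrix-vector product — and is computable before any layer has been
evaluated. `drtp_hidden_delta` implements it as a row selection, and the
test suite asserts bitwise equality with the explicit projection, plus the
two structural guarantees: hidden signals of the feedback-alignment family
never read deeper forward weights, and the sDFA/DRTP signals obey
`dy(sdfa) = 2·dy(drtp) - B^T 1` exactly (from `sign(e) = 2y* - 1`).

All updates are applied as ascent on `(y* - y_K)`:

    W_k += η · Σ_batch dz_k y_{k-1}^T,      b_k += η · Σ_batch dz_k,

optionally routed through Adam (β1 = 0.9, β2 = 0.999, ε = 1e-8,
bias-corrected) instead of plain SGD.

**Minibatch aggregation is a sum, not a mean.** The benchmarks this package
reproduces are silent on the convention. We measured both at full protocol
scale on the synthetic classification task: mean aggregation leaves every
strategy far short of the reported error levels after 500 epochs (e.g.
shallow at 17.3% train where ~9% is reported), while sum aggregation
reproduces all five strategies' levels simultaneously. Sum is also the
natural convention for the streaming/online formulation of these rules —
the minibatch is then just an accumulation of per-sample updates. Under SGD
the two conventions differ only by a factor of the batch size absorbed into
η; under Adam the difference largely cancels.

## Initialisation

He-uniform draws each weight from U(−b, b) with `b = sqrt(6/fan_in)`;
fan_in is the number of inputs per unit (kernel volume for convolutions).
Biases are always zero-initialised. The fixed random matrices `B_k` are
He-uniform as well; for the direct algorithms (`dfa`/`sdfa`/`drtp`) the
projection maps R^C to the layer width, so fan_in = C, and for `fa` it is
the fan-in of the forward matrix the hop replaces.

The synthetic-task protocol initialises forward weights He-uniform for
`bp`/`shallow` but to **zero** for the feedback-alignment family, whose
fixed random feedback breaks the symmetry that zero initialisation would
otherwise lock in (for BP, zero init is a fixed point and is therefore not
used). The image benchmarks initialise everyone He-uniform. The estimators
expose this as `weight_init='auto' | 'he_uniform' | 'zeros'`.

## Numerical choices

* Cross-entropy clamps outputs to [1e-12, 1 − 1e-12] before the log
  (sigmoid can underflow to exact 0/1 in floating point).
* Convolution is cross-correlation with zero padding; max-pooling is
  non-overlapping with ties broken at the first (lowest flat index)
  maximum, and the argmax is stored to route deltas.
* Dropout is inverted (train-time rescaling by 1/(1−p)), applied to
  fully-connected hidden activations only, same p for all of them.
* Direct projections onto convolutional blocks target the flattened
  post-pooling activations; deltas are routed back through the stored
  argmaxes to the conv pre-activations, then through f'. (Whether the
  original experiments projected pre- or post-pooling is not documented;
  post-pooling is this package's choice.)
* Experiment runs use float32 (the conventional deep-learning precision;
  halves time and memory); the linear-network theory checks use float64.
* The training set is reshuffled every epoch with a seeded generator.

## Synthetic tasks

**Cosine regression.** Each sample draws μ ~ U(−π, π) and
x ∈ R^256 ~ N(μ, 1) per coordinate; the 10 targets are
`y*_j = cos(x̄ + φ_j)`, `φ_j = −π/2 + jπ/9`. Since Var(x̄) = 1/256, the
targets are a smooth almost-deterministic function of a 1-D statistic of
the input — a task a frozen random hidden layer cannot fit but any of the
trained-hidden-layer strategies can. Default split 5k/1k.

**Hypercube-cluster classification.** `gen_classification` delegates to
scikit-learn's `make_classification` with n = 256 features, 128
informative, 10 classes, 5 clusters per class, `class_sep = 4.5`, no
redundant/repeated features, remaining options at library defaults
(including 1% label noise). The generator places unit-normal clusters on
distinct hypercube vertices, then applies a random linear mixing within the
informative subspace. That mixing is essential to the benchmark's
difficulty: `gen_classification_hypercube` implements the same geometry
*without* the mixing, and deep classifiers then reach ~0% test error, while
the mixed task leaves the 2–4% residual the benchmark is known for
(`crosscheck_generator` quantifies the gap). Default split 25k/5k; the
dataset is generated once per experiment and shared across network seeds.

What the generators do not emulate: real-data covariate structure,
class imbalance, input scaling conventions of image data. Passing the
synthetic reproductions therefore validates the *training rules and their
relative behaviour*, not performance claims on natural data.

## Alignment diagnostics

Angles are measured between an algorithm's per-layer `dz_k` and the BP
signals computed on the same minibatch with the same current weights (the
BP reference is measured, never applied). Tensors are flattened across the
minibatch before the cosine; a zero vector yields NaN (recorded as missing,
not as 0°, which matters at zero initialisation where the BP reference is
identically zero). Series are smoothed with an EWMA
(`s_t = 0.95 s_{t-1} + 0.05 x_t`) initialised at the first observation.
Monitoring cadence: every 1k samples (regression), every 2.5k (synthetic
classification).

## Linear-network guarantees

For a network with strictly linear hidden layers, sigmoid/softmax output,
cross-entropy loss, zero-initialised weights, biases omitted and training
on a single example, DRTP's dynamics have closed one-dimensional structure:
`W_1^t = tη (B_1^T y*) x^T` exactly, every hidden output is collinear with
`B_k^T y*`, intermediate `W_k^t ∝ (B_k^T y*)(B_{k-1}^T y*)^T`, and the
pseudo-inverse of the forward product above layer k applied to the error is
a positive multiple of `B_k^T y*` — hence the BP and DRTP modulatory
signals have strictly positive dot product and stay within 90° of each
other.

`theory.py` verifies this numerically rather than symbolically:
structure to relative tolerance 1e-8 (observed ≈ 1e-15), recovered-scalar
and normalised-dot positivity with margin 1e-12, SVD pseudo-inverse with
relative cutoff 1e-12. Early steps where the forward product is still
identically zero (the signal has not yet reached the deeper layers) are
skipped, as the statement requires t > 0 with a nonzero product.

On sign bookkeeping: the guarantee is often written with the scalars
negated, which corresponds to flipping every `B_k` — immaterial for a
symmetric random draw. This implementation states and asserts it in the
convention of its own (ascent-form) update rule, under which the recovered
scalars are positive; the convention-free consequences (collinearity,
rank-1 structure, positive BP·DRTP dot product) are asserted either way.
`sweep_counterexample_search` additionally *records* (never asserts) what
happens when the preconditions are violated — He init, tanh hidden units,
minibatches — where alignment is observed to persist but is no longer
guaranteed.

## Experiment protocols and problem sizes

The protocol defaults mirror the benchmarks: regression 256-100-100-10
tanh, MSE, SGD, η = 5e-4, batch 50, 500 epochs; synthetic classification
256-500-500-10 tanh/sigmoid, BCE, same optimiser settings; MNIST batch 60,
100 epochs, Adam with a per-(dataset, topology, algorithm) learning-rate
grid; CIFAR-10 batch 100, early stopping (5k validation holdout, patience
10, best weights restored) capped at 200 epochs, with optional
augmentation (random horizontal flip + random crop from 4-pixel padding)
and test error averaged over the last 10 epochs. Image data is read from
standard IDX / binary-batch files and scaled to [0, 1]; it is never
downloaded by the package.

Runtime scaling choices (the package's own desk scale): the test suite
runs the classification ordering checks at 2.5k train samples, 50 epochs,
3 seeds, and the regression checks at 5k samples, 50 epochs, 3 seeds.
`scripts/acceptance.py` runs the full 25k/5k classification data for 150
epochs with one network seed per strategy; the error levels are near their
asymptotes by then (measured drifts are a few tenths of a percentage point
from epoch 150 to 500 for all strategies except sDFA's training error,
which continues to improve slowly). The full 500-epoch, 10-seed protocol is a matter of
hours on one CPU and is available by flag (`--epochs`, `--n-seeds`).

## Known limitations

* On the classification benchmark, shallow learning generalises worse
  here (test ≈ 13%) than its commonly reported level (≈ 9.6%) although its
  training error matches, and BP's test error is likewise ~1.5–2.5 pp above
  its reported level while fitting the training set completely. Both trace
  to the same mechanism: with `b = sqrt(6/fan_in)` and the benchmark's
  high-variance raw features, first-layer pre-activations have standard
  deviation ≈ 4.6 and the tanh units saturate almost fully, so He-initialised
  networks (shallow's frozen features, BP's starting point) behave like
  near-binary random projections and partially memorise. Implementations
  whose "He uniform" bound is smaller (e.g. framework-default
  `1/sqrt(fan_in)`) saturate less and should show a smaller train/test gap;
  the zero-initialised feedback-alignment-family runs are unaffected.
* DRTP is defined for classification; the regressor refuses it (the target
  only proxies the error sign when outputs are bounded in (0, 1)).
* No batch normalisation, no learning-rate schedules, no ReLU paths for
  DRTP (saturating activations are what stops its constant-sign updates).
* Convolutional training with the direct algorithms suffers the known
  bottleneck effect (low parameter redundancy); the package implements the
  plumbing but no remedy.
* Everything is plain NumPy on one CPU; large-scale runs are out of scope.
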