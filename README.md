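# targetproj

Feedforward training of deep neural networks with fixed random learning
signals — no backpropagated errors, no automatic differentiation.

## The problem

Backpropagation (BP) trains layer k with the true loss gradient
δy_k = W_{k+1}ᵀ δz_{k+1}, which requires (i) *weight transport* — the
backward pathway must use the transpose of the forward weights — and
(ii) *update locking* — no layer can update until the full forward (and
backward) pass has completed, forcing activations to be buffered. Both
constraints are biologically implausible and expensive for low-power
adaptive hardware at the edge.

A family of alternatives replaces the backward pathway with **fixed random
matrices** B_k drawn once and never trained:

| strategy | hidden-layer signal δy_k | solves weight transport | solves update locking |
|---|---|---|---|
| `bp`  | W_{k+1}ᵀ δz_{k+1} | – | – |
| `fa`  (feedback alignment) | B_k δz_{k+1} | ✓ | – |
| `dfa` (direct feedback alignment) | B_kᵀ e,  e = y* − y_K | ✓ | – |
| `sdfa` (sign-based DFA) | B_kᵀ sign(e) | ✓ | ✓ |
| `drtp` (direct random target projection) | B_kᵀ y* | ✓ | ✓ |
| `shallow` | 0 (frozen hidden layers) | baseline | baseline |

The key observation behind `sdfa` and `drtp`: with a sigmoid/softmax output
layer the outputs lie strictly in (0, 1), so for a one-hot target y* the
sign of the error e = y* − y_K is +1 at the true class and −1 elsewhere —
known from the label alone, before any computation. The one-hot target is
exactly the shifted error sign, y* = (1 + sign(e))/2, so projecting y*
through a fixed random matrix gives each hidden layer a usable modulatory
signal δz_k = (B_kᵀ y*) ⊙ f′(z_k) that is provably within 90° of BP's on
linear networks (verified numerically in `targetproj.theory`), at the cost
of a single row lookup of B_k per sample.

Everything is implemented from scratch in NumPy with hand-derived updates
(fully-connected and convolutional layers, max-pooling, dropout, SGD and
Adam), plus the diagnostics used to study these rules: per-layer alignment
angles against the BP reference, synthetic benchmark generators, and
numeric verification of the linear-network alignment guarantee.

## Worked example

```python
from targetproj import TargetProjectionClassifier
from targetproj.datasets import gen_classification_split

train, test = gen_classification_split(5000, 1000, seed=0)
for algo in ("drtp", "shallow"):
    clf = TargetProjectionClassifier(
        algorithm=algo, hidden_layer_sizes=(500, 500), learning_rate=5e-4,
        batch_size=50, max_epochs=50, random_state=0,
    ).fit(train.X, train.y)
    err = 100.0 * (1.0 - clf.score(test.X, test.y))
    print(f"{algo:8s} test error: {err:.2f}%")
```

```
drtp     test error: 8.30%
shallow  test error: 20.70%
```

The task is a 10-class mixture of Gaussian clusters on hypercube vertices
(256 features, half informative). Projecting nothing but the one-hot label
through fixed random matrices (`drtp`) trains the two hidden layers to
8.3% test error — 2.5× better than leaving them frozen (`shallow`) —
with no feedback pathway and no waiting for the forward pass to finish.
The estimators follow the scikit-learn contract (`get_params`, `clone`,
pipelines, `cross_val_score`).

The functional core is available directly (`init_network`, `forward`,
`make_feedback`, `modulatory_signals`, `apply_updates`) for custom
topologies, including convolutional networks with trained or fixed random
kernels, and a CLI wraps the benchmark protocols:

```bash
targetproj train --task synth_classification -a bp -a dfa -a drtp \
    --seeds 0,1,2 --out runs/
targetproj angles --task regression -a dfa --seeds 0 --out runs/
targetproj theory-check --depths 2,3,4 --steps 100 --out theory.json
```

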