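"""Minibatch training loop shared by the estimators, the experiment runner
and the acceptance tooling.

The loop is deliberately plain: shuffle, slice minibatches, run the forward
pass, form the output delta and the algorithm's hidden-layer modulatory
signals, apply the (optionally Adam-transformed) updates.  When alignment
monitoring is on, the BP reference signals are computed on the same
minibatch with the same current weights — they are measured, never applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import AlignmentTrace, signal_angles
from .feedback import (
    FeedbackEnsemble,
    apply_updates,
    make_feedback,
    modulatory_signals,
    output_delta,
    target_onehot,
)
from .losses import loss as loss_fn
from .network import Network, forward, init_network
from .optim import make_optimizer


@dataclass
class RunRecord:
    """Metrics of one training run (one network seed, one algorithm)."""

    algorithm: str
    epochs: list = field(default_factory=list)
    train_metric: list = field(default_factory=list)  # error % (classification) or loss
    test_metric: list = field(default_factory=list)
    alignment: Optional[AlignmentTrace] = None
    config: dict = field(default_factory=dict)

    @property
    def final_train(self) -> float:
        return self.train_metric[-1]

    @property
    def final_test(self) -> float:
        return self.test_metric[-1]


def classification_error(net: Network, X: np.ndarray, labels: np.ndarray,
                         batch: int = 2000) -> float:
    """Test-mode error rate in percent (argmax prediction)."""
    wrong = 0
    for i in range(0, X.shape[0], batch):
        tr = forward(net, X[i : i + batch], train=False)
        wrong += int(np.sum(np.argmax(tr.ys[-1], axis=1) != labels[i : i + batch]))
    return 100.0 * wrong / X.shape[0]


def dataset_loss(net: Network, X: np.ndarray, Y: np.ndarray, loss_kind: str,
                 batch: int = 2000) -> float:
    """Test-mode mean loss over a dataset."""
    total = 0.0
    for i in range(0, X.shape[0], batch):
        tr = forward(net, X[i : i + batch], train=False)
        total += loss_fn(loss_kind, tr.ys[-1], Y[i : i + batch]) * tr.ys[-1].shape[0]
    return total / X.shape[0]


def train_network(
    net: Network,
    ensemble: FeedbackEnsemble,
    X: np.ndarray,
    Y: np.ndarray,
    loss_kind: str,
    lr: float,
    epochs: int,
    batch_size: int,
    optimizer: str = "sgd",
    dropout_p: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    labels: Optional[np.ndarray] = None,
    X_test: Optional[np.ndarray] = None,
    Y_test: Optional[np.ndarray] = None,
    labels_test: Optional[np.ndarray] = None,
    eval_every: Optional[int] = 1,
    align_every_samples: Optional[int] = None,
    trainable_mask: Optional[list] = None,
    shuffle: bool = True,
) -> RunRecord:
    """Train ``net`` in place; returns the run's metric record.

    Parameters
    ----------
    Y : (n, C) targets — one-hot for classification, real vectors for regression.
    labels : (n,) integer class labels; presence switches the recorded metric
        from dataset loss to classification error (percent).
    eval_every : record train/test metrics every this many epochs (final epoch
        always recorded); None disables intermediate evaluation.
    align_every_samples : monitoring cadence for the angle between this
        algorithm's modulatory signals and the BP reference, in training
        samples seen; None disables monitoring (it is never needed to train).
    trainable_mask : per-layer booleans; False freezes a layer (fixed random
        kernels).  Independent of the ``shallow`` strategy, which freezes all
        hidden layers by emitting no signal for them.
    """
    rng = rng if rng is not None else np.random.default_rng()
    # a string names a fresh optimizer; an instance is used as-is (lets a
    # caller keep Adam moments across epoch-level calls)
    opt = make_optimizer(optimizer, lr) if isinstance(optimizer, str) else optimizer
    classification = labels is not None
    out_act = net.layers[-1].activation

    bp_ref = None
    record = RunRecord(algorithm=ensemble.algorithm)
    if align_every_samples is not None and ensemble.algorithm not in ("bp", "shallow"):
        bp_ref = FeedbackEnsemble(algorithm="bp")
        record.alignment = AlignmentTrace(ensemble.algorithm)

    n = X.shape[0]
    samples_seen = 0
    next_align = 0

    def evaluate(epoch: int) -> None:
        record.epochs.append(epoch)
        if classification:
            record.train_metric.append(classification_error(net, X, labels))
            if X_test is not None:
                record.test_metric.append(classification_error(net, X_test, labels_test))
        else:
            record.train_metric.append(dataset_loss(net, X, Y, loss_kind))
            if X_test is not None:
                record.test_metric.append(dataset_loss(net, X_test, Y_test, loss_kind))

    for epoch in range(1, epochs + 1):
        order = rng.permutation(n) if shuffle else np.arange(n)
        # trailing partial minibatches are dropped unless the set is smaller
        # than one batch
        stop = n - (n % batch_size) or n
        for start in range(0, stop, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], Y[idx]
            trace = forward(net, xb, dropout_p=dropout_p, train=True, rng=rng)
            dz_K = output_delta(loss_kind, trace.ys[-1], yb, trace.zs[-1], out_act)
            sig = modulatory_signals(net, ensemble, trace, yb, dz_K)
            if bp_ref is not None and samples_seen >= next_align:
                sig_bp = modulatory_signals(net, bp_ref, trace, yb, dz_K)
                record.alignment.record(samples_seen, signal_angles(sig, sig_bp))
                next_align += align_every_samples
            apply_updates(net, sig, trace, opt, trainable_mask)
            samples_seen += len(idx)
        if (eval_every and (epoch % eval_every == 0)) or epoch == epochs:
            evaluate(epoch)
    if not record.epochs:
        evaluate(epochs)
    return record


def fit_classifier_network(
    topology,
    algorithm: str,
    X: np.ndarray,
    labels: np.ndarray,
    *,
    lr: float = 5e-4,
    epochs: int = 500,
    batch_size: int = 50,
    optimizer: str = "sgd",
    loss_kind: str = "bce",
    dropout_p: float = 0.0,
    weight_init: str = "auto",
    seed: Optional[int] = None,
    X_test=None,
    labels_test=None,
    eval_every: Optional[int] = None,
    align_every_samples: Optional[int] = None,
    dtype=np.float64,
    trainable_mask=None,
):
    """Convenience wrapper: build, initialise and train a classifier network.

    ``weight_init='auto'`` follows the synthetic-benchmark convention:
    He-uniform forward weights for ``bp`` and ``shallow``, zero-initialised
    forward weights for the feedback-alignment family (``fa``/``dfa``/
    ``sdfa``/``drtp``), whose fixed random feedback matrices break the
    symmetry that zero initialisation would otherwise lock in.
    """
    rng = np.random.default_rng(seed)
    net_seed, fb_seed, shuf_seed = rng.integers(0, 2**31 - 1, size=3)
    if weight_init == "auto":
        scheme = "he_uniform" if algorithm in ("bp", "shallow") else "zeros"
    else:
        scheme = weight_init
    net = init_network(topology, scheme=scheme, seed=int(net_seed), dtype=dtype)
    ensemble = make_feedback(algorithm, net, seed=int(fb_seed), dtype=dtype)
    C = net.output_dim
    Y = target_onehot(labels, C).astype(dtype)
    X = np.asarray(X, dtype=dtype)
    record = train_network(
        net,
        ensemble,
        X,
        Y,
        loss_kind,
        lr,
        epochs,
        batch_size,
        optimizer=optimizer,
        dropout_p=dropout_p,
        rng=np.random.default_rng(int(shuf_seed)),
        labels=np.asarray(labels),
        X_test=None if X_test is None else np.asarray(X_test, dtype=dtype),
        labels_test=None if labels_test is None else np.asarray(labels_test),
        eval_every=eval_every,
        align_every_samples=align_every_samples,
        trainable_mask=trainable_mask,
    )
    return net, ensemble, record
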