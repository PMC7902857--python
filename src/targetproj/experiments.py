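"""Configuration-driven experiment reproduction.

Four tasks are supported:

* ``regression`` — the cosine task: 256-100-100-10 tanh net, MSE, SGD,
  lr 5e-4, batch 50, 500 epochs, 5k/1k split; losses and alignment angles
  monitored every 1k samples.
* ``synth_classification`` — the hypercube-cluster task: 256-500-500-10
  tanh/sigmoid net, BCE, SGD, lr 5e-4, batch 50, 500 epochs, 25k/5k split;
  monitoring every 2.5k samples.
* ``mnist`` / ``cifar10`` — external data (IDX / binary batches), Adam with
  the per-(dataset, topology, algorithm) learning-rate grid, batch 60 / 100,
  100 epochs / early stopping capped at 200 epochs; test error averaged over
  the last 10 epochs.

Weight initialisation follows the benchmark protocol: He-uniform for
``bp``/``shallow`` and zero-init for the feedback-alignment family on the
synthetic tasks; He-uniform for everyone on MNIST/CIFAR-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datasets import gen_classification_split, gen_regression_split
from .feedback import make_feedback, target_onehot
from .io_datasets import read_cifar10, read_mnist
from .network import Conv2D, Dense, init_network
from .optim import make_optimizer
from .training import RunRecord, classification_error, train_network

ALGO_ORDER = ("bp", "fa", "dfa", "sdfa", "drtp", "shallow")

#: learning-rate grid for the image benchmarks, per (dataset, topology family,
#: algorithm); topology families are FC1, FC2, CONV-random, CONV-trained
LEARNING_RATE_GRID = {
    ("mnist", "FC1"): dict(bp=1.5e-4, fa=5e-4, dfa=1.5e-4, sdfa=5e-4, drtp=1.5e-4, shallow=1.5e-2),
    ("mnist", "FC2"): dict(bp=5e-4, fa=1.5e-4, dfa=5e-4, sdfa=5e-4, drtp=1.5e-4, shallow=5e-3),
    ("mnist", "CONV-random"): dict(bp=5e-5, fa=1.5e-4, dfa=5e-5, sdfa=5e-4, drtp=5e-4, shallow=5e-3),
    ("mnist", "CONV-trained"): dict(bp=5e-4, fa=5e-5, dfa=5e-5, sdfa=1.5e-4, drtp=1.5e-4),
    ("cifar10", "FC1"): dict(bp=1.5e-5, fa=1.5e-5, dfa=1.5e-5, sdfa=5e-5, drtp=1.5e-4, shallow=1.5e-4),
    ("cifar10", "FC2"): dict(bp=5e-6, fa=5e-6, dfa=5e-6, sdfa=5e-5, drtp=5e-5, shallow=5e-4),
    ("cifar10", "CONV-random"): dict(bp=5e-6, fa=5e-6, dfa=5e-6, sdfa=1.5e-4, drtp=1.5e-4, shallow=1.5e-3),
    ("cifar10", "CONV-trained"): dict(bp=1.5e-4, fa=5e-6, dfa=5e-6, sdfa=1.5e-5, drtp=5e-5),
}


def topology_family(name: str) -> str:
    if name.startswith("FC1"):
        return "FC1"
    if name.startswith("FC2"):
        return "FC2"
    return name


def build_topology(name: str, task: str) -> Tuple[list, Optional[list]]:
    """Resolve a topology name into an ``init_network`` spec list and an
    optional per-layer trainable mask (False = fixed random kernels)."""
    if task == "regression":
        return [256, Dense(100, "tanh"), Dense(100, "tanh"), Dense(10, "tanh")], None
    if task == "synth_classification":
        return [256, Dense(500, "tanh"), Dense(500, "tanh"), Dense(10, "sigmoid")], None
    input_shape = (1, 28, 28) if task == "mnist" else (3, 32, 32)
    flat = int(np.prod(input_shape))
    if name.startswith("FC"):
        n_hidden = 1 if name.startswith("FC1") else 2
        width = int(name.split("-")[1])
        return (
            [flat]
            + [Dense(width, "tanh")] * n_hidden
            + [Dense(10, "sigmoid")],
            None,
        )
    if name in ("CONV-random", "CONV-trained"):
        trainable = name == "CONV-trained"
        if task == "mnist":
            spec = [
                input_shape,
                Conv2D(32, 5, stride=1, pad=2, activation="tanh", pool=2),
                Dense(1000, "tanh"),
                Dense(10, "sigmoid"),
            ]
            mask = [trainable, True, True]
        else:
            spec = [
                input_shape,
                Conv2D(64, 3, stride=1, pad=1, activation="tanh", pool=2),
                Conv2D(256, 3, stride=1, pad=1, activation="tanh", pool=2),
                Dense(1000, "tanh"),
                Dense(1000, "tanh"),
                Dense(10, "sigmoid"),
            ]
            mask = [trainable, trainable, True, True, True]
        return spec, mask
    raise ValueError(f"unknown topology {name!r}")


@dataclass
class ExperimentConfig:
    """Resolved settings of one experiment cell (one algorithm, >= 1 seeds).

    Unset fields resolve to the task's protocol defaults (see module
    docstring).  ``dataset_seed`` fixes the synthetic dataset across network
    seeds, as in the benchmarks: runs differ only in network initialisation.
    """

    task: str = "synth_classification"
    algorithm: str = "drtp"
    topology: Optional[str] = None
    lr: Optional[float] = None
    optimizer: Optional[str] = None
    batch_size: Optional[int] = None
    epochs: Optional[int] = None
    dropout: float = 0.0
    data_augmentation: bool = False
    weight_init: str = "auto"
    seeds: Sequence[int] = (0,)
    dataset_seed: int = 12345
    n_train: Optional[int] = None
    n_test: Optional[int] = None
    monitor_every: Optional[int] = None  # alignment cadence in samples
    record_alignment: bool = False
    data_dir: Optional[str] = None
    dtype: str = "float32"

    _TASKS = ("regression", "synth_classification", "mnist", "cifar10")

    def resolved(self) -> "ExperimentConfig":
        if self.task not in self._TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {self._TASKS}")
        c = replace(self)
        defaults = {
            "regression": dict(topology="FC2-100", lr=5e-4, optimizer="sgd", batch_size=50,
                               epochs=500, monitor_every=1000, n_train=5000, n_test=1000),
            "synth_classification": dict(topology="FC2-500", lr=5e-4, optimizer="sgd",
                                         batch_size=50, epochs=500, monitor_every=2500,
                                         n_train=25000, n_test=5000),
            "mnist": dict(topology="FC1-500", optimizer="adam", batch_size=60, epochs=100),
            "cifar10": dict(topology="FC1-500", optimizer="adam", batch_size=100, epochs=200),
        }[self.task]
        for key, val in defaults.items():
            if getattr(c, key) is None:
                setattr(c, key, val)
        if c.lr is None:  # image tasks: the grid-searched value
            c.lr = LEARNING_RATE_GRID[(c.task, topology_family(c.topology))][c.algorithm]
        if c.weight_init == "auto":
            if c.task in ("mnist", "cifar10"):
                c.weight_init = "he_uniform"
            else:
                c.weight_init = "he_uniform" if c.algorithm in ("bp", "shallow") else "zeros"
        return c

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["seeds"] = list(self.seeds)
        return d


def _load_task_data(cfg: ExperimentConfig):
    """Returns (X_train, Y_train, labels_train or None, X_test, Y_test, labels_test)."""
    dtype = np.dtype(cfg.dtype).type
    if cfg.task == "regression":
        train, test = gen_regression_split(cfg.n_train, cfg.n_test, seed=cfg.dataset_seed)
        return (train.X.astype(dtype), train.y.astype(dtype), None,
                test.X.astype(dtype), test.y.astype(dtype), None)
    if cfg.task == "synth_classification":
        train, test = gen_classification_split(cfg.n_train, cfg.n_test, seed=cfg.dataset_seed)
        return (train.X.astype(dtype), target_onehot(train.y, 10).astype(dtype), train.y,
                test.X.astype(dtype), target_onehot(test.y, 10).astype(dtype), test.y)
    if cfg.data_dir is None:
        raise FileNotFoundError(
            f"task {cfg.task!r} needs external data: pass data_dir pointing at the "
            "dataset files"
        )
    loader = read_mnist if cfg.task == "mnist" else read_cifar10
    X_train, y_train, X_test, y_test = loader(cfg.data_dir)
    if cfg.n_train:  # reduced-scale runs
        X_train, y_train = X_train[: cfg.n_train], y_train[: cfg.n_train]
    if cfg.n_test:
        X_test, y_test = X_test[: cfg.n_test], y_test[: cfg.n_test]
    return (X_train.astype(dtype), target_onehot(y_train, 10).astype(dtype), y_train,
            X_test.astype(dtype), target_onehot(y_test, 10).astype(dtype), y_test)


def augment_cifar(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal flip + random 32x32 crop from 4-pixel zero padding."""
    n, c, h, w = X.shape
    out = np.pad(X, ((0, 0), (0, 0), (4, 4), (4, 4)))
    flip = rng.random(n) < 0.5
    out[flip] = out[flip, :, :, ::-1]
    oy = rng.integers(0, 9, size=n)
    ox = rng.integers(0, 9, size=n)
    crops = np.empty_like(X)
    for i in range(n):
        crops[i] = out[i, :, oy[i] : oy[i] + h, ox[i] : ox[i] + w]
    return crops


def _run_single_seed(cfg: ExperimentConfig, data, seed: int) -> RunRecord:
    X, Y, labels, X_test, Y_test, labels_test = data
    dtype = np.dtype(cfg.dtype).type
    rng = np.random.default_rng(seed)
    net_seed, fb_seed, shuf_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
    spec, mask = build_topology(cfg.topology, cfg.task)
    net = init_network(spec, scheme=cfg.weight_init, seed=net_seed, dtype=dtype)
    ensemble = make_feedback(cfg.algorithm, net, seed=fb_seed, dtype=dtype)
    loss_kind = "mse" if cfg.task == "regression" else "bce"
    train_rng = np.random.default_rng(shuf_seed)
    common = dict(
        loss_kind=loss_kind,
        lr=cfg.lr,
        batch_size=cfg.batch_size,
        dropout_p=cfg.dropout,
        labels=labels,
        X_test=X_test,
        Y_test=Y_test,
        labels_test=labels_test,
        trainable_mask=mask,
        align_every_samples=cfg.monitor_every if cfg.record_alignment else None,
    )

    if cfg.task == "cifar10":
        record = _run_early_stopped(cfg, net, ensemble, X, Y, train_rng, common)
    else:
        eval_every = 1 if cfg.task == "mnist" else max(1, cfg.epochs // 20)
        record = train_network(
            net, ensemble, X, Y, epochs=cfg.epochs, optimizer=cfg.optimizer,
            rng=train_rng, eval_every=eval_every, **common,
        )
    record.config = {**cfg.as_dict(), "seed": seed}
    return record


def _run_early_stopped(cfg, net, ensemble, X, Y, rng, common) -> RunRecord:
    """CIFAR protocol: 5k validation holdout, patience 10 epochs on
    validation error, best weights restored, hard cap on epochs."""
    n_val = 5000
    perm = rng.permutation(X.shape[0])
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, Y_tr = X[tr_idx], Y[tr_idx]
    labels = common["labels"]
    labels_tr, labels_val = labels[tr_idx], labels[val_idx]
    X_val = X[val_idx]
    opt = make_optimizer(cfg.optimizer, cfg.lr)
    best_err = np.inf
    best_weights = None
    patience_left = 10
    record = RunRecord(algorithm=cfg.algorithm)
    inner = dict(common)
    inner["labels"] = labels_tr
    for epoch in range(1, cfg.epochs + 1):
        X_in = augment_cifar(X_tr, rng) if cfg.data_augmentation else X_tr
        sub = train_network(
            net, ensemble, X_in, Y_tr, epochs=1, optimizer=opt, rng=rng,
            eval_every=1, **inner,
        )
        record.epochs.append(epoch)
        record.train_metric.append(sub.train_metric[-1])
        record.test_metric.append(sub.test_metric[-1])
        val_err = classification_error(net, X_val, labels_val)
        if val_err < best_err:
            best_err = val_err
            best_weights = [(l.W.copy(), l.b.copy()) for l in net.layers]
            patience_left = 10
        else:
            patience_left -= 1
            if patience_left == 0:
                break
    if best_weights is not None:
        for layer, (W, b) in zip(net.layers, best_weights):
            layer.W, layer.b = W, b
    return record


def run_experiment(config: ExperimentConfig) -> List[RunRecord]:
    """Run one experiment cell: one record per seed, deterministic per seed."""
    cfg = config.resolved()
    data = _load_task_data(cfg)
    return [_run_single_seed(cfg, data, seed) for seed in cfg.seeds]


def final_value(record: RunRecord, which: str = "test") -> float:
    """The run's summary metric: last-epoch value, except MNIST/CIFAR where
    the test error is averaged over the last 10 recorded epochs."""
    series = record.test_metric if which == "test" else record.train_metric
    if record.config.get("task") in ("mnist", "cifar10") and which == "test":
        return float(np.mean(series[-10:]))
    return float(series[-1])


def summarize(records: List[RunRecord], which: str = "test") -> pd.DataFrame:
    """Mean +- std of the summary metric per (topology, dropout/DA, algorithm).

    Columns follow the conventional ordering bp, fa, dfa, sdfa, drtp,
    shallow (present algorithms only); a single seed reports std 0.
    """
    rows = []
    for r in records:
        cfg = r.config
        regime = "DA" if cfg.get("data_augmentation") else f"DO {cfg.get('dropout', 0.0)}"
        rows.append(
            {
                "topology": cfg.get("topology"),
                "regime": regime,
                "algorithm": r.algorithm,
                "value": final_value(r, which),
            }
        )
    df = pd.DataFrame(rows)
    g = df.groupby(["topology", "regime", "algorithm"])["value"]
    stats = g.agg(["mean", "std", "count"]).reset_index()
    stats["std"] = stats["std"].fillna(0.0)
    stats["cell"] = stats.apply(lambda r: f"{r['mean']:.2f} ± {r['std']:.2f}", axis=1)
    table = stats.pivot(index=["topology", "regime"], columns="algorithm", values="cell")
    cols = [a for a in ALGO_ORDER if a in table.columns]
    return table[cols]
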