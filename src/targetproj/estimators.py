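"""Scikit-learn style estimators over the functional training core.

:class:`TargetProjectionClassifier` and :class:`TargetProjectionRegressor`
train fully-connected networks with one of the six strategies
(``bp``/``fa``/``dfa``/``sdfa``/``drtp``/``shallow``).  They follow the
sklearn estimator contract (``fit``/``predict``/``get_params``, fitted
attributes with trailing underscores, input validation) and compose with
pipelines and model selection.  Convolutional topologies are built through
the functional API (:func:`targetproj.network.init_network`) rather than
through these estimators.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.preprocessing import LabelEncoder
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .feedback import ALGORITHMS, make_feedback, target_onehot
from .network import Dense, forward, init_network
from .training import train_network


class _TargetProjectionBase(BaseEstimator):
    """Shared plumbing: topology construction, seeding, training loop."""

    def __init__(
        self,
        algorithm: str = "drtp",
        hidden_layer_sizes: Tuple[int, ...] = (500, 500),
        hidden_activation: str = "tanh",
        learning_rate: float = 5e-4,
        optimizer: str = "sgd",
        batch_size: int = 50,
        max_epochs: int = 100,
        dropout: float = 0.0,
        weight_init: str = "auto",
        dtype: str = "float64",
        random_state: Optional[int] = None,
    ):
        self.algorithm = algorithm
        self.hidden_layer_sizes = hidden_layer_sizes
        self.hidden_activation = hidden_activation
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.dropout = dropout
        self.weight_init = weight_init
        self.dtype = dtype
        self.random_state = random_state

    def _resolve_init(self) -> str:
        """'auto': He uniform for bp/shallow, zeros for the feedback-alignment
        family (whose fixed random feedback matrices break the symmetry that
        zero initialisation would otherwise lock in)."""
        if self.weight_init != "auto":
            return self.weight_init
        return "he_uniform" if self.algorithm in ("bp", "shallow") else "zeros"

    def _fit_network(self, X, Y, labels, loss_kind, output_activation):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        dtype = np.dtype(self.dtype).type
        rng = np.random.default_rng(self.random_state)
        net_seed, fb_seed, shuf_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
        topology = [X.shape[1]]
        topology += [Dense(int(h), self.hidden_activation) for h in self.hidden_layer_sizes]
        topology += [Dense(Y.shape[1], output_activation)]
        net = init_network(topology, scheme=self._resolve_init(), seed=net_seed, dtype=dtype)
        ensemble = make_feedback(self.algorithm, net, seed=fb_seed, dtype=dtype)
        record = train_network(
            net,
            ensemble,
            np.asarray(X, dtype=dtype),
            np.asarray(Y, dtype=dtype),
            loss_kind,
            self.learning_rate,
            self.max_epochs,
            self.batch_size,
            optimizer=self.optimizer,
            dropout_p=self.dropout,
            rng=np.random.default_rng(shuf_seed),
            labels=labels,
            eval_every=None,
        )
        self.network_ = net
        self.feedback_ = ensemble
        self.n_features_in_ = X.shape[1]
        self.loss_curve_ = list(record.train_metric)
        return self

    def _decision(self, X):
        check_is_fitted(self, "network_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the estimator was fitted with "
                f"{self.n_features_in_}"
            )
        trace = forward(self.network_, X.astype(self.network_.layers[0].W.dtype), train=False)
        return trace.ys[-1]


class TargetProjectionClassifier(ClassifierMixin, _TargetProjectionBase):
    """Multi-layer classifier trained without backpropagated errors.

    The hidden layers are updated from a fixed random projection of a
    C-dimensional teaching vector — the error (``dfa``), its sign
    (``sdfa``), or the one-hot target itself (``drtp``, which needs neither
    a feedback pathway nor a completed forward pass) — while ``bp``, ``fa``
    and ``shallow`` are included as reference strategies.  The output layer
    is always trained with the exact cross-entropy gradient.

    Parameters
    ----------
    algorithm : {'bp', 'fa', 'dfa', 'sdfa', 'drtp', 'shallow'}
    hidden_layer_sizes : tuple of int
    output_activation : {'sigmoid', 'softmax'}
        Paired with the matching loss (BCE / CCE); both keep outputs
        strictly inside (0, 1), which is what makes the class label a
        sufficient statistic for the error sign.
    weight_init : {'auto', 'he_uniform', 'zeros'}
    random_state : int, optional
        Seeds network initialisation, feedback matrices, shuffling, dropout.

    Attributes
    ----------
    network_ : the trained :class:`~targetproj.network.Network`
    feedback_ : the fixed random matrices drawn for the run
    classes_ : class labels seen in fit
    """

    def __init__(
        self,
        algorithm: str = "drtp",
        hidden_layer_sizes: Tuple[int, ...] = (500, 500),
        hidden_activation: str = "tanh",
        output_activation: str = "sigmoid",
        learning_rate: float = 5e-4,
        optimizer: str = "sgd",
        batch_size: int = 50,
        max_epochs: int = 100,
        dropout: float = 0.0,
        weight_init: str = "auto",
        dtype: str = "float64",
        random_state: Optional[int] = None,
    ):
        super().__init__(
            algorithm=algorithm,
            hidden_layer_sizes=hidden_layer_sizes,
            hidden_activation=hidden_activation,
            learning_rate=learning_rate,
            optimizer=optimizer,
            batch_size=batch_size,
            max_epochs=max_epochs,
            dropout=dropout,
            weight_init=weight_init,
            dtype=dtype,
            random_state=random_state,
        )
        self.output_activation = output_activation

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self._label_encoder_ = LabelEncoder().fit(y)
        self.classes_ = self._label_encoder_.classes_
        labels = self._label_encoder_.transform(y)
        Y = target_onehot(labels, len(self.classes_))
        loss_kind = "bce" if self.output_activation == "sigmoid" else "cce"
        return self._fit_network(X, Y, labels, loss_kind, self.output_activation)

    def predict_proba(self, X):
        """Per-class scores; softmax outputs sum to one, sigmoid outputs are
        normalised to sum to one per sample."""
        out = self._decision(X)
        if self.output_activation == "sigmoid":
            out = out / out.sum(axis=1, keepdims=True)
        return out

    def predict(self, X):
        scores = self._decision(X)
        return self.classes_[np.argmax(scores, axis=1)]


class TargetProjectionRegressor(RegressorMixin, _TargetProjectionBase):
    """Multi-output regressor counterpart (MSE loss, tanh or linear output).

    ``drtp`` is not available here: projecting the raw target only stands in
    for the error sign when outputs are bounded in (0, 1), i.e. in
    classification.  Use ``sdfa`` for the sign-based strategy on regression.
    """

    def __init__(
        self,
        algorithm: str = "dfa",
        hidden_layer_sizes: Tuple[int, ...] = (100, 100),
        hidden_activation: str = "tanh",
        output_activation: str = "tanh",
        learning_rate: float = 5e-4,
        optimizer: str = "sgd",
        batch_size: int = 50,
        max_epochs: int = 100,
        dropout: float = 0.0,
        weight_init: str = "auto",
        dtype: str = "float64",
        random_state: Optional[int] = None,
    ):
        super().__init__(
            algorithm=algorithm,
            hidden_layer_sizes=hidden_layer_sizes,
            hidden_activation=hidden_activation,
            learning_rate=learning_rate,
            optimizer=optimizer,
            batch_size=batch_size,
            max_epochs=max_epochs,
            dropout=dropout,
            weight_init=weight_init,
            dtype=dtype,
            random_state=random_state,
        )
        self.output_activation = output_activation

    def fit(self, X, y):
        X, y = check_X_y(X, y, multi_output=True)
        if self.algorithm == "drtp":
            raise ValueError(
                "drtp requires one-hot classification targets; use "
                "TargetProjectionClassifier or algorithm='sdfa'"
            )
        Y = y[:, None] if y.ndim == 1 else y
        self._single_output_ = y.ndim == 1
        return self._fit_network(X, Y, None, "mse", self.output_activation)

    def predict(self, X):
        out = self._decision(X)
        return out[:, 0] if self._single_output_ else out
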