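"""Modulatory signals and weight updates for the six training strategies.

The strategies differ only in how the per-layer modulatory signals
dz_k = dy_k * f'(z_k) are obtained for the hidden layers:

* ``bp``      dy_k = W_{k+1}^T dz_{k+1}          (exact loss gradient)
* ``fa``      dy_k = B_k dz_{k+1}                (fixed random feedback weights)
* ``dfa``     dy_k = B_k^T e                     (direct projection of the error)
* ``sdfa``    dy_k = B_k^T sign(e)               (direct projection of the error sign)
* ``drtp``    dy_k = B_k^T y*                    (direct projection of the target)
* ``shallow`` dy_k = 0                           (frozen hidden layers)

with e = y* - y_K.  The output layer is identical across strategies:
dz_K = (y* - y_K)/C for sigmoid+BCE or softmax+CCE (the exact negative loss
gradient), and all weight updates are applied as ascent,
W_k += eta * dz_k y_{k-1}^T, accumulated (summed) over the minibatch.

For classification, dy_k under DRTP depends only on (B_k, y*): it is a
label-dependent row selection of B_k, computable before any deeper layer
has been evaluated (no update locking, no weight transport).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .activations import activation_derivative
from .losses import LOSS_ACTIVATIONS
from .network import (
    ActivationTrace,
    ConvLayer,
    DenseLayer,
    Network,
    _col2im,
    _im2col,
    effective_derivative,
)

ALGORITHMS = ("bp", "fa", "dfa", "sdfa", "drtp", "shallow")

#: strategy registry: algorithm name -> whether it uses direct feedback
#: matrices (C x N_k), per-hop matrices (FA), or none
DIRECT_ALGOS = ("dfa", "sdfa", "drtp")


# ---------------------------------------------------------------------------
# targets and error signs
# ---------------------------------------------------------------------------

def target_onehot(label, C: int) -> np.ndarray:
    """One-hot encode a class index (or an array of them) among C classes."""
    labels = np.atleast_1d(np.asarray(label))
    if labels.ndim != 1:
        raise ValueError("labels must be a scalar or 1-D array")
    if np.any((labels < 0) | (labels >= C)):
        raise ValueError(f"label out of range [0, {C})")
    out = np.zeros((labels.size, C))
    out[np.arange(labels.size), labels] = 1.0
    return out[0] if np.isscalar(label) or np.asarray(label).ndim == 0 else out


def error_sign(y_out: np.ndarray, label) -> np.ndarray:
    """Sign of the error e = y* - y_K for bounded (0,1) outputs.

    Equals +1 at the true-class entry and -1 elsewhere, independent of the
    output magnitudes — which is why it is known before the forward pass.
    """
    y_out = np.atleast_2d(np.asarray(y_out))
    if np.any(y_out <= 0.0) or np.any(y_out >= 1.0):
        raise ValueError("outputs must lie strictly in (0, 1) for the class-dependent error sign")
    labels = np.atleast_1d(np.asarray(label))
    C = y_out.shape[-1]
    s = -np.ones((labels.size, C))
    s[np.arange(labels.size), labels] = 1.0
    return s[0] if np.asarray(label).ndim == 0 else s


# ---------------------------------------------------------------------------
# feedback ensembles
# ---------------------------------------------------------------------------

@dataclass
class FeedbackEnsemble:
    """The fixed random matrices B_k of an algorithm (drawn once, never updated).

    For ``fa``, ``Bs[k]`` has the shape of W_{k+1} (one matrix per feedback
    hop, used in place of W_{k+1}^T).  For the direct algorithms
    (``dfa``/``sdfa``/``drtp``), ``Bs[k]`` is C x N_k, projecting a
    C-dimensional vector onto hidden layer k's flattened output.  ``bp`` and
    ``shallow`` carry no matrices.
    """

    algorithm: str
    Bs: Dict[int, np.ndarray] = field(default_factory=dict)
    seed: Optional[int] = None


def make_feedback(algorithm: str, net: Network, seed: Optional[int] = None,
                  dtype=np.float64) -> FeedbackEnsemble:
    """Draw the fixed random connectivity matrices for ``algorithm``.

    Entries are He-uniform: U(-sqrt(6/fan_in), sqrt(6/fan_in)).  For FA the
    fan_in is that of the forward matrix the hop replaces; for the direct
    algorithms it is C, the dimension of the projected vector.
    """
    algorithm = algorithm.lower()
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    ens = FeedbackEnsemble(algorithm=algorithm, seed=seed)
    if algorithm in ("bp", "shallow"):
        return ens
    rng = np.random.default_rng(seed)
    C = net.output_dim
    if algorithm == "fa":
        for k in range(1, net.K):  # hop from layer k+1 down to k
            nxt = net.layers[k]  # layer k+1 (0-based list)
            bound = np.sqrt(6.0 / nxt.fan_in)
            ens.Bs[k] = rng.uniform(-bound, bound, size=nxt.W.shape).astype(dtype)
    else:
        bound = np.sqrt(6.0 / C)
        for k in range(1, net.K):
            n_k = net.layers[k - 1].out_size
            ens.Bs[k] = rng.uniform(-bound, bound, size=(C, n_k)).astype(dtype)
    return ens


def drtp_hidden_delta(ensemble: FeedbackEnsemble, y_star: np.ndarray, k: int) -> np.ndarray:
    """dy_k = B_k^T y* for DRTP, via label-dependent row selection.

    For one-hot targets this is a pure row lookup of B_k — no matrix-vector
    product — and depends on nothing but (B_k, y*): it can be formed before
    any deeper layer has been evaluated.
    """
    B = ensemble.Bs[k]
    y_star = np.atleast_2d(y_star)
    labels = np.argmax(y_star, axis=1)
    onehot = (y_star.sum(axis=1) == 1.0) & (
        y_star[np.arange(y_star.shape[0]), labels] == 1.0
    )
    if np.all(onehot):
        return B[labels]
    return y_star @ B


# ---------------------------------------------------------------------------
# output delta and modulatory signals
# ---------------------------------------------------------------------------

def output_delta(loss_kind: str, y_out: np.ndarray, y_star: np.ndarray,
                 z_out: Optional[np.ndarray] = None, act: str = "sigmoid") -> np.ndarray:
    """dz_K, the exact negative gradient of the loss w.r.t. z_K.

    * sigmoid+BCE, softmax+CCE: (y* - y_K)/C  (the 1/C comes from the loss prefactor)
    * tanh/linear+MSE: (2/C)(y* - y_K) * f'(z_K)
    """
    loss_kind = loss_kind.lower()
    if loss_kind not in LOSS_ACTIVATIONS:
        raise ValueError(f"unknown loss kind {loss_kind!r}")
    if act not in LOSS_ACTIVATIONS[loss_kind]:
        raise ValueError(f"loss {loss_kind!r} pairs with {LOSS_ACTIVATIONS[loss_kind]}, got {act!r}")
    y_out = np.atleast_2d(y_out)
    y_star = np.atleast_2d(y_star)
    C = y_out.shape[-1]
    e = y_star - y_out
    if loss_kind in ("bce", "cce"):
        return e / C
    if z_out is None:
        raise ValueError("MSE output delta needs the output pre-activations z_K")
    return (2.0 / C) * e * activation_derivative(act, z_out)


@dataclass
class ModulatorySignals:
    """Per-layer dz_k (and the pre-derivative dy_k) for one minibatch.

    Lists are 1-indexed like the trace: entry 0 is None; hidden entries are
    None for ``shallow`` (frozen layers receive no update).
    """

    algorithm: str
    dzs: list = field(default_factory=list)
    dys: list = field(default_factory=list)


def _backward_through(layer, delta_z: np.ndarray, W: np.ndarray, prev_shape) -> np.ndarray:
    """Propagate dz through a layer's weights to the previous layer's output."""
    n = delta_z.shape[0]
    if isinstance(layer, DenseLayer):
        dy_prev = delta_z @ W
        return dy_prev.reshape((n,) + tuple(prev_shape)) if len(prev_shape) > 1 else dy_prev
    # conv: scatter dz back through the kernels
    c, ho, wo = layer.conv_out_shape
    dzf = delta_z.reshape(n, c, ho * wo).transpose(0, 2, 1)  # (n, L, C)
    dcols = dzf @ W.reshape(c, -1)  # (n, L, Cin*k*k)
    return _col2im(dcols, (n,) + tuple(prev_shape), layer.kernel, layer.stride, layer.pad)


def modulatory_signals(
    net: Network,
    ensemble: FeedbackEnsemble,
    trace: ActivationTrace,
    y_star: np.ndarray,
    dz_K: np.ndarray,
) -> ModulatorySignals:
    """Compute dz_k for every layer under the ensemble's algorithm.

    The trace must come from the same network.  dz_K is shared by all
    algorithms (the output layer is always trained the same way); the
    strategies differ only in the hidden-layer deltas.  BP signals here are
    the true loss gradients; for the other algorithms the deeper forward
    weights W_j (j > k) are never read.
    """
    algo = ensemble.algorithm
    K = net.K
    y_star = np.atleast_2d(y_star)
    sig = ModulatorySignals(algorithm=algo)
    sig.dzs = [None] * (K + 1)
    sig.dys = [None] * (K + 1)
    sig.dzs[K] = dz_K

    if algo == "shallow":
        return sig

    if algo in ("bp", "fa"):
        delta = dz_K
        for k in range(K - 1, 0, -1):
            upper = net.layers[k]  # layer k+1
            W = upper.W if algo == "bp" else ensemble.Bs[k]
            prev_shape = net.layers[k - 1].out_shape()
            dy = _backward_through(upper, delta, W, prev_shape)
            sig.dys[k] = dy
            delta = effective_derivative(net.layers[k - 1], trace, k, dy)
            sig.dzs[k] = delta
        return sig

    # direct algorithms: one projection of a C-vector per hidden layer
    if algo == "dfa":
        vec = y_star - np.atleast_2d(trace.ys[K])
    elif algo == "sdfa":
        vec = np.sign(y_star - np.atleast_2d(trace.ys[K]))
    for k in range(1, K):
        if algo == "drtp":
            dy = drtp_hidden_delta(ensemble, y_star, k)
        else:
            dy = vec @ ensemble.Bs[k]
        sig.dys[k] = dy
        sig.dzs[k] = effective_derivative(net.layers[k - 1], trace, k, dy)
    return sig


# ---------------------------------------------------------------------------
# parameter updates
# ---------------------------------------------------------------------------

def _raw_update(layer, dz: np.ndarray, y_prev: np.ndarray):
    """Raw updates (dW, db) = (sum_i dz_i y_i^T, sum_i dz_i) over the minibatch.

    Per-sample contributions are accumulated (summed), the convention of
    streaming/online formulations of these rules: the minibatch is a plain
    accumulation of per-sample updates and the learning rate multiplies the
    accumulated total.
    """
    n = dz.shape[0]
    if isinstance(layer, DenseLayer):
        y_flat = y_prev.reshape(n, -1)
        return dz.T @ y_flat, dz.sum(axis=0)
    c, ho, wo = layer.conv_out_shape
    cols, _ = _im2col(y_prev, layer.kernel, layer.stride, layer.pad)
    dzf = dz.reshape(n, c, ho * wo)
    dW = np.einsum("ncl,nlk->ck", dzf, cols)
    return dW.reshape(layer.W.shape), dzf.sum(axis=2).sum(axis=0)


def apply_updates(
    net: Network,
    signals: ModulatorySignals,
    trace: ActivationTrace,
    optimizer,
    trainable_mask: Optional[list] = None,
    update_biases: bool = True,
) -> None:
    """Apply W_k += transform(dz_k y_{k-1}^T), b_k += transform(dz_k) in place.

    Raw updates are summed over the minibatch.  Layers whose signal is
    None (frozen hidden layers under ``shallow``) or whose entry in
    ``trainable_mask`` is False (fixed random convolutional kernels) are
    left untouched.  ``update_biases=False`` trains weights only (used by
    the bias-free linear-network theory checks).
    """
    for k in range(1, net.K + 1):
        dz = signals.dzs[k]
        if dz is None:
            continue
        if trainable_mask is not None and not trainable_mask[k - 1]:
            continue
        layer = net.layers[k - 1]
        dW, db = _raw_update(layer, dz, trace.ys[k - 1])
        layer.W += optimizer.transform(("W", k), dW)
        if update_biases:
            layer.b += optimizer.transform(("b", k), db)
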