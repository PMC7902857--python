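"""Elementwise activation functions and their analytic derivatives.

Everything in this package computes gradients by hand, so each activation
comes with its closed-form derivative.  Softmax is the one exception: its
Jacobian is never materialised because it is only ever used jointly with
the categorical cross-entropy loss, where the combined output delta has a
simple closed form.
"""

from __future__ import annotations

import numpy as np

VALID_KINDS = ("tanh", "sigmoid", "softmax", "linear")


def activation(kind: str, z: np.ndarray) -> np.ndarray:
    """Apply the activation ``kind`` elementwise to pre-activations ``z``.

    Softmax normalises over the last axis (the class axis).
    """
    if kind == "tanh":
        return np.tanh(z)
    if kind == "sigmoid":
        # numerically stable logistic
        out = np.empty_like(z, dtype=np.result_type(z, np.float32))
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    if kind == "softmax":
        shifted = z - np.max(z, axis=-1, keepdims=True)
        ez = np.exp(shifted)
        return ez / np.sum(ez, axis=-1, keepdims=True)
    if kind == "linear":
        return np.asarray(z)
    raise ValueError(f"unknown activation kind {kind!r}; expected one of {VALID_KINDS}")


def activation_derivative(kind: str, z: np.ndarray) -> np.ndarray:
    """Elementwise f'(z).

    tanh'(z) = 1 - tanh(z)^2, sigmoid'(z) = s(z)(1 - s(z)), linear' = 1.
    Softmax has no elementwise derivative; it is handled jointly with the
    cross-entropy loss at the output layer.
    """
    if kind == "tanh":
        t = np.tanh(z)
        return 1.0 - t * t
    if kind == "sigmoid":
        s = activation("sigmoid", z)
        return s * (1.0 - s)
    if kind == "linear":
        return np.ones_like(z)
    if kind == "softmax":
        raise ValueError(
            "softmax derivative is handled jointly with the categorical "
            "cross-entropy loss; request the output delta instead"
        )
    raise ValueError(f"unknown activation kind {kind!r}; expected one of {VALID_KINDS}")
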