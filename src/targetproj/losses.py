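"""Loss functions.

Both cross-entropy losses carry a 1/C prefactor (C = number of output
units), so the exact negative gradient of the loss with respect to the
output pre-activations is (y* - y_K)/C for sigmoid+BCE and softmax+CCE.
The mean squared error is the plain mean over output dimensions and batch.
"""

from __future__ import annotations

import numpy as np

#: clamp bound for cross-entropy logs; sigmoid can underflow to exact 0/1
#: at float precision even though it is strictly bounded in exact arithmetic
CLAMP_EPS = 1e-12

VALID_LOSSES = ("mse", "bce", "cce")

#: required output activation per loss kind
LOSS_ACTIVATIONS = {"bce": ("sigmoid",), "cce": ("softmax",), "mse": ("tanh", "linear")}


def loss(kind: str, y_out: np.ndarray, y_star: np.ndarray) -> float:
    """Mean loss over a batch.

    Parameters
    ----------
    kind : {'mse', 'bce', 'cce'}
    y_out : (n, C) network outputs; cross-entropy kinds require values in (0, 1)
        (values are clamped to [CLAMP_EPS, 1-CLAMP_EPS] before the log).
    y_star : (n, C) targets; one-hot for classification.
    """
    y_out = np.atleast_2d(np.asarray(y_out))
    y_star = np.atleast_2d(np.asarray(y_star))
    if y_out.shape != y_star.shape:
        raise ValueError(f"output/target shape mismatch: {y_out.shape} vs {y_star.shape}")
    C = y_out.shape[-1]
    if kind == "mse":
        d = y_star - y_out
        return float(np.mean(np.sum(d * d, axis=-1) / C))
    if kind in ("bce", "cce"):
        if np.any(y_out < 0.0) or np.any(y_out > 1.0):
            raise ValueError("cross-entropy losses require outputs within [0, 1]")
        y = np.clip(y_out, CLAMP_EPS, 1.0 - CLAMP_EPS)
        if kind == "bce":
            per = -(y_star * np.log(y) + (1.0 - y_star) * np.log(1.0 - y)).sum(axis=-1) / C
        else:
            per = -(y_star * np.log(y)).sum(axis=-1) / C
        return float(np.mean(per))
    raise ValueError(f"unknown loss kind {kind!r}; expected one of {VALID_LOSSES}")
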