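"""Optimizers carrying the raw updates onto the parameters.

All update rules in this package are written as ascent on (y* - y_K): a raw
update g is *added* to the parameter after the optimizer transform.  SGD
returns lr * g; Adam applies the standard bias-corrected moment transform
to g before scaling by lr.
"""

from __future__ import annotations

import numpy as np


class SGD:
    """Plain stochastic gradient steps: transform(g) = lr * g."""

    def __init__(self, lr: float):
        self.lr = float(lr)

    def transform(self, key, g: np.ndarray) -> np.ndarray:
        return self.lr * g

    def reset(self):
        pass


class Adam:
    """Adam with default hyperparameters (beta1=0.9, beta2=0.999, eps=1e-8).

    Moments are kept per parameter key; the step counter is per key and
    strictly increasing, one step per transform call.
    """

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = float(lr)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m = {}
        self._v = {}
        self._t = {}

    def transform(self, key, g: np.ndarray) -> np.ndarray:
        m = self._m.get(key)
        if m is None:
            m = np.zeros_like(g)
            v = np.zeros_like(g)
            t = 0
        else:
            v = self._v[key]
            t = self._t[key]
        t += 1
        m = self.beta1 * m + (1.0 - self.beta1) * g
        v = self.beta2 * v + (1.0 - self.beta2) * (g * g)
        self._m[key], self._v[key], self._t[key] = m, v, t
        mhat = m / (1.0 - self.beta1**t)
        vhat = v / (1.0 - self.beta2**t)
        return self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def reset(self):
        self._m.clear()
        self._v.clear()
        self._t.clear()


def make_optimizer(kind: str, lr: float):
    kind = kind.lower()
    if kind == "sgd":
        return SGD(lr)
    if kind == "adam":
        return Adam(lr)
    raise ValueError(f"unknown optimizer {kind!r}; expected 'sgd' or 'adam'")
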