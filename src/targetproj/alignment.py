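"""Alignment diagnostics: angles between an algorithm's modulatory signals
and the true-gradient (BP) ones, per layer, over training.

The BP reference signals are computed on the same minibatch with the same
current weights, used purely for measurement and never applied.  Angles are
taken between the flattened per-minibatch dz_k tensors and smoothed with an
exponentially-weighted moving average.
"""

from __future__ import annotations

from typing import Iterable, List, Optional

import numpy as np
import pandas as pd


def angle(dz_alg: np.ndarray, dz_bp: np.ndarray) -> float:
    """Angle in degrees between two same-shaped tensors, flattened.

    Returns NaN (an undefined-angle sentinel, recorded as missing rather
    than zero) if either tensor is all-zero.
    """
    a = np.asarray(dz_alg).ravel()
    b = np.asarray(dz_bp).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {np.asarray(dz_alg).shape} vs {np.asarray(dz_bp).shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    cos = np.dot(a, b) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def ewma(series: Iterable[float], momentum: float = 0.95) -> np.ndarray:
    """Exponentially-weighted moving average, s_t = m s_{t-1} + (1-m) x_t.

    Initialised at the first observation (s_0 = x_0).  NaN entries
    (undefined angles) are carried through without updating the state.
    """
    if not 0.0 <= momentum < 1.0:
        raise ValueError("momentum must lie in [0, 1)")
    x = np.asarray(list(series), dtype=float)
    out = np.empty_like(x)
    state = np.nan
    for i, v in enumerate(x):
        if np.isnan(v):
            out[i] = np.nan
            continue
        state = v if np.isnan(state) else momentum * state + (1.0 - momentum) * v
        out[i] = state
    return out


class AlignmentTrace:
    """Tidy per-step record of per-layer angles against the BP reference."""

    def __init__(self, algorithm: str, momentum: float = 0.95):
        self.algorithm = algorithm
        self.momentum = momentum
        self._rows: List[dict] = []

    def record(self, step: int, layer_angles: dict) -> None:
        """Append one monitoring event; ``layer_angles`` maps layer index -> degrees."""
        for layer, ang in layer_angles.items():
            self._rows.append({"step": step, "layer": layer, "angle": ang})

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame (step, layer, algorithm, angle, angle_smoothed)."""
        df = pd.DataFrame(self._rows, columns=["step", "layer", "angle"])
        if df.empty:
            df["angle_smoothed"] = pd.Series(dtype=float)
        else:
            df = df.sort_values(["layer", "step"], kind="stable").reset_index(drop=True)
            df["angle_smoothed"] = (
                df.groupby("layer")["angle"].transform(lambda s: ewma(s, self.momentum))
            )
        df.insert(2, "algorithm", self.algorithm)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def signal_angles(sig_alg, sig_bp) -> dict:
    """Per-hidden-layer angles between two sets of modulatory signals."""
    out = {}
    K = len(sig_bp.dzs) - 1
    for k in range(1, K):
        if sig_alg.dzs[k] is None or sig_bp.dzs[k] is None:
            continue
        out[k] = angle(sig_alg.dzs[k], sig_bp.dzs[k])
    return out
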