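"""Readers for the two standard external dataset formats: IDX (MNIST) and
CIFAR-10 binary batches.

Both formats are parsed with explicit byte order (IDX is big-endian).
Images are returned as float arrays scaled to [0, 1], channels-first.
"""

from __future__ import annotations

import os
from typing import List, Tuple

import numpy as np

_IDX_DTYPES = {
    0x08: np.uint8,
    0x09: np.int8,
    0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"),
    0x0D: np.dtype(">f4"),
    0x0E: np.dtype(">f8"),
}

MNIST_FILES = (
    "train-images-idx3-ubyte",
    "train-labels-idx1-ubyte",
    "t10k-images-idx3-ubyte",
    "t10k-labels-idx1-ubyte",
)

CIFAR10_TRAIN_FILES = tuple(f"data_batch_{i}.bin" for i in range(1, 6))
CIFAR10_TEST_FILE = "test_batch.bin"


def read_idx(path: str) -> np.ndarray:
    """Parse one IDX file into an ndarray (native byte order)."""
    with open(path, "rb") as f:
        magic = f.read(4)
        if len(magic) != 4 or magic[0] != 0 or magic[1] != 0:
            raise ValueError(f"{path}: bad IDX magic {magic!r}")
        code, ndim = magic[2], magic[3]
        if code not in _IDX_DTYPES:
            raise ValueError(f"{path}: unknown IDX dtype code {code:#04x}")
        dims = np.frombuffer(f.read(4 * ndim), dtype=">i4")
        if dims.size != ndim or np.any(dims <= 0):
            raise ValueError(f"{path}: truncated IDX dimension header")
        data = np.frombuffer(f.read(), dtype=_IDX_DTYPES[code])
    expected = int(np.prod(dims))
    if data.size != expected:
        raise ValueError(f"{path}: expected {expected} elements, found {data.size}")
    return data.reshape(tuple(dims)).astype(data.dtype.newbyteorder("="))


def read_mnist(data_dir: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Load the four MNIST IDX files from ``data_dir``.

    Returns (X_train, y_train, X_test, y_test) with images as float64 in
    [0, 1], shaped (n, 1, 28, 28).
    """
    missing = [f for f in MNIST_FILES if not os.path.exists(os.path.join(data_dir, f))]
    if missing:
        raise FileNotFoundError(
            f"MNIST files missing from {data_dir!r}: {missing}; expected the "
            f"uncompressed IDX files {list(MNIST_FILES)}"
        )
    xs, ys = [], []
    for img_file, lbl_file in (MNIST_FILES[:2], MNIST_FILES[2:]):
        imgs = read_idx(os.path.join(data_dir, img_file))
        labels = read_idx(os.path.join(data_dir, lbl_file))
        if imgs.ndim != 3:
            raise ValueError(f"{img_file}: expected a 3-D image tensor, got {imgs.ndim}-D")
        if imgs.shape[0] != labels.shape[0]:
            raise ValueError(f"{img_file}/{lbl_file}: image/label count mismatch")
        xs.append(imgs[:, None, :, :].astype(np.float64) / 255.0)
        ys.append(labels.astype(np.int64))
    return xs[0], ys[0], xs[1], ys[1]


def read_cifar10_batch(path: str) -> Tuple[np.ndarray, np.ndarray]:
    """Parse one CIFAR-10 binary batch (records of 1 label + 3072 pixel bytes)."""
    raw = np.fromfile(path, dtype=np.uint8)
    if raw.size == 0 or raw.size % 3073:
        raise ValueError(f"{path}: size {raw.size} is not a multiple of 3073 bytes")
    rec = raw.reshape(-1, 3073)
    labels = rec[:, 0].astype(np.int64)
    imgs = rec[:, 1:].reshape(-1, 3, 32, 32).astype(np.float64) / 255.0
    return imgs, labels


def read_cifar10(data_dir: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Load the five CIFAR-10 train batches and the test batch from ``data_dir``."""
    expected: List[str] = list(CIFAR10_TRAIN_FILES) + [CIFAR10_TEST_FILE]
    missing = [f for f in expected if not os.path.exists(os.path.join(data_dir, f))]
    if missing:
        raise FileNotFoundError(
            f"CIFAR-10 files missing from {data_dir!r}: {missing}; expected the "
            f"binary batches {expected}"
        )
    xs, ys = zip(*(read_cifar10_batch(os.path.join(data_dir, f)) for f in CIFAR10_TRAIN_FILES))
    X_test, y_test = read_cifar10_batch(os.path.join(data_dir, CIFAR10_TEST_FILE))
    return np.concatenate(xs), np.concatenate(ys), X_test, y_test
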