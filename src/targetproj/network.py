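"""Network construction and forward evaluation, with no automatic differentiation.

A :class:`Network` is an ordered list of trainable layers.  Two layer kinds
exist: fully-connected (:class:`Dense`) and convolutional (:class:`Conv2D`,
optionally fused with a non-overlapping max-pooling stage).  The forward
pass records everything an update rule is allowed to read — pre-activations
``z_k``, post-activations ``y_k``, dropout masks and pooling argmax indices —
in an :class:`ActivationTrace`.

Layer indexing follows the convention k = 1..K with ``y_0 = x`` the input;
in code, ``trace.ys[k]`` and ``trace.zs[k]`` use the same 1-based offsets
(``trace.ys[0]`` is the input batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .activations import VALID_KINDS, activation, activation_derivative


class DimensionError(ValueError):
    """Inconsistent layer dimensions; carries the offending layer index."""

    def __init__(self, layer_index: int, message: str):
        self.layer_index = layer_index
        super().__init__(f"layer {layer_index}: {message}")


# ---------------------------------------------------------------------------
# layer specifications (what the user writes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dense:
    """Fully-connected layer spec: ``n_out`` units with an activation kind."""

    n_out: int
    activation: str = "tanh"


@dataclass(frozen=True)
class Conv2D:
    """Convolutional layer spec (cross-correlation, zero padding).

    ``pool`` is the kernel-and-stride of an optional non-overlapping max-pool
    applied after the activation.
    """

    channels: int
    kernel: int
    stride: int = 1
    pad: int = 0
    activation: str = "tanh"
    pool: Optional[int] = None


LayerSpec = Union[Dense, Conv2D]


def conv_output_size(size_in: int, kernel: int, stride: int, pad: int) -> int:
    """Closed-form output size: floor((in + 2*pad - kernel)/stride) + 1."""
    return (size_in + 2 * pad - kernel) // stride + 1


# ---------------------------------------------------------------------------
# built layers (what the network holds)
# ---------------------------------------------------------------------------

class DenseLayer:
    trainable = True

    def __init__(self, n_in: int, n_out: int, act: str):
        self.n_in = int(n_in)
        self.n_out = int(n_out)
        self.activation = act
        self.W = np.zeros((n_out, n_in))
        self.b = np.zeros(n_out)

    @property
    def fan_in(self) -> int:
        return self.n_in

    @property
    def out_size(self) -> int:
        return self.n_out

    def out_shape(self):
        return (self.n_out,)


class ConvLayer:
    trainable = True

    def __init__(self, in_shape, spec: Conv2D, index: int):
        c_in, h, w = in_shape
        self.in_shape = tuple(in_shape)
        self.channels = spec.channels
        self.kernel = spec.kernel
        self.stride = spec.stride
        self.pad = spec.pad
        self.activation = spec.activation
        h2 = conv_output_size(h, spec.kernel, spec.stride, spec.pad)
        w2 = conv_output_size(w, spec.kernel, spec.stride, spec.pad)
        if h2 <= 0 or w2 <= 0:
            raise DimensionError(index, f"kernel {spec.kernel} too large for input {in_shape}")
        self.conv_out_shape = (spec.channels, h2, w2)
        self.pool = spec.pool
        if spec.pool is not None:
            if h2 % spec.pool or w2 % spec.pool:
                raise DimensionError(
                    index,
                    f"pool {spec.pool} does not divide feature map {h2}x{w2}",
                )
            self.pooled_shape = (spec.channels, h2 // spec.pool, w2 // spec.pool)
        else:
            self.pooled_shape = self.conv_out_shape
        self.W = np.zeros((spec.channels, c_in, spec.kernel, spec.kernel))
        self.b = np.zeros(spec.channels)

    @property
    def fan_in(self) -> int:
        # kernel volume: inputs per output unit
        c_in = self.in_shape[0]
        return c_in * self.kernel * self.kernel

    @property
    def out_size(self) -> int:
        return int(np.prod(self.pooled_shape))

    def out_shape(self):
        return self.pooled_shape


# ---------------------------------------------------------------------------
# im2col helpers (cross-correlation orientation, zero padding)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kernel: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, L, C*k*k) patch matrix, L = H_out*W_out."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    n, c, ho, wo, _, _ = win.shape
    return (
        win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kernel * kernel),
        (ho, wo),
    )


def _col2im(cols: np.ndarray, x_shape, kernel: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`; used only for delta routing."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, c, kernel, kernel)
    for i in range(kernel):
        for j in range(kernel):
            out[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def _maxpool(y: np.ndarray, k: int):
    """Non-overlapping max pool; returns pooled values and window argmaxes.

    Ties go to the first (lowest flat index) maximum within each window,
    in row-major window order.
    """
    n, c, h, w = y.shape
    win = y.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // k, w // k, k * k)
    arg = np.argmax(win, axis=-1)
    pooled = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
    return pooled, arg


def _unpool(delta: np.ndarray, arg: np.ndarray, k: int, conv_shape) -> np.ndarray:
    """Route deltas at pooled positions back to the stored argmax positions."""
    c, h, w = conv_shape
    n = delta.shape[0]
    win = np.zeros((n, c, h // k, w // k, k * k), dtype=delta.dtype)
    np.put_along_axis(win, arg[..., None], delta[..., None], axis=-1)
    win = win.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
    return win.reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class Network:
    """Ordered trainable layers with forward weights W_k and biases b_k."""

    def __init__(self, input_shape, layers: Sequence[Union[DenseLayer, ConvLayer]]):
        self.input_shape = input_shape if isinstance(input_shape, tuple) else (int(input_shape),)
        self.layers = list(layers)
        if not self.layers:
            raise DimensionError(0, "network needs at least one trainable layer")

    @property
    def K(self) -> int:
        return len(self.layers)

    @property
    def output_dim(self) -> int:
        return self.layers[-1].out_size

    @property
    def input_size(self) -> int:
        return int(np.prod(self.input_shape))

    def n_params(self) -> int:
        return int(sum(l.W.size + l.b.size for l in self.layers))

    def copy(self) -> "Network":
        net = Network.__new__(Network)
        net.input_shape = self.input_shape
        net.layers = []
        for l in self.layers:
            l2 = type(l).__new__(type(l))
            l2.__dict__.update({k: v for k, v in l.__dict__.items()})
            l2.W = l.W.copy()
            l2.b = l.b.copy()
            net.layers.append(l2)
        return net


def init_network(
    topology: Sequence,
    scheme: str = "he_uniform",
    seed: Optional[int] = None,
    dtype=np.float64,
) -> Network:
    """Build and initialise a network.

    Parameters
    ----------
    topology : sequence
        First element is the input shape (an int for flat inputs, or a
        (channels, height, width) tuple for images); the rest are
        :class:`Dense` / :class:`Conv2D` specs.  Plain ints are shorthand
        for ``Dense(n, 'tanh')``.
    scheme : {'he_uniform', 'zeros'}
        ``he_uniform`` draws each weight from U(-b, b) with
        b = sqrt(6 / fan_in) (fan_in = inputs per unit; kernel volume for
        convolutions).  ``zeros`` sets all weights to zero.  Biases are
        always zero-initialised.
    seed : int, optional
        Seeds the draws; identical seeds give bitwise-identical weights.
    """
    if scheme not in ("he_uniform", "zeros"):
        raise ValueError(f"unknown init scheme {scheme!r}")
    if len(topology) < 2:
        raise DimensionError(0, "topology must list an input shape and at least one layer")
    input_shape = topology[0]
    rng = np.random.default_rng(seed)
    layers = []
    cur_shape = input_shape if isinstance(input_shape, tuple) else (int(input_shape),)
    for idx, spec in enumerate(topology[1:], start=1):
        if isinstance(spec, int):
            spec = Dense(spec)
        if isinstance(spec, Dense):
            if spec.activation not in VALID_KINDS:
                raise ValueError(f"layer {idx}: unknown activation {spec.activation!r}")
            layer = DenseLayer(int(np.prod(cur_shape)), spec.n_out, spec.activation)
        elif isinstance(spec, Conv2D):
            if len(cur_shape) != 3:
                raise DimensionError(idx, f"Conv2D needs a (C, H, W) input, got {cur_shape}")
            layer = ConvLayer(cur_shape, spec, idx)
        else:
            raise DimensionError(idx, f"unknown layer spec {spec!r}")
        if scheme == "he_uniform":
            bound = np.sqrt(6.0 / layer.fan_in)
            layer.W = rng.uniform(-bound, bound, size=layer.W.shape).astype(dtype)
        else:
            layer.W = layer.W.astype(dtype)
        layer.b = layer.b.astype(dtype)
        layers.append(layer)
        cur_shape = layer.out_shape()
    return Network(input_shape, layers)


@dataclass
class ActivationTrace:
    """Per-layer record of one forward pass (what update rules may read).

    ``ys[0]`` is the input batch; ``zs[k]``/``ys[k]`` (k >= 1) are the
    pre-/post-activations of layer k.  ``ys[k]`` is the value actually fed
    to layer k+1 (post-pooling, post-dropout).  ``masks[k]`` holds the
    inverted-dropout binary mask for fully-connected hidden layers in train
    mode (None otherwise); ``pool_argmax[k]`` the max-pool argmax indices.
    """

    zs: list = field(default_factory=list)
    ys: list = field(default_factory=list)
    masks: list = field(default_factory=list)
    pool_argmax: list = field(default_factory=list)
    dropout_p: float = 0.0
    train: bool = False

    @property
    def K(self) -> int:
        return len(self.zs) - 1


def forward(
    net: Network,
    x: np.ndarray,
    dropout_p: float = 0.0,
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> ActivationTrace:
    """Evaluate the network on a batch, recording the full activation trace.

    In train mode, inverted dropout (mask, then rescale by 1/(1-p)) is
    applied to fully-connected *hidden* activations only, with the same
    probability for every such layer.  Evaluation mode applies no mask.
    """
    if not 0.0 <= dropout_p < 1.0:
        raise ValueError("dropout_p must lie in [0, 1)")
    x = np.asarray(x)
    if x.ndim == len(net.input_shape):  # single sample
        x = x[None]
    if x.shape[1:] != net.input_shape:
        if len(net.input_shape) == 1 and int(np.prod(x.shape[1:])) == net.input_size:
            x = x.reshape(x.shape[0], -1)  # flat-input net fed image batches
        else:
            raise DimensionError(0, f"input shape {x.shape[1:]} != expected {net.input_shape}")
    use_dropout = train and dropout_p > 0.0
    if use_dropout and rng is None:
        raise ValueError("train-mode dropout needs an rng")

    trace = ActivationTrace(dropout_p=dropout_p, train=train)
    trace.zs.append(None)
    trace.ys.append(x)
    trace.masks.append(None)
    trace.pool_argmax.append(None)
    y = x
    K = net.K
    for k, layer in enumerate(net.layers, start=1):
        mask = None
        arg = None
        if isinstance(layer, DenseLayer):
            flat = y.reshape(y.shape[0], -1)
            if flat.shape[1] != layer.n_in:
                raise DimensionError(k, f"got {flat.shape[1]} inputs, expected {layer.n_in}")
            z = flat @ layer.W.T + layer.b
            out = activation(layer.activation, z)
            if use_dropout and k < K:  # hidden FC layers only
                mask = (rng.random(out.shape) >= dropout_p)
                out = out * mask / (1.0 - dropout_p)
        else:  # ConvLayer
            cols, (ho, wo) = _im2col(y, layer.kernel, layer.stride, layer.pad)
            z = cols @ layer.W.reshape(layer.channels, -1).T + layer.b
            z = z.transpose(0, 2, 1).reshape(y.shape[0], layer.channels, ho, wo)
            out = activation(layer.activation, z)
            if layer.pool is not None:
                out, arg = _maxpool(out, layer.pool)
        trace.zs.append(z)
        trace.ys.append(out)
        trace.masks.append(mask)
        trace.pool_argmax.append(arg)
        y = out
    return trace


def effective_derivative(layer, trace: ActivationTrace, k: int, dy: np.ndarray) -> np.ndarray:
    """Turn a delta at layer k's *output* into the modulatory signal dz_k.

    Folds max-pool routing (delta lands on the stored argmax position),
    the activation derivative, and the inverted-dropout mask.
    """
    z = trace.zs[k]
    if isinstance(layer, ConvLayer):
        dy = dy.reshape((dy.shape[0],) + layer.pooled_shape)
        if layer.pool is not None:
            dy = _unpool(dy, trace.pool_argmax[k], layer.pool, layer.conv_out_shape)
        return dy * activation_derivative(layer.activation, z)
    mask = trace.masks[k]
    if mask is not None:
        dy = dy * mask / (1.0 - trace.dropout_p)
    if layer.activation == "tanh" and mask is None:
        # reuse the stored activation: tanh'(z) = 1 - y^2
        y = trace.ys[k]
        return dy * (1.0 - y * y)
    return dy * activation_derivative(layer.activation, z)
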