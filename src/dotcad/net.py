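"""From-scratch CNN for 32x32 gray-scale slice classification.

Architecture (shape chain asserted at construction):

    input 32x32x1
    -> conv 6 kernels 5x5, stride 1, valid   -> 28x28x6
    -> batch norm (per channel) -> sigmoid
    -> 2x2 average pool, stride 2            -> 14x14x6
    -> conv 12 kernels 5x5x6, stride 1       -> 10x10x12
    -> batch norm -> sigmoid
    -> 2x2 average pool                      -> 5x5x12 = 300
    -> fully connected 300 -> 2 -> softmax

Class encoding is one-hot with index 0 = malignant, index 1 = benign.
Everything — forward passes, analytic backward passes, the SGD-friendly
parameter container — is plain NumPy in float64; convolution is
implemented as cross-correlation (no kernel flip), the universal
convention for learned filters. All backward passes are verified against
central-difference numerical gradients in the test suite.

Arrays use NCHW layout: (batch, channels, height, width).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

INPUT_SIZE = 32
N_CLASSES = 2
BN_EPS = 1e-5
BN_MOMENTUM = 0.9  # running-statistics EMA coefficient
#: Expected per-stage spatial sizes: 32 -> 28 -> 14 -> 10 -> 5 -> 300 -> 2
SHAPE_CHAIN = (32, 28, 14, 10, 5, 300, 2)


@dataclass
class NetworkParams:
    """Every learnable array and batch-norm running statistic."""

    conv1_kernels: np.ndarray  # (6, 1, 5, 5)
    conv1_bias: np.ndarray  # (6,)
    bn1_gamma: np.ndarray  # (6,)
    bn1_beta: np.ndarray
    bn1_running_mean: np.ndarray
    bn1_running_var: np.ndarray
    conv2_kernels: np.ndarray  # (12, 6, 5, 5)
    conv2_bias: np.ndarray  # (12,)
    bn2_gamma: np.ndarray  # (12,)
    bn2_beta: np.ndarray
    bn2_running_mean: np.ndarray
    bn2_running_var: np.ndarray
    fc_weights: np.ndarray  # (300, 2)
    fc_bias: np.ndarray  # (2,)

    #: fields updated by gradient descent (running stats excluded)
    LEARNABLE = (
        "conv1_kernels", "conv1_bias", "bn1_gamma", "bn1_beta",
        "conv2_kernels", "conv2_bias", "bn2_gamma", "bn2_beta",
        "fc_weights", "fc_bias",
    )

    EXPECTED_SHAPES = {
        "conv1_kernels": (6, 1, 5, 5),
        "conv1_bias": (6,),
        "bn1_gamma": (6,),
        "bn1_beta": (6,),
        "bn1_running_mean": (6,),
        "bn1_running_var": (6,),
        "conv2_kernels": (12, 6, 5, 5),
        "conv2_bias": (12,),
        "bn2_gamma": (12,),
        "bn2_beta": (12,),
        "bn2_running_mean": (12,),
        "bn2_running_var": (12,),
        "fc_weights": (300, 2),
        "fc_bias": (2,),
    }

    def __post_init__(self) -> None:
        for f in fields(self):
            arr = getattr(self, f.name)
            expected = self.EXPECTED_SHAPES[f.name]
            if arr.shape != expected:
                raise ValueError(f"{f.name}: expected shape {expected}, got {arr.shape}")
        if np.any(self.bn1_running_var < 0) or np.any(self.bn2_running_var < 0):
            raise ValueError("running variances must be non-negative")
        # 32 -> 28 -> 14 -> 10 -> 5; 5*5*12 feature inputs to the classifier
        assert SHAPE_CHAIN == (32, 28, 14, 10, 5, 300, 2)
        assert self.fc_weights.shape[0] == 5 * 5 * self.conv2_kernels.shape[0]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def copy(self) -> "NetworkParams":
        return NetworkParams(**{k: v.copy() for k, v in self.as_dict().items()})


def init_params(seed: int = 0) -> NetworkParams:
    """Fan-in-scaled uniform initialization (LeCun uniform).

    Kernels and fully-connected weights are drawn from
    U(-sqrt(3/fan_in), sqrt(3/fan_in)), i.e. variance 1/fan_in; biases
    start at 0, batch norm at the identity (gamma 1, beta 0, running
    mean 0, running var 1). Unit pre-activation variance keeps the
    sigmoids responsive without saturating, shortening the initial
    symmetry-breaking plateau. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)

    def uniform(shape: tuple[int, ...], fan_in: int) -> np.ndarray:
        bound = np.sqrt(3.0 / fan_in)
        return rng.uniform(-bound, bound, size=shape)

    return NetworkParams(
        conv1_kernels=uniform((6, 1, 5, 5), 25),
        conv1_bias=np.zeros(6),
        bn1_gamma=np.ones(6),
        bn1_beta=np.zeros(6),
        bn1_running_mean=np.zeros(6),
        bn1_running_var=np.ones(6),
        conv2_kernels=uniform((12, 6, 5, 5), 150),
        conv2_bias=np.zeros(12),
        bn2_gamma=np.ones(12),
        bn2_beta=np.zeros(12),
        bn2_running_mean=np.zeros(12),
        bn2_running_var=np.ones(12),
        fc_weights=uniform((300, 2), 300),
        fc_bias=np.zeros(2),
    )


# ---------------------------------------------------------------------------
# layer forward passes


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Unfold sliding windows into a (N*H'*W', C*kh*kw) matrix.

    Row order is (n, out_row, out_col); column order is (channel, kernel
    row, kernel col), matching ``kernels.reshape(F, -1).T``.
    """
    n, c = x.shape[:2]
    windows = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N,C,H',W',kh,kw)
    hp, wp = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * hp * wp, c * kh * kw)
    return np.ascontiguousarray(cols)


def conv2d_forward(
    x: np.ndarray,
    kernels: np.ndarray,
    biases: np.ndarray,
    return_cols: bool = False,
):
    """Valid cross-correlation with stride 1 (im2col + matrix product).

    x: (N, C, H, W); kernels: (F, C, kh, kw); biases: (F,).
    Returns (N, F, H-kh+1, W-kw+1), or (output, im2col matrix) when
    ``return_cols`` so a training step can reuse the unfolding in the
    backward pass.
    """
    if x.ndim != 4 or kernels.ndim != 4:
        raise ValueError("conv2d_forward expects 4D input and kernels")
    if x.shape[1] != kernels.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, kernels expect {kernels.shape[1]}"
        )
    n, _, h, w = x.shape
    f = kernels.shape[0]
    kh, kw = kernels.shape[2:]
    if kh > h or kw > w:
        raise ValueError("kernel larger than input")
    hp, wp = h - kh + 1, w - kw + 1
    cols = _im2col(x, kh, kw)
    out = cols @ kernels.reshape(f, -1).T + biases
    out = out.reshape(n, hp, wp, f).transpose(0, 3, 1, 2)
    return (out, cols) if return_cols else out


def _col2im(d_cols: np.ndarray, x_shape: tuple[int, ...], kh: int, kw: int) -> np.ndarray:
    """Scatter-add window gradients back onto the input grid (inverse of im2col)."""
    n, c, h, w = x_shape
    hp, wp = h - kh + 1, w - kw + 1
    d_win = d_cols.reshape(n, hp, wp, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    d_x = np.zeros(x_shape)
    for i in range(kh):
        for j in range(kw):
            d_x[:, :, i : i + hp, j : j + wp] += d_win[:, :, :, :, i, j]
    return d_x


def conv2d_backward(
    x: np.ndarray,
    kernels: np.ndarray,
    d_out: np.ndarray,
    cols: Optional[np.ndarray] = None,
    compute_dx: bool = True,
) -> tuple[Optional[np.ndarray], np.ndarray, np.ndarray]:
    """Gradients of a valid stride-1 cross-correlation.

    Returns (d_x, d_kernels, d_biases); d_x is None when ``compute_dx``
    is False (input layer, where it is never used). ``cols`` may pass the
    im2col matrix already built in the forward pass.
    """
    f = kernels.shape[0]
    c = kernels.shape[1]
    kh, kw = kernels.shape[2:]
    if cols is None:
        cols = _im2col(x, kh, kw)
    d_out_rows = d_out.transpose(0, 2, 3, 1).reshape(-1, f)  # (N*H'*W', F)
    d_kernels = (cols.T @ d_out_rows).T.reshape(f, c, kh, kw)
    d_biases = d_out.sum(axis=(0, 2, 3))
    d_x = None
    if compute_dx:
        d_cols = d_out_rows @ kernels.reshape(f, -1)  # (N*H'*W', C*kh*kw)
        d_x = _col2im(d_cols, x.shape, kh, kw)
    return d_x, d_kernels, d_biases


def batchnorm_forward(
    x: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    mode: str = "train",
    eps: float = BN_EPS,
    momentum: float = BN_MOMENTUM,
) -> tuple[np.ndarray, Optional[dict], np.ndarray, np.ndarray]:
    """Per-channel batch normalization over (N, H, W).

    Train mode standardizes by the batch statistics, applies the learned
    affine (gamma, beta), and updates the running statistics by
    exponential moving average (biased variance, same as used for
    normalization). Inference mode standardizes by the running
    statistics, so the output of one sample does not depend on the rest
    of the batch.

    Returns (out, cache, new_running_mean, new_running_var); cache is
    None in inference mode.
    """
    if mode not in ("train", "infer"):
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    if mode == "train":
        if x.shape[0] < 2:
            raise ValueError("batch normalization in train mode needs batch size >= 2")
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        inv_std = 1.0 / np.sqrt(var + eps)
        x_hat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = gamma[None, :, None, None] * x_hat + beta[None, :, None, None]
        new_mean = momentum * running_mean + (1 - momentum) * mean
        new_var = momentum * running_var + (1 - momentum) * var
        cache = {"x_hat": x_hat, "inv_std": inv_std, "gamma": gamma}
        return out, cache, new_mean, new_var
    inv_std = 1.0 / np.sqrt(running_var + eps)
    x_hat = (x - running_mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma[None, :, None, None] * x_hat + beta[None, :, None, None]
    return out, None, running_mean, running_var


def batchnorm_backward(d_out: np.ndarray, cache: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients through train-mode batch normalization."""
    if cache is None:
        raise ValueError("batchnorm_backward requires the train-mode forward cache")
    x_hat = cache["x_hat"]
    inv_std = cache["inv_std"]
    gamma = cache["gamma"]
    m = d_out.shape[0] * d_out.shape[2] * d_out.shape[3]
    d_gamma = (d_out * x_hat).sum(axis=(0, 2, 3))
    d_beta = d_out.sum(axis=(0, 2, 3))
    d_xhat = d_out * gamma[None, :, None, None]
    sum_dxhat = d_xhat.sum(axis=(0, 2, 3))[None, :, None, None]
    sum_dxhat_xhat = (d_xhat * x_hat).sum(axis=(0, 2, 3))[None, :, None, None]
    d_x = (inv_std[None, :, None, None] / m) * (m * d_xhat - sum_dxhat - x_hat * sum_dxhat_xhat)
    return d_x, d_gamma, d_beta


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function, saturating without overflow."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid_backward(d_out: np.ndarray, s: np.ndarray) -> np.ndarray:
    """d_out * s * (1 - s), with s the forward-pass output."""
    return d_out * s * (1.0 - s)


def avgpool_forward(x: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 average pooling, stride 2."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"average pooling needs even spatial dims, got {h}x{w}")
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool_backward(d_out: np.ndarray) -> np.ndarray:
    """Spread each pooled gradient equally (g/4) over its 2x2 window."""
    return np.repeat(np.repeat(d_out, 2, axis=2), 2, axis=3) / 4.0


def fc_softmax_forward(
    features: np.ndarray, weights: np.ndarray, bias: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Affine map to class logits followed by softmax.

    features: (N, D) with D matching weights (D, K). Returns
    (probabilities, logits); probabilities are positive and each row sums
    to 1. Index 0 = malignant, 1 = benign.
    """
    if features.ndim != 2 or features.shape[1] != weights.shape[0]:
        raise ValueError(
            f"feature dim {features.shape} incompatible with weights {weights.shape}"
        )
    logits = features @ weights + bias
    shifted = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(shifted)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return probs, logits


def fc_backward(
    features: np.ndarray, weights: np.ndarray, d_logits: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the affine classifier: (d_features, d_weights, d_bias)."""
    d_weights = features.T @ d_logits
    d_bias = d_logits.sum(axis=0)
    d_features = d_logits @ weights.T
    return d_features, d_weights, d_bias


def cross_entropy_loss(
    probs: np.ndarray, one_hot: np.ndarray, eps: float = 1e-12
) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood and its gradient w.r.t. the logits.

    With softmax outputs the logit gradient has the closed form
    (probs - one_hot) / batch_size. Probabilities are clamped at ``eps``
    before the log so a confidently wrong prediction yields a large but
    finite loss.
    """
    n = probs.shape[0]
    loss = float(-np.sum(one_hot * np.log(np.clip(probs, eps, None))) / n)
    d_logits = (probs - one_hot) / n
    return loss, d_logits


# ---------------------------------------------------------------------------
# full network


def forward(
    params: NetworkParams, x: np.ndarray, mode: str = "infer"
) -> tuple[np.ndarray, Optional[dict]]:
    """Full forward pass.

    x: (N, 1, 32, 32). Returns (class probabilities (N, 2), cache).
    In train mode the cache holds every intermediate needed by
    :func:`backward` and the batch-norm running statistics are updated in
    place on ``params``; in inference mode the cache is None and the
    output of a sample is independent of its batch companions.
    """
    if x.ndim != 4 or x.shape[1:] != (1, INPUT_SIZE, INPUT_SIZE):
        raise ValueError(f"expected input (N, 1, 32, 32), got {x.shape}")
    train_mode = mode == "train"
    c1 = conv2d_forward(x, params.conv1_kernels, params.conv1_bias, return_cols=train_mode)
    cols1 = None
    if train_mode:
        c1, cols1 = c1  # (N,6,28,28)
    b1, bn1_cache, rm1, rv1 = batchnorm_forward(
        c1, params.bn1_gamma, params.bn1_beta,
        params.bn1_running_mean, params.bn1_running_var, mode=mode,
    )
    s1 = sigmoid(b1)
    p1 = avgpool_forward(s1)  # (N,6,14,14)
    c2 = conv2d_forward(p1, params.conv2_kernels, params.conv2_bias, return_cols=train_mode)
    cols2 = None
    if train_mode:
        c2, cols2 = c2  # (N,12,10,10)
    b2, bn2_cache, rm2, rv2 = batchnorm_forward(
        c2, params.bn2_gamma, params.bn2_beta,
        params.bn2_running_mean, params.bn2_running_var, mode=mode,
    )
    s2 = sigmoid(b2)
    p2 = avgpool_forward(s2)  # (N,12,5,5)
    feats = p2.reshape(p2.shape[0], -1)  # (N,300)
    probs, _ = fc_softmax_forward(feats, params.fc_weights, params.fc_bias)
    if mode == "train":
        params.bn1_running_mean, params.bn1_running_var = rm1, rv1
        params.bn2_running_mean, params.bn2_running_var = rm2, rv2
        cache = {
            "x": x, "p1": p1, "s1": s1, "s2": s2, "p2_shape": p2.shape,
            "bn1": bn1_cache, "bn2": bn2_cache, "feats": feats,
            "cols1": cols1, "cols2": cols2,
        }
        return probs, cache
    return probs, None


def backward(params: NetworkParams, cache: dict, d_logits: np.ndarray) -> dict[str, np.ndarray]:
    """Backpropagate a logit gradient through the whole network.

    Returns a dict keyed like ``NetworkParams.LEARNABLE``.
    """
    if cache is None:
        raise ValueError("backward requires the train-mode forward cache")
    d_feats, d_fc_w, d_fc_b = fc_backward(cache["feats"], params.fc_weights, d_logits)
    d_p2 = d_feats.reshape(cache["p2_shape"])
    d_s2 = avgpool_backward(d_p2)
    d_b2 = sigmoid_backward(d_s2, cache["s2"])
    d_c2, d_g2, d_be2 = batchnorm_backward(d_b2, cache["bn2"])
    d_p1, d_k2, d_cb2 = conv2d_backward(
        cache["p1"], params.conv2_kernels, d_c2, cols=cache["cols2"]
    )
    d_s1 = avgpool_backward(d_p1)
    d_b1 = sigmoid_backward(d_s1, cache["s1"])
    d_c1, d_g1, d_be1 = batchnorm_backward(d_b1, cache["bn1"])
    _, d_k1, d_cb1 = conv2d_backward(
        cache["x"], params.conv1_kernels, d_c1, cols=cache["cols1"], compute_dx=False
    )
    return {
        "conv1_kernels": d_k1, "conv1_bias": d_cb1,
        "bn1_gamma": d_g1, "bn1_beta": d_be1,
        "conv2_kernels": d_k2, "conv2_bias": d_cb2,
        "bn2_gamma": d_g2, "bn2_beta": d_be2,
        "fc_weights": d_fc_w, "fc_bias": d_fc_b,
    }


def loss_and_grads(
    params: NetworkParams, x: np.ndarray, one_hot: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Train-mode forward + backward: cross-entropy loss and all gradients."""
    probs, cache = forward(params, x, mode="train")
    loss, d_logits = cross_entropy_loss(probs, one_hot)
    return loss, backward(params, cache, d_logits)
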