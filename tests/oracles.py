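"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written as the most direct, obviously-correct computation
(nested loops, pairwise enumeration, finite differences) and shares no
code with the library paths it checks.
"""

from __future__ import annotations

import numpy as np


def bilinear_resize_loops(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Per-output-pixel corner-aligned bilinear interpolation, 4 neighbours."""
    in_h, in_w = image.shape
    out = np.zeros((out_h, out_w))
    for i in range(out_h):
        for j in range(out_w):
            r = 0.0 if out_h == 1 or in_h == 1 else i * (in_h - 1) / (out_h - 1)
            c = 0.0 if out_w == 1 or in_w == 1 else j * (in_w - 1) / (out_w - 1)
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            r0, c0 = min(r0, in_h - 1), min(c0, in_w - 1)
            r1, c1 = min(r0 + 1, in_h - 1), min(c0 + 1, in_w - 1)
            fr, fc = r - r0, c - c0
            out[i, j] = (
                image[r0, c0] * (1 - fr) * (1 - fc)
                + image[r0, c1] * (1 - fr) * fc
                + image[r1, c0] * fr * (1 - fc)
                + image[r1, c1] * fr * fc
            )
    return out


def conv2d_loops(x: np.ndarray, kernels: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Four-nested-loop valid cross-correlation."""
    n, c, h, w = x.shape
    f, _, kh, kw = kernels.shape
    out = np.zeros((n, f, h - kh + 1, w - kw + 1))
    for b in range(n):
        for k in range(f):
            for i in range(h - kh + 1):
                for j in range(w - kw + 1):
                    out[b, k, i, j] = np.sum(x[b, :, i : i + kh, j : j + kw] * kernels[k]) + biases[k]
    return out


def batchnorm_twopass(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float) -> np.ndarray:
    """Per-channel standardization with explicit two-pass mean/variance."""
    out = np.zeros_like(x)
    for ch in range(x.shape[1]):
        vals = x[:, ch]
        mean = vals.sum() / vals.size
        var = ((vals - mean) ** 2).sum() / vals.size
        out[:, ch] = gamma[ch] * (vals - mean) / np.sqrt(var + eps) + beta[ch]
    return out


def softmax_exp_normalize(logits: np.ndarray) -> np.ndarray:
    ex = np.exp(logits)
    return ex / ex.sum(axis=1, keepdims=True)


def auc_pairwise(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """O(n^2) Mann-Whitney statistic with half credit for ties."""
    pos = scores[is_positive]
    neg = scores[~is_positive]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def numerical_gradient(f, arr: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar f w.r.t. every entry of arr."""
    grad = np.zeros_like(arr, dtype=float)
    it = np.nditer(arr, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad


def max_relative_error(a: np.ndarray, b: np.ndarray) -> float:
    """Elementwise |a-b| / (|a|+|b|), floored at 1e-6 so analytically zero
    gradients (e.g. a conv bias followed by mean-subtracting batch norm)
    compare by absolute finite-difference noise instead of 0/0."""
    denom = np.maximum(np.abs(a) + np.abs(b), 1e-6)
    return float(np.max(np.abs(a - b) / denom))
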