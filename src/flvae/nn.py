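"""Minimal numpy neural-network primitives for the convolutional VAE.

Implements exactly what the model needs: 2D convolution and transposed
convolution (square kernels, symmetric padding), dense layers, ReLU,
numerically stable sigmoid / binary cross-entropy, and an Adam optimizer.
Forward and backward passes are hand-derived; every backward is covered by a
finite-difference gradient test in the suite.

Layout conventions: feature maps are ``(B, C, H, W)`` float arrays, dense
activations ``(B, F)``.  Convolution weights are ``(C_out, C_in, K, K)``;
transposed-convolution weights are ``(C_in, C_out, K, K)`` so that a
transposed conv is literally the adjoint of the matching strided conv.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_backward",
    "conv_transpose2d",
    "conv_transpose2d_backward",
    "relu",
    "relu_backward",
    "sigmoid",
    "softplus",
    "bce_with_logits",
    "Adam",
]


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Strided 2D convolution (cross-correlation), x:(B,Ci,H,W) w:(Co,Ci,K,K)."""
    B, Ci, H, W = x.shape
    Co, Ci2, K, _ = w.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input has {Ci}, kernel expects {Ci2}")
    Ho, Wo = _out_size(H, K, stride, pad), _out_size(W, K, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # accumulate in (B, Ho, Wo, Co) so each tap is a single GEMM
    out = np.zeros((B, Ho, Wo, Co), dtype=x.dtype)
    for di in range(K):
        for dj in range(K):
            xs = xp[:, :, di : di + stride * (Ho - 1) + 1 : stride,
                    dj : dj + stride * (Wo - 1) + 1 : stride]
            out += np.tensordot(xs, w[:, :, di, dj], axes=([1], [1]))
    out += b
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def conv2d_backward(dout, x, w, stride, pad):
    """Gradients of conv2d: returns (dx, dw, db). dout:(B,Co,Ho,Wo)."""
    B, Ci, H, W = x.shape
    Co, _, K, _ = w.shape
    _, _, Ho, Wo = dout.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    g = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))  # (B,Ho,Wo,Co)
    for di in range(K):
        for dj in range(K):
            sl_i = slice(di, di + stride * (Ho - 1) + 1, stride)
            sl_j = slice(dj, dj + stride * (Wo - 1) + 1, stride)
            xs = xp[:, :, sl_i, sl_j]
            # dw[o,c,di,dj] = sum_{b,i,j} g[b,i,j,o] * xs[b,c,i,j]
            dw[:, :, di, dj] = np.tensordot(g, xs, axes=([0, 1, 2], [0, 2, 3]))
            # dx contribution: (B,Ho,Wo,Ci)
            dxp[:, :, sl_i, sl_j] += np.tensordot(g, w[:, :, di, dj],
                                                  axes=([3], [0])).transpose(0, 3, 1, 2)
    db = dout.sum(axis=(0, 2, 3))
    dx = dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp
    return np.ascontiguousarray(dx), dw, db


def conv_transpose2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int,
                     pad: int, out_size: int) -> np.ndarray:
    """Transposed 2D convolution, x:(B,Ci,H,W) w:(Ci,Co,K,K) -> (B,Co,out,out).

    Adjoint of ``conv2d`` with the same stride/pad whose input is
    ``out_size`` x ``out_size``; ``out_size`` resolves the usual output-padding
    ambiguity (stride 2, k 3, pad 1, H->2H uses out_size=2H).
    """
    B, Ci, H, W = x.shape
    Ci2, Co, K, _ = w.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input has {Ci}, kernel expects {Ci2}")
    if _out_size(out_size, K, stride, pad) != H:
        raise ValueError(f"out_size {out_size} inconsistent with input {H}")
    op = np.zeros((B, Co, out_size + 2 * pad, out_size + 2 * pad), dtype=x.dtype)
    xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # (B,H,W,Ci)
    for di in range(K):
        for dj in range(K):
            sl_i = slice(di, di + stride * (H - 1) + 1, stride)
            sl_j = slice(dj, dj + stride * (W - 1) + 1, stride)
            op[:, :, sl_i, sl_j] += np.tensordot(xt, w[:, :, di, dj],
                                                 axes=([3], [0])).transpose(0, 3, 1, 2)
    out = op[:, :, pad : pad + out_size, pad : pad + out_size] if pad else op
    return np.ascontiguousarray(out + b[None, :, None, None])


def conv_transpose2d_backward(dout, x, w, stride, pad):
    """Gradients of conv_transpose2d: returns (dx, dw, db). dout:(B,Co,out,out)."""
    B, Ci, H, W = x.shape
    _, Co, K, _ = w.shape
    dop = np.pad(dout, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    dx = np.zeros((B, H, W, Ci), dtype=x.dtype)
    dw = np.zeros_like(w)
    xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # (B,H,W,Ci)
    for di in range(K):
        for dj in range(K):
            sl_i = slice(di, di + stride * (H - 1) + 1, stride)
            sl_j = slice(dj, dj + stride * (W - 1) + 1, stride)
            gs = dop[:, :, sl_i, sl_j]  # (B,Co,H,W)
            dx += np.tensordot(gs, w[:, :, di, dj], axes=([1], [1]))
            dw[:, :, di, dj] = np.tensordot(xt, gs, axes=([0, 1, 2], [0, 2, 3]))
    db = dout.sum(axis=(0, 2, 3))
    return np.ascontiguousarray(dx.transpose(0, 3, 1, 2)), dw, db


def relu(x):
    return np.maximum(x, 0)


def relu_backward(dout, x):
    return dout * (x > 0)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x):
    return np.logaddexp(np.zeros((), dtype=x.dtype), x)


def bce_with_logits(logits: np.ndarray, target: np.ndarray):
    """Pixel-wise Bernoulli cross-entropy from logits.

    Returns (per_element_loss, dloss_dlogits); the gradient is the familiar
    ``sigmoid(logits) - target``.
    """
    loss = softplus(logits) - target * logits
    return loss, sigmoid(logits) - target


class Adam:
    """Adam optimizer over a dict of named parameter arrays (in-place steps)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
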