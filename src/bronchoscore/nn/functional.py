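"""Fused losses and sampling ops used by the training harnesses."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "softmax_cross_entropy",
    "sigmoid_bce",
    "smooth_l1",
    "softmax_probs",
    "roi_align",
]


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy with integer targets.

    ``logits`` may be (N, C) or (N, C, H, W) with per-pixel targets of shape
    (N, H, W). The gradient is the usual ``(softmax - onehot) / n``.
    """
    data = logits.data
    if data.ndim == 4:
        n, c, h, w = data.shape
        flat = data.transpose(0, 2, 3, 1).reshape(-1, c)
        tgt = np.asarray(targets).reshape(-1)
    else:
        flat = data
        tgt = np.asarray(targets).reshape(-1)
        n = c = None
    shifted = flat - flat.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logsumexp
    count = flat.shape[0]
    loss_val = -logp[np.arange(count), tgt].mean()

    def backward(g):
        probs = np.exp(logp)
        probs[np.arange(count), tgt] -= 1.0
        grad_flat = g * probs / count
        if data.ndim == 4:
            grad = grad_flat.reshape(data.shape[0], data.shape[2], data.shape[3], data.shape[1])
            grad = grad.transpose(0, 3, 1, 2)
        else:
            grad = grad_flat
        logits._accumulate(grad)

    out = Tensor(loss_val)
    if logits.requires_grad or logits._prev:
        out.requires_grad = True
        out._prev = (logits,)
        out._backward = backward
    return out


def softmax_probs(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain (non-differentiable) softmax for inference."""
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid_bce(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (numerically stable fused form)."""
    z = logits.data
    t = np.asarray(targets, dtype=np.float64)
    loss_val = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))

    def backward(g):
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        logits._accumulate(g * (sig - t) / z.size)

    out = Tensor(loss_val)
    if logits.requires_grad or logits._prev:
        out.requires_grad = True
        out._prev = (logits,)
        out._backward = backward
    return out


def smooth_l1(pred: Tensor, targets: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber) loss against a constant target array."""
    diff = pred.data - np.asarray(targets, dtype=np.float64)
    absd = np.abs(diff)
    loss_val = np.mean(np.where(absd < beta, 0.5 * diff**2 / beta, absd - 0.5 * beta))

    def backward(g):
        grad = np.where(absd < beta, diff / beta, np.sign(diff)) / diff.size
        pred._accumulate(g * grad)

    out = Tensor(loss_val)
    if pred.requires_grad or pred._prev:
        out.requires_grad = True
        out._prev = (pred,)
        out._backward = backward
    return out


def roi_align(features: Tensor, box: tuple[float, float, float, float], out_size: int,
              spatial_scale: float = 1.0) -> Tensor:
    """Bilinear crop of one RoI from an (1, C, H, W) feature map.

    ``box`` is [x, y, w, h] in input-image coordinates; ``spatial_scale``
    maps image coordinates onto the feature grid. Returns (1, C, out, out).
    """
    _, c, fh, fw = features.data.shape
    x, y, w, h = box
    x, y, w, h = x * spatial_scale, y * spatial_scale, w * spatial_scale, h * spatial_scale
    w = max(w, 1e-3)
    h = max(h, 1e-3)
    # sample at bin centers
    xs = x + (np.arange(out_size) + 0.5) * w / out_size
    ys = y + (np.arange(out_size) + 0.5) * h / out_size
    xs = np.clip(xs, 0, fw - 1)
    ys = np.clip(ys, 0, fh - 1)
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    x1 = np.minimum(x0 + 1, fw - 1)
    y1 = np.minimum(y0 + 1, fh - 1)
    fx = xs - x0
    fy = ys - y0

    fdat = features.data[0]  # (C, H, W)
    wa = (1 - fy)[:, None] * (1 - fx)[None, :]
    wb = (1 - fy)[:, None] * fx[None, :]
    wc = fy[:, None] * (1 - fx)[None, :]
    wd = fy[:, None] * fx[None, :]
    out_data = (
        fdat[:, y0[:, None], x0[None, :]] * wa
        + fdat[:, y0[:, None], x1[None, :]] * wb
        + fdat[:, y1[:, None], x0[None, :]] * wc
        + fdat[:, y1[:, None], x1[None, :]] * wd
    )[None]

    def backward(g):
        grad = np.zeros_like(features.data)
        g0 = g[0]
        for corner_y, corner_x, wgt in (
            (y0, x0, wa), (y0, x1, wb), (y1, x0, wc), (y1, x1, wd)
        ):
            np.add.at(
                grad[0],
                (slice(None), corner_y[:, None], corner_x[None, :]),
                g0 * wgt,
            )
        features._accumulate(grad)

    out = Tensor(out_data)
    if features.requires_grad or features._prev:
        out.requires_grad = True
        out._prev = (features,)
        out._backward = backward
    return out
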