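"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the inpainting networks: a :class:`Tensor` that
records its parents and a backward closure, plus the functional ops the
architectures need (3x3/1x1 dilated convolution, partial convolution, 2x2
max pooling, 2x2 stride-2 transposed convolution, ReLU, channel
concatenation, dense layers, pooled means and the L1 loss).

Feature maps are laid out ``(N, C, H, W)``.  Convolutions are evaluated as
nine shifted-view matrix products (one per kernel tap) against BLAS, which
profiles faster here than explicit im2col for the small channel counts
these networks use.  Gradients are accumulated in the array dtype of the
forward pass, so float64 gradient checking works alongside float32
training.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "conv2d", "partial_conv2d", "conv_transpose2x2", "maxpool2x2",
           "relu", "concat", "linear", "global_mean_pool", "reshape", "l1_loss",
           "maxpool2x2_array", "upsample2x_array"]


class Tensor:
    """An array plus the bookkeeping needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray, own: bool = False) -> None:
        """Add ``g`` to the gradient; ``own=True`` when the caller hands over
        a freshly allocated array that may be kept without copying."""
        if self.grad is None:
            self.grad = g if own else g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------------------
# raw convolution kernels (no autodiff)

from . import _kernels


def _zero_pad(x: np.ndarray, d: int) -> np.ndarray:
    # np.empty + explicit border zeroing: writes each interior cell once
    N, C, H, W = x.shape
    out = np.empty((N, C, H + 2 * d, W + 2 * d), x.dtype)
    out[:, :, :d, :] = 0
    out[:, :, H + d :, :] = 0
    out[:, :, d : H + d, :d] = 0
    out[:, :, d : H + d, W + d :] = 0
    out[:, :, d : H + d, d : W + d] = x
    return out

#: Use the streaming numba kernels when the in-by-out channel product is at
#: most this; above it the per-tap BLAS products win.  Chosen from
#: benchmarks on 512x128 strips and their pooled levels.
_NUMBA_MAX_CHANNEL_PRODUCT = 512


def _use_numba(x: np.ndarray, W: np.ndarray) -> bool:
    return (
        _kernels.HAVE_NUMBA
        and x.dtype == np.float32
        and W.dtype == np.float32
        and W.shape[0] * W.shape[1] <= _NUMBA_MAX_CHANNEL_PRODUCT
    )


def _conv_raw(
    x: np.ndarray,
    W: np.ndarray,
    b: np.ndarray | None,
    dilation: int,
    xp: np.ndarray | None = None,
) -> np.ndarray:
    """'Same' zero-padded convolution; kernel 1x1 or 3x3 with dilation.

    ``xp`` may pass in the already zero-padded input to share the padding
    between the forward pass and the weight gradient.
    """
    N, C, H, Wd = x.shape
    O, _, kh, kw = W.shape
    if kh == 1 and kw == 1:
        y = np.matmul(W.reshape(O, C)[None], x.reshape(N, C, -1)).reshape(N, O, H, Wd)
        if b is not None:
            y += b[None, :, None, None]
        return y
    d = dilation
    if xp is None:
        xp = _zero_pad(x, d)
    if _use_numba(x, W):
        bias = b if b is not None else np.zeros(O, dtype=np.float32)
        return _kernels.conv_fwd(xp, W, np.ascontiguousarray(bias, np.float32), d, H, Wd)
    y = np.zeros((N, O, H, Wd), dtype=x.dtype)
    yf = y.reshape(N, O, -1)
    for i in range(3):
        for j in range(3):
            sub = xp[:, :, i * d : i * d + H, j * d : j * d + Wd]
            yf += np.matmul(W[:, :, i, j][None], sub.reshape(N, C, -1))
    if b is not None:
        y += b[None, :, None, None]
    return y


def _conv_dw(
    x: np.ndarray,
    dy: np.ndarray,
    kh: int,
    kw: int,
    dilation: int,
    xp: np.ndarray | None = None,
) -> np.ndarray:
    """Weight gradient of :func:`_conv_raw`."""
    N, C, H, Wd = x.shape
    O = dy.shape[1]
    if kh == 1 and kw == 1:
        dW = np.matmul(dy.reshape(N, O, -1), x.reshape(N, C, -1).transpose(0, 2, 1)).sum(0)
        return dW.reshape(O, C, 1, 1)
    d = dilation
    if xp is None:
        xp = _zero_pad(x, d)
    if (
        _kernels.HAVE_NUMBA
        and x.dtype == np.float32
        and dy.dtype == np.float32
        and O * C <= _NUMBA_MAX_CHANNEL_PRODUCT
    ):
        return _kernels.conv_dw(xp, np.ascontiguousarray(dy), d)
    dW = np.zeros((O, C, 3, 3), dtype=x.dtype)
    dyf = dy.reshape(N, O, -1)
    for i in range(3):
        for j in range(3):
            sub = xp[:, :, i * d : i * d + H, j * d : j * d + Wd]
            dW[:, :, i, j] = np.matmul(dyf, sub.reshape(N, C, -1).transpose(0, 2, 1)).sum(0)
    return dW


def _conv_dx(dy: np.ndarray, W: np.ndarray, dilation: int) -> np.ndarray:
    """Input gradient: convolution of dy with the transposed, flipped kernel."""
    O, C, kh, kw = W.shape
    if kh == 1 and kw == 1:
        Wt = W.reshape(O, C).T.reshape(C, O, 1, 1)
    else:
        Wt = W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
    return _conv_raw(dy, np.ascontiguousarray(Wt), None, dilation)


# ---------------------------------------------------------------------------
# differentiable ops

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, dilation: int = 1) -> Tensor:
    kh, kw = weight.data.shape[2:]
    xp = _zero_pad(x.data, dilation) if kh == 3 else None
    y = _conv_raw(x.data, weight.data, None if bias is None else bias.data, dilation, xp)

    def backward(dy: np.ndarray) -> None:
        if weight.requires_grad:
            weight.accumulate(_conv_dw(x.data, dy, kh, kw, dilation, xp), own=True)
        if bias is not None and bias.requires_grad:
            bias.accumulate(dy.sum(axis=(0, 2, 3)), own=True)
        if x.requires_grad:
            x.accumulate(_conv_dx(dy, weight.data, dilation), own=True)

    parents = (x, weight) + (() if bias is None else (bias,))
    return Tensor(y, parents=parents, backward=backward)


def partial_conv2d(
    x: Tensor, mask: np.ndarray, weight: Tensor, bias: Tensor, dilation: int = 1
) -> tuple[Tensor, np.ndarray]:
    """Mask-renormalized convolution with the hole-shrinking mask update.

    ``mask`` is a plain ``(N, 1, H, W)`` binary array (1 = valid pixel, not
    differentiated).  Windows with ``s = sum(mask) > 0`` valid cells yield
    ``y = (W * (x . m)) * (|W| / s) + b`` with ``|W|`` the kernel element
    count; empty windows yield 0 and stay invalid in the updated mask.

    Out-of-frame cells count as valid in the renormalization sum (so a
    fully valid input reproduces the ordinary zero-padded convolution
    exactly, borders included) but not in the mask update, which marks a
    pixel valid only once a truly known pixel enters its receptive field.
    """
    m = np.asarray(mask)
    if m.shape[0] != x.data.shape[0] or m.shape[2:] != x.data.shape[2:] or m.shape[1] != 1:
        raise ValueError("mask must be (N, 1, H, W) matching the input")
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask must be binary")
    m = m.astype(x.data.dtype)
    kh, kw = weight.data.shape[2:]
    ones = np.ones((1, 1, kh, kw), dtype=x.data.dtype)
    count = _conv_raw(m, ones, None, dilation)
    # holes counted against the window; padding counted as valid
    count_ratio = kh * kw - _conv_raw(1.0 - m, ones, None, dilation)
    ratio = np.where(count > 0, (kh * kw) / np.maximum(count_ratio, 1e-12), 0.0)
    ratio = ratio.astype(x.data.dtype)
    xm = x.data * m
    y = _conv_raw(xm, weight.data, None, dilation) * ratio + bias.data[None, :, None, None]
    new_mask = (count > 0).astype(m.dtype)

    def backward(dy: np.ndarray) -> None:
        dyr = dy * ratio
        if weight.requires_grad:
            weight.accumulate(_conv_dw(xm, dyr, kh, kw, dilation), own=True)
        if bias.requires_grad:
            bias.accumulate(dy.sum(axis=(0, 2, 3)), own=True)
        if x.requires_grad:
            x.accumulate(m * _conv_dx(dyr, weight.data, dilation), own=True)

    return Tensor(y, parents=(x, weight, bias), backward=backward), new_mask


def relu(x: Tensor) -> Tensor:
    pos = x.data > 0
    y = np.where(pos, x.data, 0)

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(np.where(pos, dy, 0), own=True)

    return Tensor(y, parents=(x,), backward=backward)


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {H}x{W}")
    blocks = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(dy: np.ndarray) -> None:
        if not x.requires_grad:
            return
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x.accumulate(np.ascontiguousarray(dx).reshape(N, C, H, W), own=True)

    return Tensor(y, parents=(x,), backward=backward)


def maxpool2x2_array(m: np.ndarray) -> np.ndarray:
    """Plain-array 2x2 max pooling (mask streams; no gradient)."""
    N, C, H, W = m.shape
    return m.reshape(N, C, H // 2, 2, W // 2, 2).max(axis=(3, 5))


def upsample2x_array(m: np.ndarray) -> np.ndarray:
    """Plain-array nearest 2x upsampling (mask streams; no gradient)."""
    return m.repeat(2, axis=2).repeat(2, axis=3)


def conv_transpose2x2(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Stride-2 2x2 transposed convolution (spatial dimension doubling).

    ``weight`` has shape ``(C_in, C_out, 2, 2)``.
    """
    N, C, H, W = x.data.shape
    _, O, _, _ = weight.data.shape
    t = np.einsum("nchw,coab->nohwab", x.data, weight.data, optimize=True)
    y = t.transpose(0, 1, 2, 4, 3, 5).reshape(N, O, 2 * H, 2 * W)
    if bias is not None:
        y = y + bias.data[None, :, None, None]

    def backward(dy: np.ndarray) -> None:
        dy6 = dy.reshape(N, O, H, 2, W, 2).transpose(0, 1, 2, 4, 3, 5)
        if weight.requires_grad:
            weight.accumulate(np.einsum("nchw,nohwab->coab", x.data, dy6, optimize=True))
        if bias is not None and bias.requires_grad:
            bias.accumulate(dy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x.accumulate(np.einsum("nohwab,coab->nchw", dy6, weight.data, optimize=True))

    parents = (x, weight) + (() if bias is None else (bias,))
    return Tensor(np.ascontiguousarray(y), parents=parents, backward=backward)


def concat(xs: Sequence[Tensor], axis: int = 1) -> Tensor:
    # snapshot: callers may keep appending to their list, and capturing it
    # live would create a reference cycle through the closure
    xs = tuple(xs)
    y = np.concatenate([t.data for t in xs], axis=axis)
    sizes = [t.data.shape[axis] for t in xs]
    splits = np.cumsum(sizes)[:-1]

    def backward(dy: np.ndarray) -> None:
        for t, piece in zip(xs, np.split(dy, splits, axis=axis)):
            if t.requires_grad:
                t.accumulate(piece)

    return Tensor(y, parents=tuple(xs), backward=backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Dense layer ``y = x @ W.T + b`` with ``W`` of shape (out, in)."""
    y = x.data @ weight.data.T + bias.data

    def backward(dy: np.ndarray) -> None:
        if weight.requires_grad:
            weight.accumulate(dy.T @ x.data)
        if bias.requires_grad:
            bias.accumulate(dy.sum(axis=0))
        if x.requires_grad:
            x.accumulate(dy @ weight.data)

    return Tensor(y, parents=(x, weight, bias), backward=backward)


def global_mean_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    N, C, H, W = x.data.shape
    y = x.data.mean(axis=(2, 3))

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(np.broadcast_to(dy[:, :, None, None] / (H * W), x.data.shape).copy())

    return Tensor(y, parents=(x,), backward=backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    y = x.data.reshape(shape)

    def backward(dy: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(dy.reshape(x.data.shape))

    return Tensor(y, parents=(x,), backward=backward)


def l1_loss(pred: Tensor, target: np.ndarray, weight: np.ndarray | None = None) -> Tensor:
    """Mean absolute error; optional per-pixel weights (e.g. gap-only loss)."""
    target = np.asarray(target, dtype=pred.data.dtype)
    if target.shape != pred.data.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {target.shape}")
    diff = pred.data - target
    if weight is None:
        y = np.abs(diff).mean()
        scale = 1.0 / diff.size
    else:
        wsum = weight.sum()
        y = (np.abs(diff) * weight).sum() / wsum
        scale = 1.0 / wsum

    def backward(dy: np.ndarray) -> None:
        if pred.requires_grad:
            g = np.sign(diff) * (dy * scale)
            if weight is not None:
                g = g * weight
            pred.accumulate(g.astype(pred.data.dtype))

    return Tensor(np.asarray(y), parents=(pred,), backward=backward)
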