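"""Numba-compiled convolution kernels for small channel counts.

The engine's generic convolution runs each kernel tap as a BLAS matrix
product over shifted views, which is efficient for wide layers but
copy-bound when the channel product is small (the mixed-scale dense
network's layers map many channels to one).  These streaming kernels work
directly on the zero-padded float32 arrays with no intermediate copies;
:mod:`scattergap.nn.tensor` dispatches to them when profitable and falls
back to the BLAS path when numba is unavailable or dtypes differ.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True, fastmath=True, boundscheck=False)
def conv_fwd(xp, W, b, d, H, Wd):
    """y[n,o,h,w] = b[o] + sum_cij W[o,c,i,j] xp[n,c,h+i*d,w+j*d].

    The three kernel-column taps are read through explicit contiguous
    slices; indexing the padded row as ``base[w + j*d]`` instead defeats
    LLVM's alias analysis and costs ~5x in vectorization.
    """
    N, C = xp.shape[0], xp.shape[1]
    O = W.shape[0]
    y = np.empty((N, O, H, Wd), np.float32)
    row = np.empty(Wd, np.float32)
    for n in range(N):
        for o in range(O):
            for h in range(H):
                for w in range(Wd):
                    row[w] = b[o]
                for c in range(C):
                    for i in range(3):
                        base = xp[n, c, h + i * d]
                        w0 = W[o, c, i, 0]
                        w1 = W[o, c, i, 1]
                        w2 = W[o, c, i, 2]
                        b0 = base[:Wd]
                        b1 = base[d : d + Wd]
                        b2 = base[2 * d : 2 * d + Wd]
                        for w in range(Wd):
                            row[w] += w0 * b0[w] + w1 * b1[w] + w2 * b2[w]
                y[n, o, h] = row
    return y


@njit(cache=True, fastmath=True, boundscheck=False)
def conv_dw(xp, dy, d):
    """dW[o,c,i,j] = sum_nhw dy[n,o,h,w] xp[n,c,h+i*d,w+j*d]."""
    N, C = xp.shape[0], xp.shape[1]
    O, H, Wd = dy.shape[1], dy.shape[2], dy.shape[3]
    dW = np.zeros((O, C, 3, 3), np.float32)
    for n in range(N):
        for o in range(O):
            for c in range(C):
                for i in range(3):
                    for h in range(H):
                        drow = dy[n, o, h]
                        xrow = xp[n, c, h + i * d]
                        a0 = np.float32(0.0)
                        a1 = np.float32(0.0)
                        a2 = np.float32(0.0)
                        x0 = xrow[:Wd]
                        x1 = xrow[d : d + Wd]
                        x2 = xrow[2 * d : 2 * d + Wd]
                        for w in range(Wd):
                            a0 += drow[w] * x0[w]
                            a1 += drow[w] * x1[w]
                            a2 += drow[w] * x2[w]
                        dW[o, c, i, 0] += a0
                        dW[o, c, i, 1] += a1
                        dW[o, c, i, 2] += a2
    return dW
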