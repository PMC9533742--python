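"""Non-learned baseline: biharmonic surface extension through the gaps.

Masked pixels are filled with the solution of the discrete biharmonic
equation (13-point ``del^4 u = 0`` stencil) clamped to the known pixel
values surrounding each gap, i.e. the known boundary data diffuse smoothly
into the gap interior.  Where the stencil reaches past the frame border
(the vertical detector gaps run the full frame height) the out-of-frame
value is closed by linear extrapolation from the two nearest in-frame rows
or columns, which keeps constant and affine images exact solutions
everywhere.  The sparse system splits into decoupled blocks (gap regions
further than the stencil reach apart); each block is LU-factorized once per
mask, so stacks of frames sharing the detector mask solve cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .geometry import GapMask

__all__ = ["InpaintProblem", "BiharmonicSolver", "biharmonic_inpaint"]

#: 13-point biharmonic stencil: (drow, dcol) -> coefficient.
_STENCIL = {
    (0, 0): 20.0,
    (1, 0): -8.0, (-1, 0): -8.0, (0, 1): -8.0, (0, -1): -8.0,
    (1, 1): 2.0, (1, -1): 2.0, (-1, 1): 2.0, (-1, -1): 2.0,
    (2, 0): 1.0, (-2, 0): 1.0, (0, 2): 1.0, (0, -2): 1.0,
}


@dataclass(frozen=True)
class InpaintProblem:
    """An image plus the boolean mask of pixels to be filled."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=np.float64)
        msk = np.asarray(self.mask, dtype=bool)
        if img.shape != msk.shape:
            raise ValueError(f"image shape {img.shape} != mask shape {msk.shape}")
        if msk.all():
            raise ValueError("fully masked image: no boundary data to extend")
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "mask", msk)


def _axis_anchors(i: np.ndarray, n: int):
    """Linear-extrapolation closure along one axis.

    Maps possibly out-of-range indices ``i`` to two in-range anchor indices
    with weights; in-range indices pass through unchanged, out-of-range
    values become the linear extrapolation from the two nearest in-range
    lines (exact for affine data).
    """
    below = i < 0
    above = i > n - 1
    a1 = np.where(below, 0, np.where(above, n - 1, i))
    a2 = np.where(below, min(1, n - 1), np.where(above, max(n - 2, 0), i))
    fi = i.astype(np.float64)
    w1 = np.where(below, 1.0 - fi, np.where(above, fi - (n - 2), 1.0))
    w2 = np.where(below, fi, np.where(above, (n - 1) - fi, 0.0))
    return a1, w1, a2, w2


class BiharmonicSolver:
    """Precomputed clamped-biharmonic fill for one mask geometry.

    Assembles the sparse 13-point system over the masked pixels, splits it
    into decoupled diagonal blocks and LU-factorizes each once; every call
    to :meth:`solve` then only builds a right-hand side from the known
    pixels of the frame at hand.
    """

    def __init__(self, mask: GapMask | np.ndarray, shape: tuple[int, int] | None = None):
        raster = mask.raster if isinstance(mask, GapMask) else np.asarray(mask, dtype=bool)
        if raster.ndim != 2:
            raise ValueError("mask must be 2-D")
        if raster.all():
            raise ValueError("fully masked image: no boundary data to extend")
        self.mask = raster
        H, W = raster.shape
        rows, cols = np.nonzero(raster)
        n = rows.size
        self._rows, self._cols, self._n = rows, cols, n
        if n == 0:
            return
        idx = np.full((H, W), -1, dtype=np.int64)
        idx[rows, cols] = np.arange(n)

        eq_i, eq_j, eq_w = [], [], []
        # RHS is a sparse combination of known pixels: collect (eq, pixel, w)
        b_i, b_r, b_c, b_w = [], [], [], []
        eqs = np.arange(n)
        for (dr, dc), coeff in _STENCIL.items():
            r1, wr1, r2, wr2 = _axis_anchors(rows + dr, H)
            c1, wc1, c2, wc2 = _axis_anchors(cols + dc, W)
            for rr, wr in ((r1, wr1), (r2, wr2)):
                for cc, wc in ((c1, wc1), (c2, wc2)):
                    w = coeff * wr * wc
                    nz = w != 0
                    if not nz.any():
                        continue
                    tgt = idx[rr[nz], cc[nz]]
                    unknown = tgt >= 0
                    e, wv = eqs[nz], w[nz]
                    eq_i.append(e[unknown])
                    eq_j.append(tgt[unknown])
                    eq_w.append(wv[unknown])
                    b_i.append(e[~unknown])
                    b_r.append(rr[nz][~unknown])
                    b_c.append(cc[nz][~unknown])
                    b_w.append(-wv[~unknown])
        A = sparse.coo_matrix(
            (np.concatenate(eq_w), (np.concatenate(eq_i), np.concatenate(eq_j))),
            shape=(n, n),
        ).tocsr()
        self._b_i = np.concatenate(b_i)
        self._b_flat = np.concatenate(b_r) * W + np.concatenate(b_c)
        self._b_w = np.concatenate(b_w)

        pattern = (abs(A) + abs(A.T)).astype(bool)
        ncomp, labels = connected_components(pattern, directed=False)
        self._blocks = []
        for comp in range(ncomp):
            sel = np.nonzero(labels == comp)[0]
            self._blocks.append((sel, splu(A[sel][:, sel].tocsc())))

    def solve(self, image: np.ndarray) -> np.ndarray:
        """Return a copy of ``image`` with masked pixels filled."""
        problem = InpaintProblem(image, self.mask)
        img = problem.image
        out = img.copy()
        if self._n == 0:
            return out
        rhs = np.zeros(self._n, dtype=np.float64)
        np.add.at(rhs, self._b_i, self._b_w * img.ravel()[self._b_flat])
        sol = np.empty(self._n, dtype=np.float64)
        for sel, lu in self._blocks:
            sol[sel] = lu.solve(rhs[sel])
        if not np.isfinite(sol).all():
            raise np.linalg.LinAlgError("biharmonic system is singular")
        out[self._rows, self._cols] = sol
        return out


def biharmonic_inpaint(image: np.ndarray, mask: GapMask | np.ndarray) -> np.ndarray:
    """Fill masked pixels of one frame by clamped biharmonic extension.

    Unmasked pixels are returned bit-exact.  For stacks of frames sharing a
    mask, build a :class:`BiharmonicSolver` once and call ``solve`` per
    frame.
    """
    raster = mask.raster if isinstance(mask, GapMask) else np.asarray(mask, dtype=bool)
    if not raster.any():
        return np.asarray(image).copy()
    return BiharmonicSolver(raster).solve(image)
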