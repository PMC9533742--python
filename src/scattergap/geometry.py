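"""Module-tiled detector geometry and the gap masks it induces.

Photon-counting area detectors such as the PILATUS3 2M are tiled from
rectangular sensor modules separated by dead stripes ("gaps") a few pixels
wide.  A frame recorded on such a detector therefore carries full-width
horizontal bands and full-height vertical bands of missing pixels.  This
module describes the tiling, rasterizes the induced boolean gap mask at
native resolution, and rescales the mask to the working resolution used by
the inpainting pipeline.

Conventions: 0-based row-major ``(row, col)`` indexing; rectangles are
half-open ``[row0, row1) x [col0, col1)``; mask value True marks a gap
(missing) pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectorGeometry",
    "GapMask",
    "PILATUS3_2M",
    "build_full_mask",
    "count_modules",
    "rescale_mask",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """A grid of detector modules separated by uniform gaps.

    Parameters
    ----------
    module_cols, module_rows:
        Number of module columns / rows (e.g. 3 x 8 for a PILATUS3 2M).
    module_width, module_height:
        Module extent in pixels.
    v_gap_width, h_gap_height:
        Width of the vertical gaps between module columns and height of the
        horizontal gaps between module rows, in pixels.
    frame_width, frame_height:
        Total frame extent; must equal modules plus inter-module gaps.
    pixel_pitch_mm:
        Physical pixel pitch, informational only.
    """

    module_cols: int
    module_rows: int
    module_width: int
    module_height: int
    v_gap_width: int
    h_gap_height: int
    frame_width: int
    frame_height: int
    pixel_pitch_mm: float = 0.172

    def __post_init__(self) -> None:
        for name in (
            "module_cols",
            "module_rows",
            "module_width",
            "module_height",
            "frame_width",
            "frame_height",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("v_gap_width", "h_gap_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        w = self.module_cols * self.module_width + (self.module_cols - 1) * self.v_gap_width
        if w != self.frame_width:
            raise ValueError(
                "geometry invariant violated: module_cols*module_width + "
                f"(module_cols-1)*v_gap_width == frame_width ({w} != {self.frame_width})"
            )
        h = self.module_rows * self.module_height + (self.module_rows - 1) * self.h_gap_height
        if h != self.frame_height:
            raise ValueError(
                "geometry invariant violated: module_rows*module_height + "
                f"(module_rows-1)*h_gap_height == frame_height ({h} != {self.frame_height})"
            )


#: The PILATUS3 2M tiling: 3 columns x 8 rows of 487x195 modules, 7 px
#: vertical and 17 px horizontal gaps, 1475 x 1679 frame, 172 um pixels.
PILATUS3_2M = DetectorGeometry(
    module_cols=3,
    module_rows=8,
    module_width=487,
    module_height=195,
    v_gap_width=7,
    h_gap_height=17,
    frame_width=1475,
    frame_height=1679,
)


@dataclass(frozen=True)
class GapMask:
    """Boolean gap raster plus the axis-aligned rectangles that generate it.

    ``rectangles`` holds half-open ``(row0, row1, col0, col1)`` tuples whose
    union equals the True cells of ``raster``.  Horizontal-gap rectangles
    span the full width, vertical-gap rectangles the full height.
    """

    raster: np.ndarray
    rectangles: tuple[tuple[int, int, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        r = np.asarray(self.raster, dtype=bool)
        object.__setattr__(self, "raster", r)
        if r.ndim != 2:
            raise ValueError("raster must be 2-D")
        rebuilt = np.zeros_like(r)
        for r0, r1, c0, c1 in self.rectangles:
            rebuilt[r0:r1, c0:c1] = True
        if not np.array_equal(rebuilt, r):
            raise ValueError("union of rectangles does not equal the raster")

    @property
    def height(self) -> int:
        return self.raster.shape[0]

    @property
    def width(self) -> int:
        return self.raster.shape[1]

    @property
    def horizontal_rectangles(self) -> tuple[tuple[int, int, int, int], ...]:
        """Rectangles spanning the full frame width (horizontal gap bands)."""
        return tuple(r for r in self.rectangles if r[2] == 0 and r[3] == self.width)

    @property
    def vertical_rectangles(self) -> tuple[tuple[int, int, int, int], ...]:
        """Rectangles spanning the full frame height (vertical gap bands)."""
        return tuple(r for r in self.rectangles if r[0] == 0 and r[1] == self.height)

    def horizontal_only(self) -> "GapMask":
        """Mask restricted to the horizontal gap bands."""
        rects = self.horizontal_rectangles
        raster = np.zeros_like(self.raster)
        for r0, r1, c0, c1 in rects:
            raster[r0:r1, c0:c1] = True
        return GapMask(raster, rects)

    def vertical_only(self) -> "GapMask":
        """Mask restricted to the vertical gap bands."""
        rects = self.vertical_rectangles
        raster = np.zeros_like(self.raster)
        for r0, r1, c0, c1 in rects:
            raster[r0:r1, c0:c1] = True
        return GapMask(raster, rects)


def build_full_mask(geometry: DetectorGeometry) -> GapMask:
    """Rasterize the full gap grid of a detector at native resolution.

    Produces ``module_rows - 1`` full-width horizontal bands of height
    ``h_gap_height`` and ``module_cols - 1`` full-height vertical bands of
    width ``v_gap_width``.
    """
    g = geometry
    rects: list[tuple[int, int, int, int]] = []
    for k in range(g.module_rows - 1):
        r0 = (k + 1) * g.module_height + k * g.h_gap_height
        rects.append((r0, r0 + g.h_gap_height, 0, g.frame_width))
    for k in range(g.module_cols - 1):
        c0 = (k + 1) * g.module_width + k * g.v_gap_width
        rects.append((0, g.frame_height, c0, c0 + g.v_gap_width))
    raster = np.zeros((g.frame_height, g.frame_width), dtype=bool)
    for r0, r1, c0, c1 in rects:
        raster[r0:r1, c0:c1] = True
    return GapMask(raster, tuple(rects))


def count_modules(mask: GapMask) -> int:
    """Number of 4-connected components of unmasked (valid) pixels."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    _, n = ndimage.label(~mask.raster, structure=structure)
    return int(n)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def rescale_mask(mask: GapMask, out_height: int, out_width: int) -> GapMask:
    """Rescale a rectangle-backed gap mask to a new raster size.

    Each rectangle edge is scaled by ``out/in`` per axis and rounded to the
    nearest integer (half up); every rectangle keeps an extent of at least
    one pixel so thin gaps survive aggressive downscaling.
    """
    if out_height <= 0 or out_width <= 0:
        raise ValueError("output dimensions must be positive")
    sy = out_height / mask.height
    sx = out_width / mask.width
    rects: list[tuple[int, int, int, int]] = []
    for r0, r1, c0, c1 in mask.rectangles:
        nr0, nr1 = _round_half_up(r0 * sy), _round_half_up(r1 * sy)
        nc0, nc1 = _round_half_up(c0 * sx), _round_half_up(c1 * sx)
        nr0 = min(nr0, out_height - 1)
        nc0 = min(nc0, out_width - 1)
        if nr1 <= nr0:
            nr1 = nr0 + 1
        if nc1 <= nc0:
            nc1 = nc0 + 1
        rects.append((nr0, min(nr1, out_height), nc0, min(nc1, out_width)))
    raster = np.zeros((out_height, out_width), dtype=bool)
    for r0, r1, c0, c1 in rects:
        raster[r0:r1, c0:c1] = True
    return GapMask(raster, tuple(rects))
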