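"""Strip cropping, artificial vertical gaps and overlap-averaged stitching.

The training pipeline never sees full frames.  Each 512 x 512 frame is cut
into seven overlapping 512 x 128 column strips (64-pixel overlap); strips
crossing a true vertical detector gap carry no ground truth there and are
discarded; each survivor gets an artificial vertical gap placed at one of
the column positions where the true gaps sit in the discarded strips, so
the network trains on gap geometry consistent with inference.  At inference
all seven strips are predicted and recombined by averaging overlapping
columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .geometry import GapMask

__all__ = [
    "STRIP_WIDTH",
    "STRIP_OVERLAP",
    "STRIP_OFFSETS",
    "DEFAULT_GAP_CANDIDATES",
    "Strip",
    "AugmentedPair",
    "crop_strips",
    "has_vertical_gap",
    "surviving_offsets",
    "insert_artificial_gap",
    "iter_augmented_pairs",
    "augment_dataset",
    "make_augmented_test_set",
    "stitch",
]

STRIP_WIDTH = 128
STRIP_OVERLAP = 64
#: Offsets of the seven strips in a 512-wide frame: k * 64 for k = 0..6.
STRIP_OFFSETS = tuple(range(0, 512 - STRIP_WIDTH + 1, STRIP_OVERLAP))

#: Local start columns for artificial vertical gaps (-1 = no gap added).
#: These are exactly the columns the two true vertical gaps of the
#: 512-rescaled PILATUS3 2M mask occupy inside the four discarded strips
#: (offsets 64/128/256/320 -> local columns 105/41/85/21), so artificial
#: gaps are consistent in location with the true ones.
DEFAULT_GAP_CANDIDATES = (-1, 21, 41, 85, 105)
DEFAULT_GAP_WIDTH = 2


@dataclass(frozen=True)
class Strip:
    """A 512-tall column band of a working-resolution frame."""

    pixels: np.ndarray
    offset: int
    parent_id: int = -1

    def __post_init__(self) -> None:
        if self.offset % STRIP_OVERLAP != 0 or self.offset not in STRIP_OFFSETS:
            raise ValueError(f"offset {self.offset} is not a multiple-of-64 strip offset")
        if self.pixels.ndim != 2 or self.pixels.shape[1] != STRIP_WIDTH:
            raise ValueError(f"strip must be H x {STRIP_WIDTH}, got {self.pixels.shape}")


@dataclass(frozen=True)
class AugmentedPair:
    """An (artificially gapped input, ground-truth target) training pair.

    ``artificial_gap`` is the local half-open column interval zeroed in the
    input, or None when the draw was the no-gap candidate.  ``valid_mask``
    marks pixels the input actually carries (False inside true horizontal
    gaps and the artificial gap); non-blind methods consume it.
    """

    input_strip: Strip
    target_strip: Strip
    artificial_gap: tuple[int, int] | None
    valid_mask: np.ndarray

    @property
    def offset(self) -> int:
        return self.input_strip.offset

    @property
    def parent_id(self) -> int:
        return self.input_strip.parent_id


def crop_strips(image: np.ndarray, parent_id: int = -1) -> list[Strip]:
    """Cut a 512 x 512 frame into seven overlapping 512 x 128 strips."""
    image = np.asarray(image)
    if image.shape != (512, 512):
        raise ValueError(f"expected a 512x512 frame, got {image.shape}")
    return [Strip(image[:, off : off + STRIP_WIDTH], off, parent_id) for off in STRIP_OFFSETS]


def has_vertical_gap(strip: Strip, mask: GapMask) -> bool:
    """True iff a vertical-gap rectangle intersects the strip's columns."""
    lo, hi = strip.offset, strip.offset + STRIP_WIDTH
    return any(c0 < hi and c1 > lo for _, _, c0, c1 in mask.vertical_rectangles)


def surviving_offsets(mask: GapMask) -> tuple[int, ...]:
    """Strip offsets whose column band avoids every vertical gap."""
    dummy = np.zeros((512, STRIP_WIDTH))
    return tuple(
        off for off in STRIP_OFFSETS if not has_vertical_gap(Strip(dummy, off), mask)
    )


def _strip_valid_mask(mask: GapMask, offset: int) -> np.ndarray:
    """Valid-pixel (True = known) mask for a strip before augmentation."""
    sub = mask.raster[:, offset : offset + STRIP_WIDTH]
    return ~sub


def insert_artificial_gap(
    strip: Strip,
    rng: np.random.Generator,
    gap_width: int = DEFAULT_GAP_WIDTH,
    candidates: Sequence[int] = DEFAULT_GAP_CANDIDATES,
    valid_mask: np.ndarray | None = None,
    fill: float = 0.0,
) -> AugmentedPair:
    """Draw one artificial-gap candidate and build the training pair.

    A candidate of -1 leaves the strip untouched (input equals target);
    otherwise columns ``[c, c + gap_width)`` of the input are set to
    ``fill``.  The target keeps the original values everywhere.
    """
    if gap_width < 1:
        raise ValueError("gap_width must be >= 1")
    candidates = tuple(candidates)
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    for c in candidates:
        if c != -1 and not (0 <= c and c + gap_width <= STRIP_WIDTH):
            raise ValueError(f"candidate {c} + gap_width {gap_width} overflows the strip")
    c = int(candidates[int(rng.integers(len(candidates)))])
    if valid_mask is None:
        valid_mask = np.ones_like(strip.pixels, dtype=bool)
    else:
        valid_mask = valid_mask.copy()
    if c == -1:
        inp = strip
        gap = None
    else:
        pix = strip.pixels.copy()
        pix[:, c : c + gap_width] = fill
        valid_mask[:, c : c + gap_width] = False
        inp = Strip(pix, strip.offset, strip.parent_id)
        gap = (c, c + gap_width)
    return AugmentedPair(inp, strip, gap, valid_mask)


def iter_augmented_pairs(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]],
    mask: GapMask,
    rng: np.random.Generator,
    gap_width: int = DEFAULT_GAP_WIDTH,
    candidates: Sequence[int] = DEFAULT_GAP_CANDIDATES,
) -> Iterator[AugmentedPair]:
    """Lazily crop, discard vertical-gap strips and augment each survivor.

    ``pairs`` yields (masked input frame, ground-truth frame) at 512 x 512.
    With the PILATUS3 2M mask four of the seven strips cross a vertical gap,
    leaving exactly three augmented pairs per frame.
    """
    keep = surviving_offsets(mask)
    valid_by_offset = {off: _strip_valid_mask(mask, off) for off in keep}
    for parent_id, (masked, truth) in enumerate(pairs):
        if masked.shape != (512, 512) or truth.shape != (512, 512):
            raise ValueError("augmentation expects 512x512 (masked, truth) frames")
        in_strips = crop_strips(masked, parent_id)
        tgt_strips = crop_strips(truth, parent_id)
        for strip_in, strip_tgt in zip(in_strips, tgt_strips):
            if strip_in.offset not in keep:
                continue
            pair = insert_artificial_gap(
                strip_tgt, rng, gap_width, candidates, valid_by_offset[strip_in.offset]
            )
            # The input must also carry the true horizontal gaps of the
            # masked frame, not the filled ground-truth rows.
            pix = pair.input_strip.pixels.copy()
            hole = ~valid_by_offset[strip_in.offset]
            pix[hole] = strip_in.pixels[hole]
            yield AugmentedPair(
                Strip(pix, strip_in.offset, parent_id),
                pair.target_strip,
                pair.artificial_gap,
                pair.valid_mask,
            )


def augment_dataset(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    mask: GapMask,
    rng: np.random.Generator,
    gap_width: int = DEFAULT_GAP_WIDTH,
    candidates: Sequence[int] = DEFAULT_GAP_CANDIDATES,
) -> list[AugmentedPair]:
    """Materialized :func:`iter_augmented_pairs`; 3 pairs per frame under
    the PILATUS3 2M mask (7 crops - 4 discarded)."""
    return list(iter_augmented_pairs(pairs, mask, rng, gap_width, candidates))


def make_augmented_test_set(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    mask: GapMask,
    rng: np.random.Generator,
    gap_width: int = DEFAULT_GAP_WIDTH,
    candidates: Sequence[int] = DEFAULT_GAP_CANDIDATES,
) -> list[AugmentedPair]:
    """Augment an evaluation split with the identical contract as training.

    The artificial gaps supply vertical-gap ground truth that the real test
    frames lack, enabling quantitative scoring of vertical-gap inpainting.
    """
    return augment_dataset(pairs, mask, rng, gap_width, candidates)


def stitch(strips: Sequence[Strip]) -> np.ndarray:
    """Recombine the seven strips by averaging overlapped columns.

    Exact left inverse of :func:`crop_strips` on unmodified strips.
    """
    offsets = sorted(s.offset for s in strips)
    if offsets != sorted(STRIP_OFFSETS):
        raise ValueError(f"need exactly the offsets {STRIP_OFFSETS}, got {offsets}")
    height = strips[0].pixels.shape[0]
    acc = np.zeros((height, 512), dtype=np.float64)
    cnt = np.zeros(512, dtype=np.int64)
    for s in strips:
        if s.pixels.shape[0] != height:
            raise ValueError("strips disagree in height")
        acc[:, s.offset : s.offset + STRIP_WIDTH] += s.pixels
        cnt[s.offset : s.offset + STRIP_WIDTH] += 1
    return acc / cnt[None, :]
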