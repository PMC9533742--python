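"""Synthetic 2D scattering frames and intensity pre-processing.

The beamline image library the inpainting pipeline was designed around is
not public, so this module generates stand-in frames with the features that
matter for gap reconstruction: a radially decaying diffuse background,
isotropic and azimuthally modulated Debye-Scherrer-like rings, localized
Gaussian peaks (optionally placed wholly inside a horizontal gap band, or
tangent to the beamstop, or as fourfold-symmetric quadruplets), a beamstop
shadow and Gaussian read noise.  Frames are nonnegative raw intensities;
:func:`preprocess` applies the log-and-normalize step that maps them into
``[0, 1]`` for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize as _skimage_resize

from .geometry import GapMask

__all__ = [
    "Ring",
    "Peak",
    "ScatterScene",
    "SceneRanges",
    "render_scene",
    "sample_scene",
    "resize_bicubic",
    "preprocess",
    "apply_mask",
    "simulate_pair",
    "simulate_dataset",
]


@dataclass(frozen=True)
class Ring:
    """An azimuthally (optionally) modulated scattering ring.

    ``modulation_order`` m with ``modulation_depth`` d scales the ring by
    ``1 - d/2 + d/2 * cos(m * theta)``, giving powder rings (d = 0) through
    strongly textured arcs (d = 1).
    """

    radius: float
    width: float
    amplitude: float
    modulation_order: int = 0
    modulation_depth: float = 0.0


@dataclass(frozen=True)
class Peak:
    """An isotropic Gaussian Bragg-like peak at a fixed detector position."""

    row: float
    col: float
    sigma: float
    amplitude: float


@dataclass(frozen=True)
class ScatterScene:
    """Parametric description of one synthetic scattering pattern."""

    center: tuple[float, float]
    rings: tuple[Ring, ...] = ()
    peaks: tuple[Peak, ...] = ()
    background_amplitude: float = 0.0
    background_decay: float = 2.0
    beamstop_halfwidth: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for ring in self.rings:
            if ring.radius <= 0 or ring.width <= 0 or ring.amplitude < 0:
                raise ValueError("ring radius/width must be > 0 and amplitude >= 0")
            if not 0.0 <= ring.modulation_depth <= 1.0:
                raise ValueError("modulation depth must lie in [0, 1]")
        for pk in self.peaks:
            if pk.sigma <= 0 or pk.amplitude < 0:
                raise ValueError("peak sigma must be > 0 and amplitude >= 0")
        if self.background_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("amplitudes must be nonnegative")


def render_scene(scene: ScatterScene, height: int, width: int) -> np.ndarray:
    """Render a scene to a nonnegative float frame, deterministic in the seed.

    Intensity model, evaluated on the pixel grid with ``r`` the distance to
    the scene center and ``theta`` the azimuth::

        I = A_bg * (1 + r)^(-decay)
          + sum_rings A * mod(theta) * exp(-(r - radius)^2 / (2 width^2))
          + sum_peaks A * exp(-d^2 / (2 sigma^2))

    Gaussian read noise of scale ``noise_sigma`` is added and the result is
    clipped at zero; the square beamstop region around the center is zeroed
    last (an opaque shadow records no counts).
    """
    if height <= 0 or width <= 0:
        raise ValueError("frame dimensions must be positive")
    rows = np.arange(height, dtype=np.float64)[:, None] - scene.center[0]
    cols = np.arange(width, dtype=np.float64)[None, :] - scene.center[1]
    r = np.hypot(rows, cols)
    frame = np.zeros((height, width), dtype=np.float64)
    if scene.background_amplitude > 0:
        frame += scene.background_amplitude * (1.0 + r) ** (-scene.background_decay)
    if any(ring.modulation_order != 0 and ring.modulation_depth > 0 for ring in scene.rings):
        theta = np.arctan2(rows, cols)
    else:
        theta = None
    for ring in scene.rings:
        profile = ring.amplitude * np.exp(-((r - ring.radius) ** 2) / (2.0 * ring.width**2))
        if ring.modulation_order != 0 and ring.modulation_depth > 0:
            d = ring.modulation_depth
            profile = profile * (1.0 - 0.5 * d + 0.5 * d * np.cos(ring.modulation_order * theta))
        frame += profile
    for pk in scene.peaks:
        d2 = (np.arange(height)[:, None] - pk.row) ** 2 + (np.arange(width)[None, :] - pk.col) ** 2
        frame += pk.amplitude * np.exp(-d2 / (2.0 * pk.sigma**2))
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        frame += rng.normal(0.0, scene.noise_sigma, size=frame.shape)
        np.clip(frame, 0.0, None, out=frame)
    if scene.beamstop_halfwidth > 0:
        hw = scene.beamstop_halfwidth
        r0 = max(int(np.floor(scene.center[0] - hw)), 0)
        r1 = min(int(np.ceil(scene.center[0] + hw)) + 1, height)
        c0 = max(int(np.floor(scene.center[1] - hw)), 0)
        c1 = min(int(np.ceil(scene.center[1] + hw)) + 1, width)
        frame[r0:r1, c0:c1] = 0.0
    return frame


@dataclass(frozen=True)
class SceneRanges:
    """Sampling ranges for :func:`sample_scene`.

    Defaults emulate ring-dominated SAXS/WAXS frames at a 512-pixel working
    resolution, on a photon-count intensity scale spanning several decades
    (so the log transform in :func:`preprocess` matters, as it does for
    real detector data): a handful of rings a few pixels wide, occasional
    localized peaks, a central beamstop and weak read noise.  Under these
    defaults the mean preprocessed intensity over the horizontal gap bands
    is about 0.25, in the range reported for measured scattering data.
    Probabilities control the stress cases the evaluation cares about: a
    peak buried wholly inside a horizontal gap band, peaks tangent to the
    beamstop, and a fourfold-symmetric peak quadruplet.
    """

    center_jitter: float = 12.0
    n_rings: tuple[int, int] = (2, 6)
    ring_radius: tuple[float, float] = (0.06, 0.45)  # fraction of min(height, width)
    ring_width: tuple[float, float] = (1.5, 6.0)
    ring_amplitude: tuple[float, float] = (100.0, 2000.0)
    p_modulated: float = 0.4
    modulation_order: tuple[int, ...] = (2, 4, 6)
    modulation_depth: tuple[float, float] = (0.3, 0.9)
    n_peaks: tuple[int, int] = (0, 4)
    peak_sigma: tuple[float, float] = (1.5, 4.0)
    peak_amplitude: tuple[float, float] = (200.0, 5000.0)
    background_amplitude: tuple[float, float] = (50.0, 500.0)
    background_decay: tuple[float, float] = (0.8, 2.0)
    beamstop_halfwidth: tuple[float, float] = (6.0, 14.0)
    noise_sigma: tuple[float, float] = (0.5, 2.0)
    p_gap_peak: float = 0.15
    p_beamstop_peaks: float = 0.15
    p_fourfold: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "n_rings",
            "ring_radius",
            "ring_width",
            "ring_amplitude",
            "modulation_depth",
            "n_peaks",
            "peak_sigma",
            "peak_amplitude",
            "background_amplitude",
            "background_decay",
            "beamstop_halfwidth",
            "noise_sigma",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return float(lo) if hi == lo else float(rng.uniform(lo, hi))


def sample_scene(
    rng: np.random.Generator,
    ranges: SceneRanges | None = None,
    height: int = 512,
    width: int = 512,
    gap_mask: GapMask | None = None,
) -> ScatterScene:
    """Draw a random scene from ``ranges`` for a ``height x width`` frame.

    When ``gap_mask`` is given, the gap-peak stress case places a peak at
    the center row of a random horizontal gap band so the feature is wholly
    hidden from any method that only sees the masked frame.
    """
    ranges = ranges or SceneRanges()
    scale = min(height, width)
    center = (
        height / 2.0 + float(rng.uniform(-ranges.center_jitter, ranges.center_jitter)),
        width / 2.0 + float(rng.uniform(-ranges.center_jitter, ranges.center_jitter)),
    )
    rings = []
    for _ in range(int(rng.integers(ranges.n_rings[0], ranges.n_rings[1] + 1))):
        order, depth = 0, 0.0
        if rng.random() < ranges.p_modulated:
            order = int(rng.choice(ranges.modulation_order))
            depth = _uniform(rng, ranges.modulation_depth)
        rings.append(
            Ring(
                radius=_uniform(rng, ranges.ring_radius) * scale,
                width=_uniform(rng, ranges.ring_width),
                amplitude=_uniform(rng, ranges.ring_amplitude),
                modulation_order=order,
                modulation_depth=depth,
            )
        )
    peaks = []
    for _ in range(int(rng.integers(ranges.n_peaks[0], ranges.n_peaks[1] + 1))):
        radius = _uniform(rng, ranges.ring_radius) * scale
        angle = float(rng.uniform(0, 2 * np.pi))
        peaks.append(
            Peak(
                row=center[0] + radius * np.sin(angle),
                col=center[1] + radius * np.cos(angle),
                sigma=_uniform(rng, ranges.peak_sigma),
                amplitude=_uniform(rng, ranges.peak_amplitude),
            )
        )
    beamstop = _uniform(rng, ranges.beamstop_halfwidth)
    if rng.random() < ranges.p_gap_peak and gap_mask is not None:
        h_rects = gap_mask.horizontal_rectangles
        if h_rects:
            r0, r1, _, _ = h_rects[int(rng.integers(len(h_rects)))]
            peaks.append(
                Peak(
                    row=(r0 + r1 - 1) / 2.0,
                    col=float(rng.uniform(0.1 * width, 0.9 * width)),
                    sigma=min(_uniform(rng, ranges.peak_sigma), (r1 - r0) / 4.0),
                    amplitude=_uniform(rng, ranges.peak_amplitude),
                )
            )
    if rng.random() < ranges.p_beamstop_peaks:
        for k in range(3):
            angle = float(rng.uniform(0, 2 * np.pi))
            peaks.append(
                Peak(
                    row=center[0] + (beamstop + 2.0) * np.sin(angle),
                    col=center[1] + (beamstop + 2.0) * np.cos(angle),
                    sigma=_uniform(rng, ranges.peak_sigma),
                    amplitude=_uniform(rng, ranges.peak_amplitude),
                )
            )
    if rng.random() < ranges.p_fourfold:
        radius = _uniform(rng, ranges.ring_radius) * scale
        angle = float(rng.uniform(0, np.pi / 2))
        sigma = _uniform(rng, ranges.peak_sigma)
        amp = _uniform(rng, ranges.peak_amplitude)
        for k in range(4):
            a = angle + k * np.pi / 2
            peaks.append(
                Peak(
                    row=center[0] + radius * np.sin(a),
                    col=center[1] + radius * np.cos(a),
                    sigma=sigma,
                    amplitude=amp,
                )
            )
    return ScatterScene(
        center=center,
        rings=tuple(rings),
        peaks=tuple(peaks),
        background_amplitude=_uniform(rng, ranges.background_amplitude),
        background_decay=_uniform(rng, ranges.background_decay),
        beamstop_halfwidth=beamstop,
        noise_sigma=_uniform(rng, ranges.noise_sigma),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def resize_bicubic(frame: np.ndarray, out_height: int, out_width: int) -> np.ndarray:
    """Bicubic resize with negative interpolation overshoot clipped to zero."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or frame.shape[0] < 4 or frame.shape[1] < 4:
        raise ValueError("input frame must be 2-D and at least 4x4")
    out = _skimage_resize(
        frame, (out_height, out_width), order=3, mode="edge", anti_aliasing=False
    )
    return np.clip(out, 0.0, None)


def preprocess(frame: np.ndarray) -> np.ndarray:
    """Log-scale and min-max normalize a nonnegative frame into ``[0, 1]``.

    ``v -> log(1 + v)`` highlights weak scattering, then a per-frame min-max
    maps to the unit interval.  A constant frame maps to all zeros.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if np.isnan(frame).any():
        raise ValueError("frame contains NaN")
    if (frame < 0).any():
        raise ValueError("frame contains negative intensities")
    out = np.log1p(frame)
    lo, hi = out.min(), out.max()
    if hi == lo:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def apply_mask(frame: np.ndarray, mask: GapMask, fill: float = 0.0) -> np.ndarray:
    """Set gap pixels to ``fill``, leaving all other pixels untouched."""
    frame = np.asarray(frame)
    if frame.shape != mask.raster.shape:
        raise ValueError(f"frame shape {frame.shape} != mask shape {mask.raster.shape}")
    out = frame.copy()
    out[mask.raster] = fill
    return out


def simulate_pair(
    scene: ScatterScene,
    mask: GapMask,
    *,
    native_shape: tuple[int, int] | None = None,
    keep_vertical_in_truth: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one (masked input, ground truth) preprocessed pair.

    Emulates the detector-translation acquisition: the ground truth has the
    horizontal gap bands filled with real signal, while its vertical gaps
    stay masked unless ``keep_vertical_in_truth`` is set.  The masked input
    has the full gap grid zeroed.  With ``native_shape`` the scene is
    rendered at detector resolution and bicubic-resized to the mask's
    working resolution; otherwise it is rendered directly at working size.
    """
    if native_shape is not None:
        scene_native = replace(
            scene,
            center=(
                scene.center[0] * native_shape[0] / mask.height,
                scene.center[1] * native_shape[1] / mask.width,
            ),
        )
        raw = render_scene(scene_native, *native_shape)
        raw = resize_bicubic(raw, mask.height, mask.width)
    else:
        raw = render_scene(scene, mask.height, mask.width)
    truth = preprocess(raw)
    if not keep_vertical_in_truth:
        truth = apply_mask(truth, mask.vertical_only())
    masked = apply_mask(truth, mask)
    return masked, truth


def simulate_dataset(
    n: int,
    mask: GapMask,
    seed: int,
    ranges: SceneRanges | None = None,
    *,
    native_shape: tuple[int, int] | None = None,
    keep_vertical_in_truth: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` (masked, truth) pairs; returns two ``(n, H, W)`` stacks."""
    rng = np.random.default_rng(seed)
    masked = np.empty((n, mask.height, mask.width), dtype=np.float32)
    truth = np.empty_like(masked)
    for i in range(n):
        scene = sample_scene(rng, ranges, mask.height, mask.width, gap_mask=mask)
        m, t = simulate_pair(
            scene,
            mask,
            native_shape=native_shape,
            keep_vertical_in_truth=keep_vertical_in_truth,
        )
        masked[i], truth[i] = m, t
    return masked, truth
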