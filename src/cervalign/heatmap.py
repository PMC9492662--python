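"""Gaussian heatmap encoding/decoding for endplate landmark regression.

A radiograph's four landmarks are represented as a 4-channel stack of
likelihood maps in [0, 1] (channel order C2A, C2P, C7A, C7P).  Training
targets are isotropic Gaussians with peak value exactly 1.0 at the grid
cell nearest each landmark.  Decoding takes the per-channel argmax back
to image pixels; the peak values double as per-landmark confidence
scores and their minimum is the whole-image confidence score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .geometry import LANDMARK_LABELS, LandmarkSet, Point2D

__all__ = [
    "GridToImage",
    "HeatmapConfig",
    "HeatmapStack",
    "encode_heatmaps",
    "decode_landmarks",
]

N_LANDMARKS = len(LANDMARK_LABELS)


@dataclass(frozen=True)
class GridToImage:
    """Invertible affine map from heatmap grid (col, row) to image (x, y).

    ``x = scale_x * col + offset_x`` and likewise for y.  A heatmap at
    half the image resolution has ``scale_x = scale_y = 2``.
    """

    scale_x: float = 1.0
    scale_y: float = 1.0
    offset_x: float = 0.0
    offset_y: float = 0.0

    def __post_init__(self) -> None:
        if self.scale_x == 0.0 or self.scale_y == 0.0:
            raise ValueError("grid_to_image must be invertible (non-zero scales)")

    def to_image(self, col: float, row: float) -> Tuple[float, float]:
        return (self.scale_x * col + self.offset_x, self.scale_y * row + self.offset_y)

    def to_grid(self, x: float, y: float) -> Tuple[float, float]:
        return ((x - self.offset_x) / self.scale_x, (y - self.offset_y) / self.scale_y)


@dataclass(frozen=True)
class HeatmapConfig:
    """Target construction parameters.

    sigma : Gaussian spread in heatmap-grid pixels.  The default 8 px is
        stated at a 128x128 heatmap; scale proportionally for other sizes
        (see :meth:`scaled_sigma`).
    heatmap_size : (height, width) of the heatmap grid.
    """

    sigma: float = 8.0
    heatmap_size: Tuple[int, int] = (128, 128)

    REFERENCE_SIZE = 128

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        h, w = self.heatmap_size
        if h < 8 or w < 8:
            raise ValueError("heatmap_size must be at least 8x8")

    @classmethod
    def for_size(cls, height: int, width: int, sigma_at_128: float = 8.0) -> "HeatmapConfig":
        """Config with sigma scaled proportionally from its 128-px reference."""
        sigma = sigma_at_128 * min(height, width) / cls.REFERENCE_SIZE
        return cls(sigma=sigma, heatmap_size=(height, width))


@dataclass
class HeatmapStack:
    """4-channel landmark likelihood maps plus their grid-to-image mapping.

    ``values`` has shape (4, height, width), every entry in [0, 1],
    channel order fixed as (C2A, C2P, C7A, C7P).
    """

    values: np.ndarray
    grid_to_image: GridToImage = field(default_factory=GridToImage)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != N_LANDMARKS:
            raise ValueError(
                f"expected (4, H, W) heatmap stack, got shape {self.values.shape}"
            )
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("heatmap values must lie in [0, 1]")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape


def encode_heatmaps(landmarks: LandmarkSet, config: HeatmapConfig,
                    grid_to_image: GridToImage | None = None) -> HeatmapStack:
    """Encode landmarks as Gaussian target heatmaps.

    Channel k is ``exp(-((r - r_k)^2 + (c - c_k)^2) / (2 sigma^2))`` where
    (r_k, c_k) is the grid cell nearest landmark k, so the peak value is
    exactly 1.0 and channels are independent.

    Raises
    ------
    ValueError
        If a landmark falls outside the heatmap grid; the message names
        the offending channel label.
    """
    if grid_to_image is None:
        grid_to_image = GridToImage()
    h, w = config.heatmap_size
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    values = np.empty((N_LANDMARKS, h, w), dtype=np.float64)
    for k, (label, point) in enumerate(zip(LANDMARK_LABELS, landmarks.as_tuple())):
        gc, gr = grid_to_image.to_grid(point.x, point.y)
        rk, ck = round(gr), round(gc)
        if not (0 <= rk < h and 0 <= ck < w):
            raise ValueError(
                f"landmark {label} at grid ({gr:.1f}, {gc:.1f}) outside "
                f"{h}x{w} heatmap"
            )
        values[k] = np.exp(
            -((rows - rk) ** 2 + (cols - ck) ** 2) / (2.0 * config.sigma**2)
        )
    return HeatmapStack(values=values, grid_to_image=grid_to_image)


def decode_landmarks(
    stack: HeatmapStack, refine: bool = False
) -> Tuple[LandmarkSet, np.ndarray, float]:
    """Decode a heatmap stack to landmarks, per-channel peaks, and confidence.

    Each channel's argmax (first occurrence in row-major order on ties) is
    mapped through ``grid_to_image`` to image pixels.  Peak values are
    clipped to [0, 1]; the image confidence score is the smallest of the
    four peaks.

    Parameters
    ----------
    refine
        When True, apply log-parabolic sub-pixel interpolation around the
        argmax (exact for Gaussian-shaped peaks).  Off by default: the
        decoded coordinate is literally the grid cell with the maximum
        value.

    Returns
    -------
    (landmarks, per_channel_peaks, confidence)
    """
    values = np.clip(stack.values, 0.0, 1.0)
    points = []
    peaks = np.empty(N_LANDMARKS, dtype=np.float64)
    for k in range(N_LANDMARKS):
        channel = values[k]
        flat_idx = int(np.argmax(channel))
        r, c = divmod(flat_idx, channel.shape[1])
        peaks[k] = channel[r, c]
        if channel.max() == channel.min():
            warnings.warn(
                f"channel {LANDMARK_LABELS[k]} is constant; decoding argmax "
                "tie-break at (0, 0)",
                RuntimeWarning,
                stacklevel=2,
            )
        rr, cc = float(r), float(c)
        if refine:
            rr, cc = _parabolic_refine(channel, r, c)
        x, y = stack.grid_to_image.to_image(cc, rr)
        points.append(Point2D(x, y))
    landmarks = LandmarkSet(*points)
    return landmarks, peaks, float(peaks.min())


def _parabolic_refine(channel: np.ndarray, r: int, c: int) -> Tuple[float, float]:
    """Log-parabolic sub-pixel interpolation around the argmax.

    Fits a 1D parabola to the log-intensities of the argmax and its two
    neighbours along each axis; for an exact Gaussian peak this recovers
    the continuous center.  Falls back to the integer argmax at borders
    or when neighbours are non-positive; offsets are clamped to half a
    cell.
    """

    def _offset(lo: float, mid: float, hi: float) -> float:
        if min(lo, mid, hi) <= 0.0:
            return 0.0
        la, lb, lc = np.log(lo), np.log(mid), np.log(hi)
        denom = la - 2.0 * lb + lc
        if denom >= 0.0:  # not a local log-concave maximum
            return 0.0
        return float(np.clip(0.5 * (la - lc) / denom, -0.5, 0.5))

    h, w = channel.shape
    rr, cc = float(r), float(c)
    if 0 < r < h - 1:
        rr += _offset(channel[r - 1, c], channel[r, c], channel[r + 1, c])
    if 0 < c < w - 1:
        cc += _offset(channel[r, c - 1], channel[r, c], channel[r, c + 1])
    return rr, cc
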