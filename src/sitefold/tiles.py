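"""Tile and region images, tessellation, and slide-statistics downsampling.

Regions are 8-bit RGB images with physical scale metadata (microns per
pixel) and an optional region-of-interest mask standing in for a tumor
annotation.  Deep-learning-style tiles are cut on a non-overlapping grid
after rescaling the region so that one tile spans a fixed physical width
(default 299 px spanning 302 um, i.e. roughly 10x optical magnification);
slide-level first/second-order statistics instead use a coarse 5 um/px
rendering of the whole region.

Coordinate convention: 0-based (row, col), half-open tile spans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.transform import resize, resize_local_mean

__all__ = [
    "TileImage",
    "RegionImage",
    "tessellate",
    "downsample_for_slide_stats",
    "DEFAULT_TILE_EDGE_PX",
    "DEFAULT_TILE_EDGE_UM",
    "SLIDE_STATS_MPP",
]

DEFAULT_TILE_EDGE_PX = 299
DEFAULT_TILE_EDGE_UM = 302.0
#: Target scale for slide-level statistics (microns per pixel).
SLIDE_STATS_MPP = 5.0
#: Tiles whose mean grayscale intensity exceeds this are background.
BACKGROUND_MEAN_THRESHOLD = 230.0


def _check_rgb8(pixels: np.ndarray, what: str) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"{what}: expected an HxWx3 array, got shape {pixels.shape}")
    if pixels.dtype != np.uint8:
        if np.any(pixels < 0) or np.any(pixels > 255):
            raise ValueError(f"{what}: intensities outside [0, 255]")
        pixels = pixels.astype(np.uint8)
    return pixels


@dataclass
class TileImage:
    """A square 8-bit RGB tile with physical scale metadata."""

    pixels: np.ndarray
    microns_per_pixel: float
    origin: tuple[int, int] = (0, 0)
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = _check_rgb8(self.pixels, "TileImage")
        h, w = self.pixels.shape[:2]
        if h != w:
            raise ValueError(f"TileImage must be square, got {h}x{w}")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def edge(self) -> int:
        return self.pixels.shape[0]


@dataclass
class RegionImage:
    """A larger RGB region (e.g. an annotated tumor area) to tessellate."""

    pixels: np.ndarray
    microns_per_pixel: float
    roi_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = _check_rgb8(self.pixels, "RegionImage")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.pixels.shape[:2]:
                raise ValueError(
                    f"roi_mask shape {self.roi_mask.shape} != pixel grid "
                    f"{self.pixels.shape[:2]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _luminance(pixels: np.ndarray) -> np.ndarray:
    # ITU-R 601 weights, shared with sitefold.features.luminance but kept
    # float here (no rounding) for the background test.
    p = pixels.astype(np.float64)
    return 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]


def tessellate(
    region: RegionImage,
    tile_edge_px: int = DEFAULT_TILE_EDGE_PX,
    tile_edge_um: float = DEFAULT_TILE_EDGE_UM,
    min_mask_fraction: float = 1.0,
    background_threshold: float = BACKGROUND_MEAN_THRESHOLD,
    slide_id: str = "",
) -> list[TileImage]:
    """Cut a region into non-overlapping square tiles at a fixed physical scale.

    The region is first resampled (bilinear) so that one output pixel covers
    ``tile_edge_um / tile_edge_px`` microns, then tiled on a grid anchored at
    (0, 0).  A tile is emitted only if at least ``min_mask_fraction`` of its
    area lies inside the ROI mask (when present) and its mean grayscale
    intensity is at most ``background_threshold`` (near-white tiles are
    background).

    Returns an empty list when the region is smaller than one tile.
    """
    if tile_edge_px <= 0 or tile_edge_um <= 0:
        raise ValueError("tile edge must be positive in both px and um")
    target_mpp = tile_edge_um / tile_edge_px
    scale = region.microns_per_pixel / target_mpp
    h, w = region.shape
    out_h, out_w = int(round(h * scale)), int(round(w * scale))
    if out_h < tile_edge_px or out_w < tile_edge_px:
        return []

    if abs(scale - 1.0) < 1e-12:
        pixels = region.pixels.astype(np.float64)
        mask = region.roi_mask
    else:
        pixels = resize(
            region.pixels.astype(np.float64),
            (out_h, out_w, 3),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        mask = None
        if region.roi_mask is not None:
            mask = (
                resize(
                    region.roi_mask.astype(np.float64),
                    (out_h, out_w),
                    order=0,
                    mode="edge",
                    anti_aliasing=False,
                    preserve_range=True,
                )
                > 0.5
            )

    tiles: list[TileImage] = []
    e = tile_edge_px
    for r0 in range(0, out_h - e + 1, e):
        for c0 in range(0, out_w - e + 1, e):
            if mask is not None:
                frac = mask[r0 : r0 + e, c0 : c0 + e].mean()
                if frac < min_mask_fraction - 1e-12:
                    continue
            block = np.clip(np.rint(pixels[r0 : r0 + e, c0 : c0 + e]), 0, 255).astype(np.uint8)
            if _luminance(block).mean() > background_threshold:
                continue
            tiles.append(
                TileImage(
                    pixels=block,
                    microns_per_pixel=target_mpp,
                    origin=(r0, c0),
                    slide_id=slide_id,
                )
            )
    return tiles


def downsample_for_slide_stats(region: RegionImage) -> RegionImage:
    """Area-average a region down to 5 um/px for slide-level statistics.

    A region already at or coarser than 5 um/px is returned unchanged with a
    warning.
    """
    if region.microns_per_pixel >= SLIDE_STATS_MPP:
        warnings.warn(
            f"region already at {region.microns_per_pixel} um/px >= "
            f"{SLIDE_STATS_MPP}; returning unchanged",
            stacklevel=2,
        )
        return region
    factor = region.microns_per_pixel / SLIDE_STATS_MPP
    h, w = region.shape
    out_h = max(1, int(round(h * factor)))
    out_w = max(1, int(round(w * factor)))
    pixels = resize_local_mean(
        region.pixels.astype(np.float64), (out_h, out_w, 3)
    )
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    mask = None
    if region.roi_mask is not None:
        mask = resize_local_mean(region.roi_mask.astype(np.float64), (out_h, out_w)) > 0.5
    return RegionImage(pixels=pixels, microns_per_pixel=SLIDE_STATS_MPP, roi_mask=mask)
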