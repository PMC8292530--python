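"""First-order channel statistics and second-order Haralick texture features.

These twenty numbers constitute the quantitative "site signature" of a
slide: per RGB channel the mean, population standard deviation, skewness
(m3 / m2^(3/2)), kurtosis (m4 / m2^2), and Shannon entropy of the 256-bin
intensity histogram in nats; plus five features of the gray level
co-occurrence matrix (GLCM) — contrast, dissimilarity, homogeneity,
angular second moment, and correlation — averaged over the four standard
angles (0, 45, 90, 135 degrees) at distance 1.

Central moments use 1/N (population) normalization throughout.  The GLCM
is the non-symmetric, 256-gray-level, normalized ordered-pair matrix:
``P[i, j]`` is the probability that a reference pixel of intensity ``i``
has a neighbor of intensity ``j`` at the given offset.  Skewness and
kurtosis of a zero-variance sample, like the correlation denominator of a
constant image, are degenerate: the former are reported as NaN (an
explicit undefined marker, never an exception), the latter is defined to
be 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .tiles import RegionImage, TileImage, downsample_for_slide_stats

__all__ = [
    "FirstOrderStats",
    "GLCM",
    "HaralickFeatures",
    "first_order",
    "first_order_rgb",
    "glcm",
    "haralick",
    "haralick_averaged",
    "luminance",
    "slide_signature",
    "tile_signature",
    "SIGNATURE_COLUMNS",
    "GLCM_ANGLES",
]

N_LEVELS = 256
GLCM_ANGLES = (0, 45, 90, 135)

#: Fixed column order of the 20-value signature vector.
SIGNATURE_COLUMNS = tuple(
    f"{stat}_{ch}"
    for ch in ("r", "g", "b")
    for stat in ("mean", "std", "skewness", "kurtosis", "entropy")
) + ("contrast", "dissimilarity", "homogeneity", "asm", "correlation")


@dataclass(frozen=True)
class FirstOrderStats:
    """First-order statistics of one intensity sample."""

    mean: float
    std: float
    skewness: float  # NaN when the sample is constant
    kurtosis: float  # NaN when the sample is constant
    entropy: float  # nats, in [0, ln 256]

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.std, self.skewness, self.kurtosis, self.entropy])


def first_order(values: np.ndarray) -> FirstOrderStats:
    """First-order statistics of an intensity sample in [0, 255].

    Moments use 1/N normalization; entropy is the Shannon entropy of the
    256-bin normalized histogram with natural log and 0*log 0 := 0.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 pixels")
    if x.min() < 0 or x.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    mean = x.mean()
    d = x - mean
    m2 = np.mean(d**2)
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    if m2 <= 0:
        skew = float("nan")
        kurt = float("nan")
    else:
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    hist = np.bincount(np.rint(x).astype(np.int64), minlength=N_LEVELS)
    p = hist / hist.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return FirstOrderStats(float(mean), float(np.sqrt(m2)), float(skew), float(kurt), entropy)


def first_order_rgb(pixels: np.ndarray, mask: Optional[np.ndarray] = None) -> dict[str, FirstOrderStats]:
    """Per-channel first-order statistics of an HxWx3 image."""
    pixels = np.asarray(pixels)
    out = {}
    for idx, ch in enumerate("rgb"):
        channel = pixels[..., idx]
        sample = channel[mask] if mask is not None else channel
        out[ch] = first_order(sample)
    return out


# ---------------------------------------------------------------------------
# GLCM

# (row, col) offset of the neighbor for each angle at distance d: angle 0 is
# the pixel to the right, angles rotate counter-clockwise.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCM:
    """Normalized gray level co-occurrence matrix with its marginals."""

    P: np.ndarray  # 256x256, sums to 1
    distance: int
    angle: int
    marginal_mean_i: float
    marginal_mean_j: float
    marginal_var_i: float
    marginal_var_j: float


def _marginals(P: np.ndarray) -> tuple[float, float, float, float]:
    levels = np.arange(N_LEVELS, dtype=np.float64)
    p_i = P.sum(axis=1)
    p_j = P.sum(axis=0)
    mu_i = float(levels @ p_i)
    mu_j = float(levels @ p_j)
    var_i = float(((levels - mu_i) ** 2) @ p_i)
    var_j = float(((levels - mu_j) ** 2) @ p_j)
    return mu_i, mu_j, var_i, var_j


def glcm(
    gray: np.ndarray,
    distance: int = 1,
    angle: int = 0,
    mask: Optional[np.ndarray] = None,
) -> GLCM:
    """Gray level co-occurrence matrix of an intensity grid.

    Ordered pixel pairs (reference -> neighbor at the angle's offset at the
    given distance) are counted over the grid and normalized to sum 1.
    When a mask is given, only pairs with both pixels inside it count.
    """
    g = np.asarray(gray)
    if g.ndim != 2 or min(g.shape) < 1:
        raise ValueError("gray must be a 2-D grid")
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}, got {angle}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if g.min() < 0 or g.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    g = np.rint(g).astype(np.int64)

    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = g.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"no valid pixel pairs: grid {h}x{w} too small for offset ({dr}, {dc})"
        )
    ref = g[r0:r1, c0:c1]
    nbr = g[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ref, nbr = ref[valid], nbr[valid]
        if ref.size == 0:
            raise ValueError("no valid pixel pairs inside the mask")
    counts = np.zeros((N_LEVELS, N_LEVELS), dtype=np.float64)
    np.add.at(counts, (ref.ravel(), nbr.ravel()), 1.0)
    P = counts / counts.sum()
    mu_i, mu_j, var_i, var_j = _marginals(P)
    return GLCM(P, distance, angle, mu_i, mu_j, var_i, var_j)


@dataclass(frozen=True)
class HaralickFeatures:
    """The five GLCM texture features used as the second-order signature."""

    contrast: float
    dissimilarity: float
    homogeneity: float
    asm: float  # angular second moment
    correlation: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.contrast, self.dissimilarity, self.homogeneity, self.asm, self.correlation]
        )


_I = np.arange(N_LEVELS, dtype=np.float64)[:, None]
_J = np.arange(N_LEVELS, dtype=np.float64)[None, :]
_DIFF = _I - _J
_DIFF2 = _DIFF**2
_ABSDIFF = np.abs(_DIFF)
_HOMOG_W = 1.0 / (1.0 + _DIFF2)


def haralick(g: GLCM) -> HaralickFeatures:
    """Texture features of one GLCM.

    contrast      = sum P[i,j] (i-j)^2
    dissimilarity = sum P[i,j] |i-j|
    homogeneity   = sum P[i,j] / (1 + (i-j)^2)
    asm           = sum P[i,j]^2
    correlation   = sum P[i,j] (i-mu_i)(j-mu_j) / sqrt(var_i var_j),
                    defined as 1 for a constant image (zero variance).
    """
    P = g.P
    contrast = float((P * _DIFF2).sum())
    dissimilarity = float((P * _ABSDIFF).sum())
    homogeneity = float((P * _HOMOG_W).sum())
    asm = float((P * P).sum())
    denom = g.marginal_var_i * g.marginal_var_j
    if denom <= 0:
        correlation = 1.0
    else:
        correlation = float(
            (P * (_I - g.marginal_mean_i) * (_J - g.marginal_mean_j)).sum() / np.sqrt(denom)
        )
    return HaralickFeatures(contrast, dissimilarity, homogeneity, asm, correlation)


def haralick_averaged(
    gray: np.ndarray, distance: int = 1, mask: Optional[np.ndarray] = None
) -> HaralickFeatures:
    """Haralick features averaged over the four standard angles."""
    feats = [haralick(glcm(gray, distance, a, mask)).as_array() for a in GLCM_ANGLES]
    mean = np.mean(feats, axis=0)
    return HaralickFeatures(*[float(v) for v in mean])


def luminance(pixels: np.ndarray) -> np.ndarray:
    """8-bit grayscale via ITU-R 601 weights, rounded to nearest integer."""
    p = np.asarray(pixels, dtype=np.float64)
    y = 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def _signature_from_pixels(
    pixels: np.ndarray, mask: Optional[np.ndarray], distance: int
) -> np.ndarray:
    fo = first_order_rgb(pixels, mask)
    har = haralick_averaged(luminance(pixels), distance, mask)
    return np.concatenate([fo["r"].as_array(), fo["g"].as_array(), fo["b"].as_array(), har.as_array()])


def slide_signature(region: RegionImage, distance: int = 1) -> np.ndarray:
    """20-value feature vector of a slide region at the 5 um/px stats scale.

    The region is area-averaged down to 5 um/px, restricted to the ROI mask
    when present, and summarized as per-channel first-order statistics plus
    angle-averaged Haralick features of the luminance.  Column order is
    :data:`SIGNATURE_COLUMNS`.
    """
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        low = downsample_for_slide_stats(region)
    mask = low.roi_mask
    if mask is not None and not mask.any():
        raise ValueError("ROI mask is empty after downsampling")
    return _signature_from_pixels(low.pixels, mask, distance)


def tile_signature(tile: TileImage, distance: int = 1) -> np.ndarray:
    """20-value feature vector of a single tile at its native scale."""
    return _signature_from_pixels(tile.pixels, None, distance)
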