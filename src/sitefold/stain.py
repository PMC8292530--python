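"""Stain normalization, HSV augmentation, and the artificial stain artifact.

Four normalizers are provided, mirroring common digital-pathology practice:

* **Reinhard** — moment matching in CIELAB: each channel is affinely mapped
  so its mean/standard deviation equal a reference's.
* **Macenko** — stain-vector deconvolution: hematoxylin/eosin absorbance
  directions are estimated from the optical-density cloud (top-2
  eigenvector plane, extreme-percentile angles), concentrations are solved
  by least squares and mapped onto a reference stain basis.
* **grayscale** — ITU-R 601 luminance replicated across channels.
* **grayscale equalized** — luminance followed by 256-bin histogram
  equalization.

Augmentation multiplies HSV channels by random scalars (light: all three by
U(0.9, 1.1); heavy: hue and saturation by U(0.7, 1.3)).  The artificial
stain artifact multiplies all three HSV channels by 1+strength with
strength at most 5% — a deliberately subtle, site-like color shift.  Hue is
circular, so hue multiplication wraps modulo 1; saturation and value clip
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .tiles import TileImage

__all__ = [
    "ReinhardReference",
    "MacenkoReference",
    "BackgroundTileError",
    "reinhard",
    "macenko",
    "estimate_macenko_reference",
    "grayscale",
    "grayscale_equalized",
    "hsv_augment",
    "apply_stain_artifact",
    "standardize",
    "scale_hsv",
    "default_reference_tile",
]

MACENKO_BETA = 0.15  # OD threshold below which a pixel is background
MACENKO_ALPHA = 1.0  # percentile for extreme stain angles (1st/99th)


class BackgroundTileError(ValueError):
    """Tile has too little tissue signal for stain estimation."""


def _as_float01(tile: TileImage) -> np.ndarray:
    return tile.pixels.astype(np.float64) / 255.0


def _to_tile(pixels01: np.ndarray, like: TileImage) -> TileImage:
    out = np.clip(np.rint(pixels01 * 255.0), 0, 255).astype(np.uint8)
    return TileImage(
        pixels=out,
        microns_per_pixel=like.microns_per_pixel,
        origin=like.origin,
        slide_id=like.slide_id,
    )


# ---------------------------------------------------------------------------
# Reinhard


@dataclass
class ReinhardReference:
    """Target per-channel LAB mean and standard deviation."""

    mean_lab: np.ndarray
    std_lab: np.ndarray

    def __post_init__(self) -> None:
        self.mean_lab = np.asarray(self.mean_lab, dtype=np.float64)
        self.std_lab = np.asarray(self.std_lab, dtype=np.float64)
        if self.mean_lab.shape != (3,) or self.std_lab.shape != (3,):
            raise ValueError("ReinhardReference needs 3 LAB means and stds")
        if np.any(self.std_lab <= 0):
            raise ValueError("reference LAB standard deviations must be > 0")

    @classmethod
    def from_tile(cls, tile: TileImage) -> "ReinhardReference":
        lab = skcolor.rgb2lab(_as_float01(tile))
        std = lab.reshape(-1, 3).std(axis=0)
        # guard: a constant channel in the reference itself
        std = np.where(std <= 0, 1e-6, std)
        return cls(lab.reshape(-1, 3).mean(axis=0), std)


def reinhard(tile: TileImage, ref: ReinhardReference) -> TileImage:
    """Map a tile's LAB channel statistics onto the reference's.

    A zero-variance source channel is set flat to the reference mean.
    """
    lab = skcolor.rgb2lab(_as_float01(tile))
    flat = lab.reshape(-1, 3)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    out = np.empty_like(flat)
    for c in range(3):
        if std[c] <= 1e-12:
            out[:, c] = ref.mean_lab[c]
        else:
            out[:, c] = (flat[:, c] - mean[c]) / std[c] * ref.std_lab[c] + ref.mean_lab[c]
    rgb = skcolor.lab2rgb(out.reshape(lab.shape))
    return _to_tile(np.clip(rgb, 0.0, 1.0), tile)


# ---------------------------------------------------------------------------
# Macenko


@dataclass
class MacenkoReference:
    """Reference H/E stain basis and 99th-percentile concentrations."""

    stain_matrix: np.ndarray  # 3x2, unit columns (hematoxylin, eosin)
    max_concentrations: np.ndarray  # length-2

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=np.float64)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=np.float64)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain_matrix columns must be unit-norm")
        if self.max_concentrations.shape != (2,) or np.any(self.max_concentrations <= 0):
            raise ValueError("max_concentrations must be 2 positive values")


def _optical_density(pixels: np.ndarray) -> np.ndarray:
    """OD = -log((I+1)/256), flattened to N x 3."""
    od = -np.log((pixels.astype(np.float64) + 1.0) / 256.0)
    return od.reshape(-1, 3)


def _estimate_stains(
    od: np.ndarray, alpha: float, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the 3x2 H/E stain matrix from an OD point cloud."""
    tissue = od[~np.all(od < beta, axis=1)]
    if tissue.shape[0] < 10:
        raise BackgroundTileError(
            f"only {tissue.shape[0]} pixels exceed the OD threshold {beta}; "
            "tile appears to be background"
        )
    cov = np.cov(tissue, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    plane = evecs[:, [2, 1]]  # top-2 eigenvectors as columns
    # orient the first axis along the mean OD direction so the angular
    # distribution does not straddle the arctan branch cut
    if tissue.mean(axis=0) @ plane[:, 0] < 0:
        plane[:, 0] = -plane[:, 0]
    # project onto the plane and find extreme angles
    proj = tissue @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi_min = np.percentile(phi, alpha)
    phi_max = np.percentile(phi, 100.0 - alpha)
    v1 = plane @ np.array([np.cos(phi_min), np.sin(phi_min)])
    v2 = plane @ np.array([np.cos(phi_max), np.sin(phi_max)])
    # stain absorbances are non-negative directions
    if v1.sum() < 0:
        v1 = -v1
    if v2.sum() < 0:
        v2 = -v2
    # hematoxylin absorbs red more strongly: larger first (R) OD component
    if v1[0] > v2[0]:
        he = np.column_stack([v1, v2])
    else:
        he = np.column_stack([v2, v1])
    he /= np.linalg.norm(he, axis=0, keepdims=True)
    return he, tissue


def estimate_macenko_reference(
    tile: TileImage, alpha: float = MACENKO_ALPHA, beta: float = MACENKO_BETA
) -> MacenkoReference:
    """Estimate a tile's own stain basis and max concentrations."""
    od = _optical_density(tile.pixels)
    he, _ = _estimate_stains(od, alpha, beta)
    conc, *_ = np.linalg.lstsq(he, od.T, rcond=None)
    max_c = np.percentile(conc, 99.0, axis=1)
    max_c = np.where(max_c <= 0, 1e-6, max_c)
    return MacenkoReference(stain_matrix=he, max_concentrations=max_c)


def macenko(
    tile: TileImage,
    ref: MacenkoReference,
    alpha: float = MACENKO_ALPHA,
    beta: float = MACENKO_BETA,
) -> TileImage:
    """Macenko stain normalization toward a reference H/E basis.

    The tile's own stain vectors are estimated from the optical-density
    cloud (pixels whose OD is below ``beta`` in every channel are excluded
    from estimation), concentrations are solved by least squares for every
    pixel, rescaled so the 99th-percentile concentration of each stain
    matches the reference, and the image is rebuilt with the reference
    stain matrix.
    """
    od = _optical_density(tile.pixels)
    he, _ = _estimate_stains(od, alpha, beta)
    conc, *_ = np.linalg.lstsq(he, od.T, rcond=None)  # 2 x N
    max_c = np.percentile(conc, 99.0, axis=1)
    max_c = np.where(max_c <= 0, 1e-6, max_c)
    conc = conc * (ref.max_concentrations / max_c)[:, None]
    od_out = (ref.stain_matrix @ conc).T.reshape(tile.pixels.shape)
    rgb = 256.0 * np.exp(-od_out) - 1.0
    return _to_tile(np.clip(rgb, 0.0, 255.0) / 255.0, tile)


# ---------------------------------------------------------------------------
# Grayscale family

#: ITU-R 601 luminance weights (R, G, B).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def _luma_u8(pixels: np.ndarray) -> np.ndarray:
    p = pixels.astype(np.float64)
    y = LUMA_WEIGHTS[0] * p[..., 0] + LUMA_WEIGHTS[1] * p[..., 1] + LUMA_WEIGHTS[2] * p[..., 2]
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def grayscale(tile: TileImage) -> TileImage:
    """Replace color with ITU-R 601 luminance replicated across channels."""
    y = _luma_u8(tile.pixels)
    return _to_tile(np.repeat(y[..., None], 3, axis=2) / 255.0, tile)


def grayscale_equalized(tile: TileImage) -> TileImage:
    """Grayscale conversion followed by 256-bin histogram equalization."""
    y = _luma_u8(tile.pixels)
    hist = np.bincount(y.ravel(), minlength=256)
    cdf = np.cumsum(hist) / y.size
    lut = np.clip(np.rint(cdf * 255.0), 0, 255).astype(np.uint8)
    eq = lut[y]
    return _to_tile(np.repeat(eq[..., None], 3, axis=2) / 255.0, tile)


# ---------------------------------------------------------------------------
# HSV scaling: augmentation and the artificial artifact


def scale_hsv(pixels: np.ndarray, factors: tuple[float, float, float]) -> np.ndarray:
    """Multiply the HSV channels of an 8-bit RGB array by per-channel factors.

    Hue wraps modulo 1 (it is circular); saturation and value clip to
    [0, 1].  This single transform underlies both the augmentation ops and
    the artificial stain artifact, and the synthetic generator's
    site-specific shifts.
    """
    hsv = skcolor.rgb2hsv(pixels.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] * factors[0]) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * factors[1], 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * factors[2], 0.0, 1.0)
    rgb = skcolor.hsv2rgb(hsv)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def hsv_augment(tile: TileImage, level: str, rng: np.random.Generator) -> TileImage:
    """Random HSV color augmentation.

    ``light`` multiplies hue, saturation, and value each by an independent
    scalar from U(0.9, 1.1); ``heavy`` multiplies hue and saturation by
    independent scalars from U(0.7, 1.3) and leaves value untouched.
    """
    if level == "light":
        f = tuple(rng.uniform(0.9, 1.1, size=3))
    elif level == "heavy":
        h, s = rng.uniform(0.7, 1.3, size=2)
        f = (h, s, 1.0)
    else:
        raise ValueError(f"level must be 'light' or 'heavy', got {level!r}")
    return TileImage(
        pixels=scale_hsv(tile.pixels, f),
        microns_per_pixel=tile.microns_per_pixel,
        origin=tile.origin,
        slide_id=tile.slide_id,
    )


def apply_stain_artifact(tile: TileImage, strength: float, force: bool = False) -> TileImage:
    """Apply the artificial site-like stain shift: HSV scaled by 1+strength.

    ``strength`` must lie in [0, 0.05] (a 0-5% increase in hue, saturation,
    and value) unless ``force`` is given.
    """
    if not force and not (0.0 <= strength <= 0.05):
        raise ValueError(
            f"artifact strength {strength} outside [0, 0.05]; pass force=True to override"
        )
    f = 1.0 + strength
    return TileImage(
        pixels=scale_hsv(tile.pixels, (f, f, f)),
        microns_per_pixel=tile.microns_per_pixel,
        origin=tile.origin,
        slide_id=tile.slide_id,
    )


def standardize(tile: TileImage) -> np.ndarray:
    """Zero-mean unit-variance float grid over all pixels and channels jointly."""
    x = tile.pixels.astype(np.float64)
    std = x.std()
    if std <= 1e-12:
        raise ValueError("cannot standardize a constant tile")
    return (x - x.mean()) / std


# ---------------------------------------------------------------------------
# Default reference


def default_reference_tile(edge: int = 128) -> TileImage:
    """Deterministic synthetic H&E-like reference tile.

    Generated in code (fixed seed) rather than shipped as an image so that
    default normalization references are reproducible offline.
    """
    from .synthetic import TextureParams, _render_one_tile

    rng = np.random.default_rng(20201205)
    params = TextureParams()
    pixels = _render_one_tile(rng, params, blob_multiplier=1.0, edge=edge)
    return TileImage(pixels=pixels, microns_per_pixel=1.0, slide_id="reference")


def default_reinhard_reference() -> ReinhardReference:
    return ReinhardReference.from_tile(default_reference_tile())


def default_macenko_reference() -> MacenkoReference:
    return estimate_macenko_reference(default_reference_tile())
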