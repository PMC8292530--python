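"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each statistic by direct summation
(plain Python loops over pixels / matrix cells / pairs) so they share no
code path with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from sitefold.synthetic import TextureParams, _render_one_tile
from sitefold.tiles import TileImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def textured_tile(rng):
    """A synthetic H&E-like tile (blobs on a pink background)."""
    pixels = _render_one_tile(rng, TextureParams(), 1.0, edge=96)
    return TileImage(pixels=pixels, microns_per_pixel=1.0, slide_id="fixture")


def make_two_stain_tile(seed: int = 5, edge: int = 64):
    """Synthetic two-stain tile from known H/E absorbance vectors.

    Concentrations are drawn uniformly from zero (so near-pure-stain pixels
    exist, as in real tissue where nuclei and stroma regions are close to
    single-stain).  Returns (tile, H, E).
    """
    gen = np.random.default_rng(seed)
    h = np.array([0.65, 0.70, 0.29])
    e = np.array([0.07, 0.99, 0.11])
    h = h / np.linalg.norm(h)
    e = e / np.linalg.norm(e)
    n = edge * edge
    c1 = gen.uniform(0.0, 1.2, n)
    c2 = gen.uniform(0.0, 1.0, n)
    od = np.outer(c1, h) + np.outer(c2, e)
    pixels = np.clip(256.0 * np.exp(-od) - 1.0, 0, 255).reshape(edge, edge, 3)
    return TileImage(pixels=pixels.astype(np.uint8), microns_per_pixel=1.0), h, e


# ---------------------------------------------------------------------------
# Naive oracles


def naive_first_order(values) -> dict:
    xs = [float(v) for v in np.asarray(values).ravel()]
    n = len(xs)
    mean = sum(xs) / n
    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    m4 = sum((x - mean) ** 4 for x in xs) / n
    hist = [0] * 256
    for x in xs:
        hist[int(round(x))] += 1
    entropy = -sum((c / n) * math.log(c / n) for c in hist if c > 0)
    return {
        "mean": mean,
        "std": math.sqrt(m2),
        "skewness": m3 / m2**1.5 if m2 > 0 else float("nan"),
        "kurtosis": m4 / m2**2 if m2 > 0 else float("nan"),
        "entropy": entropy,
    }


_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def naive_glcm(gray, distance: int, angle: int) -> np.ndarray:
    g = np.asarray(gray, dtype=int)
    dr, dc = _OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = g.shape
    P = np.zeros((256, 256))
    count = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                P[g[r, c], g[r2, c2]] += 1
                count += 1
    return P / count


def naive_haralick(P: np.ndarray) -> dict:
    mu_i = sum(i * P[i, j] for i in range(256) for j in range(256) if P[i, j])
    mu_j = sum(j * P[i, j] for i in range(256) for j in range(256) if P[i, j])
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(256) for j in range(256) if P[i, j])
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(256) for j in range(256) if P[i, j])
    contrast = dissim = homog = asm = corr = 0.0
    for i in range(256):
        for j in range(256):
            p = P[i, j]
            if not p:
                continue
            contrast += p * (i - j) ** 2
            dissim += p * abs(i - j)
            homog += p / (1 + (i - j) ** 2)
            asm += p * p
            corr += p * (i - mu_i) * (j - mu_j)
    denom = var_i * var_j
    corr = 1.0 if denom <= 0 else corr / math.sqrt(denom)
    return {
        "contrast": contrast,
        "dissimilarity": dissim,
        "homogeneity": homog,
        "asm": asm,
        "correlation": corr,
    }


def naive_auroc(labels, scores) -> float:
    """Exhaustive concordant-pair count with ties at 1/2."""
    pos = [s for y, s in zip(labels, scores) if y]
    neg = [s for y, s in zip(labels, scores) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def naive_anova_f(groups) -> float:
    allv = [x for g in groups for x in g]
    grand = sum(allv) / len(allv)
    ss_b = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_w = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ss_b / df_b) / (ss_w / df_w)
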