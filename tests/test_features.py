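import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_first_order, naive_glcm, naive_haralick
from sitefold.features import (
    GLCM_ANGLES,
    SIGNATURE_COLUMNS,
    first_order,
    glcm,
    haralick,
    haralick_averaged,
    luminance,
    slide_signature,
    tile_signature,
)
from sitefold.tiles import RegionImage


def checkerboard(n=8):
    g = np.indices((n, n)).sum(axis=0) % 2
    return (g * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# First-order


def test_symmetric_two_point_sample():
    s = first_order(np.array([0, 255] * 32))
    assert s.mean == pytest.approx(127.5)
    assert s.std == pytest.approx(127.5)
    assert s.skewness == pytest.approx(0.0, abs=1e-12)
    assert s.kurtosis == pytest.approx(1.0)
    assert s.entropy == pytest.approx(math.log(2))


def test_uniform_histogram_maximizes_entropy():
    s = first_order(np.arange(256))
    assert s.entropy == pytest.approx(math.log(256))


def test_constant_sample_marks_moments_undefined():
    s = first_order(np.full(10, 7))
    assert s.std == 0.0
    assert math.isnan(s.skewness) and math.isnan(s.kurtosis)
    assert s.entropy == pytest.approx(0.0)


def test_first_order_matches_naive_oracle(rng):
    for _ in range(20):
        sample = rng.integers(0, 256, size=(64, 64))
        ours = first_order(sample)
        ref = naive_first_order(sample)
        for name in ("mean", "std", "skewness", "kurtosis", "entropy"):
            assert getattr(ours, name) == pytest.approx(ref[name], abs=1e-10)


def test_skewness_flips_kurtosis_invariant_under_negation(rng):
    sample = rng.integers(0, 256, size=500)
    a = first_order(sample)
    b = first_order(255 - sample)
    assert a.skewness == pytest.approx(-b.skewness, abs=1e-9)
    assert a.kurtosis == pytest.approx(b.kurtosis, abs=1e-9)


# ---------------------------------------------------------------------------
# GLCM


def test_single_pair_grid():
    g = glcm(np.array([[0, 255]]), distance=1, angle=0)
    assert g.P[0, 255] == 1.0
    assert g.P.sum() == 1.0


def test_checkerboard_horizontal_pairs():
    g = glcm(checkerboard(), distance=1, angle=0)
    # 8 rows x 7 ordered pairs, alternating 0->255 and 255->0
    assert g.P[0, 255] == pytest.approx(0.5)
    assert g.P[255, 0] == pytest.approx(0.5)


def test_marginals_recomputable(rng):
    g = glcm(rng.integers(0, 256, size=(16, 16)), distance=2, angle=45)
    levels = np.arange(256.0)
    p_i = g.P.sum(axis=1)
    assert g.marginal_mean_i == pytest.approx(levels @ p_i, abs=1e-12)
    assert g.marginal_var_i == pytest.approx(((levels - g.marginal_mean_i) ** 2) @ p_i, abs=1e-12)


def test_too_small_grid_is_an_error():
    with pytest.raises(ValueError, match="pairs"):
        glcm(np.array([[0], [1]]), distance=1, angle=0)
    with pytest.raises(ValueError, match="angle"):
        glcm(np.zeros((4, 4)), distance=1, angle=30)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=2**31 - 1),
    st.sampled_from(GLCM_ANGLES),
    st.integers(min_value=1, max_value=3),
)
def test_glcm_is_a_probability_matrix(seed, angle, distance):
    g = np.random.default_rng(seed).integers(0, 256, size=(8, 8))
    out = glcm(g, distance=distance, angle=angle)
    assert out.P.min() >= 0
    assert out.P.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Haralick


def test_constant_image_features():
    h = haralick(glcm(np.full((8, 8), 42), distance=1, angle=0))
    assert (h.contrast, h.dissimilarity) == (0.0, 0.0)
    assert (h.homogeneity, h.asm, h.correlation) == (1.0, 1.0, 1.0)


def test_checkerboard_closed_forms():
    h = haralick(glcm(checkerboard(), distance=1, angle=0))
    assert h.contrast == pytest.approx(255**2)
    assert h.dissimilarity == pytest.approx(255.0)
    assert h.asm == pytest.approx(0.5)
    assert h.homogeneity == pytest.approx(1.0 / (1 + 255**2))
    assert h.correlation == pytest.approx(-1.0)


def test_haralick_matches_naive_oracle(rng):
    for _ in range(5):
        img = rng.integers(0, 256, size=(32, 32))
        for angle in GLCM_ANGLES:
            ours = haralick(glcm(img, 1, angle))
            ref = naive_haralick(naive_glcm(img, 1, angle))
            for name, val in ref.items():
                assert getattr(ours, name) == pytest.approx(val, abs=1e-10)


def test_glcm_matches_skimage(rng):
    """Cross-check against scikit-image's graycomatrix.

    scikit-image measures angles with the row axis pointing down, so its
    pair direction is the reverse of ours for the non-horizontal angles:
    our P equals its P transposed, at the mirrored angle for the diagonals.
    """
    graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
    img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
    mapping = {
        0: (0.0, False),
        45: (3 * np.pi / 4, True),
        90: (np.pi / 2, True),
        135: (np.pi / 4, True),
    }
    for angle, (rad, transpose) in mapping.items():
        ours = glcm(img, distance=1, angle=angle)
        theirs = graycomatrix(img, [1], [rad], levels=256, symmetric=False, normed=True)
        ref = theirs[:, :, 0, 0]
        if transpose:
            ref = ref.T
        assert np.allclose(ours.P, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# Signatures


def test_angle_average_invariant_under_rotation(rng):
    img = rng.integers(0, 256, size=(20, 20))
    a = haralick_averaged(img).as_array()
    b = haralick_averaged(np.rot90(img)).as_array()
    assert np.allclose(a, b, atol=1e-10)


def test_luminance_weights():
    px = np.zeros((1, 1, 3))
    px[0, 0] = (100, 200, 50)
    assert luminance(px)[0, 0] == round(0.299 * 100 + 0.587 * 200 + 0.114 * 50)


def test_slide_signature_constant_region_matches_constant_image():
    pixels = np.full((400, 400, 3), (200, 150, 170), dtype=np.uint8)
    region = RegionImage(pixels=pixels, microns_per_pixel=1.0)
    sig = dict(zip(SIGNATURE_COLUMNS, slide_signature(region)))
    assert sig["mean_r"] == pytest.approx(200.0)
    assert sig["contrast"] == 0.0
    assert sig["asm"] == 1.0
    assert sig["correlation"] == 1.0


def test_slide_signature_empty_mask_is_an_error():
    pixels = np.full((100, 100, 3), 100, dtype=np.uint8)
    region = RegionImage(
        pixels=pixels, microns_per_pixel=1.0, roi_mask=np.zeros((100, 100), dtype=bool)
    )
    with pytest.raises(ValueError, match="mask"):
        slide_signature(region)


def test_tile_signature_column_count(textured_tile):
    assert tile_signature(textured_tile).shape == (len(SIGNATURE_COLUMNS),)
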