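"""Unit and property tests for the pixel-level descriptor operators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.feature import local_binary_pattern

from mammotex.descriptors import (
    CANONICAL_ORIENTATIONS,
    DescriptorConfig,
    EllipseSpec,
    PixelNeighborhood,
    code_image,
    elbp_code,
    ellipse_coords,
    kirsch_kernels,
    kirsch_responses,
    lbp_code,
    ldp_code,
    melbp_code,
    sample_intensity,
    threshold_step,
    transition_count,
    uniform_bin_count,
    uniform_bin_index,
    uniform_bin_map,
)
from mammotex.features import descriptor_histogram


# ---------------------------------------------------------------------------
# thresholding and neighbourhood codes

@pytest.mark.parametrize("x,expected", [(0, 1), (-1, 0), (3.5, 1), (-0.001, 0)])
def test_threshold_step(x, expected):
    assert threshold_step(x) == expected


@pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
def test_threshold_step_rejects_nonfinite(bad):
    with pytest.raises(ValueError):
        threshold_step(bad)


def test_lbp_code_examples():
    # s(0) = 1 for every bit -> all-ones code
    assert lbp_code(PixelNeighborhood(100, (100,) * 8)) == 255
    # every difference negative -> zero code
    assert lbp_code(PixelNeighborhood(200, (0,) * 8)) == 0
    # alternating above/below: bits i = 1,3,5,7 set -> 1 + 4 + 16 + 64
    assert lbp_code(PixelNeighborhood(5, (6, 4, 6, 4, 6, 4, 6, 4))) == 85


def test_empty_neighborhood_rejected():
    with pytest.raises(ValueError):
        PixelNeighborhood(5, ())


# ---------------------------------------------------------------------------
# elliptical geometry and sampling

def test_ellipse_coords_canonical_points():
    spec = EllipseSpec(r1=4, r2=7, theta=0.0, p=8)
    pts = ellipse_coords((10, 10), spec)
    assert pts[0] == pytest.approx((14, 10))  # i=1: angle 0, x + R1
    assert pts[2] == pytest.approx((10, 3))   # i=3: angle 90deg, y - R2


def test_ellipse_coords_circle_degeneracy():
    pts = ellipse_coords((0, 0), EllipseSpec(r1=2, r2=2, p=8))
    assert np.allclose(np.hypot(pts[:, 0], pts[:, 1]), 2.0)
    assert pts[0] == pytest.approx((2, 0))
    assert pts[2] == pytest.approx((0, -2))


def test_ellipse_coords_rotation_swaps_axes():
    # at theta=90 the horizontal semi-axis R1 becomes vertical
    pts = ellipse_coords((0, 0), EllipseSpec(r1=4, r2=7, theta=90.0, p=8))
    assert pts[0] == pytest.approx((0, -4))
    assert pts[2] == pytest.approx((-7, 0))


def test_sample_intensity():
    img = np.arange(30, dtype=float).reshape(5, 6)
    assert sample_intensity(img, (3, 4)) == img[4, 3]
    row = np.array([[0.0, 10.0]])
    assert sample_intensity(row, (0.5, 0)) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        sample_intensity(img, (-1, 2))
    with pytest.raises(ValueError):
        sample_intensity(img, (5.5, 0))


# ---------------------------------------------------------------------------
# ELBP / M-ELBP

def test_elbp_constant_image_all_ones():
    img = np.full((30, 30), 57.0)
    spec = EllipseSpec(r1=4, r2=7)
    assert elbp_code(img, (15, 15), spec) == 255


def test_elbp_bright_center_is_zero():
    img = np.zeros((20, 20))
    img[10, 10] = 200
    assert elbp_code(img, (10, 10), EllipseSpec(r1=3, r2=2)) == 0


def test_elbp_circle_equals_lbp(rng):
    """With R1 == R2 the elliptical descriptor degenerates to circular LBP."""
    img = rng.integers(0, 256, (24, 24)).astype(float)
    spec = EllipseSpec(r1=2, r2=2)
    for y in range(3, 21):
        for x in range(3, 21):
            pts = ellipse_coords((x, y), spec)
            nb = PixelNeighborhood(
                img[y, x], tuple(sample_intensity(img, (px, py)) for px, py in pts)
            )
            assert elbp_code(img, (x, y), spec) == lbp_code(nb)


def test_circular_lbp_matches_skimage(rng):
    """Independent oracle: scikit-image's default LBP agrees exactly."""
    for _ in range(5):
        img = rng.integers(0, 256, (32, 32)).astype(float)
        cfg = DescriptorConfig("elbp", r1=2, r2=2, orientations=(0.0,))
        ci = code_image(img, cfg)
        ref = local_binary_pattern(img, 8, 2, method="default").astype(int)
        m = ci.margin
        assert np.array_equal(ci.codes[m:-m, m:-m], ref[m:-m, m:-m])


def test_melbp_constant_image():
    img = np.full((30, 30), 19.0)
    assert melbp_code(img, (15, 15), EllipseSpec(r1=4, r2=7)) == 255


def test_melbp_window_one_equals_nearest_elbp(rng):
    img = rng.integers(0, 256, (30, 30)).astype(float)
    spec = EllipseSpec(r1=3, r2=2)
    for y in range(4, 26, 3):
        for x in range(4, 26, 3):
            assert melbp_code(img, (x, y), spec, mean_window=1) == elbp_code(
                img, (x, y), spec, sampling="nearest"
            )


def test_melbp_single_low_neighbor_clears_one_bit():
    """Constructed image: neighbour 1's patch mean is below the centre,
    all other patch means above -> code 0b11111110 = 254."""
    img = np.full((17, 17), 100.0)
    spec = EllipseSpec(r1=4, r2=7)
    center = (8, 8)
    for i, (xi, yi) in enumerate(ellipse_coords(center, spec)):
        xr, yr = int(math.floor(xi + 0.5)), int(math.floor(yi + 0.5))
        img[yr - 1 : yr + 2, xr - 1 : xr + 2] = 99.0 if i == 0 else 101.0
    img[8, 8] = 100.0
    assert melbp_code(img, center, spec) == 254


# ---------------------------------------------------------------------------
# uniform patterns

@pytest.mark.parametrize(
    "code,p,expected",
    [(0b00000000, 8, 0), (0b01010101, 8, 8), (0b00001111, 8, 2), (0b1, 1, 0)],
)
def test_transition_count(code, p, expected):
    assert transition_count(code, p) == expected


def test_transition_count_range_check():
    with pytest.raises(ValueError):
        transition_count(256, 8)


def test_uniform_enumeration_oracle():
    """Brute force over all 256 eight-bit codes: 58 uniform, 59 bins,
    uniform codes map bijectively onto bins 0..57 in ascending order."""
    def brute_transitions(code):
        bits = [(code >> i) & 1 for i in range(8)]
        return sum(bits[i] != bits[(i + 1) % 8] for i in range(8))

    uniform = [c for c in range(256) if brute_transitions(c) <= 2]
    assert len(uniform) == 58
    assert uniform_bin_count(8) == 59
    assert [uniform_bin_index(c, 8) for c in uniform] == list(range(58))
    nonuniform = [c for c in range(256) if c not in uniform]
    assert {uniform_bin_index(c, 8) for c in nonuniform} == {58}
    table = uniform_bin_map(8)
    assert table.shape == (256,)


# ---------------------------------------------------------------------------
# Kirsch responses and LDP

def test_kirsch_constant_image_zero_responses():
    img = np.full((9, 9), 44.0)
    assert np.allclose(kirsch_responses(img, (4, 4)), 0.0)


def test_kirsch_kernel_structure():
    for k in kirsch_kernels():
        assert k.sum() == 0
        assert (k == 5).sum() == 3 and (k == -3).sum() == 5 and k[1, 1] == 0


def test_kirsch_mirror_permutes_directions(rng):
    """Horizontal mirroring maps direction j (angle 45j) to 180 - 45j."""
    patch = rng.uniform(0, 255, (3, 3))
    mirror = np.fliplr(patch)
    resp = kirsch_responses(patch, (1, 1))
    resp_m = kirsch_responses(mirror, (1, 1))
    perm = {0: 4, 1: 3, 2: 2, 3: 1, 4: 0, 5: 7, 6: 6, 7: 5}
    for j, jm in perm.items():
        assert resp[j] == pytest.approx(resp_m[jm])


def test_kirsch_step_edge_maximal_east_west():
    patch = np.array([[0, 0, 255], [0, 0, 255], [0, 0, 255]], dtype=float)
    img = np.pad(patch, 1, mode="edge")
    resp = np.abs(kirsch_responses(img, (2, 2)))
    assert set(np.flatnonzero(resp == resp.max())) <= {0, 4}


def test_ldp_code_examples():
    assert ldp_code([1, -2, 3, -4, 5, -6, 7, -8], 8) == 255
    assert ldp_code([1, -2, 3, -4, 5, -6, 7, -8], 0) == 0
    # |m| = 1..8 ascending: top-3 are directions 5, 6, 7 -> 224
    assert ldp_code([1, 2, 3, 4, 5, 6, 7, 8], 3) == 0b11100000
    with pytest.raises(ValueError):
        ldp_code([0] * 8, 9)
    with pytest.raises(ValueError):
        ldp_code([0] * 7, 3)


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=8, max_size=8),
    st.integers(0, 8),
)
def test_ldp_popcount_always_k(responses, k):
    assert bin(ldp_code(responses, k)).count("1") == k


def test_ldp_tie_break_prefers_lower_index():
    assert ldp_code([1, 1, 1, 1, 1, 1, 1, 1], 3) == 0b111


# ---------------------------------------------------------------------------
# code images

def test_code_image_valid_region_and_determinism(rng):
    img = rng.integers(0, 256, (40, 40)).astype(np.uint8)
    for family in ("lbp", "elbp", "uelbp", "melbp", "ldp"):
        cfg = DescriptorConfig(family)
        ci = code_image(img, cfg, theta=45.0)
        m = cfg.margin
        assert ci.valid_codes().size == (40 - 2 * m) ** 2
        ci2 = code_image(img, cfg, theta=45.0)
        assert np.array_equal(ci.codes, ci2.codes)


def test_code_image_constant_lbp():
    ci = code_image(np.full((64, 64), 90, dtype=np.uint8), DescriptorConfig("lbp"))
    assert set(ci.valid_codes().tolist()) == {255}


def test_code_image_too_small_rejected():
    with pytest.raises(ValueError):
        code_image(np.zeros((10, 10)), DescriptorConfig("elbp"))  # margin 7


def test_code_image_matches_scalar_operators(rng):
    """The vectorised path agrees with the per-pixel operators."""
    img = rng.integers(0, 256, (26, 26)).astype(float)
    cfg = DescriptorConfig("melbp", r1=3, r2=4, orientations=(30.0,))
    ci = code_image(img, cfg, theta=30.0)
    spec = cfg.ellipse(30.0)
    m = cfg.margin
    for y in range(m, 26 - m, 3):
        for x in range(m, 26 - m, 3):
            assert ci.codes[y, x] == melbp_code(img, (x, y), spec)
    cfg2 = DescriptorConfig("elbp", r1=3, r2=4)
    ci2 = code_image(img, cfg2, theta=30.0)
    spec2 = cfg2.ellipse(30.0)
    m2 = cfg2.margin
    for y in range(m2, 26 - m2, 3):
        for x in range(m2, 26 - m2, 3):
            assert ci2.codes[y, x] == elbp_code(img, (x, y), spec2)
    cfg3 = DescriptorConfig("ldp", k=3)
    ci3 = code_image(img, cfg3)
    for y in range(1, 25, 3):
        for x in range(1, 25, 3):
            assert ci3.codes[y, x] == ldp_code(kirsch_responses(img, (x, y)), 3)


def test_gray_shift_and_scale_invariance(rng):
    """Adding a constant or scaling intensities leaves the codes unchanged
    (intensity differences and response rankings are invariant)."""
    img = rng.uniform(10, 100, (36, 36))
    for family in ("lbp", "elbp", "melbp", "ldp"):
        cfg = DescriptorConfig(family)
        base = code_image(img, cfg).codes
        assert np.array_equal(base, code_image(img + 25.0, cfg).codes)
        assert np.array_equal(base, code_image(img * 2.0, cfg).codes)


def test_rotate_image_and_theta_together(smooth_image):
    """Rotating the image by 90deg and the ellipse orientation by 90deg
    gives the same code histogram (the sampling grid maps onto itself)."""
    cfg = DescriptorConfig("elbp", r1=4, r2=7)
    h0 = descriptor_histogram(smooth_image, cfg, theta=0.0)
    h1 = descriptor_histogram(np.rot90(smooth_image), cfg, theta=90.0)
    assert np.abs(h0 - h1).sum() <= 0.02
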