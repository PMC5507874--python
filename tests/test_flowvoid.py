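"""Cutoff computation, strict-below binarization, isodata thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccflowvoid import (
    DegenerateInputError,
    EnFaceImage,
    ParameterError,
    binarize_below,
    compute_cutoff,
    detect_artifacts,
    extract_slab,
    canonical_slab_specs,
    global_threshold_binarize,
    isodata_threshold,
)


def img(arr, kind="decorrelation"):
    return EnFaceImage(np.asarray(arr, float), 10.0, kind)


class TestComputeCutoff:
    def test_uniform_slab(self):
        assert compute_cutoff(img(np.full((8, 8), 0.2))).cutoff == pytest.approx(0.2)

    def test_two_value_mean(self):
        a = np.full((8, 8), 0.1)
        a[:4] = 0.3
        res = compute_cutoff(img(a))
        assert res.cutoff == pytest.approx(0.2)
        assert res.n_pixels_used == 64

    def test_exclusion_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.random((16, 16))
        exclude = a > np.quantile(a, 0.75)
        res = compute_cutoff(img(a), exclude)
        manual = np.mean([a[y, x] for y in range(16) for x in range(16) if not exclude[y, x]])
        assert res.cutoff == pytest.approx(manual)
        assert res.n_pixels_used == int((~exclude).sum())

    def test_all_excluded_raises(self):
        with pytest.raises(DegenerateInputError):
            compute_cutoff(img(np.zeros((4, 4))), np.ones((4, 4), bool))

    def test_reflectance_slab_rejected(self):
        with pytest.raises(ParameterError):
            compute_cutoff(img(np.zeros((4, 4)), kind="reflectance"))


class TestBinarizeBelow:
    def test_cutoff_zero_is_empty(self):
        assert not binarize_below(img(np.random.default_rng(0).random((8, 8))), 0.0).any()

    def test_strict_inequality_at_cutoff(self):
        mask = binarize_below(img(np.array([[0.1, 0.2, 0.3]] * 3)), 0.2)
        assert mask.sum() == 3 and mask[:, 0].all() and not mask[:, 1:].any()

    @settings(derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        c1=st.floats(0.0, 1.0),
        c2=st.floats(0.0, 1.0),
    )
    def test_monotone_in_cutoff(self, seed, c1, c2):
        lo, hi = sorted((c1, c2))
        pixels = np.random.default_rng(seed).random((12, 12))
        m_lo = binarize_below(img(pixels), lo)
        m_hi = binarize_below(img(pixels), hi)
        assert not (m_lo & ~m_hi).any()

    @pytest.mark.parametrize("scale", [0.5, 0.25])
    def test_scale_consistency(self, scale):
        pixels = np.random.default_rng(7).random((16, 16))
        cutoff = 0.4
        base = binarize_below(img(pixels), cutoff)
        scaled = binarize_below(img(pixels * scale), cutoff * scale)
        assert (base == scaled).all()


class TestIsodata:
    def test_two_value_image(self):
        a = np.full((10, 10), 0.2)
        a[5:] = 0.8
        mask, t = global_threshold_binarize(img(a))
        assert 0.2 < t < 0.8
        assert (mask == (a > 0.5)).all()

    def test_single_bright_pixel(self):
        a = np.zeros((10, 10))
        a[3, 3] = 1.0
        mask, _ = global_threshold_binarize(img(a))
        assert mask.sum() == 1 and mask[3, 3]

    def test_fixed_point_within_bin_width(self):
        a = np.random.default_rng(1).random((50, 50))
        t = isodata_threshold(a)
        hist, edges = np.histogram(a, bins=256, range=(0, 1))
        centers = 0.5 * (edges[:-1] + edges[1:])
        below = centers <= t
        midpoint = 0.5 * (
            np.average(centers[below], weights=hist[below])
            + np.average(centers[~below], weights=hist[~below])
        )
        assert abs(midpoint - t) < 1.0 / 256

    def test_shift_invariance_of_mask(self):
        """Adding a constant (a whole number of bins) leaves the bright class unchanged."""
        rng = np.random.default_rng(2)
        a = np.clip(rng.normal(0.2, 0.05, (40, 40)), 0, 1)
        a[10:15, 10:15] = 0.7
        offset = 32.0 / 256
        m1, _ = global_threshold_binarize(img(a))
        m2, _ = global_threshold_binarize(img(a + offset))
        assert (m1 == m2).all()

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateInputError):
            global_threshold_binarize(img(np.full((8, 8), 0.4)))

    def test_matches_skimage_reference(self):
        """Independent reference: skimage's isodata on an image spanning [0, 1]."""
        from skimage.filters import threshold_isodata

        a = np.random.default_rng(9).random((80, 80))
        a.flat[0], a.flat[1] = 0.0, 1.0  # pin the data range to [0, 1]
        assert abs(isodata_threshold(a) - threshold_isodata(a, nbins=256)) < 2.0 / 256


def test_cutoff_recovers_truth_voids_on_synthetic_eye(small_eye):
    """Thresholding at the outer-retina mean recovers the planted voids
    (>= 90% recall, Jaccard >= 0.8 on the artifact-free area)."""
    specs = canonical_slab_specs()
    sup = extract_slab(small_eye.volume, specs["superficial"])
    rpe = extract_slab(small_eye.volume, specs["rpe_structural"])
    outer = extract_slab(small_eye.volume, specs["outer_retina_avascular"])
    cc = extract_slab(small_eye.volume, specs["choriocapillaris_10um"])
    artifact = detect_artifacts(sup, rpe)
    cutoff = compute_cutoff(outer, exclude=artifact.combined)
    detected = binarize_below(cc, cutoff.cutoff)
    ok = ~(small_eye.truth_projection_mask | small_eye.truth_shadow_mask)
    det, truth = detected & ok, small_eye.truth_void_mask & ok
    recall = (det & truth).sum() / truth.sum()
    jaccard = (det & truth).sum() / (det | truth).sum()
    assert recall >= 0.90
    assert jaccard >= 0.80
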