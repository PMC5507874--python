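"""The synthetic-eye generator: determinism, ground-truth consistency, cohorts."""

import numpy as np
import pytest
from scipy import ndimage

from ccflowvoid import (
    ParameterError,
    SyntheticEyeParams,
    apply_artifacts,
    canonical_slab_specs,
    extract_slab,
    generate_choriocapillaris,
    generate_cohort,
    generate_eye,
    generate_superficial_vasculature,
    pearson_corr,
)
from ccflowvoid.synthetic import GRADE_VOID_FRACTION

TINY = dict(grid_size=64, axial_pitch_um=12.0)


class TestChoriocapillaris:
    def test_zero_fraction_empty_mask(self):
        _, mask = generate_choriocapillaris(SyntheticEyeParams(true_void_fraction=0.0, **TINY))
        assert not mask.any()

    def test_mask_fraction_matches_request(self):
        _, mask = generate_choriocapillaris(SyntheticEyeParams(true_void_fraction=0.05, grid_size=160, seed=2))
        assert mask.mean() == pytest.approx(0.05, abs=0.005)

    def test_deterministic_under_seed(self):
        p = SyntheticEyeParams(true_void_fraction=0.04, seed=9, **TINY)
        img1, m1 = generate_choriocapillaris(p)
        img2, m2 = generate_choriocapillaris(p)
        assert (img1.pixels == img2.pixels).all() and (m1 == m2).all()

    def test_overlarge_fraction_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticEyeParams(true_void_fraction=0.6)


class TestVasculature:
    def test_zero_density_blank(self):
        img = generate_superficial_vasculature(0.0, seed=0, grid_size=64)
        assert not img.pixels.any()

    def test_density_tracked(self):
        img = generate_superficial_vasculature(0.15, seed=1, grid_size=304)
        assert (img.pixels > 0.5).mean() == pytest.approx(0.15, abs=0.02)

    def test_tree_is_single_8_connected_component(self):
        img = generate_superficial_vasculature(0.10, seed=2, grid_size=160)
        vessels = img.pixels > 0.5
        _, n_components = ndimage.label(vessels, structure=np.ones((3, 3)))
        assert n_components == 1


class TestApplyArtifacts:
    def test_identity_without_artifacts(self, flat_volume_factory):
        vol = flat_volume_factory(nz=100, n=16, axial_pitch=4.0, dec=0.4, refl=0.3)
        out = apply_artifacts(vol, None, ())
        assert (out.decorrelation == vol.decorrelation).all()
        assert (out.reflectance == vol.reflectance).all()

    def test_shadow_attenuates_choriocapillaris(self, flat_volume_factory):
        vol = flat_volume_factory(nz=380, n=32, dec=0.4, refl=0.5)
        out = apply_artifacts(vol, None, [(16, 16, 10)])
        spec = canonical_slab_specs()["choriocapillaris_10um"]
        before = extract_slab(vol, spec).pixels
        after = extract_slab(out, spec).pixels
        assert (after[16, 16] < before[16, 16]) and after[16, 16] < 0.05
        assert after[0, 0] == pytest.approx(before[0, 0])

    def test_projection_boosts_choriocapillaris(self, flat_volume_factory):
        from ccflowvoid import EnFaceImage

        vol = flat_volume_factory(nz=380, n=32, dec=0.2)
        vessel = np.zeros((32, 32))
        vessel[10:12, :] = 0.9
        out = apply_artifacts(vol, EnFaceImage(vessel, vol.lateral_pitch), ())
        spec = canonical_slab_specs()["choriocapillaris_10um"]
        before = extract_slab(vol, spec).pixels
        after = extract_slab(out, spec).pixels
        assert (after[10] > before[10]).all()
        assert (after[20] == before[20]).all()


class TestGenerateEye:
    def test_grade_default_void_fraction(self):
        assert SyntheticEyeParams(dr_grade="no_DR").resolved_void_fraction == 0.020
        assert GRADE_VOID_FRACTION["PDR"] == 0.055

    def test_no_disruption_keeps_ez_intact(self):
        eye = generate_eye(SyntheticEyeParams(ez_disruption_fraction=0.0, seed=3, **TINY))
        assert eye.truth_ez_intact.all()

    def test_outer_retina_darker_than_choriocapillaris(self, small_eye):
        specs = canonical_slab_specs()
        outer = extract_slab(small_eye.volume, specs["outer_retina_avascular"]).pixels.mean()
        cc = extract_slab(small_eye.volume, specs["choriocapillaris_10um"]).pixels.mean()
        assert outer < cc

    def test_truth_fraction_on_artifact_free_area(self, small_eye):
        ok = ~(small_eye.truth_projection_mask | small_eye.truth_shadow_mask)
        v = small_eye.params.resolved_void_fraction
        assert small_eye.truth_void_mask[ok].mean() == pytest.approx(v, abs=0.005)

    def test_bit_identical_under_seed(self):
        p = SyntheticEyeParams(dr_grade="severe_NPDR", seed=21, **TINY)
        e1, e2 = generate_eye(p), generate_eye(p)
        assert (e1.volume.decorrelation == e2.volume.decorrelation).all()
        assert (e1.volume.reflectance == e2.volume.reflectance).all()
        assert (e1.truth_void_mask == e2.truth_void_mask).all()
        assert e1.record == e2.record

    def test_void_pixels_sit_below_noise_floor(self, small_eye):
        cc = extract_slab(small_eye.volume, canonical_slab_specs()["choriocapillaris_10um"]).pixels
        ok = ~(small_eye.truth_projection_mask | small_eye.truth_shadow_mask)
        sel = small_eye.truth_void_mask & ok
        assert cc[sel].max() < small_eye.params.outer_retina_mean


class TestCohort:
    def test_counts_per_grade(self):
        eyes = generate_cohort(5, seed=0, records_only=True, **TINY)
        assert len(eyes) == 25
        grades = [e.record.dr_grade for e in eyes]
        assert all(grades.count(g) == 5 for g in GRADE_VOID_FRACTION)

    def test_noiseless_va_correlates_perfectly(self):
        eyes = generate_cohort(5, seed=1, va_sigma=0.0, records_only=True, **TINY)
        va = [e.record.logmar_va for e in eyes]
        void = [e.truth_csf_void_pct for e in eyes]
        r, _ = pearson_corr(void, va)
        assert r == pytest.approx(1.0)

    def test_truth_void_means_increase_with_grade(self):
        eyes = generate_cohort(25, seed=2, records_only=True, **TINY)
        means = []
        for g in GRADE_VOID_FRACTION:
            means.append(np.mean([e.params.resolved_void_fraction for e in eyes if e.record.dr_grade == g]))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_ssi_always_above_gate(self):
        eyes = generate_cohort(25, seed=3, records_only=True, **TINY)
        assert min(e.record.ssi for e in eyes) > 60.0

    def test_sample_correlation_usually_strong(self):
        """Monte Carlo: the VA-void correlation exceeds 0.2 in nearly all cohorts."""
        hits = 0
        for seed in range(30):
            eyes = generate_cohort(25, seed=seed, records_only=True, **TINY)
            va = [e.record.logmar_va for e in eyes]
            void = [e.truth_csf_void_pct for e in eyes]
            r, _ = pearson_corr(void, va)
            hits += r > 0.2
        assert hits >= 27

    def test_records_match_between_light_and_full_generation(self):
        light = generate_cohort(1, seed=4, records_only=True, **TINY)
        full = generate_cohort(1, seed=4, records_only=False, **TINY)
        for a, b in zip(light, full):
            assert a.record == b.record
            assert a.params == b.params
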