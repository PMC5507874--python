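"""En-face slab geometry: canonical offsets, half-open inclusion, projections."""

import numpy as np
import pytest

from ccflowvoid import GeometryError, SlabSpec, canonical_slab_specs, extract_slab

EXPECTED_SPECS = {
    "choroid_capillary_default": ("rpe_bruch", 31.0, "rpe_bruch", 59.0, "decorrelation"),
    "choriocapillaris_10um": ("rpe_bruch", 31.0, "rpe_bruch", 40.0, "decorrelation"),
    "superficial": ("ilm", 3.0, "ipl", 15.0, "decorrelation"),
    "deep": ("ipl", 15.0, "ipl", 70.0, "decorrelation"),
    "outer_retina_avascular": ("ipl", 70.0, "rpe_ref", 30.0, "decorrelation"),
    "rpe_structural": ("rpe_ref", -14.0, "rpe_ref", 14.0, "reflectance"),
}


def slab_oracle(volume, spec):
    """Brute-force per-voxel projection, the independent reference."""
    nz, ny, nx = volume.decorrelation.shape
    chan = np.asarray(getattr(volume, spec.channel), float)
    inner = volume.surface(spec.reference_inner) + spec.offset_inner
    outer = volume.surface(spec.reference_outer) + spec.offset_outer
    out = np.zeros((ny, nx))
    for y in range(ny):
        for x in range(nx):
            vals = [
                chan[iz, y, x]
                for iz in range(nz)
                if inner[y, x] <= iz * volume.axial_pitch < outer[y, x]
            ]
            if vals:
                out[y, x] = np.mean(vals) if spec.projection == "mean" else max(vals)
    return out


def test_canonical_slab_specs_offsets():
    specs = canonical_slab_specs()
    assert set(specs) == set(EXPECTED_SPECS)
    for name, (ri, oi, ro, oo, chan) in EXPECTED_SPECS.items():
        s = specs[name]
        assert (s.reference_inner, s.offset_inner, s.reference_outer, s.offset_outer) == (ri, oi, ro, oo)
        assert s.channel == chan
    # the default choroidal window is 28 µm thick, the thin slab 9 µm
    assert specs["choroid_capillary_default"].offset_outer - specs["choroid_capillary_default"].offset_inner == 28.0


def test_constant_volume_projects_constant(flat_volume_factory):
    vol = flat_volume_factory(dec=0.5)
    for spec in canonical_slab_specs().values():
        if spec.channel == "decorrelation":
            assert np.allclose(extract_slab(vol, spec).pixels, 0.5)


@pytest.mark.parametrize(
    "depth_below_bruch,expect_positive",
    [(31, True), (35, True), (39, True), (40, False), (50, False), (30, False)],
)
def test_half_open_plane_inclusion(flat_volume_factory, depth_below_bruch, expect_positive):
    """A bright plane is included iff inner <= depth < outer (31..40 µm slab)."""
    vol = flat_volume_factory()
    dec = vol.decorrelation.copy()
    dec[int(304 + depth_below_bruch)] = 1.0
    vol.decorrelation = dec
    img = extract_slab(vol, canonical_slab_specs()["choriocapillaris_10um"])
    assert (img.pixels.max() > 0) == expect_positive


def test_mean_vs_max_projection(flat_volume_factory):
    vol = flat_volume_factory()
    dec = vol.decorrelation.copy()
    dec[304 + 31 : 304 + 36] = 0.2  # half the slab's voxels
    dec[304 + 36 : 304 + 41] = 0.8  # the other half
    vol.decorrelation = dec
    mean_img = extract_slab(vol, SlabSpec("rpe_bruch", 31.0, "rpe_bruch", 41.0))
    max_img = extract_slab(vol, SlabSpec("rpe_bruch", 31.0, "rpe_bruch", 41.0, projection="max"))
    assert np.allclose(mean_img.pixels, 0.5)
    assert np.allclose(max_img.pixels, 0.8)


def test_mean_projection_is_linear(flat_volume_factory):
    rng = np.random.default_rng(5)
    spec = canonical_slab_specs()["choriocapillaris_10um"]
    v1 = flat_volume_factory(dec=rng.random((380, 12, 12)).astype(np.float32))
    v2 = flat_volume_factory(dec=rng.random((380, 12, 12)).astype(np.float32))
    a, b = 0.25, 0.5
    combo = flat_volume_factory(dec=a * v1.decorrelation + b * v2.decorrelation)
    lhs = extract_slab(combo, spec).pixels
    rhs = a * extract_slab(v1, spec).pixels + b * extract_slab(v2, spec).pixels
    assert np.allclose(lhs, rhs, atol=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_extract_matches_bruteforce_oracle(seed):
    """Vectorized extraction equals the per-voxel loop on small random volumes."""
    from ccflowvoid import OctaVolume

    rng = np.random.default_rng(seed)
    nz, n = 32, 6
    ap = 4.0
    ilm = 10 + 4 * rng.random((n, n))
    vol = OctaVolume(
        decorrelation=rng.random((nz, n, n)).astype(np.float32),
        reflectance=rng.random((nz, n, n)).astype(np.float32),
        surface_ilm=ilm,
        surface_ipl=ilm + 30,
        surface_rpe_ref=ilm + 70,
        surface_rpe_bruch=ilm + 74,
        axial_pitch=ap,
        lateral_pitch=20.0,
    )
    for spec in (
        SlabSpec("ilm", 3.0, "ipl", 5.0),
        SlabSpec("ipl", 5.0, "ipl", 25.0, projection="max"),
        SlabSpec("rpe_ref", -8.0, "rpe_ref", 8.0, channel="reflectance"),
        SlabSpec("rpe_bruch", 10.0, "rpe_bruch", 40.0),
    ):
        got = extract_slab(vol, spec).pixels
        assert np.allclose(got, slab_oracle(vol, spec), atol=1e-6)


def test_inverted_boundary_raises_with_position(flat_volume_factory):
    vol = flat_volume_factory()
    with pytest.raises(GeometryError, match=r"row=0, col=0"):
        extract_slab(vol, SlabSpec("rpe_bruch", 40.0, "rpe_bruch", 31.0))
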