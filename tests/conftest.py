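import numpy as np
import pytest

from ccflowvoid import OctaVolume, SyntheticEyeParams, generate_eye


@pytest.fixture
def flat_volume_factory():
    """Small volumes with flat surfaces for geometry tests."""

    def make(
        nz=380,
        n=12,
        axial_pitch=1.0,
        ilm=20.0,
        ipl=130.0,
        rpe_ref=300.0,
        rpe_bruch=304.0,
        dec=0.0,
        refl=0.0,
        lateral_pitch=10.0,
    ):
        shape = (nz, n, n)
        surf = lambda d: np.full((n, n), float(d))
        dec_arr = np.full(shape, dec, np.float32) if np.isscalar(dec) else np.asarray(dec, np.float32)
        refl_arr = np.full(shape, refl, np.float32) if np.isscalar(refl) else np.asarray(refl, np.float32)
        return OctaVolume(
            decorrelation=dec_arr,
            reflectance=refl_arr,
            surface_ilm=surf(ilm),
            surface_ipl=surf(ipl),
            surface_rpe_ref=surf(rpe_ref),
            surface_rpe_bruch=surf(rpe_bruch),
            axial_pitch=axial_pitch,
            lateral_pitch=lateral_pitch,
        )

    return make


@pytest.fixture(scope="session")
def small_eye():
    """One mid-severity synthetic eye at a reduced problem size, shared."""
    params = SyntheticEyeParams(
        dr_grade="moderate_NPDR", grid_size=160, axial_pitch_um=6.0, seed=11
    )
    return generate_eye(params)
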