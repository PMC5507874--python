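"""Seeded synthetic OCTA eyes with ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis consumes,
not optical physics: a lobular choriocapillaris mosaic (bright lobule
cores, dimmer inter-lobule seams, lobule scale of dozens to hundreds of
micrometers) with embedded flow-void patches; a branching superficial
vessel tree that casts projection artifacts onto every deeper slab;
hyperreflective lesions that cast shadows through the RPE and choroid; a
low-signal avascular outer retina that defines the eye's noise floor; deep
capillary nonperfusion with colocalized ellipsoid-zone (EZ) disruption and
a configurable flow-void enrichment beneath disrupted EZ; and eye-level
covariates (visual acuity linked to the central-subfield void percentage,
CSF thickness and scan quality drawn per retinopathy grade).

Everything is deterministic under ``SyntheticEyeParams.seed``: identical
parameters produce bit-identical eyes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage import draw

from .errors import GeometryError, ParameterError
from .ez import select_scan_lines
from .slabs import DEFAULT_FIELD_MM, DEFAULT_GRID_SIZE, EnFaceImage, OctaVolume
from .stats import DR_GRADES, EyeRecord

#: Mean true flow-void fraction per retinopathy grade (monotone with severity).
GRADE_VOID_FRACTION: Dict[str, float] = {
    "no_DR": 0.020,
    "mild_NPDR": 0.025,
    "moderate_NPDR": 0.035,
    "severe_NPDR": 0.045,
    "PDR": 0.055,
}

#: Central-subfield thickness (mean, SD) in µm per grade.
GRADE_CSF_THICKNESS_UM: Dict[str, Tuple[float, float]] = {
    "no_DR": (244.0, 36.0),
    "mild_NPDR": (290.0, 58.0),
    "moderate_NPDR": (284.0, 61.0),
    "severe_NPDR": (346.0, 69.0),
    "PDR": (325.0, 120.0),
}

GRADE_SSI_MEAN: Dict[str, float] = {
    "no_DR": 70.8,
    "mild_NPDR": 68.5,
    "moderate_NPDR": 67.3,
    "severe_NPDR": 66.2,
    "PDR": 70.0,
}

GRADE_AGE_YEARS: Dict[str, Tuple[float, float]] = {
    "no_DR": (64.8, 11.7),
    "mild_NPDR": (71.5, 19.6),
    "moderate_NPDR": (67.1, 10.9),
    "severe_NPDR": (60.7, 9.8),
    "PDR": (52.9, 12.4),
}

#: Deep-capillary nonperfusion and EZ-disruption fractions used for cohort
#: eyes, scaled with severity (the params defaults model the heavily
#: ischemic eyes of the EZ substudy).
GRADE_NONPERFUSION_FRACTION: Dict[str, float] = {
    "no_DR": 0.02,
    "mild_NPDR": 0.05,
    "moderate_NPDR": 0.12,
    "severe_NPDR": 0.25,
    "PDR": 0.35,
}
GRADE_EZ_DISRUPTION_FRACTION: Dict[str, float] = {
    "no_DR": 0.0,
    "mild_NPDR": 0.05,
    "moderate_NPDR": 0.15,
    "severe_NPDR": 0.35,
    "PDR": 0.50,
}

#: Visual-acuity linkage: logMAR VA = intercept + slope * (CSF void %) + noise.
VA_INTERCEPT = -0.05
VA_SLOPE = 0.03
VA_SIGMA = 0.10

SSI_SIGMA = 5.0


@dataclass(frozen=True)
class SyntheticEyeParams:
    """Generative parameters of one synthetic eye."""

    dr_grade: str = "no_DR"
    true_void_fraction: Optional[float] = None  # None -> grade default
    lobule_diameter_um: Tuple[float, float] = (60.0, 300.0)
    lesion_count: int = 3
    vessel_density: float = 0.15
    deep_nonperfusion_fraction: float = 0.35
    ez_disruption_fraction: float = 0.50
    ez_void_enrichment: float = 3.0
    outer_retina_mean: float = 0.06
    outer_retina_sd: float = 0.02
    grid_size: int = DEFAULT_GRID_SIZE
    axial_pitch_um: float = 3.0
    field_mm: float = DEFAULT_FIELD_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dr_grade not in DR_GRADES:
            raise ParameterError(f"unknown DR grade {self.dr_grade!r}")
        v = self.resolved_void_fraction
        if not 0.0 <= v <= 0.5:
            raise ParameterError(f"true_void_fraction {v} outside [0, 0.5]")
        lo, hi = self.lobule_diameter_um
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ParameterError("lobule diameters must be positive and ordered")
        if not 0.0 <= self.vessel_density <= 1.0:
            raise ParameterError("vessel_density must lie in [0, 1]")
        if self.lesion_count < 0:
            raise ParameterError("lesion_count must be >= 0")

    @property
    def resolved_void_fraction(self) -> float:
        if self.true_void_fraction is None:
            return GRADE_VOID_FRACTION[self.dr_grade]
        return float(self.true_void_fraction)

    @property
    def lateral_pitch_um(self) -> float:
        return self.field_mm * 1000.0 / self.grid_size


@dataclass
class SyntheticEye:
    """A generated eye: volume, ground-truth masks, and its record."""

    params: SyntheticEyeParams
    record: EyeRecord
    truth_csf_void_pct: float = float("nan")
    volume: Optional[OctaVolume] = None
    truth_void_mask: Optional[np.ndarray] = None
    truth_projection_mask: Optional[np.ndarray] = None
    truth_shadow_mask: Optional[np.ndarray] = None
    truth_deep_nonperfusion_mask: Optional[np.ndarray] = None
    truth_ez_intact: Optional[np.ndarray] = None  # (10, width) bool
    ez_line_rows: Optional[np.ndarray] = None
    lesion_disks: Tuple[Tuple[int, int, int], ...] = ()


# ---------------------------------------------------------------------------
# low-level building blocks


def _smooth_field(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Stationary Gaussian random field (periodic boundary, unit-free)."""
    return gaussian_filter(rng.standard_normal((n, n)), sigma=sigma, mode="wrap")


def _kth_threshold(values: np.ndarray, frac: float) -> float:
    """Threshold such that exactly round(frac * size) values lie strictly below."""
    k = int(round(frac * values.size))
    if k <= 0:
        return -np.inf
    if k >= values.size:
        return np.inf
    return float(np.partition(values, k)[k])


def _mask_at_fraction(field_: np.ndarray, frac: float, domain: Optional[np.ndarray] = None) -> np.ndarray:
    """Boolean mask ``field < t`` whose fraction inside ``domain`` equals ``frac``."""
    if frac <= 0:
        return np.zeros(field_.shape, bool)
    vals = field_[domain] if domain is not None else field_.ravel()
    return field_ < _kth_threshold(vals, frac)


def _void_mask_with_enrichment(
    field_: np.ndarray,
    overall_fraction: float,
    enrich_region: Optional[np.ndarray],
    enrichment: float,
    domain: np.ndarray,
) -> np.ndarray:
    """Void mask with fraction ``overall_fraction`` on ``domain`` and a locally
    enriched fraction (×``enrichment``, capped at 0.5) inside ``enrich_region``."""
    if overall_fraction <= 0:
        return np.zeros(field_.shape, bool)
    if enrich_region is None or enrichment == 1.0 or not enrich_region.any():
        return _mask_at_fraction(field_, overall_fraction, domain)
    inside = enrich_region & domain
    outside = domain & ~enrich_region
    a = inside.sum() / max(1, domain.sum())
    f_in = min(enrichment * overall_fraction, 0.5)
    f_out = max(0.0, (overall_fraction - f_in * a) / max(1e-12, 1.0 - a))
    m_in = field_ < _kth_threshold(field_[inside], f_in)
    m_out = field_ < _kth_threshold(field_[outside], f_out)
    return (m_in & enrich_region) | (m_out & ~enrich_region)


def _lobule_texture(
    rng: np.random.Generator,
    n: int,
    pitch_um: float,
    diam_range_um: Tuple[float, float],
) -> np.ndarray:
    """Jittered hexagonal-lattice lobule mosaic: bright cores, dim seams."""
    lo, hi = diam_range_um
    spacing_px = max(2.0, math.sqrt(lo * hi) / pitch_um)
    row_step = spacing_px * math.sqrt(3.0) / 2.0
    ys = np.arange(-spacing_px, n + spacing_px, row_step)
    centers = []
    for i, y in enumerate(ys):
        offset = spacing_px / 2.0 if i % 2 else 0.0
        xs = np.arange(-spacing_px + offset, n + spacing_px, spacing_px)
        centers.append(np.column_stack([np.full_like(xs, y), xs]))
    centers = np.concatenate(centers)
    centers = centers + rng.normal(0.0, 0.25 * spacing_px, centers.shape)
    tree = cKDTree(centers)
    yy, xx = np.mgrid[0:n, 0:n]
    dist, _ = tree.query(np.column_stack([yy.ravel(), xx.ravel()]), workers=1)
    r = np.minimum(dist.reshape(n, n) / (0.55 * spacing_px), 1.0)
    tex = 0.57 - 0.27 * r**2 + 0.015 * rng.standard_normal((n, n))
    return np.clip(tex, 0.22, 0.68)


def _void_values(rng: np.random.Generator, count: int) -> np.ndarray:
    """Decorrelation values drawn well below the outer-retina noise floor."""
    return np.clip(rng.normal(0.018, 0.008, count), 0.0, 0.04)


def _sample_lesion_disks(
    rng: np.random.Generator, n: int, count: int, pitch_um: float
) -> Tuple[Tuple[int, int, int], ...]:
    disks = []
    for _ in range(count):
        y = int(rng.integers(int(0.12 * n), int(0.88 * n)))
        x = int(rng.integers(int(0.12 * n), int(0.88 * n)))
        r = max(2, int(round(rng.uniform(70.0, 150.0) / pitch_um)))
        disks.append((y, x, r))
    return tuple(disks)


def _disks_mask(n: int, disks: Sequence[Tuple[int, int, int]]) -> np.ndarray:
    mask = np.zeros((n, n), bool)
    yy, xx = np.ogrid[0:n, 0:n]
    for y, x, r in disks:
        mask |= (yy - y) ** 2 + (xx - x) ** 2 <= r**2
    return mask


# ---------------------------------------------------------------------------
# public generator operations


def generate_choriocapillaris(
    params: SyntheticEyeParams, seed: Optional[int] = None
) -> Tuple[EnFaceImage, np.ndarray]:
    """Lobular choriocapillaris en-face image with embedded flow voids.

    Returns the image and the ground-truth void mask; the mask's pixel
    fraction equals ``true_void_fraction`` to within one pixel's rounding.
    Deterministic for a given seed (``params.seed`` unless overridden).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.grid_size
    v = params.resolved_void_fraction
    tex = _lobule_texture(rng, n, params.lateral_pitch_um, params.lobule_diameter_um)
    void_field = _smooth_field(rng, n, sigma=max(1.0, 2.0 * n / 304))
    mask = _mask_at_fraction(void_field, v)
    tex = tex.copy()
    tex[mask] = _void_values(rng, int(mask.sum()))
    image = EnFaceImage(tex, params.lateral_pitch_um, "decorrelation", "synthetic:choriocapillaris")
    return image, mask


def generate_superficial_vasculature(
    vessel_density: float,
    seed,
    grid_size: int = DEFAULT_GRID_SIZE,
    field_mm: float = DEFAULT_FIELD_MM,
) -> EnFaceImage:
    """Branching vessel tree: bright curvilinear vessels on a dark background.

    The bright-pixel fraction tracks ``vessel_density``; every vessel pixel
    is 8-connected to the tree root at the raster center.
    """
    if not 0.0 <= vessel_density <= 1.0:
        raise ParameterError("vessel_density must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = grid_size
    pitch = field_mm * 1000.0 / n
    img = np.zeros((n, n))
    if vessel_density == 0.0:
        return EnFaceImage(img, pitch, "decorrelation", "synthetic:superficial")
    mask = np.zeros((n, n), bool)
    target = vessel_density * n * n
    tips: List[Tuple[float, float, float]] = [
        (n / 2.0, n / 2.0, a) for a in (0.4, 0.4 + np.pi / 2, 0.4 + np.pi, 0.4 + 3 * np.pi / 2)
    ]
    painted = 0
    for _ in range(50000):
        if painted >= target:
            break
        idx = int(rng.integers(len(tips)))
        y, x, ang = tips[idx]
        ang += float(rng.normal(0.0, 0.45))
        length = float(rng.uniform(0.05, 0.12)) * n
        y2 = float(np.clip(y + length * math.sin(ang), 1, n - 2))
        x2 = float(np.clip(x + length * math.cos(ang), 1, n - 2))
        rr, cc = draw.line(int(round(y)), int(round(x)), int(round(y2)), int(round(x2)))
        offs = np.array((-1, 0, 1))
        rs = np.clip(rr[None, :] + offs[:, None], 0, n - 1)
        cs = np.clip(cc[None, :] + offs[:, None], 0, n - 1)
        mask[rs[:, None, :], cs[None, :, :]] = True  # 3x3 stroke thickening
        tips[idx] = (y2, x2, ang)
        if rng.random() < 0.35 and len(tips) < 400:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            tips.append((y2, x2, ang + sign * float(rng.uniform(0.6, 1.3))))
        painted = int(mask.sum())
    img[mask] = rng.uniform(0.8, 1.0, int(mask.sum()))
    return EnFaceImage(img, pitch, "decorrelation", "synthetic:superficial")


def apply_artifacts(
    volume: OctaVolume,
    vessel_image: Optional[EnFaceImage],
    lesion_disks: Sequence[Tuple[int, int, int]] = (),
    projection_gain: float = 0.35,
    shadow_attenuation: float = 0.10,
) -> OctaVolume:
    """Imprint projection and shadow artifacts onto a copy of the volume.

    Under each superficial-vessel footprint the decorrelation of every
    voxel posterior to the superficial slab is boosted by
    ``projection_gain × vessel intensity``.  Each hyperreflective lesion
    disk is written bright into the inner-retinal reflectance and both
    channels are attenuated toward 0 beneath it (from the outer retina
    down), which darkens the RPE slab and the choriocapillaris alike.
    """
    dec = volume.decorrelation.astype(np.float32).copy()
    refl = volume.reflectance.astype(np.float32).copy()
    nz = dec.shape[0]
    n = dec.shape[1]
    ap = volume.axial_pitch
    ipl = volume.surface_ipl.astype(np.float32)
    ilm = volume.surface_ilm.astype(np.float32)

    def _zslice(lo2d: np.ndarray, hi2d: Optional[np.ndarray]) -> Tuple[slice, np.ndarray]:
        iz0 = max(0, int(math.floor(float(lo2d.min()) / ap)))
        iz1 = nz if hi2d is None else min(nz, int(math.ceil(float(hi2d.max()) / ap)) + 1)
        zs = (np.arange(iz0, iz1, dtype=np.float32) * ap)[:, None, None]
        sel = zs >= lo2d[None]
        if hi2d is not None:
            sel &= zs < hi2d[None]
        return slice(iz0, iz1), sel

    if vessel_image is not None:
        if vessel_image.pixels.shape != dec.shape[1:]:
            raise GeometryError("vessel image not congruent with the volume raster")
        footprint = vessel_image.pixels > 0.5
        if footprint.any():
            add = (projection_gain * vessel_image.pixels * footprint).astype(np.float32)
            sl, sel = _zslice(ipl + 15.0, None)
            sub = dec[sl]
            sub += sel * add[None, :, :]
            np.clip(sub, 0.0, 1.0, out=sub)

    if lesion_disks:
        disk = _disks_mask(n, lesion_disks)
        atten = np.float32(shadow_attenuation)
        sl, sel = _zslice(ilm + 20.0, ilm + 60.0)
        body = sel & disk[None, :, :]
        sub = refl[sl]
        np.maximum(sub, np.float32(0.95), out=sub, where=body)
        sl, sel = _zslice(ipl + 70.0, None)
        beneath = sel & disk[None, :, :]
        np.multiply(dec[sl], atten, out=dec[sl], where=beneath)
        np.multiply(refl[sl], atten, out=refl[sl], where=beneath)

    return OctaVolume(
        decorrelation=dec,
        reflectance=refl,
        surface_ilm=volume.surface_ilm,
        surface_ipl=volume.surface_ipl,
        surface_rpe_ref=volume.surface_rpe_ref,
        surface_rpe_bruch=volume.surface_rpe_bruch,
        axial_pitch=volume.axial_pitch,
        lateral_pitch=volume.lateral_pitch,
        field_mm=volume.field_mm,
    )


def _sample_record(
    rng: np.random.Generator,
    params: SyntheticEyeParams,
    csf_void_pct: float,
    eye_id: Optional[str] = None,
    va_sigma: float = VA_SIGMA,
) -> EyeRecord:
    grade = params.dr_grade
    csf = float(max(120.0, rng.normal(*GRADE_CSF_THICKNESS_UM[grade])))
    ssi = float(rng.normal(GRADE_SSI_MEAN[grade], SSI_SIGMA))
    for _ in range(200):
        if ssi > 60.0:
            break
        ssi = float(rng.normal(GRADE_SSI_MEAN[grade], SSI_SIGMA))
    noise = float(rng.normal(0.0, va_sigma)) if va_sigma > 0 else 0.0
    va = VA_INTERCEPT + VA_SLOPE * csf_void_pct + noise
    age_mu, age_sd = GRADE_AGE_YEARS[grade]
    return EyeRecord(
        eye_id=eye_id or f"synthetic-{grade}-{params.seed}",
        dr_grade=grade,
        logmar_va=float(va),
        csf_thickness_um=csf,
        ssi=float(max(60.1, ssi)),
        age_years=float(rng.normal(age_mu, age_sd)),
        hba1c_pct=float(rng.normal(7.4, 1.3)),
        diabetes_duration_years=float(max(0.5, rng.normal(12.0, 6.0))),
        laterality="OD" if rng.random() < 0.5 else "OS",
    )


@dataclass
class _LateralScene:
    """The 2D ground-truth scene shared by volume synthesis and covariates."""

    vessels: EnFaceImage
    lesions: Tuple[Tuple[int, int, int], ...]
    truth_projection: np.ndarray
    truth_shadow: np.ndarray
    artifact_free: np.ndarray
    nonperf: np.ndarray
    disrupted: np.ndarray
    void_mask: np.ndarray
    cc2d: np.ndarray
    sup2d: np.ndarray
    deep2d: np.ndarray


def _csf_disk(n: int, pitch_um: float) -> np.ndarray:
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return np.hypot(yy - c, xx - c) * pitch_um <= 500.0


def _lateral_scene(params: SyntheticEyeParams, children) -> _LateralScene:
    """Generate all lateral (en-face) truth elements from the spawned rngs.

    The rng consumption order is fixed so that the scene is identical
    whether or not a volume is assembled afterwards.
    """
    n = params.grid_size
    pitch = params.lateral_pitch_um
    _, c_vessel, c_lesion, c_deep, c_cc = children[:5]
    r_vessel = np.random.default_rng(c_vessel)
    r_lesion = np.random.default_rng(c_lesion)
    r_deep = np.random.default_rng(c_deep)
    r_cc = np.random.default_rng(c_cc)

    vessels = generate_superficial_vasculature(params.vessel_density, r_vessel, n, params.field_mm)
    sup_bg = np.clip(0.15 + 0.04 * _smooth_field(r_vessel, n, 1.0), 0.05, 0.30)
    sup2d = np.maximum(vessels.pixels, sup_bg)
    lesions = _sample_lesion_disks(r_lesion, n, params.lesion_count, pitch)
    truth_projection = vessels.pixels > 0.5
    truth_shadow = _disks_mask(n, lesions)
    artifact_free = ~(truth_projection | truth_shadow)

    nonperf_field = _smooth_field(r_deep, n, sigma=max(2.0, 5.0 * n / 304))
    nonperf = _mask_at_fraction(nonperf_field, params.deep_nonperfusion_fraction)
    disrupted = _mask_at_fraction(
        nonperf_field, params.deep_nonperfusion_fraction * params.ez_disruption_fraction
    )
    deep2d = np.clip(0.30 + 0.04 * _smooth_field(r_deep, n, 1.0), 0.10, 0.50)
    deep2d[nonperf] = 0.04

    v = params.resolved_void_fraction
    cc_tex = _lobule_texture(r_cc, n, pitch, params.lobule_diameter_um)
    void_field = _smooth_field(r_cc, n, sigma=max(1.0, 2.0 * n / 304))
    void_mask = _void_mask_with_enrichment(
        void_field, v, disrupted, params.ez_void_enrichment, artifact_free
    )
    cc2d = cc_tex.copy()
    cc2d[void_mask] = _void_values(r_cc, int(void_mask.sum()))
    return _LateralScene(
        vessels=vessels,
        lesions=lesions,
        truth_projection=truth_projection,
        truth_shadow=truth_shadow,
        artifact_free=artifact_free,
        nonperf=nonperf,
        disrupted=disrupted,
        void_mask=void_mask,
        cc2d=cc2d,
        sup2d=sup2d,
        deep2d=deep2d,
    )


def _scene_csf_void_pct(scene: _LateralScene, params: SyntheticEyeParams) -> float:
    """True flow-void percentage on the artifact-free central subfield."""
    sel = _csf_disk(params.grid_size, params.lateral_pitch_um) & scene.artifact_free
    if not sel.any():
        return 100.0 * params.resolved_void_fraction
    return 100.0 * float(scene.void_mask[sel].mean())


def generate_eye(params: SyntheticEyeParams) -> SyntheticEye:
    """Assemble a full synthetic eye: volume, truth masks, and record.

    All five canonical slabs are populated (vessel tree in the superficial
    plexus, textured deep plexus with nonperfusion, near-zero outer-retina
    noise floor, lobular choriocapillaris with voids, bright RPE band) and
    the projection/shadow artifacts are applied afterwards, so the
    ground-truth masks describe the pre-artifact scene.  The void mask's
    fraction of the artifact-free area equals ``true_void_fraction``, with
    the configured enrichment beneath EZ-disrupted regions.
    """
    n = params.grid_size
    ap = params.axial_pitch_um
    pitch = params.lateral_pitch_um
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(8)
    r_surf = np.random.default_rng(children[0])
    r_outer = np.random.default_rng(children[5])
    r_refl = np.random.default_rng(children[6])
    r_record = np.random.default_rng(children[7])

    # surfaces: gentle smooth undulation on top of flat anatomy
    und = _smooth_field(r_surf, n, sigma=max(2.0, n / 10))
    und = 2.5 * (und - und.mean()) / max(und.std(), 1e-9)
    ilm = np.clip(60.0 + und, 45.0, 80.0)
    ipl = ilm + 110.0
    rpe_ref = ilm + 280.0
    bruch = rpe_ref + 4.0
    depth_max = float(bruch.max()) + 59.0 + 2 * ap
    nz = int(math.ceil(depth_max / ap)) + 2

    scene = _lateral_scene(params, children)
    vessels, lesions = scene.vessels, scene.lesions
    void_mask, cc2d = scene.void_mask, scene.cc2d
    sup2d, deep2d = scene.sup2d, scene.deep2d

    # voxel grids, filled band by band (later bands overwrite earlier ones);
    # work is confined to each band's z-slice
    dec = np.full((nz, n, n), 0.02, dtype=np.float32)

    def _fill_band(arr: np.ndarray, lo2d: np.ndarray, hi2d: Optional[np.ndarray], tex2d: np.ndarray) -> None:
        iz0 = max(0, int(math.floor(float(lo2d.min()) / ap)))
        iz1 = nz if hi2d is None else min(nz, int(math.ceil(float(hi2d.max()) / ap)) + 1)
        zs = (np.arange(iz0, iz1, dtype=np.float32) * ap)[:, None, None]
        sel = zs >= lo2d.astype(np.float32)[None]
        if hi2d is not None:
            sel &= zs < hi2d.astype(np.float32)[None]
        sub = arr[iz0:iz1]
        tex = np.broadcast_to(tex2d.astype(np.float32), sub.shape)
        np.copyto(sub, tex, where=sel)

    _fill_band(dec, ilm + 3.0, ipl + 15.0, sup2d)
    _fill_band(dec, ipl + 15.0, ipl + 70.0, deep2d)
    _fill_band(dec, bruch + 26.0, None, cc2d)
    iz0 = max(0, int(math.floor(float((ipl + 70.0).min()) / ap)))
    iz1 = min(nz, int(math.ceil(float((rpe_ref + 30.0).max()) / ap)) + 1)
    zs = (np.arange(iz0, iz1, dtype=np.float32) * ap)[:, None, None]
    outer_sel = (zs >= (ipl + 70.0).astype(np.float32)[None]) & (zs < (rpe_ref + 30.0).astype(np.float32)[None])
    sub = dec[iz0:iz1]
    sub[outer_sel] = np.clip(
        r_outer.normal(params.outer_retina_mean, params.outer_retina_sd, int(outer_sel.sum())),
        0.0,
        0.5,
    ).astype(np.float32)

    refl = np.full((nz, n, n), 0.15, dtype=np.float32)
    retina2d = np.clip(0.35 + 0.04 * _smooth_field(r_refl, n, 1.5), 0.2, 0.55)
    rpe2d = np.clip(0.92 + 0.02 * _smooth_field(r_refl, n, 1.0), 0.8, 1.0)
    _fill_band(refl, ilm, rpe_ref - 20.0, retina2d)
    _fill_band(refl, rpe_ref + 16.0, None, np.full((n, n), 0.30))
    _fill_band(refl, rpe_ref - 14.0, rpe_ref + 14.0, rpe2d)

    volume = OctaVolume(
        decorrelation=dec,
        reflectance=refl,
        surface_ilm=ilm,
        surface_ipl=ipl,
        surface_rpe_ref=rpe_ref,
        surface_rpe_bruch=bruch,
        axial_pitch=ap,
        lateral_pitch=pitch,
        field_mm=params.field_mm,
    )
    volume = apply_artifacts(volume, vessels, lesions)

    line_rows = select_scan_lines(n)
    truth_ez_intact = ~scene.disrupted[line_rows, :]
    csf_void_pct = _scene_csf_void_pct(scene, params)
    record = _sample_record(r_record, params, csf_void_pct)

    return SyntheticEye(
        params=params,
        record=record,
        truth_csf_void_pct=csf_void_pct,
        volume=volume,
        truth_void_mask=void_mask,
        truth_projection_mask=scene.truth_projection,
        truth_shadow_mask=scene.truth_shadow,
        truth_deep_nonperfusion_mask=scene.nonperf,
        truth_ez_intact=truth_ez_intact,
        ez_line_rows=line_rows,
        lesion_disks=lesions,
    )


def generate_cohort(
    n_per_grade: int,
    seed: int,
    grid_size: int = DEFAULT_GRID_SIZE,
    axial_pitch_um: float = 3.0,
    va_intercept: float = VA_INTERCEPT,
    va_slope: float = VA_SLOPE,
    va_sigma: float = VA_SIGMA,
    void_jitter_sd: float = 0.002,
    records_only: bool = False,
    **param_overrides,
) -> List[SyntheticEye]:
    """A cohort of ``n_per_grade`` eyes per retinopathy grade.

    Per eye, the true void fraction is the grade default plus a small
    jitter; logMAR VA is ``va_intercept + va_slope * (CSF void %) + noise``,
    where the CSF void % is the eye's realized ground-truth flow-void
    percentage on the artifact-free central subfield; CSF thickness, SSI
    (always > 60) and demographics are drawn from the grade-specific
    distributions.  ``records_only`` skips 3D volume synthesis but still
    generates the lateral truth scene (records are identical either way),
    which keeps covariate-level Monte Carlo cheap.
    """
    if n_per_grade < 1:
        raise ParameterError("n_per_grade must be >= 1")
    root = np.random.default_rng(seed)
    eyes: List[SyntheticEye] = []
    for grade in DR_GRADES:
        for i in range(n_per_grade):
            eye_seed = int(root.integers(0, 2**31 - 1))
            v = float(np.clip(GRADE_VOID_FRACTION[grade] + root.normal(0.0, void_jitter_sd), 0.004, 0.45))
            params = SyntheticEyeParams(
                dr_grade=grade,
                true_void_fraction=v,
                deep_nonperfusion_fraction=GRADE_NONPERFUSION_FRACTION[grade],
                ez_disruption_fraction=GRADE_EZ_DISRUPTION_FRACTION[grade],
                grid_size=grid_size,
                axial_pitch_um=axial_pitch_um,
                seed=eye_seed,
                **param_overrides,
            )
            if records_only:
                scene = _lateral_scene(params, np.random.SeedSequence(eye_seed).spawn(8))
                csf_pct = _scene_csf_void_pct(scene, params)
                eye = SyntheticEye(
                    params=params,
                    record=None,  # filled below
                    truth_csf_void_pct=csf_pct,
                    truth_void_mask=scene.void_mask,
                    truth_projection_mask=scene.truth_projection,
                    truth_shadow_mask=scene.truth_shadow,
                    truth_deep_nonperfusion_mask=scene.nonperf,
                    truth_ez_intact=~scene.disrupted[select_scan_lines(params.grid_size), :],
                    ez_line_rows=select_scan_lines(params.grid_size),
                    lesion_disks=scene.lesions,
                )
            else:
                eye = generate_eye(params)
                csf_pct = eye.truth_csf_void_pct
            csf = float(max(120.0, root.normal(*GRADE_CSF_THICKNESS_UM[grade])))
            ssi = float(root.normal(GRADE_SSI_MEAN[grade], SSI_SIGMA))
            while ssi <= 60.0:
                ssi = float(root.normal(GRADE_SSI_MEAN[grade], SSI_SIGMA))
            noise = float(root.normal(0.0, va_sigma)) if va_sigma > 0 else 0.0
            age_mu, age_sd = GRADE_AGE_YEARS[grade]
            eye.record = EyeRecord(
                eye_id=f"{grade}-{i:03d}",
                dr_grade=grade,
                logmar_va=float(va_intercept + va_slope * csf_pct + noise),
                csf_thickness_um=csf,
                ssi=ssi,
                age_years=float(root.normal(age_mu, age_sd)),
                hba1c_pct=float(root.normal(7.4, 1.3)),
                diabetes_duration_years=float(max(0.5, root.normal(12.0, 6.0))),
                laterality="OD" if i % 2 == 0 else "OS",
            )
            eyes.append(eye)
    return eyes
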