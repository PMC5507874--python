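"""Layered OCTA volume model and en-face slab extraction.

An OCTA acquisition is represented as two co-registered voxel grids — the
decorrelation (motion-contrast) channel and the structural reflectance
channel — together with four segmented surfaces given as depth maps in
micrometers from the top of the volume: the internal limiting membrane
(ILM), the inner plexiform layer (IPL), the RPE reference surface, and the
RPE-Bruch membrane complex.  Every en-face image the pipeline consumes is a
projection of the voxels between two surfaces shifted by fixed axial
offsets; :func:`canonical_slab_specs` holds the standard offsets for the
superficial and deep retinal plexuses, the avascular outer retina, the two
inner-choroidal (choriocapillaris) slabs, and the structural RPE slab.

Conventions
-----------
* Depth increases posteriorly; voxel ``iz`` sits at depth ``iz * axial_pitch``.
* Slab inclusion is half-open: a voxel exactly on the inner boundary is
  included, one exactly on the outer boundary is excluded.
* Pixel values in both channels live on [0, 1]; pixel indexing is 0-based
  internally (reports use the 1-based scan-line numbering of the device).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict

import numpy as np

from .errors import GeometryError, ParameterError

SURFACE_NAMES = ("ilm", "ipl", "rpe_ref", "rpe_bruch")
CHANNELS = ("decorrelation", "reflectance")
PROJECTIONS = ("mean", "max")

#: Default lateral raster of a 3 x 3-mm scan on the device emulated here.
DEFAULT_GRID_SIZE = 304
DEFAULT_FIELD_MM = 3.0


@dataclass(frozen=True)
class SlabSpec:
    """Two surface-relative boundaries plus the channel/projection to use.

    Offsets are signed micrometers, positive posteriorly, applied to the
    named reference surface.
    """

    reference_inner: str
    offset_inner: float
    reference_outer: str
    offset_outer: float
    channel: str = "decorrelation"
    projection: str = "mean"

    def __post_init__(self) -> None:
        for ref in (self.reference_inner, self.reference_outer):
            if ref not in SURFACE_NAMES:
                raise ParameterError(f"unknown surface {ref!r}; expected one of {SURFACE_NAMES}")
        if self.channel not in CHANNELS:
            raise ParameterError(f"unknown channel {self.channel!r}")
        if self.projection not in PROJECTIONS:
            raise ParameterError(f"unknown projection {self.projection!r}")


@dataclass
class EnFaceImage:
    """A 2D scalar raster on [0, 1] with a physical pixel pitch (µm/px)."""

    pixels: np.ndarray
    lateral_pitch: float
    kind: str = "decorrelation"
    provenance: Any = "external file"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise GeometryError(f"en-face image must be a square 2D raster, got shape {self.pixels.shape}")
        if self.kind not in CHANNELS:
            raise ParameterError(f"unknown image kind {self.kind!r}")
        if self.lateral_pitch <= 0:
            raise ParameterError("lateral_pitch must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class OctaVolume:
    """Decorrelation + reflectance voxel grids with segmented surfaces.

    Arrays are ``(nz, ny, nx)``; surfaces are ``(ny, nx)`` depth maps in µm.
    """

    decorrelation: np.ndarray
    reflectance: np.ndarray
    surface_ilm: np.ndarray
    surface_ipl: np.ndarray
    surface_rpe_ref: np.ndarray
    surface_rpe_bruch: np.ndarray
    axial_pitch: float
    lateral_pitch: float
    field_mm: float = DEFAULT_FIELD_MM

    def __post_init__(self) -> None:
        self.decorrelation = np.asarray(self.decorrelation, dtype=np.float32)
        self.reflectance = np.asarray(self.reflectance, dtype=np.float32)
        if self.decorrelation.ndim != 3 or self.decorrelation.shape != self.reflectance.shape:
            raise GeometryError("decorrelation and reflectance must be congruent 3D grids")
        for name in SURFACE_NAMES:
            surf = np.asarray(self.surface(name), dtype=np.float64)
            setattr(self, f"surface_{name}", surf)
            if surf.shape != self.decorrelation.shape[1:]:
                raise GeometryError(f"surface {name!r} not congruent with the lateral raster")
            if surf.min() < 0 or surf.max() > self.axial_extent_um:
                raise GeometryError(f"surface {name!r} leaves the axial extent of the volume")
        if self.axial_pitch <= 0 or self.lateral_pitch <= 0:
            raise ParameterError("pitches must be positive")
        for chan in (self.decorrelation, self.reflectance):
            if chan.min() < 0.0 or chan.max() > 1.0:
                raise ParameterError("channel values must lie in [0, 1]")
        tol = self.axial_pitch
        if not np.all(self.surface_ipl - self.surface_ilm > -tol):
            raise GeometryError("surface ordering violated: ILM must be anterior to IPL")
        if not np.all(self.surface_rpe_ref - self.surface_ipl > -tol):
            raise GeometryError("surface ordering violated: IPL must be anterior to RPE reference")
        if not np.all(self.surface_rpe_bruch - self.surface_rpe_ref > -tol):
            raise GeometryError("surface ordering violated: RPE reference must not lie below RPE-Bruch")

    def surface(self, name: str) -> np.ndarray:
        if name not in SURFACE_NAMES:
            raise ParameterError(f"unknown surface {name!r}")
        return getattr(self, f"surface_{name}")

    @property
    def axial_extent_um(self) -> float:
        return (self.decorrelation.shape[0] - 1) * self.axial_pitch

    @property
    def n_lateral(self) -> int:
        return self.decorrelation.shape[1]


def canonical_slab_specs() -> Dict[str, SlabSpec]:
    """The six standard slabs, keyed by name.

    Offsets (µm, posterior-positive):

    ========================  =======================  =======================
    name                      inner boundary           outer boundary
    ========================  =======================  =======================
    choroid_capillary_default RPE-Bruch + 31           RPE-Bruch + 59
    choriocapillaris_10um     RPE-Bruch + 31           RPE-Bruch + 40
    superficial               ILM + 3                  IPL + 15
    deep                      IPL + 15                 IPL + 70
    outer_retina_avascular    IPL + 70                 RPE reference + 30
    rpe_structural            RPE reference - 14       RPE reference + 14
    ========================  =======================  =======================

    The first five project the decorrelation channel; the ~28-µm RPE slab
    projects reflectance and is the substrate for shadow-artifact detection.
    """
    return {
        "choroid_capillary_default": SlabSpec("rpe_bruch", 31.0, "rpe_bruch", 59.0, "decorrelation"),
        "choriocapillaris_10um": SlabSpec("rpe_bruch", 31.0, "rpe_bruch", 40.0, "decorrelation"),
        "superficial": SlabSpec("ilm", 3.0, "ipl", 15.0, "decorrelation"),
        "deep": SlabSpec("ipl", 15.0, "ipl", 70.0, "decorrelation"),
        "outer_retina_avascular": SlabSpec("ipl", 70.0, "rpe_ref", 30.0, "decorrelation"),
        "rpe_structural": SlabSpec("rpe_ref", -14.0, "rpe_ref", 14.0, "reflectance"),
    }


def extract_slab(volume: OctaVolume, spec: SlabSpec) -> EnFaceImage:
    """Project the voxels between the spec's resolved boundaries.

    Per A-scan position the inner/outer boundaries are the named surfaces
    plus their offsets; voxels with depth ``inner <= d < outer`` enter the
    projection (mean by default, max optionally).  Columns whose half-open
    window contains no voxel grid point project to 0.

    Raises
    ------
    GeometryError
        If the resolved inner boundary is not strictly above the outer
        boundary at some position (the first offending position is named).
    """
    inner = volume.surface(spec.reference_inner) + spec.offset_inner
    outer = volume.surface(spec.reference_outer) + spec.offset_outer
    bad = inner >= outer
    if bad.any():
        y, x = np.argwhere(bad)[0]
        raise GeometryError(
            f"slab boundaries inverted at pixel (row={y}, col={x}): "
            f"inner {inner[y, x]:.2f} µm >= outer {outer[y, x]:.2f} µm"
        )
    nz = volume.decorrelation.shape[0]
    # only the z-slice spanning the boundary range participates
    iz0 = max(0, int(np.floor(inner.min() / volume.axial_pitch)))
    iz1 = min(nz, int(np.ceil(outer.max() / volume.axial_pitch)) + 1)
    z = (np.arange(iz0, iz1) * volume.axial_pitch)[:, None, None]
    include = (z >= inner[None, :, :]) & (z < outer[None, :, :])
    channel = getattr(volume, spec.channel)[iz0:iz1].astype(np.float64)
    counts = include.sum(axis=0)
    if spec.projection == "mean":
        total = np.where(include, channel, 0.0).sum(axis=0)
        pixels = np.where(counts > 0, total / np.maximum(counts, 1), 0.0)
    else:
        pixels = np.where(include, channel, -np.inf).max(axis=0)
        pixels = np.where(counts > 0, pixels, 0.0)
    return EnFaceImage(pixels, volume.lateral_pitch, kind=spec.channel, provenance=spec)
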