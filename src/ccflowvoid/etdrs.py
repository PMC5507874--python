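"""Modified ETDRS grid and artifact-excluded flow-void percentages.

The grid is the 1-mm-diameter central subfield (CSF) plus the four
parafoveal quadrants of the 1-2.5-mm annulus, split along the two 45°
diagonals.  The flow-void percentage of a subfield is the void area divided
by the subfield's artifact-free area — artifact pixels leave both numerator
and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .artifacts import ArtifactMask
from .errors import GeometryError, ParameterError

SUBFIELD_NAMES = ("CSF", "superior", "nasal", "temporal", "inferior")
LATERALITIES = ("OD", "OS")


@dataclass
class EtdrsGrid:
    """Five disjoint subfield masks on a square raster.

    ``center`` is (row, col) in pixels.  Nasal/temporal assignment follows
    laterality with the image held in a fixed fundus orientation: for a
    right eye (OD) the nasal quadrant is the left half-annulus, mirrored
    for OS.
    """

    center: Tuple[float, float]
    lateral_pitch: float
    laterality: str
    subfield_masks: Dict[str, np.ndarray]
    csf_diameter_mm: float = 1.0
    parafovea_outer_diameter_mm: float = 2.5


@dataclass(frozen=True)
class SubfieldResult:
    """Flow-void percentage of one subfield with its artifact bookkeeping.

    ``void_pct`` is NaN (and ``undefined`` True) when the subfield is
    entirely artifact — an undefined ratio is reported as such, never as 0.
    """

    subfield: str
    void_pct: float
    area_analyzed_px: int
    area_artifact_px: int

    @property
    def undefined(self) -> bool:
        return self.area_analyzed_px == 0


def build_etdrs_grid(
    shape: Tuple[int, int],
    lateral_pitch: float,
    center: Optional[Tuple[float, float]] = None,
    laterality: str = "OD",
    csf_diameter_mm: float = 1.0,
    parafovea_outer_diameter_mm: float = 2.5,
) -> EtdrsGrid:
    """Construct the grid on a raster of ``shape`` with pitch µm/px.

    The center defaults to the raster center (scans are fovea-centered).
    Pixels on a diagonal boundary go to the clockwise-next quadrant.
    """
    if laterality not in LATERALITIES:
        raise ParameterError(f"laterality must be one of {LATERALITIES}")
    ny, nx = shape
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    cy, cx = center
    r_csf_um = csf_diameter_mm * 1000.0 / 2.0
    r_out_um = parafovea_outer_diameter_mm * 1000.0 / 2.0
    r_out_px = r_out_um / lateral_pitch
    if cy - r_out_px < -0.5 or cx - r_out_px < -0.5 or cy + r_out_px > ny - 0.5 or cx + r_out_px > nx - 0.5:
        raise GeometryError("grid center too close to the raster edge for the parafoveal ring")

    rows, cols = np.mgrid[0:ny, 0:nx]
    dy = rows - cy
    dx = cols - cx
    dist_um = np.hypot(dy, dx) * lateral_pitch
    csf = dist_um <= r_csf_um
    annulus = (dist_um > r_csf_um) & (dist_um <= r_out_um)

    # Angle clockwise from the superior (upward) direction; half-open 90°
    # sectors put diagonal-boundary pixels in the clockwise-next quadrant.
    phi = np.degrees(np.arctan2(dx, -dy)) % 360.0
    superior = annulus & ((phi >= 315.0) | (phi < 45.0))
    right = annulus & (phi >= 45.0) & (phi < 135.0)
    inferior = annulus & (phi >= 135.0) & (phi < 225.0)
    left = annulus & (phi >= 225.0) & (phi < 315.0)
    nasal, temporal = (left, right) if laterality == "OD" else (right, left)

    masks = {
        "CSF": csf,
        "superior": superior,
        "nasal": nasal,
        "temporal": temporal,
        "inferior": inferior,
    }
    return EtdrsGrid(
        center=(float(cy), float(cx)),
        lateral_pitch=lateral_pitch,
        laterality=laterality,
        subfield_masks=masks,
        csf_diameter_mm=csf_diameter_mm,
        parafovea_outer_diameter_mm=parafovea_outer_diameter_mm,
    )


def quantify_flow_void(
    void_mask: np.ndarray,
    artifact: "ArtifactMask | np.ndarray",
    grid: EtdrsGrid,
) -> List[SubfieldResult]:
    """Per-subfield void percentage on the artifact-free area.

    For subfield S: ``void_pct = 100 * |void & ~artifact & S| / |~artifact & S|``.
    """
    void_mask = np.asarray(void_mask, dtype=bool)
    combined = artifact.combined if isinstance(artifact, ArtifactMask) else np.asarray(artifact, dtype=bool)
    if void_mask.shape != combined.shape:
        raise GeometryError("void and artifact masks not congruent")
    results = []
    for name in SUBFIELD_NAMES:
        sub = grid.subfield_masks[name]
        if sub.shape != void_mask.shape:
            raise GeometryError(f"subfield {name!r} not congruent with the masks")
        analyzable = sub & ~combined
        n_ok = int(analyzable.sum())
        n_art = int((sub & combined).sum())
        if n_ok == 0:
            pct = float("nan")
        else:
            pct = 100.0 * int((void_mask & analyzable).sum()) / n_ok
        results.append(SubfieldResult(name, pct, n_ok, n_art))
    return results
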