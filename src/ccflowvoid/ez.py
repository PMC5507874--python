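"""Ellipsoid-zone (EZ) colocalization along the ten standard scan lines.

Photoreceptor integrity is graded on B-scans along ten evenly spaced
transverse lines (the 17th, 47th, ..., 287th rows of a 304-line raster,
counted from the most superior line).  Within regions of deep retinal
capillary nonperfusion, the transverse lengths of choriocapillaris flow
void and of artifact-free tissue are summed over the ten lines separately
for EZ-intact and EZ-disrupted spans; each class's flow-void percentage is
void length over artifact-free length.  Lengths are pixel counts — a sum of
transverse run lengths in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .artifacts import ArtifactMask
from .errors import GeometryError, ParameterError

#: 1-based scan-line rows on the native 304-line raster.
PRINTED_LINE_ROWS_1BASED = (17, 47, 77, 107, 137, 167, 197, 227, 257, 287)
N_SCAN_LINES = len(PRINTED_LINE_ROWS_1BASED)
NATIVE_N_ROWS = 304


def select_scan_lines(n_rows: int) -> np.ndarray:
    """0-based row indices of the ten EZ-grading lines for an n-row raster.

    On the native 304-row raster these are exactly the printed rows
    (1-based 17, 47, ..., 287).  Other sizes map proportionally:
    ``round(n_rows * k / 304)`` for each printed 1-based row k, then
    converted to 0-based.
    """
    if n_rows < N_SCAN_LINES:
        raise ParameterError(f"need at least {N_SCAN_LINES} rows, got {n_rows}")
    rows_1based = [round(n_rows * k / NATIVE_N_ROWS) for k in PRINTED_LINE_ROWS_1BASED]
    rows = np.array([max(0, min(n_rows - 1, r - 1)) for r in rows_1based], dtype=int)
    return rows


@dataclass
class EzLineAnnotation:
    """Per-line EZ-intact status and deep-capillary nonperfusion spans.

    ``intact`` and ``deep_nonperfusion`` are ``(10, width)`` boolean
    rasters, one row per scan line, aligned with the en-face raster's
    transverse axis.
    """

    line_rows: np.ndarray
    intact: np.ndarray
    deep_nonperfusion: np.ndarray

    def __post_init__(self) -> None:
        self.line_rows = np.asarray(self.line_rows, dtype=int)
        self.intact = np.asarray(self.intact, dtype=bool)
        self.deep_nonperfusion = np.asarray(self.deep_nonperfusion, dtype=bool)
        if self.line_rows.shape != (N_SCAN_LINES,):
            raise ParameterError(f"exactly {N_SCAN_LINES} scan lines required")
        if self.intact.shape != self.deep_nonperfusion.shape or self.intact.shape[0] != N_SCAN_LINES:
            raise GeometryError("per-line annotations must be (10, width) and congruent")


@dataclass(frozen=True)
class EzResult:
    """Flow-void percentages beneath disrupted vs intact EZ.

    Percentages are 100 * void length / artifact-free length per class;
    a class with zero artifact-free length is NaN (undefined), the other
    class is still reported.
    """

    pct_disrupted: float
    pct_intact: float
    length_void_disrupted_px: int
    length_total_disrupted_px: int
    length_void_intact_px: int
    length_total_intact_px: int

    @property
    def disrupted_undefined(self) -> bool:
        return self.length_total_disrupted_px == 0

    @property
    def intact_undefined(self) -> bool:
        return self.length_total_intact_px == 0


def ez_flow_void_fractions(
    void_mask: np.ndarray,
    artifact: "ArtifactMask | np.ndarray",
    annotation: EzLineAnnotation,
) -> EzResult:
    """Classify the ten lines' pixels and sum transverse lengths per EZ class.

    Only pixels inside deep-capillary nonperfusion count; artifact pixels
    are excluded from numerator and denominator of both classes alike.
    """
    void_mask = np.asarray(void_mask, dtype=bool)
    combined = artifact.combined if isinstance(artifact, ArtifactMask) else np.asarray(artifact, dtype=bool)
    if void_mask.shape != combined.shape:
        raise GeometryError("void and artifact masks not congruent")
    width = void_mask.shape[1]
    if annotation.intact.shape[1] != width:
        raise GeometryError("annotation width not congruent with the raster")
    if np.any(annotation.line_rows < 0) or np.any(annotation.line_rows >= void_mask.shape[0]):
        raise GeometryError("scan-line rows outside the raster")

    tot = {True: 0, False: 0}
    void = {True: 0, False: 0}
    for i, row in enumerate(annotation.line_rows):
        usable = annotation.deep_nonperfusion[i] & ~combined[row]
        for intact_flag in (True, False):
            sel = usable & (annotation.intact[i] == intact_flag)
            tot[intact_flag] += int(sel.sum())
            void[intact_flag] += int((sel & void_mask[row]).sum())

    def pct(v: int, t: int) -> float:
        return 100.0 * v / t if t > 0 else float("nan")

    return EzResult(
        pct_disrupted=pct(void[False], tot[False]),
        pct_intact=pct(void[True], tot[True]),
        length_void_disrupted_px=void[False],
        length_total_disrupted_px=tot[False],
        length_void_intact_px=void[True],
        length_total_intact_px=tot[True],
    )
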