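"""Projection- and shadow-artifact masks.

Flowing blood in the superficial retinal plexus casts spurious
decorrelation onto every deeper slab (projection artifacts); hyperreflective
lesions (hemorrhage, exudate) block the beam and darken everything beneath
them (shadow artifacts).  Both are detected with the same global isodata
binarization: the bright class of the superficial OCTA image is the
projection mask, and the dark class of the structural RPE image — where
shadows are most clearly depicted — is the shadow mask.  Their union is
excluded from every flow-void denominator downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, GeometryError, ParameterError
from .flowvoid import global_threshold_binarize
from .slabs import EnFaceImage


@dataclass
class ArtifactMask:
    """Projection and shadow component masks; ``combined`` is their union."""

    projection: np.ndarray
    shadow: np.ndarray
    thresholds_used: Tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        self.projection = np.asarray(self.projection, dtype=bool)
        self.shadow = np.asarray(self.shadow, dtype=bool)
        if self.projection.shape != self.shadow.shape:
            raise GeometryError(
                f"component masks not congruent: {self.projection.shape} vs {self.shadow.shape}"
            )

    @property
    def combined(self) -> np.ndarray:
        return self.projection | self.shadow

    @classmethod
    def empty(cls, shape: Tuple[int, int]) -> "ArtifactMask":
        return cls(np.zeros(shape, bool), np.zeros(shape, bool))


def make_projection_mask(superficial_octa: EnFaceImage, allow_blank: bool = False) -> np.ndarray:
    """Bright class of the superficial OCTA image = projection-artifact pixels.

    ``allow_blank`` maps a constant (vessel-free) image to an empty mask
    instead of raising.
    """
    if superficial_octa.kind != "decorrelation":
        raise ParameterError("projection artifacts are detected on a decorrelation image")
    try:
        mask, _ = global_threshold_binarize(superficial_octa)
    except DegenerateInputError:
        if allow_blank:
            return np.zeros(superficial_octa.shape, bool)
        raise
    return mask


def make_shadow_mask(rpe_structural: EnFaceImage, allow_blank: bool = False) -> np.ndarray:
    """Dark class of the structural RPE image = shadow-artifact pixels."""
    if rpe_structural.kind != "reflectance":
        raise ParameterError("shadow artifacts are detected on a reflectance image")
    try:
        bright, _ = global_threshold_binarize(rpe_structural)
    except DegenerateInputError:
        if allow_blank:
            return np.zeros(rpe_structural.shape, bool)
        raise
    return ~bright


def combine_artifact_masks(
    projection: np.ndarray,
    shadow: np.ndarray,
    thresholds_used: Tuple[float, float] = (float("nan"), float("nan")),
) -> ArtifactMask:
    """Pixelwise union, components retained."""
    projection = np.asarray(projection, dtype=bool)
    shadow = np.asarray(shadow, dtype=bool)
    if projection.shape != shadow.shape:
        raise GeometryError(f"raster mismatch: {projection.shape} vs {shadow.shape}")
    return ArtifactMask(projection, shadow, thresholds_used)


def detect_artifacts(
    superficial_octa: EnFaceImage,
    rpe_structural: EnFaceImage,
    allow_blank: bool = True,
    dilation_px: int = 0,
) -> ArtifactMask:
    """Full artifact mask from the superficial OCTA and RPE structural images.

    ``dilation_px`` optionally grows each component by that many pixels of
    8-connected dilation (off by default).
    """
    if superficial_octa.shape != rpe_structural.shape:
        raise GeometryError("superficial and RPE images not congruent")
    thr_proj = thr_shadow = float("nan")
    try:
        projection, thr_proj = global_threshold_binarize(superficial_octa)
    except DegenerateInputError:
        if not allow_blank:
            raise
        projection = np.zeros(superficial_octa.shape, bool)
    try:
        bright, thr_shadow = global_threshold_binarize(rpe_structural)
        shadow = ~bright
    except DegenerateInputError:
        if not allow_blank:
            raise
        shadow = np.zeros(rpe_structural.shape, bool)
    if dilation_px > 0:
        struct = np.ones((3, 3), bool)
        projection = ndimage.binary_dilation(projection, struct, iterations=dilation_px)
        shadow = ndimage.binary_dilation(shadow, struct, iterations=dilation_px)
    return combine_artifact_masks(projection, shadow, (thr_proj, thr_shadow))
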