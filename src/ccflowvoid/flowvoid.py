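"""Flow-void detection: the per-eye decorrelation cutoff and binarization.

The avascular outer retina carries no retinal or choroidal vasculature, so
its decorrelation level is the eye's own noise floor.  Its mean is used as
the eye-specific cutoff; choroidal pixels strictly below the cutoff are
flow void.  A separate global (isodata/iterative-intermeans) threshold
produces the bright-class binarization used for artifact detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .slabs import EnFaceImage

ISODATA_NBINS = 256


@dataclass(frozen=True)
class CutoffResult:
    """The eye-specific flow-void cutoff: arithmetic mean of the outer-retina pixels used."""

    cutoff: float
    n_pixels_used: int
    source_slab: str


def compute_cutoff(outer_retina_slab: EnFaceImage, exclude: Optional[np.ndarray] = None) -> CutoffResult:
    """Mean decorrelation of the avascular outer retina, outside ``exclude``.

    Parameters
    ----------
    outer_retina_slab
        Decorrelation en-face slab of the avascular outer retina.
    exclude
        Optional boolean mask (e.g., the artifact mask) of pixels to drop
        before averaging; must be congruent with the slab.
    """
    if outer_retina_slab.kind != "decorrelation":
        raise ParameterError("cutoff must be computed on a decorrelation slab")
    pixels = outer_retina_slab.pixels
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.shape != pixels.shape:
            raise ParameterError("exclusion mask not congruent with the slab")
        used = pixels[~exclude]
    else:
        used = pixels.ravel()
    if used.size == 0:
        raise DegenerateInputError("all pixels excluded; cutoff undefined")
    provenance = outer_retina_slab.provenance
    tag = provenance if isinstance(provenance, str) else "outer_retina_avascular"
    return CutoffResult(cutoff=float(used.mean()), n_pixels_used=int(used.size), source_slab=tag)


def binarize_below(slab: EnFaceImage, cutoff: float) -> np.ndarray:
    """Boolean mask of pixels strictly below the cutoff.

    Strict ``<``: a pixel exactly at the cutoff is not flow void.
    """
    if slab.kind != "decorrelation":
        raise ParameterError("flow-void binarization applies to decorrelation slabs")
    if not 0.0 <= cutoff <= 1.0:
        raise ParameterError(f"cutoff {cutoff} outside [0, 1]")
    return slab.pixels < cutoff


def isodata_threshold(values: np.ndarray, nbins: int = ISODATA_NBINS) -> float:
    """Iterative-intermeans (isodata) threshold on a fixed [0, 1] histogram.

    The histogram always spans [0, 1] with ``nbins`` bins regardless of the
    input's dynamic range, so the threshold is stable across bit depths.
    Starting from the overall mean, the threshold is iterated to the fixed
    point t = (mean below t + mean above t) / 2, evaluated on bin centers.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    hist, edges = np.histogram(values, bins=nbins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = np.nonzero(hist)[0]
    if occupied.size < 2:
        raise DegenerateInputError("histogram occupies fewer than two bins; no bimodality")
    t = float(np.average(centers, weights=hist))
    for _ in range(500):
        below = centers <= t
        w_lo, w_hi = hist[below].sum(), hist[~below].sum()
        if w_lo == 0 or w_hi == 0:  # mean always separates occupied extremes
            break
        mean_lo = np.average(centers[below], weights=hist[below])
        mean_hi = np.average(centers[~below], weights=hist[~below])
        t_new = 0.5 * (mean_lo + mean_hi)
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    return float(t)


def global_threshold_binarize(image: EnFaceImage) -> Tuple[np.ndarray, float]:
    """Isodata binarization: (mask of the bright class, threshold used).

    Raises
    ------
    DegenerateInputError
        For a constant image (no bimodal histogram to split).
    """
    pixels = image.pixels
    if np.ptp(pixels) == 0:
        raise DegenerateInputError("constant image; global threshold undefined")
    t = isodata_threshold(pixels)
    return pixels > t, t
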