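"""Orchestration: volume -> slabs -> cutoff -> masks -> quantification -> cohort.

``analyze_eye`` runs the per-eye imaging stages and returns the in-memory
objects; ``run_eye`` wraps them into a JSON-serializable report;
``run_cohort`` applies the quality gate, runs every eye, and adds the
cohort statistics (grade comparisons, VA correlation overall and by DME
status, paired EZ comparison).  A run is reproducible from config + inputs:
identical inputs yield byte-identical JSON reports.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .artifacts import ArtifactMask, detect_artifacts
from .errors import CcFlowVoidError, CohortError
from .etdrs import EtdrsGrid, SubfieldResult, build_etdrs_grid, quantify_flow_void
from .ez import EzLineAnnotation, EzResult, ez_flow_void_fractions
from .flowvoid import CutoffResult, binarize_below, compute_cutoff
from .slabs import EnFaceImage, OctaVolume, canonical_slab_specs, extract_slab
from .stats import DR_GRADES, EyeRecord, anova_bonferroni, pearson_corr, ssi_gate
from .synthetic import SyntheticEye

HEADLINE_SLAB = "choriocapillaris_10um"


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of a run."""

    artifact_removal: bool = True
    exclude_artifacts_from_cutoff: bool = True
    allow_blank_artifacts: bool = True
    artifact_dilation_px: int = 0
    laterality: str = "OD"
    grid_center: Optional[Tuple[float, float]] = None
    min_ssi: float = 60.0
    choroid_slabs: Tuple[str, ...] = ("choroid_capillary_default", "choriocapillaris_10um")
    headline_slab: str = HEADLINE_SLAB
    equal_variance_t: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["choroid_slabs"] = list(self.choroid_slabs)
        d["grid_center"] = list(self.grid_center) if self.grid_center is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("choroid_slabs") is not None:
            d["choroid_slabs"] = tuple(d["choroid_slabs"])
        if d.get("grid_center") is not None:
            d["grid_center"] = tuple(d["grid_center"])
        return cls(**d)


@dataclass
class EyeAnalysis:
    """In-memory result of the per-eye imaging stages."""

    cutoff: CutoffResult
    artifact: ArtifactMask
    slabs: Dict[str, EnFaceImage]
    void_masks: Dict[str, np.ndarray]
    grid: EtdrsGrid
    subfields: Dict[str, List[SubfieldResult]]
    ez: Optional[EzResult] = None


def analyze_eye(
    volume: OctaVolume,
    config: Optional[RunConfig] = None,
    ez_annotation: Optional[EzLineAnnotation] = None,
    laterality: Optional[str] = None,
) -> EyeAnalysis:
    """Run slab extraction, artifact masking, cutoff, and quantification."""
    cfg = config or RunConfig()
    specs = canonical_slab_specs()
    wanted = ("superficial", "rpe_structural", "outer_retina_avascular") + tuple(cfg.choroid_slabs)
    slabs = {name: extract_slab(volume, specs[name]) for name in dict.fromkeys(wanted)}
    shape = slabs["superficial"].shape

    if cfg.artifact_removal:
        artifact = detect_artifacts(
            slabs["superficial"],
            slabs["rpe_structural"],
            allow_blank=cfg.allow_blank_artifacts,
            dilation_px=cfg.artifact_dilation_px,
        )
    else:
        artifact = ArtifactMask.empty(shape)

    exclude = None
    if cfg.artifact_removal and cfg.exclude_artifacts_from_cutoff and artifact.combined.any():
        exclude = artifact.combined
    cutoff = compute_cutoff(slabs["outer_retina_avascular"], exclude=exclude)

    grid = build_etdrs_grid(
        shape,
        volume.lateral_pitch,
        center=cfg.grid_center,
        laterality=laterality or cfg.laterality,
    )
    void_masks = {name: binarize_below(slabs[name], cutoff.cutoff) for name in cfg.choroid_slabs}
    subfields = {name: quantify_flow_void(void_masks[name], artifact, grid) for name in cfg.choroid_slabs}
    ez = None
    if ez_annotation is not None:
        ez = ez_flow_void_fractions(void_masks[cfg.headline_slab], artifact, ez_annotation)
    return EyeAnalysis(cutoff, artifact, slabs, void_masks, grid, subfields, ez)


def annotation_from_truth(eye: SyntheticEye) -> Optional[EzLineAnnotation]:
    """Build the per-line EZ annotation a grader would supply, from ground truth."""
    if eye.truth_ez_intact is None or eye.ez_line_rows is None:
        return None
    return EzLineAnnotation(
        line_rows=eye.ez_line_rows,
        intact=eye.truth_ez_intact,
        deep_nonperfusion=eye.truth_deep_nonperfusion_mask[eye.ez_line_rows, :],
    )


def _round(x: float, nd: int = 6) -> float:
    return float("nan") if x != x else round(float(x), nd)


def _subfield_dict(results: Sequence[SubfieldResult]) -> dict:
    return {
        r.subfield: {
            "void_pct": _round(r.void_pct),
            "area_analyzed_px": r.area_analyzed_px,
            "area_artifact_px": r.area_artifact_px,
            "undefined": r.undefined,
        }
        for r in results
    }


def run_eye(
    eye,
    config: Optional[RunConfig] = None,
    ez_annotation: Optional[EzLineAnnotation] = None,
    record: Optional[EyeRecord] = None,
) -> dict:
    """Per-eye report as a plain dict.

    ``eye`` may be a :class:`SyntheticEye` (its truth annotation and record
    are used unless overridden) or a bare :class:`OctaVolume`.
    """
    cfg = config or RunConfig()
    if isinstance(eye, SyntheticEye):
        if eye.volume is None:
            raise CcFlowVoidError("eye has no volume (records-only generation)")
        volume = eye.volume
        record = record or eye.record
        if ez_annotation is None:
            ez_annotation = annotation_from_truth(eye)
    else:
        volume = eye
    laterality = record.laterality if record is not None else cfg.laterality
    analysis = analyze_eye(volume, cfg, ez_annotation=ez_annotation, laterality=laterality)

    slab_reports = {}
    for name in cfg.choroid_slabs:
        void = analysis.void_masks[name]
        usable = ~analysis.artifact.combined
        denom = int(usable.sum())
        whole = 100.0 * int((void & usable).sum()) / denom if denom else float("nan")
        slab_reports[name] = {
            "whole_field_void_pct": _round(whole),
            "subfields": _subfield_dict(analysis.subfields[name]),
        }

    report = {
        "eye_id": record.eye_id if record is not None else "anonymous",
        "config": cfg.to_dict(),
        "cutoff": {
            "value": _round(analysis.cutoff.cutoff),
            "n_pixels_used": analysis.cutoff.n_pixels_used,
            "source_slab": analysis.cutoff.source_slab,
        },
        "artifact": {
            "projection_threshold": _round(analysis.artifact.thresholds_used[0]),
            "shadow_threshold": _round(analysis.artifact.thresholds_used[1]),
            "n_projection_px": int(analysis.artifact.projection.sum()),
            "n_shadow_px": int(analysis.artifact.shadow.sum()),
            "n_combined_px": int(analysis.artifact.combined.sum()),
        },
        "slabs": slab_reports,
        "ez": None,
        "record": None,
    }
    if analysis.ez is not None:
        ez = analysis.ez
        report["ez"] = {
            "pct_disrupted": _round(ez.pct_disrupted),
            "pct_intact": _round(ez.pct_intact),
            "length_void_disrupted_px": ez.length_void_disrupted_px,
            "length_total_disrupted_px": ez.length_total_disrupted_px,
            "length_void_intact_px": ez.length_void_intact_px,
            "length_total_intact_px": ez.length_total_intact_px,
        }
    if record is not None:
        report["record"] = {
            "dr_grade": record.dr_grade,
            "logmar_va": _round(record.logmar_va),
            "csf_thickness_um": _round(record.csf_thickness_um),
            "ssi": _round(record.ssi),
            "dme": bool(record.dme),
            "laterality": record.laterality,
        }
    return report


def _csf_void_pct(report: dict, slab: str) -> float:
    return report["slabs"][slab]["subfields"]["CSF"]["void_pct"]


def run_cohort(eyes: Sequence[SyntheticEye], config: Optional[RunConfig] = None) -> dict:
    """Gate, analyze, and statistically summarize a cohort of eyes.

    Per-eye failures abort that eye with a structured diagnostic; the run
    continues.  Raises :class:`CohortError` when no eye passes the SSI gate.
    """
    cfg = config or RunConfig()
    if not eyes:
        raise CohortError("empty cohort")
    kept_records = ssi_gate([e.record for e in eyes], cfg.min_ssi)
    kept_ids = {r.eye_id for r in kept_records}
    if not kept_ids:
        raise CohortError(f"no eye has SSI > {cfg.min_ssi}")

    eye_reports: List[dict] = []
    failures: List[dict] = []
    for eye in eyes:
        if eye.record.eye_id not in kept_ids:
            continue
        try:
            eye_reports.append(run_eye(eye, cfg))
        except CcFlowVoidError as exc:
            failures.append({"eye_id": eye.record.eye_id, "error": type(exc).__name__, "message": str(exc)})

    slab = cfg.headline_slab
    rows = [
        {
            "eye_id": rep["eye_id"],
            "dr_grade": rep["record"]["dr_grade"],
            "csf_void_pct": _csf_void_pct(rep, slab),
            "logmar_va": rep["record"]["logmar_va"],
            "dme": rep["record"]["dme"],
        }
        for rep in eye_reports
        if rep["record"] is not None and not math.isnan(_csf_void_pct(rep, slab))
    ]

    grade_groups = {
        g: [r["csf_void_pct"] for r in rows if r["dr_grade"] == g]
        for g in DR_GRADES
        if any(r["dr_grade"] == g for r in rows)
    }
    grade_means = {g: _round(float(np.mean(v))) for g, v in grade_groups.items()}
    ordered_means = [grade_means[g] for g in DR_GRADES if g in grade_means]
    monotone = all(a < b for a, b in zip(ordered_means, ordered_means[1:]))

    usable_groups = {g: v for g, v in grade_groups.items() if len(v) >= 2}
    if len(usable_groups) >= 2:
        names = [g for g in DR_GRADES if g in usable_groups]
        res = anova_bonferroni([usable_groups[g] for g in names], equal_var=cfg.equal_variance_t)
        grade_comparison = {
            "groups": names,
            "anova_f": _round(res["f"]),
            "anova_p": _round(res["p"]),
            "pairwise_bonferroni_p": {
                f"{names[i]}|{names[j]}": _round(p) for (i, j), p in res["pairwise"].items()
            },
            "skipped": False,
            "warning": None,
        }
    else:
        grade_comparison = {
            "groups": list(usable_groups),
            "skipped": True,
            "warning": "fewer than two grades with n >= 2; grade comparison skipped",
        }

    def _corr(selected: List[dict]) -> Optional[dict]:
        if len(selected) < 3:
            return None
        x = [r["csf_void_pct"] for r in selected]
        y = [r["logmar_va"] for r in selected]
        if np.std(x) == 0 or np.std(y) == 0:
            return None
        r, p = pearson_corr(x, y)
        return {"r": _round(r), "p": _round(p), "n": len(selected)}

    va_correlation = {
        "all": _corr(rows),
        "without_dme": _corr([r for r in rows if not r["dme"]]),
        "with_dme": _corr([r for r in rows if r["dme"]]),
    }

    ez_pairs = [
        (rep["ez"]["pct_disrupted"], rep["ez"]["pct_intact"])
        for rep in eye_reports
        if rep["ez"] is not None
        and not math.isnan(rep["ez"]["pct_disrupted"])
        and not math.isnan(rep["ez"]["pct_intact"])
    ]
    if len(ez_pairs) >= 2:
        d = [p[0] for p in ez_pairs]
        i = [p[1] for p in ez_pairs]
        t_res = sps.ttest_rel(d, i)
        ez_comparison = {
            "n_eyes": len(ez_pairs),
            "mean_pct_disrupted": _round(float(np.mean(d))),
            "mean_pct_intact": _round(float(np.mean(i))),
            "paired_t": _round(float(t_res.statistic)),
            "paired_p": _round(float(t_res.pvalue)),
        }
    else:
        ez_comparison = None

    return {
        "config": cfg.to_dict(),
        "n_eyes_input": len(eyes),
        "n_eyes_after_ssi_gate": len(kept_ids),
        "n_eyes_analyzed": len(eye_reports),
        "failures": failures,
        "eyes": eye_reports,
        "grade_means_csf_void_pct": grade_means,
        "grade_means_monotone_increasing": monotone,
        "grade_comparison": grade_comparison,
        "va_correlation": va_correlation,
        "ez_comparison": ez_comparison,
    }
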