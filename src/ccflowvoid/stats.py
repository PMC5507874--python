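"""Eye-level classification and cohort statistics.

Holds the per-eye record type, the center-involved-DME classification from
central-subfield (CSF) thickness, the scan-quality (SSI) gate, and the
statistical tests applied to cohort results: Kolmogorov-Smirnov normality
screening, Student's t, one-way ANOVA with Bonferroni-corrected pairwise
comparisons, and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError, SampleSizeError

#: Retinopathy severity grades, in increasing order.
DR_GRADES = ("no_DR", "mild_NPDR", "moderate_NPDR", "severe_NPDR", "PDR")

#: Device-scale CSF-thickness boundary (µm) for center-involved DME; an eye
#: is DME only when thickness strictly exceeds this value.
DME_CSF_CUTOFF_UM = 299.52

#: Eyes with a signal strength index at or below this are excluded.
DEFAULT_MIN_SSI = 60.0


@dataclass
class EyeRecord:
    """Per-eye metadata feeding the cohort analyses."""

    eye_id: str
    dr_grade: str
    logmar_va: float
    csf_thickness_um: float
    ssi: float
    dme: Optional[bool] = None
    age_years: float = float("nan")
    hba1c_pct: float = float("nan")
    diabetes_duration_years: float = float("nan")
    laterality: str = "OD"

    def __post_init__(self) -> None:
        if self.dr_grade not in DR_GRADES:
            raise ParameterError(f"unknown DR grade {self.dr_grade!r}")
        if self.csf_thickness_um < 0:
            raise ParameterError("CSF thickness must be non-negative")
        if self.dme is None:
            self.dme = classify_center_involved_dme(self.csf_thickness_um)


def classify_center_involved_dme(csf_thickness_um: float) -> bool:
    """True iff CSF thickness strictly exceeds 299.52 µm."""
    if csf_thickness_um < 0:
        raise ParameterError("CSF thickness must be non-negative")
    return csf_thickness_um > DME_CSF_CUTOFF_UM


def ssi_gate(records: Sequence[EyeRecord], min_ssi: float = DEFAULT_MIN_SSI) -> List[EyeRecord]:
    """Keep eyes with SSI strictly above ``min_ssi`` (an SSI of 60 is excluded)."""
    return [r for r in records if r.ssi > min_ssi]


def ks_normality(sample: Sequence[float]) -> Tuple[float, float]:
    """One-sample KS statistic and p against a normal fitted to the sample.

    The reference normal uses the sample mean and (ddof=1) SD; note that
    with estimated parameters the resulting p-values are conservative.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.size < 5:
        raise SampleSizeError(f"normality screening needs n >= 5, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant sample; normality test undefined")
    res = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def anova_bonferroni(
    groups: Sequence[Sequence[float]],
    equal_var: bool = True,
) -> Dict:
    """One-way ANOVA plus Bonferroni-adjusted pairwise comparisons.

    Each pairwise two-sample test's p is multiplied by the number of pairs
    and capped at 1.  Returns ``{"f", "p", "pairwise": {(i, j): p_adj}}``.
    """
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise SampleSizeError("ANOVA needs at least two groups")
    for g in arrays:
        if g.size < 2:
            raise SampleSizeError("every group needs n >= 2")
    f_stat, p = sps.f_oneway(*arrays)
    pairs = list(combinations(range(len(arrays)), 2))
    pairwise: Dict[Tuple[int, int], float] = {}
    for i, j in pairs:
        t_res = sps.ttest_ind(arrays[i], arrays[j], equal_var=equal_var)
        pairwise[(i, j)] = float(min(1.0, t_res.pvalue * len(pairs)))
    return {"f": float(f_stat), "p": float(p), "pairwise": pairwise}


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r and two-sided p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    if x.size < 3:
        raise SampleSizeError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance; correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def welch_or_student_t(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = True,
) -> Tuple[float, float]:
    """Two-sample t (Student's by default, Welch optional); two-sided p."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateInputError("both samples constant; t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
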