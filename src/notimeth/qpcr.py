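"""Efficiency-corrected relative mRNA quantification with reference genes.

For a target gene with amplification efficiency ``E_tar`` and a reference
gene with ``E_ref`` (fractional efficiencies; one cycle multiplies template
by 1 + E), the relative mRNA level of the tumor against its paired normal
tissue is

    R = 2^[log2(1+E_tar)*Ct_tar - log2(1+E_ref)*Ct_ref] (normal)
        -----------------------------------------------
        2^[log2(1+E_tar)*Ct_tar - log2(1+E_ref)*Ct_ref] (tumor)

with replicate-averaged Ct values. R < 1 means downregulation in the tumor.
With E = 1 everywhere this reduces to the textbook 2^(-ddCt). Multiple
reference genes are combined by the geometric mean of per-reference R.
A change is called significant at the study's 2-fold rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import QpcrSampleSet, RelExpr, TestResult, ValidationError
from . import stats

__all__ = [
    "CohortSummary",
    "classify_change",
    "relative_expression",
    "stage_association",
    "summarize_cohort",
]

#: Minimum assay efficiency expected of a well-behaved qPCR (warn below).
MIN_EFFICIENCY = 0.9


def classify_change(r: float, fold_threshold: float = 2.0) -> str:
    """Apply the fold-change significance rule to a relative level R.

    Boundary values classify as changed: R <= 1/threshold is "down",
    R >= threshold is "up", anything between is "unchanged".
    """
    if r <= 0:
        raise ValidationError("relative expression must be positive")
    if fold_threshold < 1:
        raise ValidationError("fold_threshold must be >= 1")
    if r <= 1.0 / fold_threshold:
        return "down"
    if r >= fold_threshold:
        return "up"
    return "unchanged"


def relative_expression(q: QpcrSampleSet, fold_threshold: float = 2.0) -> RelExpr:
    """Efficiency-corrected relative mRNA level of one sample pair."""
    for name, e in (("target", q.e_tar), *q.e_ref.items()):
        if e < MIN_EFFICIENCY:
            warnings.warn(
                f"{q.gene}/{q.sample_id}: {name} efficiency {e:.2f} below {MIN_EFFICIENCY}",
                stacklevel=2,
            )
    a_tar = np.log2(1.0 + q.e_tar)
    tar_n = float(np.mean(q.ct_tar_normal))
    tar_c = float(np.mean(q.ct_tar_tumor))
    per_ref: dict[str, float] = {}
    for ref in q.references:
        a_ref = np.log2(1.0 + q.e_ref[ref])
        ref_n = float(np.mean(q.ct_ref_normal[ref]))
        ref_c = float(np.mean(q.ct_ref_tumor[ref]))
        log2_r = (a_tar * tar_n - a_ref * ref_n) - (a_tar * tar_c - a_ref * ref_c)
        per_ref[ref] = float(2.0 ** log2_r)
    r = float(2.0 ** np.mean([np.log2(v) for v in per_ref.values()]))
    return RelExpr(
        gene=q.gene,
        sample_id=q.sample_id,
        r=r,
        per_reference=per_ref,
        direction=classify_change(r, fold_threshold),
    )


@dataclass(frozen=True)
class CohortSummary:
    """Cohort summary of relative mRNA levels for one gene.

    ``median_fold`` is the n-fold magnitude of the median log2 change and is
    1 (direction "unchanged") when the median change is below the fold
    threshold — the convention used for genes whose typical change is not
    significant. ``r_max``/``r_min`` bound the observed relative levels.
    """

    gene: str
    n: int
    n_down: int
    n_up: int
    freq_down: int
    freq_up: int
    median_fold: float
    median_direction: str
    r_max: float
    r_min: float


def summarize_cohort(
    rel_exprs: Sequence[RelExpr], fold_threshold: float = 2.0
) -> CohortSummary:
    """Frequencies of significant change and the median n-fold change."""
    if not rel_exprs:
        raise ValidationError("at least one sample required")
    from .frequency import percent_half_up

    genes = {r.gene for r in rel_exprs}
    if len(genes) != 1:
        raise ValidationError(f"summary expects one gene, got {sorted(genes)}")
    n = len(rel_exprs)
    n_down = sum(1 for r in rel_exprs if classify_change(r.r, fold_threshold) == "down")
    n_up = sum(1 for r in rel_exprs if classify_change(r.r, fold_threshold) == "up")
    med_log2 = median(float(np.log2(r.r)) for r in rel_exprs)
    if 2.0 ** abs(med_log2) >= fold_threshold:
        fold = float(2.0 ** abs(med_log2))
        direction = "down" if med_log2 < 0 else "up"
    else:
        fold, direction = 1.0, "unchanged"
    values = [r.r for r in rel_exprs]
    return CohortSummary(
        gene=genes.pop(),
        n=n,
        n_down=n_down,
        n_up=n_up,
        freq_down=percent_half_up(n_down, n),
        freq_up=percent_half_up(n_up, n),
        median_fold=fold,
        median_direction=direction,
        r_max=float(max(values)),
        r_min=float(min(values)),
    )


def stage_association(
    rel_exprs: Sequence[RelExpr],
    stages: Mapping[str, str],
    late_stages: Iterable[str] = ("III",),
) -> TestResult:
    """Rank-sum comparison of log2 relative level between early and late stage.

    Groups samples into stages I+II versus III (configurable) and applies a
    two-sided Mann-Whitney test on log2(R). Raises when a group is empty.
    """
    late = set(late_stages)
    early_vals, late_vals = [], []
    for r in rel_exprs:
        if r.sample_id not in stages:
            raise ValidationError(f"no stage annotation for sample {r.sample_id}")
        (late_vals if stages[r.sample_id] in late else early_vals).append(
            float(np.log2(r.r))
        )
    if not early_vals or not late_vals:
        raise ValidationError("both stage groups must be nonempty")
    res = stats.mann_whitney(early_vals, late_vals)
    note = (
        f"{res.method_note}; groups: stages I+II (n={len(early_vals)}) "
        f"vs {'+'.join(sorted(late))} (n={len(late_vals)}) on log2(R)"
    )
    return TestResult(res.test_name, res.statistic, res.p_value, note)
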