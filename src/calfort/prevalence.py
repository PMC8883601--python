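"""EAR cut-point prevalence of inadequacy and UL exceedance.

Prevalence of inadequate intake is the weighted fraction of the usual-intake
distribution strictly below the group EAR; prevalence of excess is the
fraction strictly above the UL. Ties exactly at a threshold count as
adequate/safe (thresholds are interior points of continuous distributions, so
the convention is immaterial in the limit but is fixed and tested here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dri import DRIGroup
from .usual import UsualIntakeModel, estimate_usual_auto

__all__ = ["GroupReport", "cutpoint_prevalence", "report_from_usual", "group_report",
           "reports_to_frame"]


def cutpoint_prevalence(
    usual_values,
    threshold_mg: float,
    direction: str = "below",
    weights=None,
) -> float:
    """Weighted percentage of usual intakes strictly below/above a threshold."""
    x = np.asarray(usual_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty group: cannot compute prevalence")
    if threshold_mg <= 0:
        raise ValueError("threshold_mg must be > 0")
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    hit = x < threshold_mg if direction == "below" else x > threshold_mg
    return float(100.0 * w[hit].sum() / w.sum())


@dataclass(frozen=True)
class GroupReport:
    """Per-group summary mirroring a fortification-planning results table row."""

    group_id: str
    scenario: str
    n: int
    mean_mg: float
    sd_mg: float
    pct_below_ear: float
    pct_above_ul: float
    ear_mg: float
    ul_mg: float


def report_from_usual(
    usual_values,
    weights,
    dri_group: DRIGroup,
    group_id: str | None = None,
    scenario: str = "baseline",
) -> GroupReport:
    """Summarize a usual-intake distribution against a DRI stratum."""
    x = np.asarray(usual_values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    mean = float(np.average(x, weights=w))
    var = float(np.average((x - mean) ** 2, weights=w))
    return GroupReport(
        group_id=group_id or dri_group.group_id,
        scenario=scenario,
        n=int(x.size),
        mean_mg=mean,
        sd_mg=var**0.5,
        pct_below_ear=cutpoint_prevalence(x, dri_group.ear_mg, "below", w),
        pct_above_ul=cutpoint_prevalence(x, dri_group.ul_mg, "above", w),
        ear_mg=dri_group.ear_mg,
        ul_mg=dri_group.ul_mg,
    )


def group_report(
    records: pd.DataFrame,
    dri_group: DRIGroup,
    scenario: str = "baseline",
    group_id: str | None = None,
    **estimate_kwargs,
) -> tuple[GroupReport, UsualIntakeModel]:
    """Estimate usual intakes for one group's records and report EAR/UL prevalence.

    Extra keyword arguments are passed to
    :func:`calfort.usual.estimate_usual_auto` (e.g. ``external_ratio``).
    """
    model = estimate_usual_auto(records, **estimate_kwargs)
    report = report_from_usual(
        model.usual_values, model.weights, dri_group, group_id, scenario
    )
    return report, model


def reports_to_frame(reports) -> pd.DataFrame:
    """Tabulate reports, percentages rounded to one decimal as in survey tables."""
    df = pd.DataFrame([r.__dict__ for r in reports])
    for col in ("pct_below_ear", "pct_above_ul"):
        df[col] = df[col].round(1)
    for col in ("mean_mg", "sd_mg"):
        df[col] = df[col].round(1)
    return df
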