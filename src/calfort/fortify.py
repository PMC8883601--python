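"""Water-fortification scenarios: dose assignment, gap sizing, ladder search.

A scenario adds ``concentration (mg/l) x daily water volume (l/d)`` of calcium
to each individual's intake. Volumes come either from the data (``reported``
policy, using each individual's mean reported volume so the fortificant adds
no artificial day-to-day variance) or from fixed age-band assumptions
(``fixed`` policy; infants under 6 months receive no fortified water since the
recommendation at that age is exclusive breastfeeding).

Because the per-individual dose is constant across days, fortification shifts
each individual's usual (long-run mean) intake by exactly the dose. Scenario
evaluation therefore estimates the usual-intake distribution once from the
baseline records and applies the dose as a location shift — an exact identity,
not an approximation, and it keeps the whole concentration ladder consistent
with a single estimation per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .dri import DRIGroup
from .prevalence import GroupReport, report_from_usual
from .usual import UsualIntakeModel, estimate_usual_auto

__all__ = [
    "FortificationScenario",
    "SearchResult",
    "individual_dose",
    "apply_scenario",
    "initial_gap",
    "fortified_usual",
    "scenario_search",
    "weighted_quantile",
]

DEFAULT_LADDER = (500.0, 400.0, 300.0, 200.0)

#: (age_lo, age_hi, litres/day): 0.6 l for infants 6-<12 months, 1 l from age 1
DEFAULT_FIXED_VOLUMES = ((0.5, 1.0, 0.6), (1.0, math.inf, 1.0))


@dataclass(frozen=True)
class FortificationScenario:
    """One fortification policy plus the search ladder and safety threshold."""

    concentration_mg_per_l: float = 500.0
    volume_policy: str = "fixed"
    fixed_volumes: tuple = DEFAULT_FIXED_VOLUMES
    safety_threshold_pct: float = 2.5
    ladder: tuple = DEFAULT_LADDER

    def __post_init__(self) -> None:
        if self.concentration_mg_per_l < 0:
            raise ValueError("concentration must be >= 0")
        if self.volume_policy not in ("fixed", "reported"):
            raise ValueError("volume_policy must be 'fixed' or 'reported'")
        if any(v <= 0 for _, _, v in self.fixed_volumes):
            raise ValueError("fixed volumes must be > 0")
        if any(b >= a for a, b in zip(self.ladder, self.ladder[1:])):
            raise ValueError("ladder concentrations must be strictly decreasing")
        if not self.ladder or any(c < 0 for c in self.ladder):
            raise ValueError("ladder concentrations must be >= 0")

    def fixed_volume_for_age(self, age_years: float) -> float:
        """Assumed daily water volume (l); 0 below 6 months (not fortified)."""
        for lo, hi, vol in self.fixed_volumes:
            if lo <= age_years < hi:
                return vol
        return 0.0


def individual_dose(
    records: pd.DataFrame,
    scenario: FortificationScenario,
    concentration_mg_per_l: float | None = None,
) -> pd.Series:
    """Daily fortificant dose (mg/d) per individual, indexed by id.

    Under the ``reported`` policy the dose uses the individual's mean reported
    water volume; individuals with no reported volume at all raise an error
    naming them.
    """
    c = (
        scenario.concentration_mg_per_l
        if concentration_mg_per_l is None
        else concentration_mg_per_l
    )
    per_ind = records.groupby("id", sort=True)
    if scenario.volume_policy == "reported":
        if "water_l" not in records:
            raise ValueError("reported-volume scenario requires a water_l column")
        vol = per_ind["water_l"].mean()
        missing = vol.index[vol.isna()].tolist()
        if missing:
            raise ValueError(
                "reported-volume scenario but no water volume for individuals: "
                f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
            )
    else:
        age = per_ind["age_years"].first()
        vol = age.map(scenario.fixed_volume_for_age)
    return c * vol


def apply_scenario(
    records: pd.DataFrame, scenario: FortificationScenario
) -> pd.DataFrame:
    """Add the per-individual daily dose to every person-day calcium intake.

    Record count and ids are conserved; a zero concentration returns an equal
    copy. Used to materialize fortified recall files; scenario *evaluation*
    shifts usual values directly (see module docstring).
    """
    dose = individual_dose(records, scenario)
    out = records.copy()
    out["calcium_mg"] = out["calcium_mg"].to_numpy() + dose.reindex(
        out["id"]
    ).to_numpy()
    return out


def weighted_quantile(values, q: float, weights=None) -> float:
    """Weighted quantile (inverted-CDF definition)."""
    x = np.asarray(values, dtype=float)
    if weights is None:
        return float(np.quantile(x, q, method="inverted_cdf"))
    w = np.asarray(weights, dtype=float)
    return float(np.quantile(x, q, weights=w, method="inverted_cdf"))


def initial_gap(
    usual_values,
    dri_group: DRIGroup,
    target_prevalence_pct: float,
    weights=None,
) -> float:
    """Additional mg/d needed to bring a group to a target prevalence of inadequacy.

    Shifting the usual-intake distribution up by the returned amount leaves
    approximately ``target_prevalence_pct`` of the group below the EAR; 0 when
    the target is already met.
    """
    x = np.asarray(usual_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty group: cannot compute initial gap")
    if not 0 < target_prevalence_pct < 100:
        raise ValueError("target_prevalence_pct must be in (0, 100)")
    q = weighted_quantile(x, target_prevalence_pct / 100.0, weights)
    return max(0.0, dri_group.ear_mg - q)


def fortified_usual(
    records: pd.DataFrame,
    scenario: FortificationScenario,
    **estimate_kwargs,
):
    """Usual-intake distribution under a scenario: baseline estimate + dose shift.

    Returns ``(model, fortified_values)`` with ``fortified_values`` aligned to
    ``model.ids``. Exact for any per-individual constant daily dose (see
    module docstring).
    """
    model = estimate_usual_auto(records, **estimate_kwargs)
    dose = individual_dose(records, scenario)
    shifted = model.usual_values + dose.reindex(pd.Index(model.ids)).to_numpy()
    return model, shifted


@dataclass
class SearchResult:
    """Outcome of a concentration-ladder search."""

    chosen_mg_per_l: float
    safe: bool
    baseline: list[GroupReport]
    steps: dict[float, list[GroupReport]] = field(default_factory=dict)
    models: dict[str, UsualIntakeModel] = field(default_factory=dict)


def scenario_search(
    groups: Mapping[str, tuple[pd.DataFrame, DRIGroup]],
    scenario: FortificationScenario = FortificationScenario(),
    evaluate_all: bool = False,
    **estimate_kwargs,
) -> SearchResult:
    """Walk the concentration ladder until every group satisfies the UL constraint.

    Parameters
    ----------
    groups : mapping of label -> (records, DRIGroup)
        Person-day recall records per population group.
    scenario : FortificationScenario
        Volume policy, ladder and safety threshold.
    evaluate_all : bool
        Evaluate every rung instead of stopping at the first safe one
        (useful for reporting the full ladder).

    Returns the first ladder concentration at which no group exceeds the UL in
    more than ``safety_threshold_pct`` percent of individuals, with full
    reports per evaluated rung; if no rung is safe the last one is returned
    flagged unsafe.
    """
    if not groups:
        raise ValueError("need at least one group")

    models: dict[str, UsualIntakeModel] = {}
    doses: dict[str, pd.Series] = {}
    baseline: list[GroupReport] = []
    for label, (records, dri) in groups.items():
        model = estimate_usual_auto(records, **estimate_kwargs)
        models[label] = model
        doses[label] = individual_dose(records, scenario, 1.0)  # per mg/l
        baseline.append(
            report_from_usual(model.usual_values, model.weights, dri,
                              group_id=label, scenario="baseline")
        )

    steps: dict[float, list[GroupReport]] = {}
    chosen, safe = scenario.ladder[-1], False
    for c in scenario.ladder:
        reports = []
        for label, (records, dri) in groups.items():
            model = models[label]
            dose = doses[label].reindex(pd.Index(model.ids)).to_numpy() * c
            reports.append(
                report_from_usual(
                    model.usual_values + dose, model.weights, dri,
                    group_id=label, scenario=f"{c:g} mg/l",
                )
            )
        steps[c] = reports
        rung_safe = all(
            r.pct_above_ul <= scenario.safety_threshold_pct for r in reports
        )
        if rung_safe and not safe:
            chosen, safe = c, True
            if not evaluate_all:
                break
    return SearchResult(
        chosen_mg_per_l=chosen, safe=safe, baseline=baseline, steps=steps,
        models=models,
    )
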