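"""IOM calcium dietary reference values (EAR/UL) and demographic classification.

The Institute of Medicine defines the calcium estimated average requirement
(EAR) and tolerable upper intake level (UL) per age/sex stratum. Age intervals
are half-open ``[lo, hi)``: an individual aged exactly 19.0 years belongs to
the 19-<51 stratum, and one aged 50.999 years is still in it while 51.0 is
not. Pregnant and lactating women aged 14-50 share the values of non-pregnant
women of the same age, so classification ignores pregnancy except to validate
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "DRIGroup",
    "MAX_AGE",
    "build_dri_table",
    "classify_individual",
    "write_dri_table",
    "read_dri_table",
]

#: open upper bound for the oldest stratum (years); no survey reports older ages
MAX_AGE = 121.0

_SEXES = ("female", "male", "any")


@dataclass(frozen=True)
class DRIGroup:
    """One age/sex stratum with its calcium EAR and UL (mg/d)."""

    group_id: str
    sex: str
    age_lo_years: float
    age_hi_years: float
    pregnant: bool
    ear_mg: float
    ul_mg: float

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if not self.age_lo_years < self.age_hi_years:
            raise ValueError("age_lo_years must be < age_hi_years")
        if not 0 < self.ear_mg < self.ul_mg:
            raise ValueError("require 0 < ear_mg < ul_mg")

    def contains(self, age_years: float, sex: str) -> bool:
        """Whether (age, sex) falls in this stratum; ages are [lo, hi)."""
        return (
            self.age_lo_years <= age_years < self.age_hi_years
            and self.sex in ("any", sex)
        )


def build_dri_table() -> list[DRIGroup]:
    """The complete IOM calcium EAR/UL table.

    EAR and UL are sex-invariant except in the 51-<71 band, where the EAR is
    1000 mg/d for women but 800 mg/d for men. Pregnancy is not a separate
    stratum: values are inherited from the age group.
    """
    rows = [
        ("0-<1y", "any", 0.0, 1.0, 270.0, 1500.0),
        ("1-<4y", "any", 1.0, 4.0, 400.0, 2500.0),
        ("4-<9y", "any", 4.0, 9.0, 640.0, 2500.0),
        ("9-<19y", "any", 9.0, 19.0, 1100.0, 3000.0),
        ("19-<51y", "any", 19.0, 51.0, 800.0, 2500.0),
        ("51-<71y-f", "female", 51.0, 71.0, 1000.0, 2000.0),
        ("51-<71y-m", "male", 51.0, 71.0, 800.0, 2000.0),
        (">=71y", "any", 71.0, MAX_AGE, 1000.0, 2000.0),
    ]
    return [
        DRIGroup(gid, sex, lo, hi, False, ear, ul)
        for gid, sex, lo, hi, ear, ul in rows
    ]


def classify_individual(
    age_years: float,
    sex: str,
    pregnant: bool = False,
    table: list[DRIGroup] | None = None,
) -> DRIGroup:
    """Return the unique DRI stratum for an individual.

    Parameters
    ----------
    age_years : float
        Age in years, >= 0. Boundaries are half-open, so 19.0 classifies
        into 19-<51.
    sex : {"female", "male"}
    pregnant : bool
        Pregnant or lactating. Only valid for females; values are inherited
        from the non-pregnant age group. A pregnancy recorded outside the
        14-50 y range (occasionally present in survey data) is classified by
        age with a warning, since no pregnancy-specific reference values
        exist there.
    table : list of DRIGroup, optional
        Override table (e.g. loaded from file); defaults to the IOM values.
    """
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    if age_years < 0 or age_years >= MAX_AGE:
        raise ValueError(f"age_years must be in [0, {MAX_AGE}), got {age_years}")
    if pregnant and sex == "male":
        raise ValueError("unsupported stratum: pregnant male")
    if pregnant and not (14.0 <= age_years <= 50.0):
        warnings.warn(
            f"pregnancy recorded at age {age_years}; no pregnancy-specific "
            "reference values outside 14-50 y, classifying by age group",
            stacklevel=2,
        )
    if table is None:
        table = build_dri_table()
    matches = [g for g in table if g.contains(age_years, sex)]
    if len(matches) != 1:
        raise ValueError(
            f"DRI table does not uniquely classify age={age_years}, sex={sex} "
            f"({len(matches)} matches)"
        )
    return matches[0]


def write_dri_table(table: list[DRIGroup], path: str | Path) -> None:
    """Export a DRI table as CSV (the same schema ``read_dri_table`` accepts)."""
    pd.DataFrame(
        [
            {
                "group_id": g.group_id,
                "sex": g.sex,
                "age_lo": g.age_lo_years,
                "age_hi": g.age_hi_years,
                "pregnant": g.pregnant,
                "ear_mg": g.ear_mg,
                "ul_mg": g.ul_mg,
            }
            for g in table
        ]
    ).to_csv(path, index=False)


def read_dri_table(path: str | Path) -> list[DRIGroup]:
    """Load a user-supplied DRI table (CSV with the exported schema)."""
    df = pd.read_csv(path)
    required = {"group_id", "sex", "age_lo", "age_hi", "pregnant", "ear_mg", "ul_mg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DRI table missing columns: {sorted(missing)}")
    return [
        DRIGroup(
            str(r.group_id),
            str(r.sex),
            float(r.age_lo),
            float(r.age_hi),
            bool(r.pregnant),
            float(r.ear_mg),
            float(r.ul_mg),
        )
        for r in df.itertuples()
    ]
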