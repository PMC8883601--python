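"""Synthetic 24-h recall data with realistic between/within-person structure.

Each individual draws a usual (long-run average) daily calcium intake from a
right-skewed family, and each recall day adds within-person day-to-day noise.
The marginal mean/SD of observed daily intake match the requested values, and
the within:between variance ratio is controlled exactly on the model scale
(log scale for the lognormal family, original scale for gamma and truncated
normal).

Country presets encode the group means/SDs that national 24-h recall surveys
report for low- and middle-income settings, so downstream estimation can be
exercised against populations with known structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["GroupSpec", "generate_recalls", "country_preset", "COUNTRY_PRESETS"]

RECALL_COLUMNS = [
    "id",
    "age_years",
    "sex",
    "pregnant",
    "day",
    "calcium_mg",
    "water_l",
    "weight",
]

_FAMILIES = ("lognormal", "gamma", "normal")


@dataclass(frozen=True)
class GroupSpec:
    """Recipe for one synthetic population group.

    mean_mg/sd_mg are the target marginal mean and SD of *observed daily*
    intake (what survey tables print), not of usual intake. variance_ratio is
    within-person over between-person variance on the model scale; 0 means
    every recall day repeats the individual's usual intake exactly.
    """

    group_id: str
    n_individuals: int
    mean_mg: float
    sd_mg: float
    variance_ratio: float = 1.0
    n_days: int = 2
    intake_family: str = "lognormal"
    age_years: float = 30.0
    sex: str = "female"
    pregnant: bool = False
    water_mean_l: float | None = None  # None: no water column
    water_sd_l: float = 0.4
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (self.mean_mg > 0 and self.sd_mg > 0):
            raise ValueError("mean_mg and sd_mg must be > 0")
        if self.variance_ratio < 0 or not math.isfinite(self.variance_ratio):
            raise ValueError("variance_ratio must be finite and >= 0")
        if not 1 <= self.n_days <= 3:
            raise ValueError("n_days must be in 1..3")
        if self.intake_family not in _FAMILIES:
            raise ValueError(f"intake_family must be one of {_FAMILIES}")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")


def _lognormal_daily(spec: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    # log Y_ij = mu + b_i + w_ij with Var(w)/Var(b) = variance_ratio exactly
    cv2 = (spec.sd_mg / spec.mean_mg) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(spec.mean_mg) - sigma2 / 2
    sb2 = sigma2 / (1 + spec.variance_ratio)
    sw2 = sigma2 - sb2
    b = rng.normal(0.0, math.sqrt(sb2), size=spec.n_individuals)
    w = rng.normal(0.0, math.sqrt(sw2), size=(spec.n_individuals, spec.n_days))
    return np.exp(mu + b[:, None] + w)


def _gamma_daily(spec: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    # usual intake gamma; multiplicative mean-one lognormal day noise
    var_u = spec.sd_mg**2 / (1 + spec.variance_ratio)
    if var_u <= 0:
        raise ValueError("spec implies non-positive between-person variance")
    shape = spec.mean_mg**2 / var_u
    scale = var_u / spec.mean_mg
    u = rng.gamma(shape, scale, size=spec.n_individuals)
    if spec.variance_ratio == 0:
        return np.repeat(u[:, None], spec.n_days, axis=1)
    # relative day-noise variance solving Var_within = ratio/(1+ratio) * sd^2
    v_w = (spec.sd_mg**2 - var_u) / (var_u + spec.mean_mg**2)
    s2 = math.log1p(v_w)
    w = rng.normal(-s2 / 2, math.sqrt(s2), size=(spec.n_individuals, spec.n_days))
    return u[:, None] * np.exp(w)


def _positive_normal(
    rng: np.random.Generator, loc: np.ndarray, scale: float, shape: tuple[int, ...]
) -> np.ndarray:
    """Normal draws resampled until positive (light truncation assumed)."""
    out = rng.normal(loc, scale, size=shape)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(np.broadcast_to(loc, shape)[bad], scale)
    return np.maximum(out, 1e-6)


def _normal_daily(spec: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    var_u = spec.sd_mg**2 / (1 + spec.variance_ratio)
    sd_w = math.sqrt(spec.sd_mg**2 - var_u)
    u = _positive_normal(
        rng, np.full(spec.n_individuals, spec.mean_mg), math.sqrt(var_u),
        (spec.n_individuals,),
    )
    if spec.variance_ratio == 0:
        return np.repeat(u[:, None], spec.n_days, axis=1)
    return _positive_normal(
        rng, u[:, None], sd_w, (spec.n_individuals, spec.n_days)
    )


def generate_recalls(spec: GroupSpec, seed) -> pd.DataFrame:
    """Generate person-day recall records for one group.

    Returns the standard recall frame (columns ``id, age_years, sex, pregnant,
    day, calcium_mg, water_l, weight``), one row per individual per day,
    deterministic given (spec, seed). ``seed`` is anything accepted by
    :func:`numpy.random.default_rng`.
    """
    rng = np.random.default_rng(seed)
    if spec.intake_family == "lognormal":
        y = _lognormal_daily(spec, rng)
    elif spec.intake_family == "gamma":
        y = _gamma_daily(spec, rng)
    else:
        y = _normal_daily(spec, rng)

    n, k = spec.n_individuals, spec.n_days
    if spec.water_mean_l is not None:
        cv2 = (spec.water_sd_l / spec.water_mean_l) ** 2
        s2 = math.log1p(cv2)
        water = np.exp(
            rng.normal(math.log(spec.water_mean_l) - s2 / 2, math.sqrt(s2), (n, k))
        )
        # few individuals drink >1.5 l/d; cap the synthetic range accordingly
        water = np.clip(water, 0.1, 4.0).ravel()
    else:
        water = np.full(n * k, np.nan)

    ids = [f"{spec.group_id}-{i + 1:05d}" for i in range(n)]
    return pd.DataFrame(
        {
            "id": np.repeat(ids, k),
            "age_years": spec.age_years,
            "sex": spec.sex,
            "pregnant": spec.pregnant,
            "day": np.tile(np.arange(1, k + 1), n),
            "calcium_mg": y.ravel(),
            "water_l": water,
            "weight": float(spec.weight),
        }
    )


def _specs(country: str, n_days: int, groups) -> list[GroupSpec]:
    return [
        GroupSpec(
            group_id=f"{country}-{gid}",
            n_individuals=5000,
            mean_mg=mean,
            sd_mg=sd,
            n_days=n_days,
            age_years=age,
            sex=sex,
            pregnant=preg,
        )
        for gid, mean, sd, age, sex, preg in groups
    ]


# Group mean/SD of observed daily calcium intake (mg/d) as national surveys
# report them; ranges become one spec per endpoint, with representative ages
# placing children endpoints in the 1-<4 and 4-<9 strata and adults in 19-<51.
COUNTRY_PRESETS: dict[str, list[GroupSpec]] = {
    "uganda": _specs("uganda", 2, [
        ("women-a", 363.3, 163.2, 25.0, "female", False),
        ("women-b", 462.7, 283.7, 40.0, "female", False),
        ("pregnant-a", 372.3, 118.5, 25.0, "female", True),
        ("pregnant-b", 389.3, 137.4, 35.0, "female", True),
    ]),
    "lao": _specs("lao", 2, [
        ("children-a", 214.1, 104.6, 2.5, "female", False),
        ("children-b", 364.1, 257.8, 6.0, "male", False),
        ("women-a", 207.2, 93.4, 25.0, "female", False),
        ("women-b", 263.5, 109.9, 40.0, "female", False),
        ("pregnant-a", 229.6, 103.1, 25.0, "female", True),
        ("pregnant-b", 313.7, 185.5, 35.0, "female", True),
        ("men-a", 212.0, 62.5, 25.0, "male", False),
        ("men-b", 435.6, 318.3, 40.0, "male", False),
    ]),
    "bangladesh": _specs("bangladesh", 2, [
        ("women-a", 151.8, 53.7, 25.0, "female", False),
        ("women-b", 160.8, 55.6, 40.0, "female", False),
        ("pregnant-a", 143.2, 80.3, 25.0, "female", True),
        ("pregnant-b", 150.2, 58.8, 35.0, "female", True),
    ]),
    "zambia": _specs("zambia", 2, [
        ("children-a", 202.6, 70.8, 2.5, "female", False),
        ("children-b", 220.2, 64.0, 6.0, "male", False),
        ("women-a", 311.5, 24.5, 25.0, "female", False),
        ("women-b", 339.3, 9.6, 40.0, "female", False),
        ("pregnant-a", 317.4, 85.6, 25.0, "female", True),
        ("pregnant-b", 322.2, 114.4, 35.0, "female", True),
    ]),
    # single 24-h recall per person: estimation must use an external ratio
    "argentina": _specs("argentina", 1, [
        ("children-a", 609.3, 348.0, 2.5, "female", False),
        ("children-b", 752.2, 323.4, 6.0, "male", False),
        ("women-a", 361.6, 180.2, 25.0, "female", False),
        ("women-b", 460.7, 167.6, 40.0, "female", False),
        ("pregnant-a", 470.6, 246.7, 25.0, "female", True),
        ("pregnant-b", 491.3, 244.7, 35.0, "female", True),
    ]),
}


def country_preset(
    name: str,
    n_individuals: int | None = None,
    variance_ratio: float | None = None,
    n_days: int | None = None,
) -> list[GroupSpec]:
    """Return the GroupSpecs for a named country-like preset.

    Optional arguments override every group's sample size, variance ratio or
    number of recall days (Argentina defaults to a single day).
    """
    try:
        specs = COUNTRY_PRESETS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(COUNTRY_PRESETS)}"
        ) from None
    overrides = {}
    if n_individuals is not None:
        overrides["n_individuals"] = n_individuals
    if variance_ratio is not None:
        overrides["variance_ratio"] = variance_ratio
    if n_days is not None:
        overrides["n_days"] = n_days
    return [replace(s, **overrides) for s in specs]
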