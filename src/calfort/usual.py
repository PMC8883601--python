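"""Usual-intake estimation from replicate 24-h recalls.

A single recall day overstates the spread of a group's intake distribution
because it mixes between-person differences with within-person day-to-day
variation. The estimator here follows the classical measurement-error recipe
used for daily-consumed nutrients:

1. choose a normalizing power transform (Box-Cox family, log included as the
   zero-power limit) by maximizing a normal probability-plot correlation;
2. decompose the transformed-scale variance into between- and within-person
   components with a one-way random-effects method-of-moments fit (or, when
   replicate days are unavailable, split the total variance with an external
   within:between variance ratio);
3. shrink each individual's transformed day-mean toward the group mean by
   sqrt(vb / (vb + vw / k_i));
4. back-transform with a second-order (half-variance) bias correction so the
   mean of the usual-intake distribution tracks the observed mean intake.

Survey weights are treated as frequency weights throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerTransform",
    "UsualIntakeModel",
    "InsufficientReplicationError",
    "fit_transform",
    "estimate_variance_components",
    "estimate_usual",
    "estimate_usual_auto",
]


class InsufficientReplicationError(ValueError):
    """Raised when too few individuals have replicate recall days.

    Callers should re-run with an ``external_ratio`` (the IMAPP-style
    external within:between variance ratio) instead of fitted components.
    """


@dataclass(frozen=True)
class PowerTransform:
    """Box-Cox power transform; ``lmbda == 0`` is the natural log."""

    lmbda: float

    def apply(self, x):
        x = np.asarray(x, dtype=float)
        if self.lmbda == 0:
            return np.log(x)
        return (np.power(x, self.lmbda) - 1.0) / self.lmbda

    def inverse(self, t):
        t = np.asarray(t, dtype=float)
        if self.lmbda == 0:
            return np.exp(t)
        base = np.maximum(self.lmbda * t + 1.0, 1e-12)
        return np.power(base, 1.0 / self.lmbda)

    def inverse_d2(self, t):
        """Second derivative of the inverse, for the back-transform correction."""
        t = np.asarray(t, dtype=float)
        if self.lmbda == 0:
            return np.exp(t)
        base = np.maximum(self.lmbda * t + 1.0, 1e-12)
        return (1.0 - self.lmbda) * np.power(base, 1.0 / self.lmbda - 2.0)


#: candidate powers; 0 is log, 1 identity
DEFAULT_POWER_GRID = (-1.0, -0.5, -0.25, 0.0, 0.25, 1.0 / 3.0, 0.5, 2.0 / 3.0,
                      0.75, 1.0, 1.25, 1.5)


def fit_transform(intakes, grid=DEFAULT_POWER_GRID) -> PowerTransform:
    """Select the grid power maximizing the normal probability-plot correlation.

    Requires at least 10 positive values; constant data are rejected since no
    power transform can normalize them.
    """
    x = np.asarray(intakes, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite intake values to fit a transform")
    if (x <= 0).any():
        raise ValueError("intakes must be positive for the power-transform family")
    if np.ptp(x) == 0:
        raise ValueError("constant intakes: transform selection is degenerate")

    best, best_r = None, -np.inf
    for lam in grid:
        t = PowerTransform(lam).apply(x)
        if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
            continue
        (_, _), (_, _, r) = stats.probplot(t, dist="norm", fit=True)
        if r > best_r:
            best, best_r = lam, r
    if best is None:
        raise ValueError("no candidate power produced finite transformed values")
    return PowerTransform(best)


def _per_individual(records: pd.DataFrame, transform: PowerTransform):
    df = pd.DataFrame(
        {
            "id": records["id"].to_numpy(),
            "t": transform.apply(records["calcium_mg"].to_numpy()),
            "w": records["weight"].to_numpy()
            if "weight" in records
            else np.ones(len(records)),
        }
    )
    g = df.groupby("id", sort=True)
    m = g["t"].mean()
    k = g["t"].size()
    w = g["w"].first()
    ss = g["t"].apply(lambda v: float(((v - v.mean()) ** 2).sum()))
    return m, k, w, ss


def _wmean(x, w):
    return float(np.average(x, weights=w))


def _wvar(x, w):
    """Frequency-weighted unbiased variance."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    n = x.size
    if n < 2:
        return 0.0
    mu = np.average(x, weights=w)
    return float(np.average((x - mu) ** 2, weights=w) * n / (n - 1))


def estimate_variance_components(
    records: pd.DataFrame,
    transform: PowerTransform,
    min_replicated: int = 30,
) -> tuple[float, float]:
    """One-way random-effects variance decomposition on the transformed scale.

    Returns ``(var_between_t, var_within_t)``. The within component pools
    squared deviations from individual means over replicated individuals;
    the between component subtracts the within contribution from the variance
    of individual means using the harmonic mean number of days, clipping
    negative method-of-moments estimates to zero with a warning.
    """
    m, k, w, ss = _per_individual(records, transform)
    replicated = int((k >= 2).sum())
    if replicated < min_replicated:
        raise InsufficientReplicationError(
            f"only {replicated} individuals have >=2 recall days "
            f"(need {min_replicated}); re-run with external_ratio"
        )
    rep = k >= 2
    vw = float((w[rep] * ss[rep]).sum() / (w[rep] * (k[rep] - 1)).sum())
    k_harm = float(w.sum() / (w / k).sum())
    var_means = _wvar(m, w)
    vb = var_means - vw / k_harm
    if vb < 0:
        warnings.warn(
            "negative between-person variance estimate clipped to 0 "
            "(method-of-moments small-sample pathology)",
            stacklevel=2,
        )
        vb = 0.0
    return vb, vw


@dataclass
class UsualIntakeModel:
    """Fitted usual-intake distribution for one group.

    usual_values are per-individual shrunken usual intakes (mg/d), aligned
    with ``ids`` and ``weights``.
    """

    transform: PowerTransform
    grand_mean_t: float
    var_between_t: float
    var_within_t: float
    ids: np.ndarray
    usual_values: np.ndarray
    weights: np.ndarray

    @property
    def variance_ratio(self) -> float:
        if self.var_between_t == 0:
            return math.inf
        return self.var_within_t / self.var_between_t

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "usual_mg": self.usual_values, "weight": self.weights}
        )


def estimate_usual(
    records: pd.DataFrame,
    transform: PowerTransform | None = None,
    external_ratio: float | None = None,
    min_replicated: int = 30,
) -> UsualIntakeModel:
    """Estimate per-individual usual intakes for one group.

    Parameters
    ----------
    records : DataFrame
        Person-day recalls with columns ``id``, ``calcium_mg``, optional
        ``weight`` (frequency-style survey weight, constant within person).
    transform : PowerTransform, optional
        Pre-fitted transform; fitted on the daily intakes when omitted.
    external_ratio : float, optional
        Within:between variance ratio to use instead of fitting components
        (required when replicate days are unavailable). ``math.inf`` shrinks
        every individual to the group mean; 0 disables shrinkage.
    """
    if "calcium_mg" not in records or "id" not in records:
        raise ValueError("records must have 'id' and 'calcium_mg' columns")
    if transform is None:
        transform = fit_transform(records["calcium_mg"].to_numpy())

    m, k, w, ss = _per_individual(records, transform)

    if external_ratio is not None:
        if external_ratio < 0:
            raise ValueError("external_ratio must be >= 0")
        t_all = transform.apply(records["calcium_mg"].to_numpy())
        w_all = (
            records["weight"].to_numpy()
            if "weight" in records
            else np.ones(len(records))
        )
        total = _wvar(t_all, w_all)
        if math.isinf(external_ratio):
            vb, vw = 0.0, total
        else:
            vb = total / (1.0 + external_ratio)
            vw = total - vb
    else:
        vb, vw = estimate_variance_components(
            records, transform, min_replicated=min_replicated
        )

    gbar = _wmean(m, w)
    kv = k.to_numpy(dtype=float)
    denom = vb + vw / kv
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, np.sqrt(np.where(denom > 0, vb / denom, 1.0)), 1.0)
    u = gbar + f * (m.to_numpy() - gbar)
    usual = transform.inverse(u) + 0.5 * transform.inverse_d2(u) * vw
    usual = np.maximum(usual, 1e-9)

    return UsualIntakeModel(
        transform=transform,
        grand_mean_t=gbar,
        var_between_t=vb,
        var_within_t=vw,
        ids=m.index.to_numpy(),
        usual_values=usual,
        weights=w.to_numpy(dtype=float),
    )


def estimate_usual_auto(
    records: pd.DataFrame,
    external_ratio: float | None = None,
    default_external_ratio: float = 1.0,
    min_replicated: int = 30,
) -> UsualIntakeModel:
    """Fit components when replication allows, else fall back to an external ratio.

    This is the pipeline's default policy: surveys with replicate recall days
    use their own day-to-day variability; single-day surveys use
    ``default_external_ratio`` (a configurable stand-in for the external
    calcium variance ratio distributed with intake-modelling software).
    """
    if external_ratio is not None:
        return estimate_usual(records, external_ratio=external_ratio)
    try:
        return estimate_usual(records, min_replicated=min_replicated)
    except InsufficientReplicationError:
        warnings.warn(
            "insufficient replicate days; using default external variance "
            f"ratio {default_external_ratio}",
            stacklevel=2,
        )
        return estimate_usual(records, external_ratio=default_external_ratio)
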