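# Methods

## Problem setting

A dietary survey observes each individual's calcium intake on one to three
recall days. Group-level policy questions (what fraction of a population has
inadequate usual intake? would fortification push anyone past the safe upper
level?) are about *usual* intake — the individual's long-run daily average —
whose distribution is narrower than any single-day distribution. `calfort`
estimates that distribution per IOM demographic stratum, applies the EAR
cut-point and UL-exceedance metrics, and searches fortification scenarios.

## Dietary reference values

The IOM calcium EAR/UL table is encoded with half-open age intervals
`[lo, hi)`: age 19.0 belongs to 19-<51, age 50.999 does too, 51.0 does not.
EAR and UL are sex-invariant except 51-<71 y, where the EAR is 1000 mg/d for
women and 800 mg/d for men. Pregnancy and lactation (ages 14-50) inherit the
non-pregnant values; a pregnancy recorded outside that range — occasionally
present in survey files as a data error — is classified by age with a warning,
since no pregnancy-specific values exist there. The table partitions
(age, sex) space exactly (property-tested on a dense grid) and is exportable/
overridable as CSV.

## Usual-intake estimator

A transform–decompose–shrink–back-transform procedure for a daily-consumed
nutrient:

1. **Transform.** A Box-Cox power is selected from a fixed grid
   (−1 … 1.5, log at 0) by maximizing the normal probability-plot (Filliben)
   correlation of the transformed daily intakes. Constant or near-empty data
   are rejected. The transform/inverse pair round-trips to < 1e-9 relative
   error on the data range.
2. **Decompose.** One-way random-effects method of moments on the transformed
   scale: the within-person variance pools squared deviations from individual
   day-means over individuals with ≥ 2 days (default minimum 30 such
   individuals, configurable); the between-person variance subtracts
   `vw / k̄` (harmonic-mean days per person) from the variance of individual
   means. Negative between estimates — the standard small-sample pathology of
   this estimator — are clipped to 0 with a warning. When replication is
   insufficient the caller supplies an **external variance ratio** `r`, and
   the total transformed-scale variance is split as `vb = total/(1+r)`.
   The package default is `r = 1.0`: the external calcium ratio shipped with
   intake-modelling software is not publicly printed, so it is a configurable
   parameter rather than an asserted constant.
3. **Shrink.** Each individual's transformed day-mean moves toward the group
   mean by the factor `sqrt(vb / (vb + vw/k_i))`, which maps the day-mean
   distribution (variance `vb + vw/k`) onto the usual distribution (variance
   `vb`). The factor is in [0, 1], so the usual SD never exceeds the day-mean
   SD; an infinite ratio collapses the group to its mean, ratio 0 leaves the
   single-day distribution untouched.
4. **Back-transform.** `usual_i = g⁻¹(u_i) + ½ g⁻¹''(u_i) · vw`. The
   half-variance term is the second-order correction for the noise variance
   removed, which keeps the mean of the usual distribution within ~2 % of the
   observed mean intake (tested at n ≥ 1000 across generator families).

Survey weights are frequency-style throughout (means, variances, prevalences,
quantiles); design-based variance estimation for complex samples is out of
scope.

## Prevalence

EAR cut-point: weighted share of usual intakes **strictly below** the EAR;
excess: strictly above the UL. Values exactly at a threshold count as
adequate/safe — thresholds are interior points of continuous distributions so
the convention is immaterial asymptotically, but it is fixed and tested.
Reports print percentages to one decimal, matching survey-table style.

## Fortification

The dose for individual `i` is `c × V_i`, with `V_i` either the individual's
*mean reported* water volume (so the fortificant adds no artificial
within-person variance) or a fixed age-band volume: 0.6 l/d (alternative
0.8 l/d) for infants 6-<12 months and 1.0 l/d (alternative 1.5 l/d) from age
1. Infants under 6 months receive dose 0 — the feeding recommendation at that
age is exclusive breastfeeding — but their records are retained so record
counts and ids are conserved.

Because the dose is constant across an individual's days, the individual's
long-run mean shifts by exactly `c × V_i`. Scenario evaluation therefore
estimates the usual distribution once from baseline records and shifts each
usual value by the dose. This is an exact identity, not an approximation, and
it is deliberately preferred over re-running the estimator on dose-shifted
records: the Box-Cox re-fit is not translation-equivariant, so the naive
re-estimate would perturb quantiles for no statistical benefit and would cost
one estimation per ladder rung. The exact-location-shift property is tested
to 1e-6 relative tolerance on every quantile. `apply_scenario` still
materializes dose-shifted person-day records for export.

The **initial gap** toward a target prevalence `p` is
`max(0, EAR − Q(p/100))` with `Q` the weighted (inverted-CDF) quantile of the
usual distribution: shifting by the gap leaves ≈ `p` % below the EAR. The
**ladder search** walks 500 → 400 → 300 → 200 mg/l and returns the first
concentration at which every group's UL exceedance is ≤ the safety threshold
(default 2.5 %, with 2 % exposed as an alternative), or the last rung flagged
unsafe if none passes.

## Synthetic data generator

Each group draws usual intakes `U_i` from a configurable family and recall
days around them, so that the *marginal* mean/SD of observed daily intake hit
the published survey values (published SDs are SDs of daily intake, not of
usual intake) and the within:between variance ratio equals the requested
value on the model scale:

- **lognormal** (default; daily intakes are right-skewed):
  `log Y_ij = μ + b_i + w_ij` with `Var(w)/Var(b)` equal to the ratio exactly
  and `μ, σ²` solved from the target moments;
- **gamma** usual intakes with mean-one multiplicative lognormal day noise
  (ratio controlled on the original scale) — used to check that the estimator
  does not depend on the generator's family;
- **truncated-normal** with additive noise, resampled to positivity.

Optional per-day water volumes are lognormal clipped to [0.1, 4] l/d (few
people drink more than ~1.5 l/d). Output is deterministic given (spec, seed).

Country presets encode the group means/SDs that the source national surveys
report (e.g. Bangladesh non-pregnant women 151.8 (SD 53.7) mg/d; Zambia
children 202.6 (SD 70.8) mg/d). Where a survey reports a range across its age
groups, one group per endpoint is created, with representative ages placing
children endpoints in the 1-<4 and 4-<9 strata and adults in 19-<51. Defaults:
5000 individuals per group, 2 recall days (Argentina: 1, since that survey
took a single recall — exercising the external-ratio path), variance ratio 1,
lognormal family. The true within:between ratios of the source surveys are
unpublished, so the ratio is a parameter, not an asserted fact.

**What the generator does not emulate:** food-level composition, seasonal and
weekday effects, correlated nutrient intakes, complex-sample design effects,
reporting error beyond day-to-day noise, and intra-individual water/calcium
correlation. Passing tests demonstrate correct recovery of the assumed
measurement-error model, not robustness to every feature of real surveys.

## Numerical choices

- Transform grid fixed (no continuous optimization): deterministic,
  sufficient resolution for shrinkage purposes; ties resolve to the first
  grid point, i.e. the smaller power.
- Weighted quantiles use numpy's inverted-CDF definition.
- Back-transformed usual values are floored at a tiny positive number to
  guarantee positivity under extreme negative-power transforms.
- Simulation sizes: tests use 200–5000 individuals per group and the
  acceptance script 5000 (the size at which Monte-Carlo error in group
  prevalence is well under a percentage point), chosen to keep the whole
  suite fast while leaving clear margins against the stated tolerances.

## Known limitations

- The estimator targets daily-consumed nutrients; episodically consumed
  nutrients (two-part models) are out of scope.
- Method-of-moments components can be noisy below ~30 replicated
  individuals; the threshold is configurable but the default is deliberate.
- Baseline calcium already present in local water is not modelled (surveys
  rarely record it); reported scenarios assume the fortificant is the only
  change.
- Day indices are treated as exchangeable; non-consecutive-day designs get
  no special correction.
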