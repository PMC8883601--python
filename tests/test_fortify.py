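"""Fortification scenarios: dosing, gap arithmetic, ladder search."""

import numpy as np
import pandas as pd
import pytest

from calfort.dri import classify_individual
from calfort.fortify import (FortificationScenario, apply_scenario,
                             fortified_usual, individual_dose, initial_gap,
                             scenario_search, weighted_quantile)
from calfort.synth import GroupSpec, generate_recalls
from conftest import make_records


ADULT = classify_individual(30.0, "female")


def fixed(conc, general=1.0, infant=0.6, **kw):
    return FortificationScenario(
        concentration_mg_per_l=conc,
        fixed_volumes=((0.5, 1.0, infant), (1.0, float("inf"), general)),
        **kw,
    )


def test_scenario_validation():
    with pytest.raises(ValueError):
        FortificationScenario(concentration_mg_per_l=-1)
    with pytest.raises(ValueError):
        FortificationScenario(volume_policy="magic")
    with pytest.raises(ValueError, match="decreasing"):
        FortificationScenario(ladder=(300.0, 400.0))
    with pytest.raises(ValueError):
        FortificationScenario(fixed_volumes=((1.0, 2.0, 0.0),))


def test_zero_concentration_is_identity():
    rec = generate_recalls(GroupSpec("g", 50, 300, 100), seed=1)
    out = apply_scenario(rec, fixed(0.0))
    pd.testing.assert_frame_equal(out, rec)


def test_dose_arithmetic_adult():
    rec = make_records([160.8], age=30.0)
    out = apply_scenario(rec, fixed(500.0, general=1.5))
    assert out.loc[0, "calcium_mg"] == pytest.approx(910.8)


def test_fixed_volumes_by_age_band():
    rec = make_records([100.0] * 3, ids=["a", "b", "c"])
    rec["age_years"] = [0.3, 0.7, 12.0]
    dose = individual_dose(rec, fixed(500.0))
    assert dose["a"] == 0.0  # under 6 months: not fortified
    assert dose["b"] == pytest.approx(300.0)  # 0.6 l
    assert dose["c"] == pytest.approx(500.0)  # 1.0 l


def test_reported_policy_uses_mean_volume_and_names_missing():
    rec = make_records(
        [100.0, 100.0, 100.0, 100.0],
        ids=["a", "a", "b", "b"],
        days=[1, 2, 1, 2],
        water=[1.0, 2.0, np.nan, np.nan],
    )
    with pytest.raises(ValueError, match="b"):
        individual_dose(rec, FortificationScenario(volume_policy="reported"))
    rec.loc[2, "water_l"] = 0.5  # one reported day is enough: mean of available
    dose = individual_dose(
        rec, FortificationScenario(volume_policy="reported",
                                   concentration_mg_per_l=100.0)
    )
    assert dose["a"] == pytest.approx(150.0)
    assert dose["b"] == pytest.approx(50.0)


def test_apply_conserves_records_and_ids():
    rec = generate_recalls(GroupSpec("g", 40, 300, 100, n_days=2), seed=2)
    out = apply_scenario(rec, fixed(500.0))
    assert len(out) == len(rec)
    assert (out["id"] == rec["id"]).all()
    assert (out["calcium_mg"] > rec["calcium_mg"]).all()


def test_initial_gap_examples(rng):
    vals = np.linspace(0.0, 800.0, 1001)
    assert initial_gap(vals, ADULT, 50.0) == pytest.approx(400.0)
    # shifting by the gap leaves ~ the target fraction below the EAR
    shifted = vals + 400.0
    assert np.mean(shifted < ADULT.ear_mg) == pytest.approx(0.5, abs=0.01)
    assert initial_gap([900.0, 1000.0], ADULT, 10.0) == 0.0
    assert initial_gap([300.0], ADULT, 25.0) == pytest.approx(500.0)
    with pytest.raises(ValueError):
        initial_gap(vals, ADULT, 0.0)


def test_weighted_quantile_uses_weights():
    assert weighted_quantile([1.0, 2.0], 0.5, weights=[10.0, 1.0]) == 1.0


def test_usual_quantiles_shift_by_exact_dose():
    """Fixed-volume fortification is an exact location shift of the usual
    distribution: estimate-then-shift and the scenario-evaluation path agree
    at every quantile to 1e-6 relative tolerance."""
    rec = generate_recalls(GroupSpec("g", 800, 300, 100, n_days=2), seed=4)
    scenario = fixed(500.0, general=1.5)
    model, fortified = fortified_usual(rec, scenario)
    qs = np.linspace(0.01, 0.99, 33)
    base_q = np.quantile(model.usual_values, qs)
    fort_q = np.quantile(fortified, qs)
    np.testing.assert_allclose(fort_q, base_q + 750.0, rtol=1e-6)


def _high_intake_group(seed=10):
    # engineered so 500 mg/l breaches the UL (2500) but 400 mg/l does not
    rng = np.random.default_rng(seed)
    vals = np.clip(rng.normal(1680.0, 200.0, size=2000), 100.0, None)
    return make_records(vals, age=30.0)


def test_search_descends_ladder_until_safe():
    rec = _high_intake_group()
    groups = {"adults": (rec, ADULT)}
    res = scenario_search(groups, fixed(500.0), external_ratio=0.0)
    # oracle: direct counting of the shifted values per rung
    vals = rec["calcium_mg"].to_numpy()
    expected = next(
        c for c in (500.0, 400.0, 300.0, 200.0)
        if 100.0 * np.mean(vals + c > 2500.0) <= 2.5
    )
    assert 100.0 * np.mean(vals + 500.0 > 2500.0) > 2.5  # first rung unsafe
    assert expected == 400.0
    assert res.chosen_mg_per_l == expected
    assert res.safe
    assert set(res.steps) == {500.0, 400.0}


def test_search_stops_at_first_safe_rung():
    rec = generate_recalls(GroupSpec("g", 200, 300, 100, n_days=2), seed=5)
    res = scenario_search({"g": (rec, ADULT)}, fixed(500.0))
    assert res.chosen_mg_per_l == 500.0
    assert res.safe
    assert list(res.steps) == [500.0]


def test_search_exhaustion_flags_unsafe():
    vals = np.full(100, 2400.0) + np.linspace(0, 50, 100)
    rec = make_records(vals, age=30.0)
    res = scenario_search({"g": (rec, ADULT)}, fixed(500.0), external_ratio=0.0)
    assert res.chosen_mg_per_l == 200.0
    assert not res.safe
    assert len(res.steps) == 4


def test_ladder_monotonicity():
    """As concentration falls, inadequacy can only rise and excess only fall."""
    rec = _high_intake_group(seed=11)
    res = scenario_search({"g": (rec, ADULT)}, fixed(500.0),
                          evaluate_all=True, external_ratio=0.0)
    below = [res.steps[c][0].pct_below_ear for c in (500.0, 400.0, 300.0, 200.0)]
    above = [res.steps[c][0].pct_above_ul for c in (500.0, 400.0, 300.0, 200.0)]
    assert below == sorted(below)
    assert above == sorted(above, reverse=True)


def test_benefit_and_risk_monotone_versus_baseline():
    rec = generate_recalls(GroupSpec("g", 300, 700, 250, n_days=2), seed=6)
    res = scenario_search({"g": (rec, ADULT)}, fixed(500.0), evaluate_all=True)
    base = res.baseline[0]
    for reports in res.steps.values():
        assert reports[0].pct_below_ear <= base.pct_below_ear
        assert reports[0].pct_above_ul >= base.pct_above_ul


def test_empty_groups_rejected():
    with pytest.raises(ValueError):
        scenario_search({}, fixed(500.0))
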