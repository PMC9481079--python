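"""Projection core: multiplier algebra, coverage paths, and the deaths loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brute_force import brute_force_deaths
from conftest import random_scenario, single_cause_profile
from listlite import (
    DegenerateRiskError,
    DomainError,
    GeneratorConfig,
    RiskFactor,
    SaturationError,
    Scenario,
    ScheduleError,
    ValidationError,
    cause_multiplier,
    combine_multipliers,
    effective_coverage,
    generate_profile,
    interpolate_coverage,
    null_scenario,
    project,
    risk_multiplier,
    shift_risk_prevalence,
    uniform_scenario,
)

# ---------------------------------------------------------------------------
# coverage paths


def test_linear_ramp_matches_hand_example():
    values = interpolate_coverage(0.2, 0.7, start=1, end=5, horizon=5)
    assert values == pytest.approx([0.2, 0.3, 0.4, 0.5, 0.6, 0.7])


def test_constant_when_target_equals_baseline():
    assert interpolate_coverage(0.4, 0.4, 2, 4, 6) == pytest.approx([0.4] * 7)


def test_degenerate_ramp_steps_at_start():
    assert interpolate_coverage(0.1, 0.9, 1, 1, 3) == pytest.approx([0.1, 0.9, 0.9, 0.9])


def test_schedule_errors():
    with pytest.raises(ScheduleError):
        interpolate_coverage(0.1, 0.9, start=4, end=2, horizon=5)
    with pytest.raises(ScheduleError):
        interpolate_coverage(0.1, 0.9, start=1, end=9, horizon=5)
    with pytest.raises(DomainError):
        interpolate_coverage(-0.1, 0.9, 1, 2, 5)


@given(
    c0=st.floats(0, 1),
    target=st.floats(0, 1),
    start=st.integers(1, 6),
    length=st.integers(0, 6),
)
@settings(deadline=None, derandomize=True)
def test_ramp_stays_between_endpoints_and_is_monotone(c0, target, start, length):
    end = start + length
    values = interpolate_coverage(c0, target, start, end, horizon=end + 2)
    lo, hi = min(c0, target), max(c0, target)
    assert np.all(values >= lo - 1e-12) and np.all(values <= hi + 1e-12)
    diffs = np.diff(values)
    assert np.all(diffs >= -1e-12) if target >= c0 else np.all(diffs <= 1e-12)
    assert values[0] == pytest.approx(c0)
    assert values[-1] == pytest.approx(target)


# ---------------------------------------------------------------------------
# multipliers


def test_effective_coverage_product_and_passthrough():
    assert effective_coverage(0.8, 0.5) == pytest.approx(0.4)
    assert effective_coverage(0.37) == pytest.approx(0.37)
    assert effective_coverage(0.6, 1.0) == pytest.approx(0.6)
    assert effective_coverage(0.0, 0.9) == 0.0
    with pytest.raises(DomainError):
        effective_coverage(1.2, 0.5)


def test_cause_multiplier_hand_values():
    assert cause_multiplier(1.0, 1.0, 0.0, 1.0) == pytest.approx(0.0)
    assert cause_multiplier(0.3, 0.8, 0.5, 0.5) == pytest.approx(1.0)
    assert cause_multiplier(0.5, 1.0, 0.2, 0.6) == pytest.approx(1 - 0.2 / 0.9)


def test_cause_multiplier_exceeds_one_on_coverage_loss():
    assert cause_multiplier(0.5, 1.0, 0.6, 0.2) > 1.0


def test_saturation_error_when_baseline_removes_all_amenable_deaths():
    with pytest.raises(SaturationError):
        cause_multiplier(1.0, 1.0, 1.0, 1.0)


def test_combine_multipliers_is_an_order_free_product():
    assert combine_multipliers([0.9, 0.8]) == pytest.approx(0.72)
    assert combine_multipliers([0.8, 0.9]) == pytest.approx(combine_multipliers([0.9, 0.8]))
    assert combine_multipliers([]) == 1.0
    assert combine_multipliers([0.63]) == 0.63


def _bf_factor():
    return RiskFactor(
        id="bf",
        states=["none", "ebf"],
        baseline_prevalence={"none": 0.6, "ebf": 0.4},
        relative_risks={"none": {"child_1_59m": {"diarrhea": 2.0}}},
    )


def test_shift_risk_prevalence_hand_values():
    rf = _bf_factor()
    assert shift_risk_prevalence(rf, []) == pytest.approx(rf.baseline_prevalence)
    full = shift_risk_prevalence(rf, [(1.0, 1.0, 0.0, 1.0)])
    assert full == pytest.approx({"none": 0.0, "ebf": 1.0})
    half = shift_risk_prevalence(rf, [(0.5, 1.0, 0.0, 1.0)])
    assert half == pytest.approx({"none": 0.3, "ebf": 0.7})
    assert sum(half.values()) == pytest.approx(1.0)


def test_risk_multiplier_hand_values():
    rr = {"none": 2.0, "ebf": 1.0}
    p0 = {"none": 0.6, "ebf": 0.4}
    assert risk_multiplier(p0, p0, rr) == pytest.approx(1.0)
    assert risk_multiplier(p0, {"none": 0.2, "ebf": 0.8}, rr) == pytest.approx(0.75)
    flat = {"none": 1.7, "ebf": 1.7}
    assert risk_multiplier(p0, {"none": 0.1, "ebf": 0.9}, flat) == pytest.approx(1.0)
    with pytest.raises(DegenerateRiskError):
        risk_multiplier({"none": 1.0, "ebf": 0.0}, p0, {"none": 0.0, "ebf": 5.0})


# ---------------------------------------------------------------------------
# full projection


def test_null_scenario_saves_no_lives(demo, demo_null):
    result = project(demo, demo_null)
    assert result.table["lives_saved"].abs().max() == 0.0
    assert np.allclose(result.totals["deaths_baseline"], result.totals["deaths_scenario"])


def test_full_chain_hand_example():
    """60/1,000 on 100,000 births, e=0.5, AF=1, coverage 0 -> 1: 6,000 deaths halve."""
    profile = single_cause_profile(rate=60.0, births=100_000.0, horizon=5)
    scenario = Scenario(name="full", targets={"tx": 1.0}, scale_up_start=1, scale_up_end=5)
    result = project(profile, scenario)
    final = result.totals[result.totals["year"] == 5].iloc[0]
    assert final["deaths_baseline"] == pytest.approx(6000.0)
    assert final["deaths_scenario"] == pytest.approx(3000.0)
    assert final["lives_saved"] == pytest.approx(3000.0)
    assert result.lives_saved_total(year=0) == 0.0


def test_projection_linear_in_denominator():
    p1 = single_cause_profile(births=100_000.0)
    p2 = single_cause_profile(births=200_000.0)
    scenario = Scenario(name="s", targets={"tx": 0.8}, scale_up_start=1, scale_up_end=5)
    t1, t2 = project(p1, scenario).table, project(p2, scenario).table
    for col in ("deaths_baseline", "deaths_scenario", "lives_saved"):
        assert np.allclose(2 * t1[col], t2[col])


def test_intervention_order_does_not_matter():
    profile = generate_profile(GeneratorConfig(seed=5, n_interventions=4, n_risk_factors=1))
    scenario = uniform_scenario(profile, 0.95)
    flipped = profile.model_copy(
        update={"interventions": list(reversed(profile.interventions))}
    )
    assert project(profile, scenario).allclose(project(flipped, scenario), tol=1e-12)


def test_scenario_deaths_bounded_by_baseline_when_scaling_up():
    rng = np.random.default_rng(11)
    for seed in range(5):
        profile = generate_profile(GeneratorConfig(seed=seed))
        result = project(profile, random_scenario(profile, rng))
        totals = result.totals
        assert (totals["deaths_scenario"] >= -1e-9).all()
        assert (totals["deaths_scenario"] <= totals["deaths_baseline"] + 1e-9).all()


def test_affected_fraction_floors_the_reduction():
    """With e=1 and full coverage, residual deaths are baseline x (1 - AF)."""
    profile = single_cause_profile(efficacy=1.0, affected_fraction=0.6)
    scenario = Scenario(name="s", targets={"tx": 1.0}, scale_up_start=1, scale_up_end=5)
    final = project(profile, scenario).totals.query("year == 5").iloc[0]
    assert final["deaths_scenario"] == pytest.approx(final["deaths_baseline"] * 0.4)


def test_flat_relative_risks_leave_mortality_untouched(demo):
    """A risk factor whose RRs are all 1 contributes nothing, however hard it is shifted."""
    flat = demo.model_copy(deep=True)
    flat.risk_factors[0].relative_risks = {
        "none": {"child_1_59m": {"diarrhea": 1.0}},
        "partial": {"child_1_59m": {"diarrhea": 1.0}},
    }
    sc = Scenario(name="ebf", targets={"ebf_promotion": 1.0}, scale_up_start=1, scale_up_end=10)
    res_flat = project(flat, sc)
    assert res_flat.table["lives_saved"].abs().max() == 0.0


def test_quality_adjustment_discounts_coverage():
    """A readiness series below 1 shrinks impact relative to crude coverage."""
    profile = single_cause_profile(horizon=3)
    adjusted = profile.model_copy(deep=True)
    adjusted.interventions[0].readiness = [0.5, 0.5, 0.5, 0.5]
    sc = Scenario(name="s", targets={"tx": 1.0}, scale_up_start=1, scale_up_end=3)
    crude = project(profile, sc).horizon_lives_saved()
    qual = project(adjusted, sc).horizon_lives_saved()
    assert 0 < qual < crude
    # with e=0.5, AF=1, c0=0: crude saves 50%, readiness 0.5 saves 25%
    assert qual == pytest.approx(crude / 2)


def test_quality_improvement_alone_creates_impact():
    """Rising readiness at flat crude coverage still averts deaths."""
    profile = single_cause_profile(horizon=2, baseline_coverage=0.5)
    better = profile.model_copy(deep=True)
    better.interventions[0].readiness = [0.5, 0.75, 1.0]
    result = project(better, null_scenario(better))
    assert result.horizon_lives_saved() > 0


def test_scenario_cross_validation_errors(demo):
    with pytest.raises(ValidationError, match="unknown intervention"):
        project(demo, Scenario(name="x", targets={"nope": 0.9}, scale_up_start=1, scale_up_end=5))
    with pytest.raises(ScheduleError, match="horizon"):
        project(demo, Scenario(name="x", targets={}, scale_up_start=1, scale_up_end=99))


def test_saturation_reported_with_intervention_context():
    profile = single_cause_profile(efficacy=1.0, affected_fraction=1.0, baseline_coverage=1.0)
    scenario = Scenario(name="s", targets={"tx": 1.0}, scale_up_start=1, scale_up_end=5)
    with pytest.raises(SaturationError, match="tx"):
        project(profile, scenario)


@pytest.mark.parametrize("seed", [1, 13, 77])
def test_matches_brute_force_oracle_on_tiny_profiles(seed):
    profile = generate_profile(
        GeneratorConfig(seed=seed, n_causes=2, n_interventions=3, n_risk_factors=1, horizon=3)
    )
    scenario = random_scenario(profile, np.random.default_rng(seed))
    result = project(profile, scenario)
    expected = brute_force_deaths(profile, scenario)
    for row in result.totals.itertuples():
        d0, d1 = expected[(row.year, row.group, row.cause)]
        assert row.deaths_baseline == pytest.approx(d0, rel=1e-9)
        assert row.deaths_scenario == pytest.approx(d1, rel=1e-9)


@given(seed=st.integers(0, 500), bump=st.floats(0.01, 0.3))
@settings(deadline=None, derandomize=True, max_examples=25)
def test_raising_one_target_never_loses_lives(seed, bump):
    """Monotonicity: a higher single coverage target cannot cost lives."""
    profile = generate_profile(GeneratorConfig(seed=seed, n_interventions=3))
    if not profile.interventions:
        return
    rng = np.random.default_rng(seed)
    scenario = random_scenario(profile, rng)
    base = project(profile, scenario).cumulative_lives_saved()
    iid = profile.interventions[int(rng.integers(len(profile.interventions)))].id
    raised = scenario.model_copy(deep=True)
    raised.targets[iid] = min(1.0, raised.targets[iid] + bump)
    assert project(profile, raised).cumulative_lives_saved() >= base - 1e-9
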