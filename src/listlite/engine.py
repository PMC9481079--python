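"""Projection core.

The model holds cause-specific mortality rates constant at their baseline
values and moves deaths only through intervention coverage.  Scaling an
intervention's coverage from its baseline c0 to c_t multiplies the deaths of
each cause it acts on by the residual-mortality survival multiplier

    m = 1 - (efficacy * AF * (c_t - c0)) / (1 - efficacy * AF * c0)

where AF is the affected fraction.  The denominator reflects that baseline
deaths already exclude deaths averted by baseline coverage, so scale-up acts
on the residual.  Multipliers from different interventions (and from
risk-factor paths) combine as an independence product on each cause.

Risk-factor mediation: interventions targeting a categorical risk factor move
a fraction f = 1 - prod_i m_i of each harmful state's baseline prevalence to
the reference state; the cause-specific multiplier is then the ratio of
RR-weighted prevalence sums after vs. before the shift (a comparative-risk
argument).

Quality adjustment: when an intervention carries utilization and/or readiness
series, the coverage entering the multiplier at every year t (including the
baseline year) is c(t) * utilization(t) * readiness(t), with a missing series
treated as 1.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateRiskError,
    DomainError,
    SaturationError,
    ScheduleError,
    ValidationError,
)
from .profile_model import (
    RESULT_COLUMNS,
    TOTAL_LABEL,
    Effect,
    Intervention,
    Profile,
    ProjectionResult,
    RiskFactor,
    Scenario,
    baseline_deaths,
)

logger = logging.getLogger(__name__)


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise DomainError(f"{name}={value:g} outside [0, 1]")


def interpolate_coverage(
    c0: float, target: float, start: int, end: int, horizon: int
) -> np.ndarray:
    """Linear coverage ramp from c0 to ``target`` between year offsets
    ``start`` and ``end``; constant before and after.

    Returns an array of length ``horizon + 1`` with index 0 = baseline.
    The ramp takes its first step *at* ``start`` (value c0 holds strictly
    before it) and reaches ``target`` at ``end``.
    """
    _check_proportion("c0", c0)
    _check_proportion("target", target)
    if start > end:
        raise ScheduleError(f"scale_up_start={start} after scale_up_end={end}")
    if start < 1:
        raise ScheduleError(f"scale_up_start={start} must be >= 1")
    if end > horizon:
        raise ScheduleError(f"scale_up_end={end} exceeds horizon={horizon}")
    values = np.empty(horizon + 1)
    steps = end - start + 1
    for t in range(horizon + 1):
        if t < start:
            values[t] = c0
        elif t >= end:
            values[t] = target
        else:
            values[t] = c0 + (target - c0) * (t - start + 1) / steps
    return values


def effective_coverage(utilization: float, readiness: Optional[float] = None) -> float:
    """Quality-adjusted coverage: utilization x readiness.

    With ``readiness`` absent the utilization passes through unchanged.
    """
    _check_proportion("utilization", utilization)
    if readiness is None:
        return utilization
    _check_proportion("readiness", readiness)
    return utilization * readiness


def cause_multiplier(efficacy: float, affected_fraction: float, c0: float, ct: float) -> float:
    """Survival multiplier on cause-specific deaths for one intervention.

    Equals 1 at ct == c0; falls below 1 as coverage rises; exceeds 1 when
    coverage is lost (ct < c0).  Raises :class:`SaturationError` when baseline
    coverage already removes all amenable deaths
    (efficacy * affected_fraction * c0 >= 1).
    """
    _check_proportion("efficacy", efficacy)
    _check_proportion("affected_fraction", affected_fraction)
    _check_proportion("c0", c0)
    _check_proportion("ct", ct)
    impact = efficacy * affected_fraction
    denom = 1.0 - impact * c0
    if denom <= 0.0:
        raise SaturationError(
            f"efficacy*AF*c0 = {impact * c0:g} >= 1: baseline coverage already "
            "removes all amenable deaths"
        )
    return 1.0 - impact * (ct - c0) / denom


def combine_multipliers(multipliers: Iterable[float]) -> float:
    """Independence product of survival multipliers; empty input gives 1."""
    out = 1.0
    for m in multipliers:
        if m <= 0.0:
            raise DomainError(f"multiplier {m:g} must be positive")
        out *= m
    return out


def shift_risk_prevalence(
    rf: RiskFactor,
    exposures: Sequence[tuple[float, float, float, float]],
) -> dict[str, float]:
    """Prevalence map after interventions act on a risk factor.

    ``exposures`` lists (efficacy, affected_fraction, c0, ct) for every effect
    targeting the risk factor at the year of interest.  A fraction
    f = 1 - prod_i cause_multiplier(...) of each harmful state's baseline
    prevalence moves to the reference state; the output sums to 1.
    """
    shrink = 1.0
    for (e, af, c0, ct) in exposures:
        # 0 is legal here: full efficacy at full coverage empties the state
        shrink *= cause_multiplier(e, af, c0, ct)
    f = 1.0 - shrink
    ref = rf.reference_state
    out: dict[str, float] = {}
    moved = 0.0
    for state in rf.states:
        p = rf.baseline_prevalence[state]
        if state == ref:
            out[state] = p
        else:
            out[state] = p * (1.0 - f)
            moved += p * f
    out[ref] += moved
    return out


def risk_multiplier(
    p0: Mapping[str, float], pt: Mapping[str, float], rr: Mapping[str, float]
) -> float:
    """Cause-specific mortality multiplier from a prevalence shift.

    M = sum_s pt(s) RR(s) / sum_s p0(s) RR(s); equal maps or flat RRs give 1.
    """
    if set(p0) != set(pt):
        raise DomainError("prevalence maps must cover the same states")
    values = {rr.get(s, 1.0) for s in p0}
    if len(values) == 1:
        # flat risk: shifting prevalence cannot change mortality; return
        # exactly 1 rather than a ratio carrying rounding noise
        if next(iter(values)) <= 0.0 and sum(p0.values()) > 0:
            raise DegenerateRiskError("all relative risks are zero")
        return 1.0
    num = sum(pt[s] * rr.get(s, 1.0) for s in pt)
    den = sum(p0[s] * rr.get(s, 1.0) for s in p0)
    if den <= 0.0:
        raise DegenerateRiskError(f"RR-weighted baseline prevalence is {den:g}")
    return num / den


# ---------------------------------------------------------------------------
# Full projection


def validate_scenario(profile: Profile, scenario: Scenario) -> None:
    """Cross-check a scenario against its profile."""
    known = {iv.id for iv in profile.interventions}
    for iid in scenario.targets:
        if iid not in known:
            raise ValidationError(
                f"scenario '{scenario.name}' targets unknown intervention '{iid}'"
            )
    if scenario.scale_up_end > profile.demography.horizon:
        raise ScheduleError(
            f"scale_up_end={scenario.scale_up_end} exceeds horizon="
            f"{profile.demography.horizon}"
        )


def _quality(iv: Intervention, t: int) -> float:
    u = iv.utilization[t] if iv.utilization is not None else 1.0
    r = iv.readiness[t] if iv.readiness is not None else 1.0
    return effective_coverage(u, r)


def effective_coverage_series(
    profile: Profile, scenario: Scenario, intervention: Intervention
) -> np.ndarray:
    """Quality-adjusted coverage path for one intervention under a scenario."""
    demo = profile.demography
    c0 = intervention.baseline_coverage
    target = scenario.targets.get(intervention.id, c0)
    crude = interpolate_coverage(
        c0, target, scenario.scale_up_start, scenario.scale_up_end, demo.horizon
    )
    if target < c0:
        logger.warning(
            "intervention '%s': target coverage %.3f below baseline %.3f "
            "(mortality will rise)",
            intervention.id,
            target,
            c0,
        )
    quality = np.array([_quality(intervention, t) for t in range(demo.horizon + 1)])
    return crude * quality


class _CellMultipliers:
    """Per-(year, group, cause) survival multipliers, split by intervention.

    ``total`` is the product actually applied to baseline deaths.
    ``deficit_by_intervention`` maps intervention id -> (1 - combined m_i),
    where m_i folds in the intervention's direct effects and its share of any
    risk-factor path it feeds (split within the path by the same
    proportional-deficit rule).  Used for attribution.
    """

    def __init__(self) -> None:
        self.total = 1.0
        self.m_by_intervention: dict[str, float] = {}

    def apply_direct(self, iid: str, m: float) -> None:
        self.total *= m
        self.m_by_intervention[iid] = self.m_by_intervention.get(iid, 1.0) * m

    def apply_risk_path(self, m_path: float, feeder_deficits: dict[str, float]) -> None:
        self.total *= m_path
        total_w = sum(feeder_deficits.values())
        if total_w <= 0.0:
            return
        for iid, w in feeder_deficits.items():
            share = w / total_w
            self.m_by_intervention[iid] = self.m_by_intervention.get(iid, 1.0) * (
                1.0 - share * (1.0 - m_path)
            )

    def deficits(self) -> dict[str, float]:
        return {iid: 1.0 - m for iid, m in self.m_by_intervention.items()}


def _cell_multipliers(
    profile: Profile,
    coverage: Mapping[str, np.ndarray],
    t: int,
) -> dict[tuple[str, str], _CellMultipliers]:
    """Multipliers for every (group, cause) cell at year t."""
    cells: dict[tuple[str, str], _CellMultipliers] = {}
    for env in profile.envelopes:
        for cause in env.cause_fractions:
            cells[(env.group, cause)] = _CellMultipliers()

    def _mult(iv: Intervention, eff: Effect) -> float:
        c_path = coverage[iv.id]
        try:
            return cause_multiplier(eff.efficacy, eff.affected_fraction, c_path[0], c_path[t])
        except SaturationError as exc:
            raise SaturationError(
                f"intervention '{iv.id}', target '{eff.target}': {exc}"
            ) from exc

    # direct effects
    for iv in profile.interventions:
        for eff in iv.effects:
            if eff.target_kind != "cause":
                continue
            cells[(eff.group, eff.target)].apply_direct(iv.id, _mult(iv, eff))

    # risk-factor paths
    for rf in profile.risk_factors:
        feeders: list[tuple[Intervention, Effect]] = [
            (iv, eff)
            for iv in profile.interventions
            for eff in iv.effects
            if eff.target_kind == "risk_factor" and eff.target == rf.id
        ]
        exposures = []
        feeder_deficits: dict[str, float] = {}
        for iv, eff in feeders:
            c_path = coverage[iv.id]
            exposures.append((eff.efficacy, eff.affected_fraction, c_path[0], c_path[t]))
            m_shift = _mult(iv, eff)
            feeder_deficits[iv.id] = feeder_deficits.get(iv.id, 0.0) + (1.0 - m_shift)
        pt = shift_risk_prevalence(rf, exposures)
        for group, cause in rf.cause_keys():
            if (group, cause) not in cells:
                continue  # RR on a cause this profile does not track
            rr = {s: rf.rr(s, group, cause) for s in rf.states}
            m_path = risk_multiplier(rf.baseline_prevalence, pt, rr)
            cells[(group, cause)].apply_risk_path(m_path, dict(feeder_deficits))
    return cells


def project(profile: Profile, scenario: Scenario) -> ProjectionResult:
    """Run the year-by-year deaths loop for a scenario.

    Baseline deaths keep rates constant (denominators may still grow);
    scenario deaths apply the combined survival multiplier per cell.  Year 0
    is the baseline year and always shows zero lives saved.
    """
    validate_scenario(profile, scenario)
    demo = profile.demography
    coverage = {
        iv.id: effective_coverage_series(profile, scenario, iv)
        for iv in profile.interventions
    }
    iids = [iv.id for iv in profile.interventions]
    rows: list[tuple] = []
    for t in range(demo.horizon + 1):
        cells = _cell_multipliers(profile, coverage, t)
        for env in profile.envelopes:
            for cause in env.cause_fractions:
                cell = cells[(env.group, cause)]
                d0 = baseline_deaths(profile, env.group, cause, t)
                d1 = d0 * cell.total
                saved = d0 - d1
                rows.append((t, env.group, cause, TOTAL_LABEL, d0, d1, saved))
                deficits = cell.deficits()
                total_deficit = sum(deficits.values())
                for iid in iids:
                    # share = 0 when no intervention moves this cell at all
                    if total_deficit != 0.0:
                        share = deficits.get(iid, 0.0) / total_deficit
                    else:
                        share = 0.0
                    rows.append((t, env.group, cause, iid, d0, d1, share * saved))
    table = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    result = ProjectionResult(table)
    logger.info(
        "projection '%s': %.1f cumulative lives saved (%.1f in final year)",
        scenario.name,
        result.cumulative_lives_saved(),
        result.horizon_lives_saved(),
    )
    return result


__all__ = [
    "interpolate_coverage",
    "effective_coverage",
    "effective_coverage_series",
    "cause_multiplier",
    "combine_multipliers",
    "shift_risk_prevalence",
    "risk_multiplier",
    "validate_scenario",
    "project",
]
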