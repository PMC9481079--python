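"""Analyses over engine output: attribution, missed-opportunity ranking,
input-data summaries, and modeled-vs-measured comparison.

These mirror the three workflows a program evaluator runs against a
projection model: review the inputs, rank single interventions by the
additional deaths they could avert, and decompose a package's impact into
per-intervention contributions.  A fourth helper compares modeled mortality
rates with independently measured ones, reporting gaps without any
statistical testing — the comparison is a learning device, not a hypothesis
test.
"""

from __future__ import annotations

import logging
from typing import Mapping, Union

import pandas as pd

from . import engine
from .errors import AlignmentError, ConsistencyError, DomainError, SaturationError
from .profile_model import (
    Profile,
    ProjectionResult,
    Scenario,
    baseline_deaths,
    denominator_count,
)

logger = logging.getLogger(__name__)

#: Conventional "high coverage" target for missed-opportunity ranking.
DEFAULT_STANDARD_TARGET = 0.9


def attribute(
    profile: Profile, scenario: Scenario, result: ProjectionResult
) -> pd.DataFrame:
    """Per-intervention lives saved for every (year, group, cause) cell.

    Within a cell, intervention i receives the share
    (1 - m_i) / sum_j (1 - m_j) of the cell's total lives saved, where m_i is
    its combined survival multiplier (direct effects plus its share of any
    risk-factor path it feeds).  Shares conserve the total exactly; a cell no
    intervention moves attributes zero to everyone.

    ``result`` must be the projection of (profile, scenario); a mismatch
    raises :class:`ConsistencyError`.
    """
    recomputed = engine.project(profile, scenario)
    if not recomputed.allclose(result, tol=1e-9):
        raise ConsistencyError(
            "result table does not match a projection of this profile and scenario"
        )
    table = recomputed.by_intervention.loc[
        :, ["year", "group", "cause", "intervention", "lives_saved"]
    ].reset_index(drop=True)
    return table


def rank_missed_opportunities(
    profile: Profile, standard_target: float = DEFAULT_STANDARD_TARGET
) -> list[tuple[str, float]]:
    """Rank interventions by solo scale-up impact.

    Each intervention is scaled alone from its baseline coverage to
    ``standard_target`` (linear, year 1 through the horizon) and the
    final-year lives saved are recorded.  Returns (intervention id, deaths
    averted) sorted by impact descending, ties broken by id.  An intervention
    whose baseline coverage already saturates its causes is reported with 0
    and a warning.
    """
    if not 0.0 <= standard_target <= 1.0:
        raise DomainError(f"standard_target={standard_target:g} outside [0, 1]")
    horizon = profile.demography.horizon
    entries: list[tuple[str, float]] = []
    for iv in profile.interventions:
        solo = Scenario(
            name=f"solo:{iv.id}",
            targets={iv.id: standard_target},
            scale_up_start=1,
            scale_up_end=horizon,
        )
        try:
            result = engine.project(profile, solo)
        except SaturationError as exc:
            logger.warning("intervention '%s' saturated, reporting 0: %s", iv.id, exc)
            entries.append((iv.id, 0.0))
            continue
        entries.append((iv.id, result.horizon_lives_saved()))
    entries.sort(key=lambda pair: (-pair[1], pair[0]))
    return entries


def explore_summary(profile: Profile) -> dict[str, pd.DataFrame]:
    """Input-data review tables, derived purely from the profile.

    Returns a dict of tidy tables:

    * ``coverage`` — intervention x baseline coverage;
    * ``mortality`` — outcome group x baseline rate (in the group's units);
    * ``causes`` — group x cause x fraction x baseline-year deaths;
    * ``risk_factors`` — risk factor x state x baseline prevalence (empty
      when the profile has none).
    """
    coverage = pd.DataFrame(
        [(iv.id, iv.name, iv.baseline_coverage) for iv in profile.interventions],
        columns=["intervention", "name", "baseline_coverage"],
    )
    mortality = pd.DataFrame(
        [(env.group, env.base_rate) for env in profile.envelopes],
        columns=["group", "base_rate"],
    )
    causes = pd.DataFrame(
        [
            (env.group, cause, frac, baseline_deaths(profile, env.group, cause, 0))
            for env in profile.envelopes
            for cause, frac in env.cause_fractions.items()
        ],
        columns=["group", "cause", "fraction", "baseline_deaths"],
    )
    risk = pd.DataFrame(
        [
            (rf.id, state, rf.baseline_prevalence[state], state == rf.reference_state)
            for rf in profile.risk_factors
            for state in rf.states
        ],
        columns=["risk_factor", "state", "baseline_prevalence", "is_reference"],
    )
    return {
        "coverage": coverage,
        "mortality": mortality,
        "causes": causes,
        "risk_factors": risk,
    }


def proportional_to_absolute(base_rate: float, proportional_reduction: float) -> float:
    """Convert a proportional mortality reduction into rate units.

    E.g. a 5% reduction on an under-five mortality rate of 60 per 1,000 live
    births is 3 deaths per 1,000 live births.
    """
    if base_rate < 0:
        raise DomainError(f"base_rate={base_rate:g} must be non-negative")
    if not 0.0 <= proportional_reduction <= 1.0:
        raise DomainError(
            f"proportional_reduction={proportional_reduction:g} outside [0, 1]"
        )
    return base_rate * proportional_reduction


def compare_to_measured(
    result: ProjectionResult,
    measured_rates: Union[Mapping[int, float], pd.Series],
    profile: Profile,
    group: str,
) -> pd.DataFrame:
    """Modeled vs. measured mortality rates for one outcome group.

    The modeled rate per year is scenario deaths (summed over the group's
    causes) divided by the group's denominator, in the group's rate units.
    Only years present in both series are reported — no interpolation.
    Gaps are modeled minus measured; ``relative_gap`` is a fraction of the
    measured rate.
    """
    measured = dict(pd.Series(measured_rates).items())
    totals = result.totals
    scenario_deaths = (
        totals[totals["group"] == group].groupby("year")["deaths_scenario"].sum()
    )
    rows = []
    for year, deaths in scenario_deaths.items():
        if year not in measured:
            continue
        denom = denominator_count(profile.demography, group, int(year))
        if denom <= 0:
            continue
        modeled = deaths / denom
        obs = measured[year]
        gap = modeled - obs
        rows.append(
            (int(year), modeled, obs, gap, gap / obs if obs != 0 else float("nan"))
        )
    if not rows:
        raise AlignmentError("no overlapping years between modeled and measured series")
    return pd.DataFrame(
        rows,
        columns=["year", "modeled_rate", "measured_rate", "absolute_gap", "relative_gap"],
    )


__all__ = [
    "DEFAULT_STANDARD_TARGET",
    "attribute",
    "rank_missed_opportunities",
    "explore_summary",
    "proportional_to_absolute",
    "compare_to_measured",
]
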