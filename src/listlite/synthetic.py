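"""Seeded generator of plausible profiles and scenarios.

Stands in for a real country database so the whole pipeline is testable
without any download.  Generation is a pure function of the configuration
(one integer seed feeds a single ``numpy`` Generator), and every generated
artifact passes full schema validation.

Distributions (fixed so tests can regenerate fixtures exactly):

* cause-of-death fractions — symmetric Dirichlet (a random point on the
  simplex);
* intervention efficacies — uniform on [0.1, 0.9];
* affected fractions — uniform on [0.3, 1.0];
* baseline coverages — uniform on [0.05, 0.8];
* harmful-state relative risks — log-uniform on [1, 4], reference RR = 1.

The ``demo_profile`` preset is a fixed hand-written profile anchored on an
under-five-scale child mortality rate of 60 deaths per 1,000 live births; all
of its other values (neonatal rate, cause fractions, breastfeeding states and
relative risks, intervention set) are invented illustrations, not estimates
for any real country.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .profile_model import (
    GROUPS,
    Demography,
    Effect,
    Intervention,
    MortalityEnvelope,
    Profile,
    RiskFactor,
    Scenario,
)

#: Plausible cause names per outcome group, consumed in order.
CAUSE_POOL = {
    "maternal": [
        "hemorrhage",
        "sepsis",
        "hypertensive_disorders",
        "obstructed_labor",
        "other_maternal",
    ],
    "stillbirth": ["antepartum", "intrapartum"],
    "neonatal": [
        "prematurity",
        "birth_asphyxia",
        "neonatal_sepsis",
        "congenital",
        "other_neonatal",
    ],
    "child_1_59m": ["diarrhea", "pneumonia", "malaria", "measles", "other_child"],
}

#: Baseline-rate ranges per group, in each group's own units.
RATE_RANGE = {
    "maternal": (100.0, 800.0),  # per 100,000 live births
    "stillbirth": (8.0, 30.0),  # per 1,000 pregnancies
    "neonatal": (15.0, 45.0),  # per 1,000 live births
    "child_1_59m": (30.0, 100.0),  # per 1,000 live births
}

_RISK_FACTOR_POOL = [
    ("stunting", ["severe", "moderate", "not_stunted"]),
    ("breastfeeding", ["none", "partial", "exclusive"]),
    ("maternal_anemia", ["anemic", "not_anemic"]),
]


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic-profile generator."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_causes: int = Field(default=3, ge=1)
    n_interventions: int = Field(default=4, ge=0)
    n_risk_factors: int = Field(default=1, ge=0)
    horizon: int = Field(default=5, ge=1)
    births_per_year: float = Field(default=100_000.0, ge=0)


def _causes_for(group: str, n: int) -> list[str]:
    pool = CAUSE_POOL[group]
    causes = pool[: min(n, len(pool))]
    for k in range(len(causes), n):
        causes = causes + [f"{group}_cause_{k}"]
    return causes


def generate_profile(config: GeneratorConfig) -> Profile:
    """Draw a random, always-valid profile. Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    horizon = config.horizon
    growth = rng.uniform(1.00, 1.03)
    births = [config.births_per_year * growth**t for t in range(horizon + 1)]
    demography = Demography(base_year=2020, horizon=horizon, live_births=births)

    envelopes = []
    for group in GROUPS:
        causes = _causes_for(group, config.n_causes)
        fractions = rng.dirichlet(np.ones(len(causes)))
        # renormalise exactly so the sum-to-one invariant holds bit-for-bit
        fractions = fractions / fractions.sum()
        lo, hi = RATE_RANGE[group]
        envelopes.append(
            MortalityEnvelope(
                group=group,
                base_rate=float(rng.uniform(lo, hi)),
                cause_fractions={c: float(f) for c, f in zip(causes, fractions)},
            )
        )
    cause_index = [
        (env.group, cause) for env in envelopes for cause in env.cause_fractions
    ]

    risk_factors = []
    for k in range(config.n_risk_factors):
        if k < len(_RISK_FACTOR_POOL):
            rf_id, states = _RISK_FACTOR_POOL[k]
        else:
            rf_id, states = f"rf_{k}", [f"exposed_{k}", f"reference_{k}"]
        prev = rng.dirichlet(np.ones(len(states)))
        prev = prev / prev.sum()
        n_links = int(rng.integers(1, 3))
        links = [cause_index[i] for i in rng.choice(len(cause_index), n_links, replace=False)]
        rrs: dict[str, dict[str, dict[str, float]]] = {}
        for state in states[:-1]:  # last state is the reference, RR = 1
            per_group: dict[str, dict[str, float]] = {}
            for group, cause in links:
                rr = float(math.exp(rng.uniform(0.0, math.log(4.0))))
                per_group.setdefault(group, {})[cause] = rr
            rrs[state] = per_group
        risk_factors.append(
            RiskFactor(
                id=rf_id,
                states=states,
                baseline_prevalence={s: float(p) for s, p in zip(states, prev)},
                relative_risks=rrs,
            )
        )

    interventions = []
    for i in range(config.n_interventions):
        efficacy = float(rng.uniform(0.1, 0.9))
        af = float(rng.uniform(0.3, 1.0))
        cov = float(rng.uniform(0.05, 0.8))
        if risk_factors and rng.random() < 0.3:
            rf = risk_factors[int(rng.integers(len(risk_factors)))]
            effect = Effect(
                target_kind="risk_factor",
                target=rf.id,
                efficacy=efficacy,
                affected_fraction=af,
            )
        else:
            group, cause = cause_index[int(rng.integers(len(cause_index)))]
            effect = Effect(
                target_kind="cause",
                group=group,
                target=cause,
                efficacy=efficacy,
                affected_fraction=af,
            )
        utilization = readiness = None
        if rng.random() < 0.2:
            utilization = [float(rng.uniform(0.6, 1.0))] * (horizon + 1)
        if rng.random() < 0.2:
            readiness = [float(rng.uniform(0.5, 0.95))] * (horizon + 1)
        interventions.append(
            Intervention(
                id=f"int_{i:02d}",
                name=f"synthetic intervention {i}",
                baseline_coverage=cov,
                utilization=utilization,
                readiness=readiness,
                effects=[effect],
            )
        )

    return Profile(
        region=f"synthetic-{config.seed}",
        demography=demography,
        envelopes=envelopes,
        risk_factors=risk_factors,
        interventions=interventions,
    )


def demo_profile() -> Profile:
    """Fixed demonstration profile (invented values around a 60/1,000 child rate)."""
    horizon = 10
    births = [100_000.0] * (horizon + 1)
    return Profile(
        region="demo-country",
        demography=Demography(base_year=2020, horizon=horizon, live_births=births),
        envelopes=[
            MortalityEnvelope(
                group="neonatal",
                base_rate=25.0,
                cause_fractions={
                    "prematurity": 0.35,
                    "birth_asphyxia": 0.30,
                    "neonatal_sepsis": 0.20,
                    "other_neonatal": 0.15,
                },
            ),
            MortalityEnvelope(
                group="child_1_59m",
                base_rate=60.0,  # under-five-scale anchor
                cause_fractions={
                    "diarrhea": 0.25,
                    "pneumonia": 0.25,
                    "malaria": 0.15,
                    "other_child": 0.35,
                },
            ),
        ],
        risk_factors=[
            RiskFactor(
                id="breastfeeding",
                states=["none", "partial", "exclusive"],
                baseline_prevalence={"none": 0.2, "partial": 0.5, "exclusive": 0.3},
                relative_risks={
                    "none": {
                        "child_1_59m": {"diarrhea": 2.5, "pneumonia": 1.9},
                        "neonatal": {"neonatal_sepsis": 1.8},
                    },
                    "partial": {
                        "child_1_59m": {"diarrhea": 1.7, "pneumonia": 1.4},
                        "neonatal": {"neonatal_sepsis": 1.3},
                    },
                },
            )
        ],
        interventions=[
            Intervention(
                id="ebf_promotion",
                name="Exclusive breastfeeding promotion",
                baseline_coverage=0.30,
                effects=[
                    Effect(
                        target_kind="risk_factor",
                        target="breastfeeding",
                        efficacy=0.5,
                        affected_fraction=1.0,
                    )
                ],
            ),
            Intervention(
                id="ors",
                name="Oral rehydration solution",
                baseline_coverage=0.40,
                effects=[
                    Effect(
                        target_kind="cause",
                        group="child_1_59m",
                        target="diarrhea",
                        efficacy=0.69,
                        affected_fraction=0.93,
                    )
                ],
            ),
            Intervention(
                id="pneumonia_tx",
                name="Antibiotics for childhood pneumonia",
                baseline_coverage=0.35,
                effects=[
                    Effect(
                        target_kind="cause",
                        group="child_1_59m",
                        target="pneumonia",
                        efficacy=0.70,
                        affected_fraction=0.90,
                    )
                ],
            ),
            Intervention(
                id="itn",
                name="Insecticide-treated bednets",
                baseline_coverage=0.50,
                effects=[
                    Effect(
                        target_kind="cause",
                        group="child_1_59m",
                        target="malaria",
                        efficacy=0.55,
                        affected_fraction=1.0,
                    )
                ],
            ),
            Intervention(
                id="neonatal_resus",
                name="Neonatal resuscitation",
                baseline_coverage=0.25,
                readiness=[0.7] * (horizon + 1),
                effects=[
                    Effect(
                        target_kind="cause",
                        group="neonatal",
                        target="birth_asphyxia",
                        efficacy=0.30,
                        affected_fraction=0.80,
                    )
                ],
            ),
        ],
    )


def null_scenario(profile: Profile, name: str = "null") -> Scenario:
    """Scenario holding every intervention at its baseline coverage."""
    horizon = profile.demography.horizon
    return Scenario(
        name=name,
        targets={iv.id: iv.baseline_coverage for iv in profile.interventions},
        scale_up_start=1,
        scale_up_end=horizon,
    )


def uniform_scenario(
    profile: Profile, target: float = 0.9, name: str = "scale-up"
) -> Scenario:
    """Scenario scaling every intervention to one common target coverage."""
    horizon = profile.demography.horizon
    return Scenario(
        name=name,
        targets={iv.id: target for iv in profile.interventions},
        scale_up_start=1,
        scale_up_end=horizon,
    )


__all__ = [
    "CAUSE_POOL",
    "RATE_RANGE",
    "GeneratorConfig",
    "generate_profile",
    "demo_profile",
    "null_scenario",
    "uniform_scenario",
]
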