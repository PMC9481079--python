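import numpy as np
import pytest

from listlite import (
    Demography,
    Effect,
    Intervention,
    MortalityEnvelope,
    Profile,
    Scenario,
    demo_profile,
    null_scenario,
)


@pytest.fixture
def demo():
    return demo_profile()


@pytest.fixture
def demo_null(demo):
    return null_scenario(demo)


def single_cause_profile(
    rate: float = 60.0,
    births: float = 100_000.0,
    horizon: int = 5,
    efficacy: float = 0.5,
    affected_fraction: float = 1.0,
    baseline_coverage: float = 0.0,
) -> Profile:
    """One child cause carrying the whole envelope, one intervention on it."""
    return Profile(
        region="unit-test",
        demography=Demography(
            base_year=2020, horizon=horizon, live_births=[births] * (horizon + 1)
        ),
        envelopes=[
            MortalityEnvelope(
                group="child_1_59m", base_rate=rate, cause_fractions={"all_causes": 1.0}
            )
        ],
        interventions=[
            Intervention(
                id="tx",
                name="treatment",
                baseline_coverage=baseline_coverage,
                effects=[
                    Effect(
                        target_kind="cause",
                        group="child_1_59m",
                        target="all_causes",
                        efficacy=efficacy,
                        affected_fraction=affected_fraction,
                    )
                ],
            )
        ],
    )


def random_scenario(profile: Profile, rng: np.random.Generator) -> Scenario:
    """Targets drawn uniformly between each baseline coverage and 1."""
    horizon = profile.demography.horizon
    start = int(rng.integers(1, horizon + 1))
    end = int(rng.integers(start, horizon + 1))
    targets = {
        iv.id: float(rng.uniform(iv.baseline_coverage, 1.0))
        for iv in profile.interventions
    }
    return Scenario(
        name="random", targets=targets, scale_up_start=start, scale_up_end=end
    )
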