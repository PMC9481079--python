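"""Independent brute-force projection used as an oracle in tests.

Composes the documented formulas directly with plain dict/loop arithmetic,
deliberately sharing no code with the engine's vectorised/year-loop
implementation.  Only meant for tiny profiles.
"""

from __future__ import annotations


def _ramp(c0: float, target: float, start: int, end: int, t: int) -> float:
    if t < start:
        return c0
    if t >= end:
        return target
    return c0 + (target - c0) * (t - start + 1) / (end - start + 1)


def _coverage_pair(iv, scenario, t: int) -> tuple[float, float]:
    """(effective baseline coverage, effective coverage at year t)."""
    target = scenario.targets.get(iv.id, iv.baseline_coverage)
    crude_t = _ramp(
        iv.baseline_coverage, target, scenario.scale_up_start, scenario.scale_up_end, t
    )

    def qual(year: int) -> float:
        u = iv.utilization[year] if iv.utilization is not None else 1.0
        r = iv.readiness[year] if iv.readiness is not None else 1.0
        return u * r

    return iv.baseline_coverage * qual(0), crude_t * qual(t)


def _mult(eff, c0: float, ct: float) -> float:
    x = eff.efficacy * eff.affected_fraction
    return 1.0 - x * (ct - c0) / (1.0 - x * c0)


def brute_force_deaths(profile, scenario) -> dict[tuple[int, str, str], tuple[float, float]]:
    """Map (year, group, cause) -> (baseline deaths, scenario deaths)."""
    demo = profile.demography
    out: dict[tuple[int, str, str], tuple[float, float]] = {}
    for t in range(demo.horizon + 1):
        for env in profile.envelopes:
            persons = demo.pregnancies[t] if env.group == "stillbirth" else demo.live_births[t]
            scale = 100_000.0 if env.group == "maternal" else 1_000.0
            for cause, frac in env.cause_fractions.items():
                d0 = persons / scale * env.base_rate * frac
                m = 1.0
                for iv in profile.interventions:
                    for eff in iv.effects:
                        if (
                            eff.target_kind == "cause"
                            and eff.group == env.group
                            and eff.target == cause
                        ):
                            c0, ct = _coverage_pair(iv, scenario, t)
                            m *= _mult(eff, c0, ct)
                for rf in profile.risk_factors:
                    rr = {
                        s: rf.relative_risks.get(s, {}).get(env.group, {}).get(cause, 1.0)
                        for s in rf.states
                    }
                    touches = any(
                        cause in rf.relative_risks.get(s, {}).get(env.group, {})
                        for s in rf.states
                    )
                    if not touches:
                        continue
                    keep = 1.0
                    for iv in profile.interventions:
                        for eff in iv.effects:
                            if eff.target_kind == "risk_factor" and eff.target == rf.id:
                                c0, ct = _coverage_pair(iv, scenario, t)
                                keep *= _mult(eff, c0, ct)
                    f = 1.0 - keep
                    ref = rf.states[-1]
                    pt = {}
                    moved = 0.0
                    for s in rf.states:
                        p = rf.baseline_prevalence[s]
                        if s == ref:
                            pt[s] = p
                        else:
                            pt[s] = p * (1.0 - f)
                            moved += p * f
                    pt[ref] += moved
                    num = sum(pt[s] * rr[s] for s in rf.states)
                    den = sum(rf.baseline_prevalence[s] * rr[s] for s in rf.states)
                    m *= num / den
                out[(t, env.group, cause)] = (d0, d0 * m)
    return out
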