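"""Domain types, schema validation and readers/writers.

A *profile* describes a setting in a baseline year: demography, mortality
envelopes with cause-of-death structure, categorical risk factors, and the
interventions available with their baseline coverage and effects.  A
*scenario* says which interventions are scaled up, to what target coverage,
and over which years.  A *projection result* is the tidy table of deaths and
lives saved the engine produces.

Profiles and scenarios are serialized as YAML documents carrying an explicit
``schema_version``; results are plain CSV in long format so they round-trip
through any spreadsheet or ``pandas.read_csv``.

Conventions fixed here (and documented in ``docs/methods.md``):

* year index 0 is the baseline year; projected years run 1..horizon;
* outcome groups and their denominators are fixed: maternal deaths per
  100,000 live births, stillbirths per 1,000 pregnancies, neonatal and
  child (1-59 months) deaths per 1,000 live births;
* when pregnancies are not supplied they default to live births x 1.03,
  a pure denominator convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import FormatError, ValidationError

SCHEMA_VERSION = "1.0"

#: Outcome groups, in reporting order.
GROUPS = ("maternal", "stillbirth", "neonatal", "child_1_59m")

#: Persons per rate unit: maternal mortality is expressed per 100,000 live
#: births, every other group per 1,000 of its denominator.
RATE_SCALE = {
    "maternal": 100_000.0,
    "stillbirth": 1_000.0,
    "neonatal": 1_000.0,
    "child_1_59m": 1_000.0,
}

#: Which demographic series provides the denominator for each group.
DENOMINATOR_SERIES = {
    "maternal": "live_births",
    "stillbirth": "pregnancies",
    "neonatal": "live_births",
    "child_1_59m": "live_births",
}

#: Default pregnancies / live-births ratio used when pregnancies are absent.
PREGNANCY_RATIO = 1.03

#: Tolerance for sum-to-one checks on fractions and prevalences.
SUM_TOL = 1e-9

GroupName = Literal["maternal", "stillbirth", "neonatal", "child_1_59m"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Demography(_Model):
    """Baseline year, horizon and per-year denominators.

    ``live_births`` and ``pregnancies`` have ``horizon + 1`` entries, index 0
    being the baseline year.
    """

    base_year: int
    horizon: int = Field(ge=1)
    live_births: list[float]
    pregnancies: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check_series(self) -> "Demography":
        n = self.horizon + 1
        if len(self.live_births) != n:
            raise ValueError(
                f"live_births has {len(self.live_births)} entries, expected horizon+1 = {n}"
            )
        if any(b < 0 for b in self.live_births):
            raise ValueError("live_births entries must be non-negative")
        if self.pregnancies is None:
            self.pregnancies = [b * PREGNANCY_RATIO for b in self.live_births]
        if len(self.pregnancies) != n:
            raise ValueError(
                f"pregnancies has {len(self.pregnancies)} entries, expected horizon+1 = {n}"
            )
        if any(p < 0 for p in self.pregnancies):
            raise ValueError("pregnancies entries must be non-negative")
        for t, (p, b) in enumerate(zip(self.pregnancies, self.live_births)):
            if p < b:
                raise ValueError(
                    f"pregnancies[{t}]={p:g} is below live_births[{t}]={b:g}"
                )
        return self


class MortalityEnvelope(_Model):
    """Baseline mortality rate of one outcome group and its cause structure."""

    group: GroupName
    base_rate: float = Field(ge=0)
    cause_fractions: dict[str, float]

    @model_validator(mode="after")
    def _check_fractions(self) -> "MortalityEnvelope":
        if not self.cause_fractions:
            raise ValueError("cause_fractions must name at least one cause")
        for cause, frac in self.cause_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"cause fraction {cause}={frac:g} outside [0, 1]")
        total = sum(self.cause_fractions.values())
        if abs(total - 1.0) > SUM_TOL:
            raise ValueError(f"cause fractions sum to {total:g}, expected 1")
        return self


class Effect(_Model):
    """One pathway of an intervention: direct on a cause, or via a risk factor.

    ``efficacy`` is the proportional reduction in amenable deaths (for a cause
    target) or in harmful-state prevalence (for a risk-factor target) among
    those reached; ``affected_fraction`` is the share of the target's deaths
    the intervention can act on at all, the guard against double counting.
    """

    target_kind: Literal["cause", "risk_factor"]
    target: str
    group: Optional[GroupName] = None
    efficacy: float = Field(ge=0, le=1)
    affected_fraction: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _check_group(self) -> "Effect":
        if self.target_kind == "cause" and self.group is None:
            raise ValueError(f"cause effect on '{self.target}' must name an outcome group")
        if self.target_kind == "risk_factor" and self.group is not None:
            raise ValueError(
                f"risk-factor effect on '{self.target}' must not carry a group"
            )
        return self


def _check_series_01(name: str, values: Optional[list[float]]) -> None:
    if values is None:
        return
    for t, v in enumerate(values):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}[{t}]={v:g} outside [0, 1]")


class Intervention(_Model):
    """An intervention with baseline coverage and one or more effects.

    ``utilization`` and ``readiness`` are optional per-year series in [0, 1]
    used for quality adjustment of coverage; both default to 1 when absent.
    """

    id: str = Field(min_length=1)
    name: str = ""
    baseline_coverage: float = Field(ge=0, le=1)
    utilization: Optional[list[float]] = None
    readiness: Optional[list[float]] = None
    effects: list[Effect] = Field(min_length=1)

    @model_validator(mode="after")
    def _check_quality(self) -> "Intervention":
        _check_series_01("utilization", self.utilization)
        _check_series_01("readiness", self.readiness)
        return self


class RiskFactor(_Model):
    """Categorical exposure with per-state prevalence and per-cause relative risks.

    The last state in ``states`` is the reference (non-exposed) state and must
    carry RR = 1 everywhere it appears.  ``relative_risks`` is nested as
    state -> group -> cause -> RR; missing entries default to RR = 1.
    """

    id: str = Field(min_length=1)
    states: list[str] = Field(min_length=2)
    baseline_prevalence: dict[str, float]
    relative_risks: dict[str, dict[str, dict[str, float]]] = Field(default_factory=dict)

    @property
    def reference_state(self) -> str:
        return self.states[-1]

    def rr(self, state: str, group: str, cause: str) -> float:
        return self.relative_risks.get(state, {}).get(group, {}).get(cause, 1.0)

    def cause_keys(self) -> set[tuple[str, str]]:
        """All (group, cause) pairs this risk factor modulates."""
        keys: set[tuple[str, str]] = set()
        for per_group in self.relative_risks.values():
            for group, per_cause in per_group.items():
                keys.update((group, cause) for cause in per_cause)
        return keys

    @model_validator(mode="after")
    def _check(self) -> "RiskFactor":
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"risk factor '{self.id}' has duplicate states")
        if set(self.baseline_prevalence) != set(self.states):
            raise ValueError(
                f"risk factor '{self.id}' baseline_prevalence must cover exactly its states"
            )
        for state, p in self.baseline_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {state}={p:g} outside [0, 1]")
        total = sum(self.baseline_prevalence.values())
        if abs(total - 1.0) > SUM_TOL:
            raise ValueError(f"prevalences sum to {total:g}, expected 1")
        for state, per_group in self.relative_risks.items():
            if state not in self.states:
                raise ValueError(f"relative_risks names unknown state '{state}'")
            for group, per_cause in per_group.items():
                if group not in GROUPS:
                    raise ValueError(f"relative_risks names unknown group '{group}'")
                for cause, rr in per_cause.items():
                    if rr < 0:
                        raise ValueError(f"RR for ({state}, {group}, {cause}) is negative")
        ref = self.reference_state
        for group, per_cause in self.relative_risks.get(ref, {}).items():
            for cause, rr in per_cause.items():
                if rr != 1.0:
                    raise ValueError(
                        f"reference state '{ref}' must have RR = 1 for ({group}, {cause}), got {rr:g}"
                    )
        return self


class Profile(_Model):
    """Full model input for one setting."""

    region: str
    demography: Demography
    envelopes: list[MortalityEnvelope] = Field(min_length=1)
    risk_factors: list[RiskFactor] = Field(default_factory=list)
    interventions: list[Intervention] = Field(default_factory=list)

    def envelope(self, group: str) -> MortalityEnvelope:
        for env in self.envelopes:
            if env.group == group:
                return env
        raise KeyError(group)

    def intervention(self, intervention_id: str) -> Intervention:
        for iv in self.interventions:
            if iv.id == intervention_id:
                return iv
        raise KeyError(intervention_id)

    def risk_factor(self, rf_id: str) -> RiskFactor:
        for rf in self.risk_factors:
            if rf.id == rf_id:
                return rf
        raise KeyError(rf_id)

    @property
    def groups(self) -> list[str]:
        return [env.group for env in self.envelopes]

    @model_validator(mode="after")
    def _check_references(self) -> "Profile":
        groups = [env.group for env in self.envelopes]
        if len(set(groups)) != len(groups):
            raise ValueError("duplicate outcome group among envelopes")
        iids = [iv.id for iv in self.interventions]
        if len(set(iids)) != len(iids):
            raise ValueError("intervention ids must be unique within a profile")
        rf_ids = [rf.id for rf in self.risk_factors]
        if len(set(rf_ids)) != len(rf_ids):
            raise ValueError("risk factor ids must be unique within a profile")
        causes = {env.group: set(env.cause_fractions) for env in self.envelopes}
        n = self.demography.horizon + 1
        for iv in self.interventions:
            for series_name in ("utilization", "readiness"):
                series = getattr(iv, series_name)
                if series is not None and len(series) != n:
                    raise ValueError(
                        f"intervention '{iv.id}' {series_name} has {len(series)} entries, "
                        f"expected horizon+1 = {n}"
                    )
            for eff in iv.effects:
                if eff.target_kind == "cause":
                    if eff.group not in causes:
                        raise ValueError(
                            f"intervention '{iv.id}' targets group '{eff.group}' "
                            "which has no mortality envelope"
                        )
                    if eff.target not in causes[eff.group]:
                        raise ValueError(
                            f"intervention '{iv.id}' targets unknown cause "
                            f"'{eff.target}' in group '{eff.group}'"
                        )
                else:
                    if eff.target not in rf_ids:
                        raise ValueError(
                            f"intervention '{iv.id}' targets unknown risk factor "
                            f"'{eff.target}'"
                        )
        return self


class Scenario(_Model):
    """Coverage targets and a linear scale-up schedule.

    ``scale_up_start`` and ``scale_up_end`` are year offsets from baseline
    (year 0 is never altered).  Interventions absent from ``targets`` stay at
    their baseline coverage.
    """

    name: str
    targets: dict[str, float] = Field(default_factory=dict)
    scale_up_start: int = Field(ge=1)
    scale_up_end: int = Field(ge=1)
    shape: Literal["linear"] = "linear"

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.scale_up_end < self.scale_up_start:
            raise ValueError(
                f"scale_up_end={self.scale_up_end} before scale_up_start={self.scale_up_start}"
            )
        for iid, c in self.targets.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"target coverage for '{iid}' is {c:g}, outside [0, 1]")
        return self


# ---------------------------------------------------------------------------
# Projection results


#: Column order of the tidy result table.
RESULT_COLUMNS = (
    "year",
    "group",
    "cause",
    "intervention",
    "deaths_baseline",
    "deaths_scenario",
    "lives_saved",
)

#: Intervention label used for the per-cell totals rows.
TOTAL_LABEL = "ALL"


@dataclass
class ProjectionResult:
    """Tidy long-format projection output.

    One row per (year, group, cause, intervention) holding that intervention's
    attributed lives saved, plus a totals row per cell with
    ``intervention == "ALL"`` carrying the cell's baseline and scenario deaths
    and total lives saved.  Per-intervention rows repeat the cell's deaths
    columns for self-containedness.
    """

    table: pd.DataFrame = field(default_factory=lambda: _empty_result_table())

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"result table missing columns {missing}")
        self.table = self.table.loc[:, list(RESULT_COLUMNS)].reset_index(drop=True)

    @property
    def totals(self) -> pd.DataFrame:
        """Rows with intervention == 'ALL' (one per year x group x cause)."""
        return self.table[self.table["intervention"] == TOTAL_LABEL]

    @property
    def by_intervention(self) -> pd.DataFrame:
        return self.table[self.table["intervention"] != TOTAL_LABEL]

    @property
    def years(self) -> list[int]:
        return sorted(self.table["year"].unique()) if len(self.table) else []

    def lives_saved_total(self, year: Optional[int] = None) -> float:
        """Total lives saved, summed over groups and causes (one year or all)."""
        t = self.totals
        if year is not None:
            t = t[t["year"] == year]
        return float(t["lives_saved"].sum())

    def cumulative_lives_saved(self) -> float:
        """Cumulative lives saved over the whole projection."""
        return self.lives_saved_total()

    def horizon_lives_saved(self) -> float:
        """Lives saved in the final projected year."""
        if not self.years:
            return 0.0
        return self.lives_saved_total(year=self.years[-1])

    def check_invariants(self, atol: float = 1e-6) -> None:
        """Raise ValidationError if deaths are negative or attribution leaks."""
        if (self.totals[["deaths_baseline", "deaths_scenario"]] < 0).any().any():
            raise ValidationError("negative deaths in result table")
        parts = (
            self.by_intervention.groupby(["year", "group", "cause"])["lives_saved"]
            .sum()
            .rename("attributed")
        )
        tot = self.totals.set_index(["year", "group", "cause"])["lives_saved"]
        if len(parts):
            joined = pd.concat([parts, tot], axis=1).fillna(0.0)
            gap = (joined["attributed"] - joined["lives_saved"]).abs().max()
            if gap > atol:
                raise ValidationError(
                    f"attributed lives saved differ from totals by up to {gap:g}"
                )

    def allclose(self, other: "ProjectionResult", tol: float = 1e-12) -> bool:
        a = self.table.sort_values(list(RESULT_COLUMNS[:4])).reset_index(drop=True)
        b = other.table.sort_values(list(RESULT_COLUMNS[:4])).reset_index(drop=True)
        if len(a) != len(b):
            return False
        if not a[["year", "group", "cause", "intervention"]].equals(
            b[["year", "group", "cause", "intervention"]]
        ):
            return False
        num = ["deaths_baseline", "deaths_scenario", "lives_saved"]
        return bool(
            ((a[num] - b[num]).abs() <= tol + tol * b[num].abs()).all().all()
        )


def _empty_result_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": pd.Series(dtype=int),
            "group": pd.Series(dtype=str),
            "cause": pd.Series(dtype=str),
            "intervention": pd.Series(dtype=str),
            "deaths_baseline": pd.Series(dtype=float),
            "deaths_scenario": pd.Series(dtype=float),
            "lives_saved": pd.Series(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# Readers / writers


def _load_yaml_document(path) -> dict:
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise FormatError(f"{path}: parse failure{where}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: document is not a mapping")
    version = data.pop("schema_version", SCHEMA_VERSION)
    if str(version) != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: schema_version {version!r} not supported (expected {SCHEMA_VERSION})"
        )
    return data


def _format_pydantic_error(exc: pydantic.ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(part) for part in err["loc"]) or "<document>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def load_profile(path) -> Profile:
    """Read and validate a profile document.

    Raises :class:`FormatError` on parse failure and :class:`ValidationError`
    (naming the failing field and rule) on an invariant violation.
    """
    data = _load_yaml_document(path)
    try:
        return Profile.model_validate(data)
    except pydantic.ValidationError as exc:
        raise ValidationError(f"{path}: {_format_pydantic_error(exc)}") from exc


def save_profile(profile: Profile, path) -> None:
    data = {"schema_version": SCHEMA_VERSION, **profile.model_dump(exclude_none=True)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_scenario(path) -> Scenario:
    """Read and validate a scenario document (cross-references to a profile
    are checked at projection time)."""
    data = _load_yaml_document(path)
    try:
        return Scenario.model_validate(data)
    except pydantic.ValidationError as exc:
        raise ValidationError(f"{path}: {_format_pydantic_error(exc)}") from exc


def save_scenario(scenario: Scenario, path) -> None:
    data = {"schema_version": SCHEMA_VERSION, **scenario.model_dump()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def save_result(result: ProjectionResult, path) -> None:
    """Write the tidy result table as CSV (lossless round-trip)."""
    result.table.to_csv(path, index=False)


def load_result(path) -> ProjectionResult:
    df = pd.read_csv(
        path,
        dtype={
            "year": int,
            "group": str,
            "cause": str,
            "intervention": str,
            "deaths_baseline": float,
            "deaths_scenario": float,
            "lives_saved": float,
        },
    )
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: result table missing columns {missing}")
    return ProjectionResult(df)


def denominator_count(demography: Demography, group: str, year: int) -> float:
    """Rate denominator for one group-year, in rate units.

    E.g. for neonatal mortality (per 1,000 live births) this is
    ``live_births[year] / 1000``; multiplying by the rate gives deaths.
    """
    if group not in RATE_SCALE:
        raise KeyError(group)
    series = (
        demography.pregnancies
        if DENOMINATOR_SERIES[group] == "pregnancies"
        else demography.live_births
    )
    return series[year] / RATE_SCALE[group]


def baseline_deaths(profile: Profile, group: str, cause: str, year: int) -> float:
    """Deaths for one cell under constant baseline rates."""
    env = profile.envelope(group)
    frac = env.cause_fractions[cause]
    return denominator_count(profile.demography, group, year) * env.base_rate * frac


__all__ = [
    "SCHEMA_VERSION",
    "GROUPS",
    "RATE_SCALE",
    "DENOMINATOR_SERIES",
    "PREGNANCY_RATIO",
    "RESULT_COLUMNS",
    "TOTAL_LABEL",
    "Demography",
    "MortalityEnvelope",
    "Effect",
    "Intervention",
    "RiskFactor",
    "Profile",
    "Scenario",
    "ProjectionResult",
    "load_profile",
    "save_profile",
    "load_scenario",
    "save_scenario",
    "load_result",
    "save_result",
    "denominator_count",
    "baseline_deaths",
]
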