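"""Model parameter containers, config (de)serialization, and validation.

A model run is driven by a :class:`ParameterSet`: a named collection of
:class:`Parameter` values (probabilities, unit costs, utilities, counts)
together with the cohort's life expectancy, the annual discount rate and
the willingness-to-pay threshold.  Parameter sets are read from and written
to a single YAML document, one block per parameter, so that a scenario is
human-editable and diffable.

Validation is report-based: :func:`validate_parameters` returns a list of
violation strings (empty means valid) rather than raising, so callers can
surface every problem at once.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

log = logging.getLogger(__name__)

ROLES = ("probability", "cost", "utility", "count", "rate")
COHORTS = ("mid-20s", "mid-30s", "mid-40s", "mid-50s")
DISTRIBUTION_FAMILIES = ("point", "uniform", "beta", "gamma", "truncated-normal")

#: Parameter names the treatment models require.  Loading a config that
#: omits any of these raises; validate_parameters also reports them.
REQUIRED_PARAMETERS = (
    # clinical probabilities, rTMS arm
    "p_remission_rtms",
    "p_response_rtms",
    "attenuation_rtms",
    "relapse_annual_rtms",
    # clinical probabilities, pharmacotherapy arm
    "p_remission_pharma",
    "p_response_pharma",
    "attenuation_pharma",
    "relapse_annual_pharma",
    # shared fallback
    "p_remission_ect",
    # unit costs and resource counts
    "cost_per_rtms_session",
    "cost_rtms_initial_session",
    "cost_rtms_mt_redetermination",
    "rtms_sessions_per_year",
    "rtms_mt_redeterminations_per_year",
    "drug_cost_monthly",
    "psychotherapy_session_rate",
    "psychotherapy_sessions_per_year",
    "ect_course_cost_annual",
    "other_direct_annual",
    # Euro-QoL state utilities
    "utility_in_treatment",
    "utility_nonresponse",
    "utility_response",
    "utility_remission",
    "utility_relapse",
    "utility_ect",
)


class ConfigError(ValueError):
    """Raised when a config file cannot be parsed or violates the schema."""


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric sampling distribution for probabilistic sensitivity analysis.

    ``family`` is one of ``point`` (degenerate, one parameter: the value),
    ``uniform`` (low, high), ``beta`` (alpha, beta), ``gamma`` (shape, scale)
    or ``truncated-normal`` (mu, sigma, lower, upper).
    """

    family: str
    parameters: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in DISTRIBUTION_FAMILIES:
            raise ConfigError(f"unknown distribution family {self.family!r}")
        object.__setattr__(self, "parameters", tuple(float(p) for p in self.parameters))

    def to_dict(self) -> dict:
        return {"family": self.family, "parameters": list(self.parameters)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        return cls(family=d["family"], parameters=tuple(d["parameters"]))


@dataclass(frozen=True)
class Parameter:
    """One named model input with its point estimate and one-way range.

    ``role`` fixes the units and admissible bounds: probabilities and
    utilities live on [0, 1]; costs (USD) and counts are non-negative;
    rates are unrestricted annual rates.
    """

    name: str
    role: str
    base: float
    low: float
    high: float
    units: str = ""
    source_note: str = ""
    distribution: Optional[DistributionSpec] = None

    def violations(self) -> list[str]:
        v: list[str] = []
        if self.role not in ROLES:
            v.append(f"{self.name}: unknown role {self.role!r}")
            return v
        if not (self.low <= self.base <= self.high):
            v.append(
                f"{self.name}: range must satisfy low <= base <= high "
                f"(got {self.low} / {self.base} / {self.high})"
            )
        if self.role in ("probability", "utility"):
            if self.low < 0 or self.high > 1:
                v.append(f"{self.name}: {self.role} range must lie in [0, 1]")
        if self.role in ("cost", "count") and self.low < 0:
            v.append(f"{self.name}: {self.role} low must be >= 0")
        if self.distribution is not None:
            fam = self.distribution.family
            if fam == "beta" and self.role not in ("probability", "utility"):
                v.append(f"{self.name}: beta distribution restricted to probability/utility roles")
            if fam == "gamma" and self.role not in ("cost", "count"):
                v.append(f"{self.name}: gamma distribution restricted to cost/count roles")
            if fam == "truncated-normal" and len(self.distribution.parameters) != 4:
                v.append(f"{self.name}: truncated-normal requires explicit (mu, sigma, lower, upper)")
        return v

    def role_bounds(self) -> tuple[float, float]:
        """Admissible interval for values of this parameter, from its role."""
        if self.role in ("probability", "utility"):
            return (0.0, 1.0)
        if self.role in ("cost", "count"):
            return (0.0, math.inf)
        return (-math.inf, math.inf)

    def to_dict(self) -> dict:
        d = {
            "role": self.role,
            "base": float(self.base),
            "low": float(self.low),
            "high": float(self.high),
            "units": self.units,
            "source_note": self.source_note,
        }
        if self.distribution is not None:
            d["distribution"] = self.distribution.to_dict()
        return d


@dataclass(frozen=True)
class LifeExpectancy:
    """Expected additional years of life for a cohort, with its range."""

    likely: int
    low: int
    high: int

    def violations(self) -> list[str]:
        v = []
        if not (self.low <= self.likely <= self.high):
            v.append(f"life_expectancy: low <= likely <= high violated ({self.low}/{self.likely}/{self.high})")
        if min(self.low, self.likely, self.high) <= 0:
            v.append("life_expectancy: all values must be positive")
        return v


@dataclass(frozen=True)
class ModelOptions:
    """Structural switches that are part of a scenario, not of the engine.

    include_background_mortality
        When True, an annual death hazard of 1/likely-life-expectancy acts on
        every alive state (competing risk applied first each cycle).  When
        False the model runs in pure fixed-horizon mode.
    half_cycle_correction
        When True, rewards accrue on the average of start- and end-of-cycle
        occupancy instead of start-of-cycle occupancy.
    relapse_reentry_attempt
        Treatment attempt index to which a relapsing patient returns
        (1 = the attempt counter fully resets).
    """

    include_background_mortality: bool = True
    half_cycle_correction: bool = False
    relapse_reentry_attempt: int = 1


@dataclass(frozen=True)
class ParameterSet:
    """A complete, named scenario for one age cohort."""

    cohort_label: str
    life_expectancy: LifeExpectancy
    parameters: Mapping[str, Parameter]
    discount_rate: float = 0.03
    wtp: float = 0.0
    options: ModelOptions = field(default_factory=ModelOptions)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameters", dict(self.parameters))

    def __getitem__(self, name: str) -> Parameter:
        return self.parameters[name]

    def __contains__(self, name: str) -> bool:
        return name in self.parameters

    def value(self, name: str) -> float:
        """Point (base) value of a named parameter."""
        return self.parameters[name].base

    def names(self) -> list[str]:
        return list(self.parameters)

    def with_parameter(self, param: Parameter) -> "ParameterSet":
        new = dict(self.parameters)
        new[param.name] = param
        return dataclasses.replace(self, parameters=new)


# ---------------------------------------------------------------------------
# validation


def validate_parameters(ps: ParameterSet) -> list[str]:
    """Check every invariant; return a report of violations (empty = valid)."""
    report: list[str] = []
    if ps.cohort_label not in COHORTS:
        report.append(f"cohort_label {ps.cohort_label!r} not one of {COHORTS}")
    report.extend(ps.life_expectancy.violations())
    if ps.discount_rate < 0:
        report.append("discount_rate must be >= 0")
    if ps.wtp < 0:
        report.append("wtp must be >= 0")
    for name, p in ps.parameters.items():
        if name != p.name:
            report.append(f"parameter keyed {name!r} carries name {p.name!r}")
        report.extend(p.violations())
    for req in REQUIRED_PARAMETERS:
        if req not in ps.parameters:
            report.append(f"required parameter missing: {req}")
    # cross-parameter consistency used by the treatment models
    if all(n in ps.parameters for n in ("utility_remission", "utility_response", "utility_nonresponse")):
        ur, ue, un = (ps.value(n) for n in ("utility_remission", "utility_response", "utility_nonresponse"))
        if not (ur >= ue >= un):
            report.append("utilities must satisfy remission >= response >= nonresponse")
    for arm in ("rtms", "pharma"):
        pr, pe = f"p_remission_{arm}", f"p_response_{arm}"
        if pr in ps.parameters and pe in ps.parameters:
            if ps.value(pr) + ps.value(pe) > 1.0 + 1e-12:
                report.append(f"p_remission_{arm} + p_response_{arm} must not exceed 1")
    return report


# ---------------------------------------------------------------------------
# realize


def realize(ps: ParameterSet, draw: Optional[Mapping[str, float]] = None) -> ParameterSet:
    """Return a point ParameterSet with drawn values substituted for bases.

    ``draw`` maps parameter names to values; names absent from the draw keep
    their base value.  Values must respect each parameter's role bounds.
    """
    if not draw:
        return ps
    new = dict(ps.parameters)
    for name, value in draw.items():
        if name not in new:
            raise KeyError(f"unknown parameter in draw: {name!r}")
        p = new[name]
        lo, hi = p.role_bounds()
        if not (lo <= value <= hi):
            raise ValueError(
                f"draw for {name!r} ({value}) violates {p.role} bounds [{lo}, {hi}]"
            )
        new[name] = dataclasses.replace(p, base=float(value), low=min(p.low, float(value)), high=max(p.high, float(value)))
    return dataclasses.replace(ps, parameters=new)


# ---------------------------------------------------------------------------
# YAML I/O


def _parameter_from_dict(name: str, d: Mapping) -> Parameter:
    try:
        dist = d.get("distribution")
        return Parameter(
            name=name,
            role=d["role"],
            base=float(d["base"]),
            low=float(d.get("low", d["base"])),
            high=float(d.get("high", d["base"])),
            units=str(d.get("units", "")),
            source_note=str(d.get("source_note", "")),
            distribution=DistributionSpec.from_dict(dist) if dist else None,
        )
    except KeyError as e:
        raise ConfigError(f"parameter {name!r}: missing required field {e.args[0]!r}") from e


_KNOWN_TOP_KEYS = {
    "cohort", "life_expectancy", "discount_rate", "wtp", "parameters",
    "include_background_mortality", "half_cycle_correction", "relapse_reentry_attempt",
}


def parameter_set_from_dict(doc: Mapping, cohort: Optional[str] = None) -> ParameterSet:
    """Build and validate a ParameterSet from a parsed config document."""
    if not isinstance(doc, Mapping):
        raise ConfigError("config root must be a mapping")
    for key in doc:
        if key not in _KNOWN_TOP_KEYS:
            log.warning("ignoring unknown config key %r", key)
    for req in ("cohort", "life_expectancy", "parameters"):
        if req not in doc:
            raise ConfigError(f"missing required config key {req!r}")
    label = doc["cohort"]
    if cohort is not None and cohort != label:
        raise ConfigError(f"config is for cohort {label!r}, not requested {cohort!r}")
    le = doc["life_expectancy"]
    try:
        life = LifeExpectancy(likely=int(le["likely"]), low=int(le["low"]), high=int(le["high"]))
    except (KeyError, TypeError) as e:
        raise ConfigError("life_expectancy must provide integer likely/low/high") from e
    params = {
        name: _parameter_from_dict(name, block)
        for name, block in dict(doc["parameters"]).items()
    }
    for req in REQUIRED_PARAMETERS:
        if req not in params:
            raise ConfigError(f"missing required parameter {req!r}")
    options = ModelOptions(
        include_background_mortality=bool(doc.get("include_background_mortality", True)),
        half_cycle_correction=bool(doc.get("half_cycle_correction", False)),
        relapse_reentry_attempt=int(doc.get("relapse_reentry_attempt", 1)),
    )
    ps = ParameterSet(
        cohort_label=label,
        life_expectancy=life,
        parameters=params,
        discount_rate=float(doc.get("discount_rate", 0.03)),
        wtp=float(doc.get("wtp", 0.0)),
        options=options,
    )
    report = validate_parameters(ps)
    if report:
        raise ConfigError("invalid parameter set:\n  " + "\n  ".join(report))
    return ps


def parameter_set_to_dict(ps: ParameterSet) -> dict:
    return {
        "cohort": ps.cohort_label,
        "life_expectancy": {
            "likely": ps.life_expectancy.likely,
            "low": ps.life_expectancy.low,
            "high": ps.life_expectancy.high,
        },
        "discount_rate": float(ps.discount_rate),
        "wtp": float(ps.wtp),
        "include_background_mortality": ps.options.include_background_mortality,
        "half_cycle_correction": ps.options.half_cycle_correction,
        "relapse_reentry_attempt": ps.options.relapse_reentry_attempt,
        "parameters": {name: p.to_dict() for name, p in sorted(ps.parameters.items())},
    }


def load_parameters(path: str | Path, cohort: Optional[str] = None) -> ParameterSet:
    """Load and validate a scenario config (YAML or JSON-as-YAML)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    return parameter_set_from_dict(doc, cohort=cohort)


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Serialize a ParameterSet to YAML; load_parameters inverts this."""
    Path(path).write_text(
        yaml.safe_dump(parameter_set_to_dict(ps), sort_keys=False, default_flow_style=False)
    )


def load_bundled_config(cohort: str) -> ParameterSet:
    """Load one of the four bundled cohort scenarios (mid-20s … mid-50s).

    The bundled values pin everything the source analysis prints (Medicare
    per-session rate, monthly drug cost, sessions per year, discount rate,
    cohort life expectancies); clinical probabilities and utilities are
    documented reconstructions, not published values.
    """
    if cohort not in COHORTS:
        raise ConfigError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
    from importlib.resources import files

    resource = files("mddcea") / "configs" / f"{cohort.replace('mid-', 'mid')}.yaml"
    doc = yaml.safe_load(resource.read_text())
    return parameter_set_from_dict(doc, cohort=cohort)
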