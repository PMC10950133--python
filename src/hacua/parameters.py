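"""Model inputs for the hearing-aid cost-utility model.

Everything the cohort engine consumes is collected in a single
:class:`ModelParameters` object: the economic settings (willingness to pay,
discount rate, horizon), the treatment-uptake pathway probabilities, the
utility weights attached to hearing states, unit costs, the injurious-falls
risk model, and productivity-loss inputs.  Defaults reproduce the published
Italian base case (2021 euros); every value can be overridden through a flat
key-value configuration file (YAML syntax, one key per input).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "SEVERITIES",
    "GENDERS",
    "COST_MIX_MODES",
    "EconomicSettings",
    "PathwayProbabilities",
    "UtilitySet",
    "CostParameters",
    "FallsParameters",
    "ProductivityParameters",
    "ModelParameters",
    "ParameterError",
    "default_parameters",
    "utility_set",
    "validate_parameters",
    "load_parameters",
    "serialize_parameters",
    "save_parameters",
]

#: Hearing-loss severity grades used to stratify the uptake pathway and the
#: utility weights (normal hearing is handled separately).
SEVERITIES = ("mild", "moderate", "severe")

GENDERS = ("male", "female")

#: Device / visit supply assumptions: equal public-private mix (base case),
#: private market only, public tariffs only, public provision priced at the
#: private market level, or a market-share weighted device mix.
COST_MIX_MODES = (
    "base_mix",
    "private_only",
    "public_only",
    "public_at_private_price",
    "market_mix",
)


class ParameterError(ValueError):
    """Raised when a configuration file or parameter set is invalid."""


@dataclass
class EconomicSettings:
    """Decision-analytic framing: threshold, discounting and time horizon."""

    wtp_per_qaly: float = 16265.0  # euro per QALY gained
    annual_discount_rate: float = 0.03
    start_age: int = 55
    horizon_end_age: int = 110
    cycle_length: int = 1  # years; the engine assumes annual cycles


@dataclass
class PathwayProbabilities:
    """Four-stage treatment-uptake journey, stratified by severity.

    ``completion`` is the probability of seeking help and completing the
    journey up to the ENT specialist visit; ``prescription`` and ``purchase``
    condition on the previous stage; ``compliance`` is the probability of
    actually using a purchased device.  ``pps_compliance_decrement`` is the
    expected change in compliance when the device comes without post-purchase
    service; it is negative and by default applied multiplicatively
    (``compliance * (1 + decrement)``), switchable to an absolute shift.
    """

    completion: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.27, "moderate": 0.27, "severe": 0.54}
    )
    prescription: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.7037, "moderate": 0.7037, "severe": 0.9259}
    )
    purchase: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.8421, "moderate": 0.8421, "severe": 0.94}
    )
    compliance: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.94, "moderate": 0.94, "severe": 0.94}
    )
    pps_compliance_decrement: float = -0.36
    decrement_mode: str = "relative"  # "relative" | "absolute"


@dataclass
class UtilitySet:
    """Utility weights for hearing states, aided and unaided.

    Two published sets are packaged: ``base_case`` (HUI3-flavoured grades of
    loss with aided increments) and ``alternative`` (EQ-5D-flavoured).
    Normal hearing carries utility 1.0: hearing loss is the only
    quality-of-life decrement the model represents.
    """

    label: str = "base_case"
    normal_hearing: float = 1.0
    unaided: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.80, "moderate": 0.65, "severe": 0.45}
    )
    aided: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.93, "moderate": 0.93, "severe": 0.69}
    )


def utility_set(label: str) -> UtilitySet:
    """Return one of the packaged utility-weight sets by label."""
    if label == "base_case":
        return UtilitySet()
    if label == "alternative":
        return UtilitySet(
            label="alternative",
            unaided={"mild": 0.81, "moderate": 0.77, "severe": 0.62},
            aided={"mild": 0.90, "moderate": 0.86, "severe": 0.71},
        )
    raise ParameterError(f"unknown utility set {label!r}; expected base_case or alternative")


@dataclass
class CostParameters:
    """Unit costs (2021 euros) and supply-mix assumptions."""

    first_visit_public: float = 29.00
    first_visit_private: float = 125.00
    followup_public: float = 17.00
    followup_private: float = 75.00
    public_visit_share: float = 0.50
    device_private_price: float = 1990.90  # includes post-purchase service bundle
    device_public_tariff: float = 672.50
    device_replacement_interval: int = 5  # years
    transport_per_visit: float = 5.84
    femur_drg_tariff: float = 6099.00  # proxy cost of a fall leading to hospitalisation
    mercato_sociale_share: float = 0.20
    mercato_riconducibile_share: float = 0.26
    cost_mix_mode: str = "base_mix"


@dataclass
class FallsParameters:
    """Annual incidence of injurious falls leading to hospitalisation.

    Baseline incidence is banded by age; hearing impairment raises the odds
    of falling (``or_unaided``) while aided hearing lowers the hazard
    (``hr_aided``).  No incidence is modelled below age 60.
    """

    baseline_incidence: dict[str, float] = field(
        default_factory=lambda: {
            "60-64": 0.0035,
            "65-69": 0.0052,
            "70-74": 0.0092,
            "75+": 0.0369,
        }
    )
    or_unaided: float = 1.97
    hr_aided: float = 0.87


@dataclass
class ProductivityParameters:
    """Productivity losses for working-age (<= ``productivity_age_limit``) members."""

    annual_excess_occupational_cost: float = 82.87
    unemployment_unaided: dict[str, float] = field(
        default_factory=lambda: {"moderate": 0.1070, "severe": 0.1560}
    )
    unemployment_aided: dict[str, float] = field(
        default_factory=lambda: {"moderate": 0.0540, "severe": 0.0820}
    )
    daily_gdp_per_capita: float = 71.73
    productivity_age_limit: int = 64  # last eligible age


@dataclass
class ModelParameters:
    """Complete input set for one model run (one gender, one arm set)."""

    economic: EconomicSettings = field(default_factory=EconomicSettings)
    pathway: PathwayProbabilities = field(default_factory=PathwayProbabilities)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    costs: CostParameters = field(default_factory=CostParameters)
    falls: FallsParameters = field(default_factory=FallsParameters)
    productivity: ProductivityParameters = field(default_factory=ProductivityParameters)
    gender: str = "male"

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


def default_parameters(gender: str = "male") -> ModelParameters:
    """Full published base-case parameter set for the given gender."""
    if gender not in GENDERS:
        raise ParameterError(f"gender must be one of {GENDERS}, got {gender!r}")
    return ModelParameters(gender=gender)


# ---------------------------------------------------------------------------
# validation

def _check_prob(name: str, value: float, out: list[str]) -> None:
    if not (0.0 <= value <= 1.0):
        out.append(f"{name} = {value} outside [0, 1]")


def validate_parameters(p: ModelParameters) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid).

    Violations are data, not exceptions: callers that perturb parameters
    (sensitivity analyses, configuration loading) inspect the list and decide
    how to react.
    """
    v: list[str] = []
    e = p.economic
    if not e.wtp_per_qaly > 0:
        v.append(f"wtp_per_qaly = {e.wtp_per_qaly} must be > 0")
    if not (0.0 <= e.annual_discount_rate < 1.0):
        v.append(f"annual_discount_rate = {e.annual_discount_rate} outside [0, 1)")
    if not e.start_age < e.horizon_end_age:
        v.append(f"start_age {e.start_age} must be < horizon_end_age {e.horizon_end_age}")
    if e.cycle_length != 1:
        v.append(f"cycle_length = {e.cycle_length} but the engine requires annual cycles (1)")

    pw = p.pathway
    for attr, label in (
        ("completion", "p_journey_completion"),
        ("prescription", "p_prescription"),
        ("purchase", "p_purchase"),
        ("compliance", "p_compliance"),
    ):
        d = getattr(pw, attr)
        for sev in SEVERITIES:
            _check_prob(f"{label}[{sev}]", d[sev], v)
        if attr != "compliance":
            if d["severe"] < max(d["mild"], d["moderate"]) - 1e-12:
                v.append(
                    f"{label}[severe] = {d['severe']} must be >= milder severities "
                    f"(mild {d['mild']}, moderate {d['moderate']})"
                )
    if not (-1.0 <= pw.pps_compliance_decrement <= 0.0):
        v.append(
            f"pps_compliance_decrement = {pw.pps_compliance_decrement} outside [-1, 0]"
        )
    if pw.decrement_mode not in ("relative", "absolute"):
        v.append(f"decrement_mode = {pw.decrement_mode!r} must be relative or absolute")

    u = p.utilities
    _check_prob("utility.normal", u.normal_hearing, v)
    for sev in SEVERITIES:
        _check_prob(f"utility.unaided[{sev}]", u.unaided[sev], v)
        _check_prob(f"utility.aided[{sev}]", u.aided[sev], v)
        if u.aided[sev] < u.unaided[sev] - 1e-12:
            v.append(
                f"utility.aided[{sev}] = {u.aided[sev]} must be >= "
                f"utility.unaided[{sev}] = {u.unaided[sev]}"
            )
    for d, lbl in ((u.unaided, "unaided"), (u.aided, "aided")):
        if not (d["mild"] + 1e-12 >= d["moderate"] >= d["severe"] - 1e-12):
            v.append(
                f"utility.{lbl} must be non-increasing with severity, got "
                f"{d['mild']}, {d['moderate']}, {d['severe']}"
            )

    c = p.costs
    for name in (
        "first_visit_public",
        "first_visit_private",
        "followup_public",
        "followup_private",
        "device_private_price",
        "device_public_tariff",
        "transport_per_visit",
        "femur_drg_tariff",
    ):
        if getattr(c, name) < 0:
            v.append(f"{name} = {getattr(c, name)} must be >= 0")
    _check_prob("public_visit_share", c.public_visit_share, v)
    _check_prob("mercato_sociale_share", c.mercato_sociale_share, v)
    _check_prob("mercato_riconducibile_share", c.mercato_riconducibile_share, v)
    if c.mercato_sociale_share + c.mercato_riconducibile_share > 1.0 + 1e-12:
        v.append("mercato shares must sum to <= 1")
    if c.device_replacement_interval < 1:
        v.append(
            f"device_replacement_interval = {c.device_replacement_interval} must be >= 1"
        )
    if c.cost_mix_mode not in COST_MIX_MODES:
        v.append(f"cost_mix_mode = {c.cost_mix_mode!r} not one of {COST_MIX_MODES}")

    f = p.falls
    bands = ("60-64", "65-69", "70-74", "75+")
    prev = 0.0
    for band in bands:
        val = f.baseline_incidence[band]
        _check_prob(f"falls_incidence[{band}]", val, v)
        if val < prev - 1e-12:
            v.append("falls baseline incidence must be non-decreasing with age band")
        prev = val
    if f.or_unaided < 1.0:
        v.append(f"falls_or_unaided = {f.or_unaided} must be >= 1")
    if f.hr_aided > 1.0:
        v.append(f"falls_hr_aided = {f.hr_aided} must be <= 1")
    if f.hr_aided <= 0.0:
        v.append(f"falls_hr_aided = {f.hr_aided} must be > 0")

    pr = p.productivity
    if pr.annual_excess_occupational_cost < 0:
        v.append("annual_excess_occupational_cost must be >= 0")
    if pr.daily_gdp_per_capita < 0:
        v.append("daily_gdp_per_capita must be >= 0")
    for sev in ("moderate", "severe"):
        _check_prob(f"unemployment_unaided[{sev}]", pr.unemployment_unaided[sev], v)
        _check_prob(f"unemployment_aided[{sev}]", pr.unemployment_aided[sev], v)
        if not pr.unemployment_aided[sev] < pr.unemployment_unaided[sev]:
            v.append(
                f"unemployment_aided[{sev}] = {pr.unemployment_aided[sev]} must be < "
                f"unemployment_unaided[{sev}] = {pr.unemployment_unaided[sev]}"
            )
    if pr.productivity_age_limit != 64:
        v.append(
            f"productivity_age_limit = {pr.productivity_age_limit}; losses apply up to age 64"
        )

    if p.gender not in GENDERS:
        v.append(f"gender = {p.gender!r} not one of {GENDERS}")
    return v


# ---------------------------------------------------------------------------
# flat configuration schema
#
# One key per model input; dotted keys address severity- or band-specific
# entries.  The same schema is used for loading and serialising, so a
# round-trip through a file is exact.

def _schema() -> dict[str, tuple[str, ...]]:
    keys: dict[str, tuple[str, ...]] = {
        "wtp_per_qaly": ("economic", "wtp_per_qaly"),
        "annual_discount_rate": ("economic", "annual_discount_rate"),
        "start_age": ("economic", "start_age"),
        "horizon_end_age": ("economic", "horizon_end_age"),
        "cycle_length": ("economic", "cycle_length"),
        "pps_compliance_decrement": ("pathway", "pps_compliance_decrement"),
        "decrement_mode": ("pathway", "decrement_mode"),
        "utility.normal": ("utilities", "normal_hearing"),
        "first_visit_public": ("costs", "first_visit_public"),
        "first_visit_private": ("costs", "first_visit_private"),
        "followup_public": ("costs", "followup_public"),
        "followup_private": ("costs", "followup_private"),
        "public_visit_share": ("costs", "public_visit_share"),
        "device_private_price": ("costs", "device_private_price"),
        "device_public_tariff": ("costs", "device_public_tariff"),
        "device_replacement_interval": ("costs", "device_replacement_interval"),
        "transport_per_visit": ("costs", "transport_per_visit"),
        "femur_drg_tariff": ("costs", "femur_drg_tariff"),
        "mercato_sociale_share": ("costs", "mercato_sociale_share"),
        "mercato_riconducibile_share": ("costs", "mercato_riconducibile_share"),
        "cost_mix_mode": ("costs", "cost_mix_mode"),
        "falls_or_unaided": ("falls", "or_unaided"),
        "falls_hr_aided": ("falls", "hr_aided"),
        "annual_excess_occupational_cost": (
            "productivity",
            "annual_excess_occupational_cost",
        ),
        "daily_gdp_per_capita": ("productivity", "daily_gdp_per_capita"),
        "productivity_age_limit": ("productivity", "productivity_age_limit"),
        "gender": ("gender",),
    }
    for attr, label in (
        ("completion", "p_journey_completion"),
        ("prescription", "p_prescription"),
        ("purchase", "p_purchase"),
        ("compliance", "p_compliance"),
    ):
        for sev in SEVERITIES:
            keys[f"{label}.{sev}"] = ("pathway", attr, sev)
    for sev in SEVERITIES:
        keys[f"utility.unaided.{sev}"] = ("utilities", "unaided", sev)
        keys[f"utility.aided.{sev}"] = ("utilities", "aided", sev)
    for band in ("60-64", "65-69", "70-74", "75+"):
        keys[f"falls_incidence.{band}"] = ("falls", "baseline_incidence", band)
    for sev in ("moderate", "severe"):
        keys[f"unemployment_unaided.{sev}"] = ("productivity", "unemployment_unaided", sev)
        keys[f"unemployment_aided.{sev}"] = ("productivity", "unemployment_aided", sev)
    return keys


_SCHEMA = _schema()


def _resolve(p: ModelParameters, path: tuple[str, ...]):
    """Walk to (container, final key) for a schema path."""
    obj: Any = p
    for i, step in enumerate(path[:-1]):
        nxt = getattr(obj, step)
        if isinstance(nxt, dict):
            # the remaining single step is a dict key
            return nxt, path[i + 1]
        obj = nxt
    return obj, path[-1]


def get_value(p: ModelParameters, key: str) -> Any:
    container, last = _resolve(p, _SCHEMA[key])
    return container[last] if isinstance(container, dict) else getattr(container, last)


def set_value(p: ModelParameters, key: str, value: Any) -> None:
    container, last = _resolve(p, _SCHEMA[key])
    if isinstance(container, dict):
        container[last] = value
    else:
        setattr(container, last, value)


def serialize_parameters(p: ModelParameters) -> dict[str, Any]:
    """Flatten a parameter set to the configuration-file key space."""
    out = {key: get_value(p, key) for key in _SCHEMA}
    out["utility_set"] = p.utilities.label
    return out


def save_parameters(p: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(serialize_parameters(p), fh, sort_keys=True)


def load_parameters(path, gender: str | None = None) -> ModelParameters:
    """Load a flat key-value configuration file on top of the defaults.

    Every input is overridable; unknown keys are rejected by name.  An empty
    file yields the defaults.  The returned set is validated and a
    :class:`ParameterError` listing each violated invariant is raised if it
    does not pass.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ParameterError(f"configuration file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ParameterError(f"cannot parse {path}: {exc}") from None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: expected a flat key-value mapping")

    unknown = sorted(set(raw) - set(_SCHEMA) - {"utility_set"})
    if unknown:
        raise ParameterError(f"unknown configuration key(s): {', '.join(unknown)}")

    g = gender or raw.get("gender", "male")
    p = default_parameters(g)
    # the preset swap must come first so individual overrides win
    if "utility_set" in raw:
        p.utilities = utility_set(str(raw["utility_set"]))
    for key, value in raw.items():
        if key in ("utility_set", "gender"):
            continue
        expected = get_value(p, key)
        if isinstance(expected, (int, float)) and not isinstance(expected, bool):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ParameterError(f"{key}: expected a number, got {value!r}")
        set_value(p, key, value)
    violations = validate_parameters(p)
    if violations:
        raise ParameterError("invalid configuration:\n" + "\n".join(violations))
    return p
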