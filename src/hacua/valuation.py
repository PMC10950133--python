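"""Per-cycle valuation rules: utilities, costs, and discounting.

The perspective is a "restricted" societal one: direct healthcare costs
(specialist visits, the device, hospitalised injurious falls), direct
non-healthcare costs (transport to visits), and productivity losses (excess
occupational health expenditure and lost working days for visits, both
restricted to working age).  Utilities attach to hearing states, with an
aided weight applied only to mass that actually uses a device; wider
consequences of hearing loss (isolation, depression, dementia) are assumed
to be captured by those weights rather than costed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .natural_history import HealthState, SEVERITY_KEY
from .parameters import (
    CostParameters,
    FallsParameters,
    ModelParameters,
    ProductivityParameters,
)

__all__ = [
    "AidStatus",
    "CycleValuation",
    "discount_factor",
    "visit_costs",
    "device_cost",
    "falls_probability",
    "productivity_costs",
    "visit_day_productivity_loss",
    "cycle_valuation",
]


class AidStatus(IntEnum):
    """Treatment-uptake status attached to each alive hearing state.

    NAIVE mass has never attempted the patient journey at its current
    severity; DECLINED attempted it but holds no device in use;
    OWNER_NONCOMPLIANT bought a device but does not use it; USER_COMPLIANT
    uses the device and, by assumption, keeps using it for life.
    """

    NAIVE = 0
    DECLINED = 1
    OWNER_NONCOMPLIANT = 2
    USER_COMPLIANT = 3


COST_COMPONENTS = (
    "first_visits",
    "followup_visits",
    "device",
    "falls",
    "transport",
    "productivity_excess",
    "productivity_visit_days",
)


@dataclass
class CycleValuation:
    """Utility and itemised cost accrued by the cohort in one annual cycle."""

    utility: float
    cost_components: dict[str, float] = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return sum(self.cost_components.values())


def discount_factor(rate: float, t: int) -> float:
    """``(1 + rate) ** -t`` for ``t`` completed years since model start."""
    if t < 0:
        raise ValueError(f"cycle index must be >= 0, got {t}")
    return (1.0 + rate) ** (-t)


def visit_costs(c: CostParameters, kind: str) -> float:
    """Euro cost of one specialist visit under the configured supply mix."""
    if kind == "first":
        public, private = c.first_visit_public, c.first_visit_private
    elif kind == "followup":
        public, private = c.followup_public, c.followup_private
    else:
        raise ValueError(f"visit kind must be 'first' or 'followup', got {kind!r}")
    mode = c.cost_mix_mode
    if mode in ("base_mix", "market_mix"):
        return c.public_visit_share * public + (1.0 - c.public_visit_share) * private
    if mode == "private_only":
        return private
    if mode == "public_only":
        return public
    if mode == "public_at_private_price":
        # public provision, but the reimbursed tariff equals the private price
        return private
    raise ValueError(f"unknown cost_mix_mode {mode!r}")


def device_cost(c: CostParameters) -> float:
    """Euro cost of one device acquisition under the configured supply mix.

    The private price bundles the post-purchase service.  ``market_mix``
    weights the public tariff by the publicly financed market share (the
    "mercato sociale" plus the share traceable to public channels) and the
    private price by the remainder.
    """
    mode = c.cost_mix_mode
    if mode in ("base_mix", "private_only", "public_at_private_price"):
        return c.device_private_price
    if mode == "public_only":
        return c.device_public_tariff
    if mode == "market_mix":
        public_share = c.mercato_sociale_share + c.mercato_riconducibile_share
        return public_share * c.device_public_tariff + (1.0 - public_share) * c.device_private_price
    raise ValueError(f"unknown cost_mix_mode {mode!r}")


def _baseline_falls(f: FallsParameters, age: float) -> float:
    if age < 60:
        return 0.0  # no incidence is published below 60
    if age < 65:
        return f.baseline_incidence["60-64"]
    if age < 70:
        return f.baseline_incidence["65-69"]
    if age < 75:
        return f.baseline_incidence["70-74"]
    return f.baseline_incidence["75+"]


def falls_probability(
    f: FallsParameters, age: float, aided: bool, hearing_impaired: bool
) -> float:
    """Annual probability of an injurious fall leading to hospitalisation.

    Unimpaired members take the age-band baseline.  Unaided hearing-impaired
    members have their odds multiplied by ``or_unaided``; aided members have
    the hazard ratio ``hr_aided`` applied on the complement scale,
    ``1 - (1 - p) ** HR`` — each ratio acting on the scale it was measured on.
    """
    if age < 55:
        raise ValueError(f"age must be >= 55, got {age}")
    p = _baseline_falls(f, age)
    if not hearing_impaired or p == 0.0:
        return p
    if aided:
        return 1.0 - (1.0 - p) ** f.hr_aided
    odds = p / (1.0 - p)
    odds *= f.or_unaided
    return odds / (1.0 + odds)


def productivity_costs(
    pp: ProductivityParameters, age: float, severity: HealthState, aided: bool
) -> float:
    """Annual excess occupational cost for one cohort member.

    Applies to moderate and severe loss up to the working-age limit.  Aided
    members incur the unaided amount reduced by the relative gap between
    unaided and aided unemployment rates for the matching severity.
    """
    if age > pp.productivity_age_limit:
        return 0.0
    if severity not in (HealthState.MODERATE, HealthState.SEVERE):
        return 0.0
    base = pp.annual_excess_occupational_cost
    if not aided:
        return base
    key = SEVERITY_KEY[severity]
    u_un = pp.unemployment_unaided[key]
    if u_un == 0:
        raise ZeroDivisionError(
            f"unemployment_unaided[{key}] is 0; the aided reduction is undefined"
        )
    reduction = (u_un - pp.unemployment_aided[key]) / u_un
    return base * (1.0 - reduction)


def visit_day_productivity_loss(
    pp: ProductivityParameters, visits: float, age: float
) -> float:
    """Lost production for the days on which specialist visits take place."""
    if visits < 0:
        raise ValueError("visit count must be >= 0")
    if age > pp.productivity_age_limit:
        return 0.0
    return visits * pp.daily_gdp_per_capita


def cycle_valuation(
    occupancy: np.ndarray,
    events: dict[str, float],
    params: ModelParameters,
    age: int,
) -> CycleValuation:
    """Value one cycle of a cohort trace.

    ``occupancy`` is a 4x4 array of alive mass indexed by (hearing state,
    aid status); ``events`` carries the expected counts of first visits,
    follow-up visits and device acquisitions generated this cycle.  Returns
    the undiscounted utility accrual and the itemised euro cost.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape != (4, 4):
        raise ValueError(f"occupancy must be 4x4 (hearing x aid status), got {occupancy.shape}")
    u = params.utilities
    c = params.costs
    n_first = float(events.get("first_visits", 0.0))
    n_fu = float(events.get("followup_visits", 0.0))
    n_dev = float(events.get("device_acquisitions", 0.0))

    utility = occupancy[HealthState.NORMAL].sum() * u.normal_hearing
    falls_cost = 0.0
    prod_excess = 0.0
    for h in (HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE):
        key = SEVERITY_KEY[h]
        aided_mass = occupancy[h, AidStatus.USER_COMPLIANT]
        unaided_mass = occupancy[h].sum() - aided_mass
        utility += aided_mass * u.aided[key] + unaided_mass * u.unaided[key]
        falls_cost += unaided_mass * falls_probability(params.falls, age, False, True)
        falls_cost += aided_mass * falls_probability(params.falls, age, True, True)
        prod_excess += unaided_mass * productivity_costs(params.productivity, age, h, False)
        if aided_mass > 0:
            prod_excess += aided_mass * productivity_costs(params.productivity, age, h, True)
    falls_cost += occupancy[HealthState.NORMAL].sum() * falls_probability(
        params.falls, age, False, False
    )
    falls_cost *= c.femur_drg_tariff

    components = {
        "first_visits": n_first * visit_costs(c, "first"),
        "followup_visits": n_fu * visit_costs(c, "followup"),
        "device": n_dev * device_cost(c),
        "falls": falls_cost,
        "transport": (n_first + n_fu) * c.transport_per_visit,
        "productivity_excess": prod_excess,
        "productivity_visit_days": visit_day_productivity_loss(
            params.productivity, n_first + n_fu, age
        ),
    }
    return CycleValuation(utility=float(utility), cost_components=components)
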