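"""Expected-value cohort engine for the three strategies.

One arm is simulated at a time: no treatment (pure natural history),
hearing-aid provision alone, or hearing aids with post-purchase service.
The two treatment arms share every input except the compliance probability
— the post-purchase service exists in the model solely to keep purchasers
using their device.

The cohort starts 100% normal-hearing and treatment-naive at the model
start age.  Each annual cycle applies, in order:

1. hearing/death transitions (mortality state-independent, competing first);
2. the four-stage uptake journey for mass that just entered a new, more
   severe hearing state without a device in use (journey completion ->
   prescription -> purchase -> compliance);
3. utility accrual on the post-transition occupancy;
4. cost accrual: first-visit bundle for completed journeys, annual
   follow-up bundle for compliant users, device cost at purchase and at
   every replacement interval while the purchasing cohort survives
   compliant, falls, transport, and productivity items;
5. discounting of costs and QALYs at the annual rate.

Compliant use is absorbing: once mass is compliant it stays compliant (and
keeps its device through severity progression) until death.  Replacement is
tracked per purchase vintage rather than as extra Markov states — exact
here because replacement timing depends only on time since purchase and on
survival, which is identical for everyone.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .natural_history import (
    ALIVE_STATES,
    HealthState,
    LifeTable,
    SEVERITY_KEY,
    TransitionModel,
    transition_row,
)
from .parameters import ModelParameters, PathwayProbabilities
from .valuation import AidStatus, cycle_valuation, discount_factor

__all__ = [
    "ArmKind",
    "ArmResult",
    "uptake_split",
    "compliance_for_arm",
    "run_arm",
    "run_all_arms",
]


class ArmKind(str, Enum):
    NO_TREATMENT = "no_treatment"
    HA_ALONE = "ha_alone"
    HA_PLUS_PPS = "ha_plus_pps"


TREATMENT_ARMS = (ArmKind.HA_ALONE, ArmKind.HA_PLUS_PPS)


def compliance_for_arm(
    p: PathwayProbabilities, arm: ArmKind, severity: str = "mild"
) -> float:
    """Probability that a purchaser actually uses the device, by arm.

    With post-purchase service the surveyed compliance applies directly.
    Without it the expected decrement applies either multiplicatively
    (default: ``c * (1 + d)`` with ``d`` negative) or as an absolute shift.
    """
    if arm not in TREATMENT_ARMS:
        raise ValueError(f"compliance is undefined for arm {arm}")
    base = p.compliance[severity]
    if arm is ArmKind.HA_PLUS_PPS:
        return base
    d = p.pps_compliance_decrement
    value = base * (1.0 + d) if p.decrement_mode == "relative" else base + d
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"compliance without service = {value} outside [0, 1]")
    return value


def uptake_split(
    p: PathwayProbabilities, severity: HealthState | str, arm: ArmKind
) -> tuple[float, float, float, float]:
    """Split newly eligible mass across the four journey outcomes.

    Returns ``(compliant_user, owner_noncompliant, journey_no_device,
    no_journey)`` — probabilities summing to 1.  The first two outcomes buy
    a device; the third completes the journey (and incurs the first-visit
    bundle) but ends without a device; the fourth never reaches the
    specialist.
    """
    if arm not in TREATMENT_ARMS:
        raise ValueError(f"uptake split undefined for arm {arm}")
    key = severity if isinstance(severity, str) else SEVERITY_KEY[HealthState(severity)]
    comp = p.completion[key]
    presc = p.prescription[key]
    purch = p.purchase[key]
    use = compliance_for_arm(p, arm, key)
    buy = comp * presc * purch
    compliant = buy * use
    owner_noncompliant = buy * (1.0 - use)
    no_device = comp * (1.0 - presc * purch)
    no_journey = 1.0 - comp
    return compliant, owner_noncompliant, no_device, no_journey


@dataclass
class ArmResult:
    """Discounted totals and the full per-cycle trace for one arm."""

    arm: ArmKind
    gender: str
    mean_cost: float  # discounted euro per cohort member
    mean_qaly: float  # discounted QALYs per cohort member
    mean_ly: float  # undiscounted life years per cohort member
    nmb: float  # wtp * mean_qaly - mean_cost
    wtp: float
    trace: pd.DataFrame


def _trace_columns() -> list[str]:
    cols = ["cycle", "age", "alive", "dead"]
    for h in ALIVE_STATES:
        for s in AidStatus:
            cols.append(f"occ_{h.name.lower()}_{s.name.lower()}")
    cols += [
        "journeys_completed",
        "first_visits",
        "followup_visits",
        "purchases",
        "replacements",
        "device_acquisitions",
        "expected_falls",
        "utility",
        "discounted_cost",
        "discounted_qaly",
    ]
    return cols


def run_arm(
    params: ModelParameters,
    tm: TransitionModel,
    lt: LifeTable,
    arm: ArmKind,
) -> ArmResult:
    """Run one strategy arm over the full horizon and accrue outcomes."""
    arm = ArmKind(arm)
    e = params.economic
    if lt.start_age > e.start_age or lt.end_age < e.horizon_end_age:
        raise ValueError(
            f"life table covers [{lt.start_age}, {lt.end_age}] but the model needs "
            f"[{e.start_age}, {e.horizon_end_age}]"
        )
    n_cycles = e.horizon_end_age - e.start_age + 1
    treat = arm in TREATMENT_ARMS
    interval = params.costs.device_replacement_interval

    occ = np.zeros((4, 4))  # (hearing state, aid status), alive mass only
    occ[HealthState.NORMAL, AidStatus.NAIVE] = 1.0
    dead = 0.0
    # purchase vintages: cycle -> compliant mass at purchase, with the
    # cumulative survival level at that cycle for later replacement scaling
    vintages: list[tuple[int, float, float]] = []
    cum_survival = 1.0

    total_cost = 0.0
    total_qaly = 0.0
    total_ly = 0.0
    rows = []

    for t in range(n_cycles):
        age = e.start_age + t
        q = lt.annual_death_prob(age)

        # 1. hearing/death transitions; aid status travels with the mass
        new_occ = np.zeros((4, 4))
        arrivals = np.zeros((4, 4))  # mass entering a strictly more severe state
        for h in range(4):
            col = occ[h]
            if col.sum() == 0:
                continue
            row = transition_row(tm, lt, h, age)
            new_occ[h] += col * row[h]
            for j in range(h + 1, 4):
                if row[j] > 0:
                    arrivals[j] += col * row[j]
            dead += col.sum() * row[HealthState.DEAD]
        cum_survival *= 1.0 - q

        # 2. uptake journey for newly progressed mass without a device in use
        journeys = 0.0
        purchases = 0.0
        newly_compliant = 0.0
        for h in (HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE):
            arr = arrivals[h]
            # owners keep their device and status through progression
            new_occ[h, AidStatus.OWNER_NONCOMPLIANT] += arr[AidStatus.OWNER_NONCOMPLIANT]
            new_occ[h, AidStatus.USER_COMPLIANT] += arr[AidStatus.USER_COMPLIANT]
            eligible = arr[AidStatus.NAIVE] + arr[AidStatus.DECLINED]
            if eligible == 0:
                continue
            if not treat:
                new_occ[h, AidStatus.NAIVE] += eligible
                continue
            key = SEVERITY_KEY[HealthState(h)]
            compliant, owner_nc, no_device, no_journey = uptake_split(
                params.pathway, key, arm
            )
            new_occ[h, AidStatus.USER_COMPLIANT] += eligible * compliant
            new_occ[h, AidStatus.OWNER_NONCOMPLIANT] += eligible * owner_nc
            new_occ[h, AidStatus.DECLINED] += eligible * no_device
            new_occ[h, AidStatus.NAIVE] += eligible * no_journey
            journeys += eligible * params.pathway.completion[key]
            purchases += eligible * (compliant + owner_nc)
            newly_compliant += eligible * compliant
        occ = new_occ

        compliant_mass = float(occ[:, AidStatus.USER_COMPLIANT].sum())

        # 3-4. events for this cycle; only compliant buyers enter the
        # replacement stream (non-users never replace)
        replacements = 0.0
        if treat:
            if newly_compliant > 0:
                vintages.append((t, newly_compliant, cum_survival))
            for t0, mass, surv0 in vintages:
                dt = t - t0
                if dt > 0 and dt % interval == 0:
                    replacements += mass * (cum_survival / surv0)
        acquisitions = purchases + replacements

        events = {
            "first_visits": journeys,
            "followup_visits": compliant_mass if treat else 0.0,
            "device_acquisitions": acquisitions,
        }
        val = cycle_valuation(occ, events, params, age)
        disc = discount_factor(e.annual_discount_rate, t)
        alive = float(occ.sum())
        total_cost += val.total_cost * disc
        total_qaly += val.utility * disc
        total_ly += alive

        tariff = params.costs.femur_drg_tariff
        expected_falls = val.cost_components["falls"] / tariff if tariff > 0 else 0.0
        row_out = [t, age, alive, dead]
        row_out += [occ[h, s] for h in range(4) for s in range(4)]
        row_out += [
            journeys,
            journeys,
            events["followup_visits"],
            purchases,
            replacements,
            acquisitions,
            expected_falls,
            val.utility,
            val.total_cost * disc,
            val.utility * disc,
        ]
        rows.append(row_out)

    trace = pd.DataFrame(rows, columns=_trace_columns())
    wtp = e.wtp_per_qaly
    return ArmResult(
        arm=arm,
        gender=params.gender,
        mean_cost=total_cost,
        mean_qaly=total_qaly,
        mean_ly=total_ly,
        nmb=wtp * total_qaly - total_cost,
        wtp=wtp,
        trace=trace,
    )


def run_all_arms(
    params: ModelParameters, tm: TransitionModel, lt: LifeTable
) -> dict[ArmKind, ArmResult]:
    """Convenience wrapper running all three strategies on shared inputs."""
    return {arm: run_arm(params, tm, lt, arm) for arm in ArmKind}
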