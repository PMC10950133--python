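"""Deterministic and probabilistic sensitivity analysis, and scenarios.

One-way DSA perturbs each input to the ends of a plausible range (default
+/-20% of the base value, clipped to validity) and re-runs the model,
yielding an INMB tornado.  PSA draws a joint parameter set per iteration —
Beta for probabilities and utilities (moment-matched to the mean with a
default standard error of 10% of the mean), Gamma for unit costs (SE 20% of
the mean), log-normal for the falls odds and hazard ratios — runs both arms
and records the incremental cost/QALY pair; the cloud feeds the
cost-effectiveness plane and the acceptability curve.  Draws are
independent across parameters; a whole set violating a joint invariant
(e.g. an aided utility falling below its unaided counterpart) is redrawn.

The scenario grid crosses the supply-mix assumptions (public/private cost
mixes) with uptake assumptions: the current dropout mix, no dropout with
surveyed compliance, and no dropout with full compliance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import ArmKind, run_arm
from .natural_history import LifeTable, TransitionModel
from .outcomes import compare
from .parameters import (
    SEVERITIES,
    ModelParameters,
    get_value,
    set_value,
    validate_parameters,
)

__all__ = [
    "ParamRef",
    "parameter_registry",
    "DsaSpec",
    "one_way_dsa",
    "tornado_order",
    "PsaSpec",
    "PsaResult",
    "run_psa",
    "CeacCurve",
    "ceac",
    "DROPOUT_SCENARIOS",
    "apply_dropout_scenario",
    "run_scenarios",
]

DEFAULT_ARM_PAIR = (ArmKind.HA_PLUS_PPS, ArmKind.NO_TREATMENT)


@dataclass(frozen=True)
class ParamRef:
    """A named, typed handle on one scalar model input."""

    name: str  # flat configuration key
    kind: str  # probability | utility | cost | ratio

    def get(self, p: ModelParameters) -> float:
        return float(get_value(p, self.name))

    def set(self, p: ModelParameters, value: float) -> None:
        set_value(p, self.name, float(value))


def parameter_registry(include_compliance_decrement: bool = True) -> list[ParamRef]:
    """The inputs varied by default in DSA and PSA.

    Structural settings (ages, horizon, discount timing, replacement
    interval, supply-mix mode) are excluded: they are scenario levers, not
    stochastic quantities.
    """
    refs: list[ParamRef] = []
    for label in ("p_journey_completion", "p_prescription", "p_purchase", "p_compliance"):
        for sev in SEVERITIES:
            refs.append(ParamRef(f"{label}.{sev}", "probability"))
    for sev in SEVERITIES:
        refs.append(ParamRef(f"utility.unaided.{sev}", "utility"))
        refs.append(ParamRef(f"utility.aided.{sev}", "utility"))
    for key in (
        "first_visit_public",
        "first_visit_private",
        "followup_public",
        "followup_private",
        "device_private_price",
        "device_public_tariff",
        "transport_per_visit",
        "femur_drg_tariff",
        "annual_excess_occupational_cost",
        "daily_gdp_per_capita",
    ):
        refs.append(ParamRef(key, "cost"))
    refs.append(ParamRef("public_visit_share", "probability"))
    for band in ("60-64", "65-69", "70-74", "75+"):
        refs.append(ParamRef(f"falls_incidence.{band}", "probability"))
    refs.append(ParamRef("falls_or_unaided", "ratio"))
    refs.append(ParamRef("falls_hr_aided", "ratio"))
    for sev in ("moderate", "severe"):
        refs.append(ParamRef(f"unemployment_unaided.{sev}", "probability"))
        refs.append(ParamRef(f"unemployment_aided.{sev}", "probability"))
    if include_compliance_decrement:
        refs.append(ParamRef("pps_compliance_decrement", "decrement"))
    return refs


def _clip_for_kind(kind: str, value: float) -> float:
    if kind in ("probability", "utility"):
        return min(max(value, 0.0), 1.0)
    if kind == "decrement":
        return min(max(value, -1.0), 0.0)
    if kind == "cost":
        return max(value, 0.0)
    return value  # ratio: sign-free here; joint validation handles bounds


def _nearest_valid(
    base: ModelParameters, ref: ParamRef, target: float, iterations: int = 60
) -> float:
    """Move ``target`` toward the (valid) base value until the set validates.

    Bisection between the base value and the requested perturbation finds
    the closest admissible point; used to honour ordering constraints such
    as aided >= unaided utilities when a range end would cross them.
    """
    p = base.copy()
    ref.set(p, target)
    if not validate_parameters(p):
        return target
    lo = ref.get(base)  # valid end
    hi = target  # invalid end
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        ref.set(p, mid)
        if validate_parameters(p):  # violations -> mid is still invalid
            hi = mid
        else:
            lo = mid
    return lo


@dataclass
class DsaSpec:
    """Per-parameter (low, high) ranges; defaults are +/-``rel_range``."""

    rel_range: float = 0.20
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    parameters: list[ParamRef] = field(default_factory=parameter_registry)

    def bounds(self, base: ModelParameters, ref: ParamRef) -> tuple[float, float]:
        if ref.name in self.ranges:
            lo, hi = self.ranges[ref.name]
        else:
            v = ref.get(base)
            lo, hi = v * (1 - self.rel_range), v * (1 + self.rel_range)
            if v < 0:  # negative inputs (the compliance decrement)
                lo, hi = hi, lo
        lo = _clip_for_kind(ref.kind, lo)
        hi = _clip_for_kind(ref.kind, hi)
        base_v = ref.get(base)
        lo, hi = min(lo, base_v), max(hi, base_v)
        lo = _nearest_valid(base, ref, lo)
        hi = _nearest_valid(base, ref, hi)
        return lo, hi


def _pair_inmb(
    params: ModelParameters,
    tm: TransitionModel,
    lt: LifeTable,
    arm_pair: tuple[ArmKind, ArmKind],
) -> float:
    a = run_arm(params, tm, lt, arm_pair[0])
    b = run_arm(params, tm, lt, arm_pair[1])
    return compare(a, b).inmb


def one_way_dsa(
    base: ModelParameters,
    tm: TransitionModel,
    lt: LifeTable,
    arm_pair: tuple[ArmKind, ArmKind] = DEFAULT_ARM_PAIR,
    spec: DsaSpec | None = None,
) -> pd.DataFrame:
    """One-way sensitivity of the pairwise INMB to each registered input."""
    spec = spec or DsaSpec()
    violations = validate_parameters(base)
    if violations:
        raise ValueError("base parameter set invalid: " + "; ".join(violations))
    base_inmb = _pair_inmb(base, tm, lt, arm_pair)
    rows = []
    for ref in spec.parameters:
        lo, hi = spec.bounds(base, ref)
        inmbs = []
        for v in (lo, hi):
            if v == ref.get(base):
                inmbs.append(base_inmb)
                continue
            p = base.copy()
            ref.set(p, v)
            inmbs.append(_pair_inmb(p, tm, lt, arm_pair))
        rows.append(
            {
                "parameter": ref.name,
                "kind": ref.kind,
                "base_value": ref.get(base),
                "low_value": lo,
                "high_value": hi,
                "inmb_low": inmbs[0],
                "inmb_high": inmbs[1],
                "inmb_base": base_inmb,
                "width": abs(inmbs[1] - inmbs[0]),
            }
        )
    return pd.DataFrame(rows)


def tornado_order(dsa: pd.DataFrame) -> pd.DataFrame:
    """Sort DSA output by descending bar width, ties broken by name."""
    if len(dsa) == 0:
        raise ValueError("empty sensitivity table")
    out = dsa.copy()
    out["width"] = (out["inmb_high"] - out["inmb_low"]).abs()
    out = out.sort_values(
        ["width", "parameter"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


@dataclass
class PsaSpec:
    """Distribution settings for probabilistic sensitivity analysis."""

    n_iterations: int = 1000
    rel_se_probability: float = 0.10  # Beta SE as a fraction of the mean
    rel_se_cost: float = 0.20  # Gamma SE as a fraction of the mean
    sigma_log_ratio: float = 0.10  # log-scale SD for OR/HR draws
    max_redraws: int = 1000
    parameters: list[ParamRef] = field(default_factory=parameter_registry)

    def spec_hash(self) -> str:
        txt = (
            f"{self.n_iterations}|{self.rel_se_probability}|{self.rel_se_cost}|"
            f"{self.sigma_log_ratio}|" + ",".join(r.name for r in self.parameters)
        )
        return hashlib.sha256(txt.encode()).hexdigest()[:12]


@dataclass
class PsaResult:
    """Paired incremental draws: column 0 = delta cost, column 1 = delta QALY."""

    deltas: np.ndarray
    seed: int
    spec_hash: str
    arm_pair: tuple[ArmKind, ArmKind]

    @property
    def n(self) -> int:
        return len(self.deltas)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.deltas, columns=["delta_cost", "delta_qaly"])


def _draw_value(rng: np.random.Generator, kind: str, mean: float, spec: PsaSpec) -> float:
    if kind in ("probability", "utility", "decrement"):
        sign = -1.0 if kind == "decrement" else 1.0
        m = abs(mean)
        se = spec.rel_se_probability * m
        if se == 0 or m <= 0 or m >= 1:
            return mean  # degenerate at the boundary
        var = min(se**2, 0.999 * m * (1 - m))
        nu = m * (1 - m) / var - 1.0
        return sign * float(rng.beta(m * nu, (1 - m) * nu))
    if kind == "cost":
        se = spec.rel_se_cost * mean
        if se == 0 or mean == 0:
            return mean
        shape = (mean / se) ** 2
        return float(rng.gamma(shape, mean / shape))
    if kind == "ratio":
        if spec.sigma_log_ratio == 0:
            return mean
        return float(mean * np.exp(rng.normal(0.0, spec.sigma_log_ratio)))
    raise ValueError(f"unknown parameter kind {kind!r}")


def run_psa(
    base: ModelParameters,
    tm: TransitionModel,
    lt: LifeTable,
    spec: PsaSpec | None = None,
    seed: int = 0,
    arm_pair: tuple[ArmKind, ArmKind] = DEFAULT_ARM_PAIR,
) -> PsaResult:
    """Monte-Carlo PSA: joint draws, two arm runs per iteration.

    Bit-reproducible for a fixed seed: a single numpy Generator drives every
    draw, including redraws of jointly invalid sets.
    """
    spec = spec or PsaSpec()
    rng = np.random.default_rng(seed)
    deltas = np.empty((spec.n_iterations, 2))
    for it in range(spec.n_iterations):
        attempts = 0
        while True:
            p = base.copy()
            for ref in spec.parameters:
                ref.set(p, _draw_value(rng, ref.kind, ref.get(base), spec))
            if not validate_parameters(p):  # empty violation list = valid
                break
            attempts += 1
            if attempts > spec.max_redraws:  # noqa: retry loop guard
                raise RuntimeError(
                    f"PSA iteration {it}: exceeded {spec.max_redraws} consecutive "
                    "redraws of a jointly invalid parameter set; widen the "
                    "distributions or drop the conflicting parameters"
                )
        a = run_arm(p, tm, lt, arm_pair[0])
        b = run_arm(p, tm, lt, arm_pair[1])
        cmp = compare(a, b)
        deltas[it] = (cmp.delta_cost, cmp.delta_qaly)
    return PsaResult(deltas=deltas, seed=seed, spec_hash=spec.spec_hash(), arm_pair=arm_pair)


@dataclass
class CeacCurve:
    """Probability of cost-effectiveness across willingness-to-pay values."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(result: PsaResult, wtp_grid) -> CeacCurve:
    """Fraction of PSA iterations with positive net benefit at each threshold."""
    if result.n == 0:
        raise ValueError("empty PSA result")
    wtp = np.asarray(wtp_grid, dtype=float)
    d_cost = result.deltas[:, 0]
    d_qaly = result.deltas[:, 1]
    nb = wtp[:, None] * d_qaly[None, :] - d_cost[None, :]
    return CeacCurve(wtp=wtp, probability=(nb > 0).mean(axis=1))


DROPOUT_SCENARIOS = ("current", "no_dropout_partial_compliance", "no_dropout_full_compliance")


def apply_dropout_scenario(base: ModelParameters, scenario: str) -> ModelParameters:
    """Return a copy of ``base`` under one of the uptake scenarios.

    ``no_dropout_partial_compliance`` forces journey completion,
    prescription and purchase to 1 at every severity while keeping surveyed
    compliance; ``no_dropout_full_compliance`` additionally forces
    compliance to 1 (and zeroes the post-purchase-service decrement, so both
    treatment arms reach full use).
    """
    if scenario not in DROPOUT_SCENARIOS:
        raise ValueError(f"unknown dropout scenario {scenario!r}")
    p = base.copy()
    if scenario == "current":
        return p
    for sev in SEVERITIES:
        p.pathway.completion[sev] = 1.0
        p.pathway.prescription[sev] = 1.0
        p.pathway.purchase[sev] = 1.0
    if scenario == "no_dropout_full_compliance":
        for sev in SEVERITIES:
            p.pathway.compliance[sev] = 1.0
        p.pathway.pps_compliance_decrement = 0.0
    return p


_SCENARIO_PAIRS = (
    (ArmKind.HA_PLUS_PPS, ArmKind.NO_TREATMENT),
    (ArmKind.HA_ALONE, ArmKind.NO_TREATMENT),
    (ArmKind.HA_PLUS_PPS, ArmKind.HA_ALONE),
)


def run_scenarios(
    base: ModelParameters, tm: TransitionModel, lt: LifeTable
) -> pd.DataFrame:
    """Cartesian scenario grid: supply mixes x dropout/compliance scenarios.

    Each cell reports incremental cost, incremental QALYs, ICUR and INMB for
    all three pairwise comparisons.
    """
    mixes = ("base_mix", "private_only", "public_only", "public_at_private_price")
    rows = []
    for mix in mixes:
        for scenario in DROPOUT_SCENARIOS:
            p = apply_dropout_scenario(base, scenario)
            p.costs.cost_mix_mode = mix
            results = {arm: run_arm(p, tm, lt, arm) for arm in ArmKind}
            for a_kind, b_kind in _SCENARIO_PAIRS:
                cmp = compare(results[a_kind], results[b_kind])
                rows.append(
                    {
                        "cost_mix": mix,
                        "dropout_scenario": scenario,
                        "intervention": cmp.intervention,
                        "comparator": cmp.comparator,
                        "delta_cost": cmp.delta_cost,
                        "delta_qaly": cmp.delta_qaly,
                        "icur": cmp.icur,
                        "inmb": cmp.inmb,
                    }
                )
    return pd.DataFrame(rows)
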