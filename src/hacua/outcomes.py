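"""Pairwise economic comparison of strategy arms.

ICUR = incremental cost / incremental QALYs; NMB = WTP x QALYs - cost;
INMB = WTP x dQALY - dCost = NMB difference.  Where the ICUR is undefined
or misleading (no QALY difference, or one strategy dominating), a flag is
reported instead of a number so downstream tables stay printable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import ArmKind, ArmResult

__all__ = ["DOMINANT", "DOMINATED", "UNDEFINED", "Comparison", "icur", "inmb", "compare", "comparison_table"]

DOMINANT = "dominant"  # cheaper and more effective
DOMINATED = "dominated"  # costlier and less effective
UNDEFINED = "undefined"  # no QALY difference


def icur(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost-utility ratio, or a dominance flag."""
    if delta_qaly == 0:
        return UNDEFINED
    if delta_cost < 0 and delta_qaly > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return DOMINATED
    return delta_cost / delta_qaly


def inmb(wtp: float, delta_qaly: float, delta_cost: float) -> float:
    """Incremental net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * delta_qaly - delta_cost


@dataclass
class Comparison:
    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icur: float | str
    inmb: float
    wtp: float


def compare(a: ArmResult, b: ArmResult, wtp: float | None = None) -> Comparison:
    """Compare intervention ``a`` against comparator ``b``."""
    if a.gender != b.gender:
        raise ValueError(
            f"arms were run for different cohorts ({a.gender} vs {b.gender})"
        )
    if wtp is None:
        wtp = a.wtp
    d_cost = a.mean_cost - b.mean_cost
    d_qaly = a.mean_qaly - b.mean_qaly
    return Comparison(
        intervention=a.arm.value,
        comparator=b.arm.value,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        icur=icur(d_cost, d_qaly),
        inmb=inmb(wtp, d_qaly, d_cost),
        wtp=wtp,
    )


_PAIRS = (
    (ArmKind.HA_PLUS_PPS, ArmKind.HA_ALONE),
    (ArmKind.HA_PLUS_PPS, ArmKind.NO_TREATMENT),
    (ArmKind.HA_ALONE, ArmKind.NO_TREATMENT),
)


def comparison_table(
    results: dict[ArmKind, ArmResult], wtp: float | None = None
) -> pd.DataFrame:
    """Base-case results table: per-arm means plus the three pairwise blocks."""
    rows = []
    for a_kind, b_kind in _PAIRS:
        a, b = results[a_kind], results[b_kind]
        cmp = compare(a, b, wtp)
        rows.append(
            {
                "intervention": cmp.intervention,
                "comparator": cmp.comparator,
                "gender": a.gender,
                "mean_cost_intervention": a.mean_cost,
                "mean_cost_comparator": b.mean_cost,
                "mean_ly_intervention": a.mean_ly,
                "mean_ly_comparator": b.mean_ly,
                "mean_qaly_intervention": a.mean_qaly,
                "mean_qaly_comparator": b.mean_qaly,
                "nmb_intervention": a.nmb,
                "nmb_comparator": b.nmb,
                "delta_cost": cmp.delta_cost,
                "delta_qaly": cmp.delta_qaly,
                "icur": cmp.icur,
                "inmb": cmp.inmb,
                "wtp": cmp.wtp,
            }
        )
    return pd.DataFrame(rows)
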