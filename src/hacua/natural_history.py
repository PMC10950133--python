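"""Natural history of age-related hearing loss: progression and mortality.

The disease process is a five-state Markov chain — normal hearing, mild,
moderate and severe-to-profound loss (defined audiometrically on the better
ear), plus death.  Hearing never recovers, so the only transitions are
forward across severity grades; death is absorbing and competes first:
annual progression probabilities are conditional on survival and the whole
alive row is multiplied by ``1 - q(age)`` from a gender-specific life table.
Mortality does not depend on hearing state and treatment does not alter
progression, so survival is identical across arms by construction.

Progression probabilities are "gradual": from any state, a one-grade step is
at least as likely as a two-grade step, which is at least as likely as a
three-grade step.  Because published annual probabilities rarely reproduce
observed prevalence when iterated over a lifetime, the module calibrates the
whole set with a single multiplicative scale factor so that the modelled
prevalence of any hearing loss among the alive matches stated targets
(for Italy, roughly 25% between ages 61-80 and 50% above 80).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "HealthState",
    "ALIVE_STATES",
    "HEARING_LOSS_STATES",
    "AUDIOMETRIC_DB",
    "LifeTable",
    "TransitionModel",
    "PrevalenceTargets",
    "CalibrationError",
    "transition_row",
    "predicted_prevalence",
    "any_hl_prevalence",
    "calibrate_to_prevalence",
]


class HealthState(IntEnum):
    NORMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    DEAD = 4


#: Audiometric definition (better hearing ear) attached to each alive state.
AUDIOMETRIC_DB = {
    HealthState.NORMAL: "<25 dB",
    HealthState.MILD: "25-44 dB",
    HealthState.MODERATE: "45-64 dB",
    HealthState.SEVERE: ">=65 dB",
}

ALIVE_STATES = (
    HealthState.NORMAL,
    HealthState.MILD,
    HealthState.MODERATE,
    HealthState.SEVERE,
)
HEARING_LOSS_STATES = (HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE)

#: Map from hearing-loss state to the severity key used by parameter dicts.
SEVERITY_KEY = {
    HealthState.MILD: "mild",
    HealthState.MODERATE: "moderate",
    HealthState.SEVERE: "severe",
}


class CalibrationError(RuntimeError):
    """Prevalence targets cannot be met by scaling; carries diagnostics."""

    def __init__(self, message: str, achieved: dict[int, float], scale: float):
        super().__init__(message)
        self.achieved = achieved  # age -> best achievable any-HL prevalence
        self.scale = scale


@dataclass
class LifeTable:
    """Annual death probabilities ``q(age)`` for one gender, ages 55..110.

    The final age closes the horizon: ``q(110)`` must equal 1 so the cohort
    is extinct when the model ends.
    """

    gender: str
    start_age: int
    q: np.ndarray  # q[i] is the death probability at age start_age + i

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)

    @property
    def end_age(self) -> int:
        return self.start_age + len(self.q) - 1

    def annual_death_prob(self, age: int) -> float:
        if not self.start_age <= age <= self.end_age:
            raise ValueError(
                f"age {age} outside life table range [{self.start_age}, {self.end_age}]"
            )
        return float(self.q[age - self.start_age])

    def validate(self) -> None:
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("life table probabilities must lie in [0, 1]")
        if not math.isclose(self.q[-1], 1.0):
            raise ValueError(
                f"q({self.end_age}) = {self.q[-1]}; the final age must have q = 1"
            )

    def survival_curve(self) -> np.ndarray:
        """Cumulative survival from start_age to the end of each age-year."""
        return np.cumprod(1.0 - self.q)

    @classmethod
    def from_csv(cls, path, gender: str = "unspecified") -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "q"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'age' and 'q'")
        df = df.sort_values("age")
        ages = df["age"].to_numpy(dtype=int)
        if np.any(np.diff(ages) != 1):
            raise ValueError(f"{path}: ages must be consecutive")
        lt = cls(gender=gender, start_age=int(ages[0]), q=df["q"].to_numpy(dtype=float))
        lt.validate()
        return lt

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age": np.arange(self.start_age, self.end_age + 1), "q": self.q}
        ).to_csv(path, index=False)


_STATE_BY_NAME = {s.name: s for s in HealthState}


@dataclass
class TransitionModel:
    """Annual hearing-loss progression probabilities, conditional on survival.

    ``probs`` maps ``(from_state, to_state)`` pairs (forward only, among the
    four alive states) to base annual probabilities.  The effective
    probability at a given age is ``base * scale * exp(age_slope * (age -
    start_age))``: ``scale`` is the global calibration factor and
    ``age_slope`` an optional log-linear age trend (0 for age-constant
    progression).  If the scaled forward mass of a row would exceed 1 it is
    renormalised to 1 (capped) and the cap is reported on ``capped_rows``.
    """

    probs: dict[tuple[int, int], float]
    scale: float = 1.0
    age_slope: float = 0.0
    start_age: int = 55
    calibration: dict | None = None
    capped_rows: set = field(default_factory=set)

    def forward_probs(self, state: int, age: float) -> dict[int, float]:
        """Scaled conditional-on-survival progression probabilities from ``state``."""
        mult = self.scale * math.exp(self.age_slope * (age - self.start_age))
        fwd = {
            j: p * mult for (i, j), p in self.probs.items() if i == state and p > 0
        }
        total = sum(fwd.values())
        if total > 1.0:
            fwd = {j: p / total for j, p in fwd.items()}
            self.capped_rows.add((int(state), float(age)))
        return fwd

    def validate(self) -> None:
        for (i, j), p in self.probs.items():
            if not (0 <= i < j <= 3):
                raise ValueError(f"transition ({i}->{j}) is not a forward alive pair")
            if p < 0:
                raise ValueError(f"p({i}->{j}) = {p} must be >= 0")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        for i in range(4):
            steps = [self.probs.get((i, i + k), 0.0) for k in (1, 2, 3) if i + k <= 3]
            for a, b in zip(steps, steps[1:]):
                if b > a + 1e-12:
                    raise ValueError(
                        f"gradual ordering violated from state {i}: {steps}"
                    )

    def max_feasible_scale(self, max_age: int) -> float:
        """Largest extra multiplier keeping every row sum <= 1 up to ``max_age``."""
        worst = math.exp(self.age_slope * (max_age - self.start_age)) if self.age_slope > 0 else 1.0
        bound = math.inf
        for i in range(4):
            f = sum(p for (a, b), p in self.probs.items() if a == i) * self.scale * worst
            if f > 0:
                bound = min(bound, 1.0 / f)
        return bound

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TransitionModel":
        df = pd.read_csv(path)
        probs = {}
        for _, row in df.iterrows():
            i = _STATE_BY_NAME[str(row["from_state"]).upper()]
            j = _STATE_BY_NAME[str(row["to_state"]).upper()]
            probs[(int(i), int(j))] = float(row["probability"])
        tm = cls(probs=probs, **kwargs)
        tm.validate()
        return tm

    def to_csv(self, path) -> None:
        rows = [
            {
                "from_state": HealthState(i).name,
                "to_state": HealthState(j).name,
                "probability": p,
            }
            for (i, j), p in sorted(self.probs.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class PrevalenceTargets:
    """Target proportions of the alive cohort with any hearing loss."""

    targets: list[tuple[int, float]]  # (age, proportion)

    def validate(self, start_age: int = 55, end_age: int = 110) -> None:
        if not self.targets:
            raise ValueError("at least one prevalence target is required")
        for age, prop in self.targets:
            if not (0.0 <= prop <= 1.0):
                raise ValueError(f"target proportion {prop} at age {age} outside [0, 1]")
            if not (start_age <= age <= end_age):
                raise ValueError(f"target age {age} outside horizon [{start_age}, {end_age}]")


def transition_row(
    tm: TransitionModel, lt: LifeTable, state: int, age: int
) -> np.ndarray:
    """One row of the annual transition matrix at a given age.

    Returns a probability vector over (NORMAL, MILD, MODERATE, SEVERE, DEAD)
    summing to 1.  Death takes ``q(age)`` regardless of hearing state; the
    conditional-on-survival stay/progress split is multiplied by ``1 - q``.
    """
    if not lt.start_age <= age <= lt.end_age:
        raise ValueError(f"age {age} outside [{lt.start_age}, {lt.end_age}]")
    row = np.zeros(5)
    if state == HealthState.DEAD:
        row[HealthState.DEAD] = 1.0
        return row
    q = lt.annual_death_prob(age)
    fwd = tm.forward_probs(state, age)
    stay = 1.0 - sum(fwd.values())
    row[state] = stay * (1.0 - q)
    for j, p in fwd.items():
        row[j] = p * (1.0 - q)
    row[HealthState.DEAD] = q
    return row


def predicted_prevalence(tm: TransitionModel, lt: LifeTable, age: int) -> np.ndarray:
    """Hearing-state distribution among the alive at ``age``.

    The cohort starts 100% normal-hearing at the model start age and is
    iterated one annual cycle at a time; the four alive proportions are
    renormalised to sum to 1.
    """
    if age < lt.start_age:
        raise ValueError(f"age {age} precedes the start age {lt.start_age}")
    occ = np.zeros(5)
    occ[HealthState.NORMAL] = 1.0
    for a in range(lt.start_age, age):
        nxt = np.zeros(5)
        for s in range(5):
            if occ[s] > 0:
                nxt += occ[s] * transition_row(tm, lt, s, a)
        occ = nxt
    alive = occ[:4]
    total = alive.sum()
    if total <= 0:
        raise ValueError(f"cohort extinct before age {age}")
    return alive / total


def any_hl_prevalence(tm: TransitionModel, lt: LifeTable, age: int) -> float:
    """Proportion of the alive cohort with any hearing loss at ``age``."""
    return float(1.0 - predicted_prevalence(tm, lt, age)[HealthState.NORMAL])


def calibrate_to_prevalence(
    tm0: TransitionModel,
    lt: LifeTable,
    targets: PrevalenceTargets,
    tolerance: float = 0.01,
) -> TransitionModel:
    """Scale all progression probabilities so prevalence matches targets.

    A single positive multiplicative factor is applied to every progression
    probability (the minimal identifiable correction against any-loss
    prevalence targets).  Because prevalence is strictly increasing in the
    factor, the sum of squared target errors is unimodal and a bounded
    scalar minimisation finds the best factor; each target must then fall
    within ``tolerance`` wherever that is jointly feasible.  If the search
    exhausts its bracket (the factor is capped by row validity, or pinned at
    zero) while a target is still missed, a :class:`CalibrationError` with
    the best achievable prevalences is raised.
    """
    tm0.validate()
    targets.validate(lt.start_age, lt.end_age)
    max_age = max(age for age, _ in targets.targets)
    s_max = min(tm0.max_feasible_scale(max_age), 1e6)

    def sse(s: float) -> float:
        tm = replace(tm0, scale=tm0.scale * s, capped_rows=set())
        return sum(
            (any_hl_prevalence(tm, lt, age) - prop) ** 2
            for age, prop in targets.targets
        )

    res = minimize_scalar(
        sse, bounds=(0.0, s_max), method="bounded", options={"xatol": 1e-12}
    )
    s_best = float(res.x)
    # A pinned optimum at the bracket edge can sit half an xatol inside it;
    # snap to the edge when that is at least as good.
    for edge in (0.0, s_max):
        if sse(edge) <= res.fun + 1e-18:
            s_best = edge
            break
    tm = replace(tm0, scale=tm0.scale * s_best, capped_rows=set())
    achieved = {age: any_hl_prevalence(tm, lt, age) for age, _ in targets.targets}
    misses = {
        age: (achieved[age], prop)
        for age, prop in targets.targets
        if abs(achieved[age] - prop) > tolerance
    }
    at_edge = s_best >= s_max * (1 - 1e-9) or s_best <= s_max * 1e-12
    if misses and at_edge:
        raise CalibrationError(
            "prevalence targets infeasible under single-factor scaling: "
            + ", ".join(
                f"age {a}: best {b:.4f} vs target {t:.4f}" for a, (b, t) in misses.items()
            ),
            achieved=achieved,
            scale=s_best,
        )
    tm.calibration = {
        "scale_factor": s_best,
        "achieved": achieved,
        "targets": list(targets.targets),
        "within_tolerance": not misses,
        "tolerance": tolerance,
        "capped": bool(tm0.capped_rows),
    }
    return tm
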