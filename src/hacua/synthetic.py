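"""Synthetic stand-ins for the model's two external inputs.

The cohort engine needs (a) gender-specific life tables and (b) an annual
hearing-loss progression model.  Neither is bundled with published primary
data, so this module generates both with the statistical structure the
analysis assumes:

* Mortality follows a Gompertz-Makeham hazard ``h(x) = a + b e^{c(x-55)}``
  — the standard adult-mortality law — with gender presets shaped like
  recent Italian mortality (female hazard below male at every age in the
  horizon, so female life expectancy is longer).
* Progression is a gradual forward chain (one-grade steps more likely than
  two-grade, more likely than three-grade) with a log-linear age trend, and
  is calibrated by a single scale factor so the modelled prevalence of any
  hearing loss matches the stated Italian targets: about 25% in the 61-80
  age range and 50% above 80 (anchored at representative ages 70 and 85).

The generators emit the same CSV formats the natural-history loaders
consume, so real life tables or literature-derived transition probabilities
can be dropped in with no code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .natural_history import (
    HealthState,
    LifeTable,
    PrevalenceTargets,
    TransitionModel,
    calibrate_to_prevalence,
)
from .parameters import ModelParameters, default_parameters

__all__ = [
    "MortalityCurveSpec",
    "MALE_MORTALITY",
    "FEMALE_MORTALITY",
    "synth_life_table",
    "ProgressionSpec",
    "synth_transition_model",
    "FixtureBundle",
    "fixture_bundle",
]


@dataclass(frozen=True)
class MortalityCurveSpec:
    """Gompertz-Makeham hazard parameters for one gender.

    ``makeham_a`` is the age-independent background rate, ``gompertz_b`` the
    senescent level at the start age and ``gompertz_c`` the log-linear slope
    per year of age.  Optional multiplicative log-normal jitter (seeded)
    roughens the curve without changing its shape.
    """

    gender: str
    makeham_a: float = 3e-4
    gompertz_b: float = 4e-3
    gompertz_c: float = 0.095
    start_age: int = 55
    end_age: int = 110
    jitter_sd: float = 0.0
    seed: int = 0

    def hazard(self, age: np.ndarray) -> np.ndarray:
        return self.makeham_a + self.gompertz_b * np.exp(
            self.gompertz_c * (age - self.start_age)
        )


#: Presets roughly shaped to recent Italian adult mortality; the female
#: hazard sits below the male hazard throughout ages 55-110.
MALE_MORTALITY = MortalityCurveSpec("male", makeham_a=3e-4, gompertz_b=4e-3, gompertz_c=0.095)
FEMALE_MORTALITY = MortalityCurveSpec("female", makeham_a=2e-4, gompertz_b=2e-3, gompertz_c=0.103)


def synth_life_table(spec: MortalityCurveSpec) -> LifeTable:
    """Annual death probabilities from the hazard, horizon closed at the end age."""
    if spec.makeham_a < 0 or spec.gompertz_b <= 0 or spec.gompertz_c <= 0:
        raise ValueError(
            "invalid hazard parameters: require a >= 0, b > 0, c > 0, got "
            f"a={spec.makeham_a}, b={spec.gompertz_b}, c={spec.gompertz_c}"
        )
    ages = np.arange(spec.start_age, spec.end_age + 1)
    h = spec.hazard(ages.astype(float))
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        h = h * np.exp(rng.normal(0.0, spec.jitter_sd, size=h.shape))
    q = 1.0 - np.exp(-h)
    q[-1] = 1.0  # force horizon closure
    lt = LifeTable(gender=spec.gender, start_age=spec.start_age, q=q)
    lt.validate()
    return lt


@dataclass(frozen=True)
class ProgressionSpec:
    """Structure of the synthetic hearing-loss progression model.

    One-grade annual probabilities are given per step; two- and three-grade
    jumps are fixed fractions (<= 1) of the next-shorter jump, which makes
    the gradual ordering hold by construction.  ``age_slope`` grows all
    rates log-linearly with age (presbycusis incidence accelerates late in
    life); its default makes the two prevalence targets jointly attainable
    by a single calibration factor: with cumulative progression hazard
    proportional to ``(e^{g t} - 1)/g``, matching 25% at 15 years and 50% at
    30 years from the start age requires ``e^{15 g} = 1.41``, i.e.
    ``g = 0.0229``.
    """

    p_normal_to_mild: float = 0.008
    p_mild_to_moderate: float = 0.010
    p_moderate_to_severe: float = 0.008
    skip_one_fraction: float = 0.20  # two-grade jump, as a fraction of one-grade
    skip_two_fraction: float = 0.05  # three-grade jump, as a fraction of two-grade
    age_slope: float = 0.0229
    targets: tuple[tuple[int, float], ...] = ((70, 0.25), (85, 0.50))

    def base_probs(self) -> dict[tuple[int, int], float]:
        n, m, s = HealthState.NORMAL, HealthState.MILD, HealthState.MODERATE
        p01 = self.p_normal_to_mild
        p12 = self.p_mild_to_moderate
        p23 = self.p_moderate_to_severe
        probs = {
            (int(n), int(m)): p01,
            (int(n), int(s)): p01 * self.skip_one_fraction,
            (int(n), int(HealthState.SEVERE)): p01 * self.skip_one_fraction * self.skip_two_fraction,
            (int(m), int(s)): p12,
            (int(m), int(HealthState.SEVERE)): p12 * self.skip_one_fraction,
            (int(s), int(HealthState.SEVERE)): p23,
        }
        return probs


def synth_transition_model(spec: ProgressionSpec, lt: LifeTable) -> TransitionModel:
    """Build the gradual progression matrix and calibrate it to prevalence."""
    if not (0.0 <= spec.skip_one_fraction <= 1.0 and 0.0 <= spec.skip_two_fraction <= 1.0):
        raise ValueError("skip fractions must lie in [0, 1]")
    tm0 = TransitionModel(
        probs=spec.base_probs(), age_slope=spec.age_slope, start_age=lt.start_age
    )
    tm0.validate()
    targets = PrevalenceTargets(list(spec.targets))
    return calibrate_to_prevalence(tm0, lt, targets, tolerance=0.01)


@dataclass
class FixtureBundle:
    """Everything a full three-arm run needs, for both genders."""

    params: dict[str, ModelParameters]
    life_tables: dict[str, LifeTable]
    transition_models: dict[str, TransitionModel]
    seed: int = 0


def fixture_bundle(seed: int = 0) -> FixtureBundle:
    """Deterministic ready-to-run inputs for both genders.

    The seed only matters when mortality jitter is enabled; the default
    bundle is fully deterministic, so equal seeds give bit-identical
    bundles.
    """
    params = {g: default_parameters(g) for g in ("male", "female")}
    lts = {
        "male": synth_life_table(
            MortalityCurveSpec(**{**MALE_MORTALITY.__dict__, "seed": seed})
        ),
        "female": synth_life_table(
            MortalityCurveSpec(**{**FEMALE_MORTALITY.__dict__, "seed": seed})
        ),
    }
    spec = ProgressionSpec()
    tms = {g: synth_transition_model(spec, lts[g]) for g in ("male", "female")}
    return FixtureBundle(params=params, life_tables=lts, transition_models=tms, seed=seed)
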