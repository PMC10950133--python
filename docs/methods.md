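# Methods

## Model overview

`hacua` implements an expected-value (cohort) multistate Markov model of
age-related hearing loss and hearing-aid (HA) provision, evaluated from a
restricted societal perspective in 2021 euros. A cohort enters at age 55
with normal hearing and is followed in annual cycles to age 110 (lifetime
horizon). Hearing states are normal (<25 dB in the better ear), mild
(25–44 dB), moderate (45–64 dB) and severe-to-profound (≥65 dB), plus
death. Hearing never recovers; transitions run forward only and are
"gradual": from any state a one-grade step is at least as likely as a
two-grade step, which is at least as likely as a three-grade step.

Three strategies are compared: no treatment, HA provision alone, and HA
provision with post-purchase service. The treatment arms share every input
except compliance — the service exists in the model solely to keep
purchasers using their device.

### Mortality

Death competes first. Each alive row takes the gender- and age-specific
annual death probability `q(age)` from a life table; the conditional
stay/progress split is multiplied by `1 − q`, so every row sums to 1 by
construction. Mortality is independent of hearing state and of treatment
(no excess-mortality input exists), so undiscounted life years are
identical across arms to machine precision — a structural property the
tests assert rather than an empirical finding.

### Treatment uptake

When mass enters a new, more severe hearing state without a device in use,
it passes a four-stage journey: journey completion up to the ENT specialist
(`c`), prescription (`r`), purchase (`b`), compliance (`u`). The resulting
split is

- compliant user: `c·r·b·u`
- owner, non-compliant: `c·r·b·(1 − u)`
- journey completed, no device: `c·(1 − r·b)`
- no journey: `1 − c`

Compliance without post-purchase service is `u·(1 + d)` with the decrement
`d = −0.36` applied multiplicatively by default (`0.94 × 0.64 = 0.6016`);
an absolute mode (`0.94 − 0.36 = 0.58`) is switchable in configuration.
The multiplicative default keeps the result a valid probability for any
baseline.

Compliant use is absorbing: compliant mass stays compliant (and keeps its
device through severity progression) until death. Mass that failed the
journey, or completed it without a device, re-attempts the journey only in
the cycle it progresses to a more severe state, using the new severity's
probabilities. Non-compliant owners never re-enter the journey — they
already hold a device; this is the conservative reading of an input set
that is silent on the point. They receive unaided utility, no follow-up
visits and no replacements, but their initial purchase cost was incurred.

### Valuation

Occupancy **after** each annual transition is valued for that cycle (no
half-cycle correction; switchable by design but not exposed as a default).
Cycle `t` (first cycle `t = 0`) is discounted by `(1 + r)^−t` with
`r = 0.03`, identically for costs and QALYs.

Utility: normal hearing 1.0 (the upper bound; hearing loss is the only
quality-of-life decrement modelled), unaided/aided weights per severity
from one of two packaged sets (a HUI3-flavoured base-case set and an
EQ-5D-flavoured alternative set). Aided weights apply only to compliant
users; non-compliant owners count as unaided.

Costs per cycle:

- **First specialist visit** for every journey completed that cycle — also
  for journeys that end without a prescription or purchase (the visit is
  what completes the journey).
- **Annual follow-up visit** for every compliant user.
- **Device** at purchase and, while the purchasing cohort survives
  compliant, every 5 years thereafter (battery obsolescence is subsumed in
  replacement). Replacement is tracked per purchase vintage, not as extra
  Markov states — exact because replacement timing depends only on time
  since purchase and survival, which is state-independent.
- **Injurious falls leading to hospitalisation**: age-band baseline
  incidence (zero below 60, where no incidence is published) times the
  femur-fracture DRG tariff (€6,099). Unaided hearing-impaired mass has
  the odds ratio 1.97 applied on the odds scale,
  `p' = OR·o/(1 + OR·o)` with `o = p/(1 − p)`; aided mass has the hazard
  ratio 0.87 applied on the complement scale, `p' = 1 − (1 − p)^HR` — each
  ratio acting on the scale it was measured on.
- **Transport** €5.84 per visit of either kind, any age.
- **Productivity**: €82.87/year excess occupational cost for unaided
  moderate/severe mass up to age 64; aided mass pays that amount reduced by
  the relative unaided-vs-aided unemployment gap for its severity
  (moderate: `82.87 × (1 − (0.1070 − 0.0540)/0.1070) ≈ €41.82`). Lost
  working days for visits are costed at the daily GDP per capita (€71.73),
  also restricted to age ≤ 64 for consistency with the occupational block.

Visit costs come from an equal-weight public/private mix by default;
alternative supply mixes (private only, public tariffs only, public
provision at the private price, and an optional market-share-weighted
device mix) are scenario levers. The private device price (€1,990.90)
bundles the post-purchase service, so the two treatment arms carry the
same device cost.

### Outcome measures

Per arm: discounted mean cost, discounted mean QALYs, undiscounted life
years, and NMB = WTP × QALYs − cost at the €16,265/QALY threshold.
Pairwise: ΔC, ΔQ, ICUR = ΔC/ΔQ (with `dominant` / `dominated` /
`undefined` flags replacing the ratio when ΔQ ≤ 0 or ΔC < 0 cross signs),
and INMB = WTP × ΔQ − ΔC, which equals the NMB difference and is additive
across the three pairwise comparisons — both identities are asserted to
1e−9 in the tests.

## Synthetic inputs

The two external inputs — national life tables and literature-derived
progression probabilities — are generated synthetically with the
statistical structure the analysis assumes, and the generators emit the
same CSV formats the loaders consume, so real data can be dropped in
without code changes.

**Mortality** follows a Gompertz–Makeham hazard
`h(x) = a + b·e^{c(x−55)}`. Presets (male `a = 3×10⁻⁴, b = 4×10⁻³,
c = 0.095`; female `a = 2×10⁻⁴, b = 2×10⁻³, c = 0.103`) are shaped to
recent Italian adult mortality: `q(55) ≈ 0.004` (male) / `0.002` (female),
`q(85) ≈ 0.07 / 0.045`, female hazard below male throughout the horizon so
female life expectancy is longer. `q(110)` is forced to 1 to close the
horizon. Optional seeded log-normal jitter can roughen the curve; the
default bundle is fully deterministic.

**Progression** uses one-grade annual probabilities (normal→mild 0.008,
mild→moderate 0.010, moderate→severe 0.008 before calibration) with
two-grade jumps at 20% and three-grade jumps at 5%-of-two-grade, which
makes the gradual ordering hold by construction. All rates grow
log-linearly with age (`× e^{g(age−55)}`, default `g = 0.0229`), reflecting
the late-life acceleration of presbycusis incidence. The slope default has
a closed-form rationale: with cumulative progression hazard proportional
to `(e^{gT} − 1)/g`, matching 25% any-loss prevalence 15 years after entry
and 50% after 30 years requires `(e^{30g} − 1)/(e^{15g} − 1) = 
ln 0.5 / ln 0.75 ≈ 2.41`, i.e. `e^{15g} = 1.41`, `g ≈ 0.0229`. Without an
age trend the two targets are jointly unattainable by any single scaling
(a constant rate that gives 25% at 15 years gives only `1 − 0.75² =
43.75%` at 30).

**Calibration** multiplies every progression probability by a single
positive scale factor — the minimal identifiable correction against
any-loss prevalence targets. Because prevalence among the alive is
strictly increasing in the factor (and, with state-independent mortality,
equal to the immortal-cohort prevalence), the sum of squared target errors
is unimodal; a bounded scalar minimisation (`scipy.optimize
.minimize_scalar`, bracket `[0, max feasible scale]`, `xatol = 10⁻¹²`)
finds it. Targets are 25% at age 70 and 50% at age 85 — representative
ages inside the stated 61–80 and >80 ranges. The default bundle hits both
within 0.05 percentage points; calibrating against the prevalence produced
by a known factor recovers it to better than 10⁻³. If the optimum is
pinned at a bracket edge while a target is still missed, calibration fails
loudly with the best achievable prevalence.

### What the synthetic fixture does and does not show

The fixture reproduces the *structure* of the analysis — survival
invariance, QALY ordering across arms, calibrated prevalence, and a
base-case ICUR well below the threshold for both genders — but not the
published point estimates, which depend on external inputs (the original
transition probabilities, national life tables, and supplementary
sensitivity ranges) that are not printed anywhere reproducible. Passing
tests therefore demonstrate correctness of the machinery and the direction
and rough magnitude of the economics (incremental costs of a few hundred
euros, QALY gains of ~0.2, ICURs around €2,000/QALY), not agreement with
any specific published cell. The published results table is used the other
way around: its printed means are inputs to arithmetic acceptance checks
on the ICUR/NMB/INMB operations.

## Sensitivity analysis

**One-way DSA** perturbs each of ~40 registered inputs (pathway
probabilities, utility weights of the active set, unit costs, falls
incidence and effect ratios, unemployment rates, the compliance decrement)
to the ends of ±20% ranges, clipped to validity: a range end that violates
a joint invariant (e.g. unaided mild utility 0.96 > aided 0.93) is pulled
back to the nearest valid point by bisection toward the base value.
Structural integers (ages, replacement interval) and mix modes are
excluded — they are scenario levers. Output is the INMB at each end,
sorted by bar width (ties alphabetical). On the default fixture the
utility weights produce the widest bars by a wide margin.

**PSA** draws each registered input independently per iteration: Beta for
probabilities and utilities, moment-matched to the base value with SE =
10% of the mean (values at 0 or 1 stay degenerate); Gamma for unit costs,
SE = 20% of the mean; log-normal about the point estimate with log-SD 0.1
for the odds and hazard ratios. A drawn set violating any joint invariant
is rejected and redrawn whole (acceptance ≈ 0.4, dominated by the two
equal aided-utility means 0.93/0.93 against the non-increasing-severity
constraint and by HR draws above 1); this truncation is the standard price
of enforcing coherence with independent draws. More than 1000 consecutive
rejections aborts with a diagnostic. A single seeded `numpy` Generator
drives everything, so results are bit-reproducible per seed. Default 1000
iterations run in well under a minute per gender; the CEAC is the fraction
of iterations with positive net benefit at each threshold.

**Scenarios** cross four supply mixes with three uptake scenarios:
current dropout; no dropout (journey completion, prescription and purchase
forced to 1) with surveyed compliance; and no dropout with full compliance,
which also zeroes the post-purchase-service decrement — making the two
treatment arms coincide there by construction.

## Numerical conventions and limitations

- Occupancy is conserved to 1e−10 per cycle; transition rows sum to 1 to
  1e−12 (property-tested over random valid models).
- Scaled forward rows that would exceed probability 1 are renormalised and
  the cap recorded; the default fixture never caps.
- The falls age argument, productivity age cut-off and band lookups use the
  age at the start of the cycle being valued.
- The cohort is homogeneous within (state, status): no individual-level
  heterogeneity, no microsimulation mode.
- Prevalence calibration targets any hearing loss, not per-severity
  prevalence; a per-severity variant would need more than one scale factor
  to be identifiable.
- The model does not represent waiting-time differences between public and
  private provision, battery replacement as a separate stream, or costs of
  isolation/depression/dementia (assumed captured by the utility weights).
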