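# hacua — cost-utility of hearing-aid provision for age-related hearing loss

`hacua` is a multistate Markov cohort model for health-economic evaluation
of hearing aids (HAs) in age-related hearing loss, built for health
technology assessment analysts. A cohort of 55-year-olds with normal
hearing progresses annually through mild, moderate and severe-to-profound
loss (or dies) to age 110; three strategies are compared — no treatment,
HA provision alone, and HA provision with post-purchase service — on
discounted costs and QALYs from a restricted societal perspective
(healthcare resources, transport, productivity; 2021 euros, Italian
setting, 3%/year discounting).

What distinguishes the model is an explicit four-stage treatment-uptake
journey: when a cohort member enters a (new) hearing-loss state they may
complete the care journey up to the ENT specialist (probability *c*),
receive a prescription (*r*), purchase the device (*b*), and actually use
it (*u*), so the compliant-user fraction is *c·r·b·u* and each stage is a
separately testable dropout lever. The post-purchase service acts only
through *u* (0.94 with service, 0.94 × (1 − 0.36) without).

Outcomes follow standard decision-analytic notation: for intervention *i*
versus comparator *j*,

- **ICUR** = ΔC/ΔE, incremental cost per QALY gained,
- **NMB** = λ·E − C and **INMB** = λ·ΔE − ΔC at willingness-to-pay
  λ = €16,265/QALY,

with one-way deterministic sensitivity analysis (INMB tornado),
probabilistic sensitivity analysis (Beta/Gamma/log-normal draws, CE plane,
CEAC), and a scenario grid crossing public/private supply mixes with
dropout/compliance assumptions.

Because the original external inputs (national life tables,
literature-derived transition probabilities) are not redistributable, the
package ships a synthetic-data module: Gompertz–Makeham life tables per
gender and a gradual progression model calibrated by a single scale factor
so that any-loss prevalence matches the stated Italian targets (≈25% at
ages 61–80, ≈50% above 80). Real data in the same CSV formats can be
dropped in without code changes. See `docs/methods.md` for the full model
description.

## Worked example

```python
from hacua import ArmKind, compare, fixture_bundle, run_all_arms

bundle = fixture_bundle(seed=0)           # synthetic life tables + calibrated progression
params = bundle.params["male"]            # published base-case inputs, male cohort
results = run_all_arms(params,
                       bundle.transition_models["male"],
                       bundle.life_tables["male"])
for arm in ArmKind:
    r = results[arm]
    print(f"{arm.value:>12}: cost {r.mean_cost:8.0f}  QALYs {r.mean_qaly:8.4f}"
          f"  LYs {r.mean_ly:8.4f}  NMB {r.nmb:9.0f}")
cmp = compare(results[ArmKind.HA_PLUS_PPS], results[ArmKind.NO_TREATMENT])
print(f"HA+service vs no treatment: dCost {cmp.delta_cost:.0f}, "
      f"dQALY {cmp.delta_qaly:.4f}, ICUR {cmp.icur:.0f} euro/QALY, "
      f"INMB {cmp.inmb:.0f}")
```

prints

```
no_treatment: cost     1872  QALYs  17.6053  LYs  28.6966  NMB    284478
    ha_alone: cost     2155  QALYs  17.7173  LYs  28.6966  NMB    286018
 ha_plus_pps: cost     2224  QALYs  17.7804  LYs  28.6966  NMB    286974
HA+service vs no treatment: dCost 352, dQALY 0.1751, ICUR 2010 euro/QALY, INMB 2496
```

Reading the numbers: undiscounted life expectancy (28.70 years from age
55) is identical across arms because treatment affects quality of life,
not survival. Treatment with service adds €352 of discounted lifetime
cost and 0.175 discounted QALYs per cohort member, an ICUR of
€2,010/QALY — far below the €16,265/QALY threshold — and an incremental
net monetary benefit of €2,496.

The same pipeline is available from the shell:

```sh
hacua synth --out inputs/            # write the synthetic input bundle as CSV
hacua run --gender female --out out/ # three arms + pairwise comparison table
hacua dsa --out out/                 # INMB tornado
hacua psa --iterations 1000 --seed 7 --out out/   # CE plane + CEAC
hacua scenarios --out out/           # supply-mix x dropout grid
```

Every command writes a `manifest.json` (command, config, seed, package
version), and identical config + seed reproduce outputs byte-for-byte.
Inputs can be overridden with a flat YAML file (`--params`), e.g.
`wtp_per_qaly: 20000` or `utility_set: alternative`; unknown keys and
invariant violations are rejected by name.

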