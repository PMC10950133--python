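"""One-way DSA, tornado ordering, PSA reproducibility, CEAC, scenarios."""

import numpy as np
import pandas as pd
import pytest

from hacua import (
    ArmKind,
    DsaSpec,
    PsaSpec,
    apply_dropout_scenario,
    ceac,
    compare,
    one_way_dsa,
    run_arm,
    run_psa,
    run_scenarios,
    tornado_order,
    uptake_split,
)
from hacua.sensitivity import ParamRef


def small_dsa_spec(*names_kinds) -> DsaSpec:
    return DsaSpec(parameters=[ParamRef(n, k) for n, k in names_kinds])


@pytest.fixture(scope="module")
def base_inmb(male_inputs):
    params, tm, lt = male_inputs
    a = run_arm(params, tm, lt, ArmKind.HA_PLUS_PPS)
    b = run_arm(params, tm, lt, ArmKind.NO_TREATMENT)
    return compare(a, b).inmb


class TestOneWayDsa:
    def test_null_perturbation(self, male_inputs, base_inmb):
        params, tm, lt = male_inputs
        spec = small_dsa_spec(("transport_per_visit", "cost"))
        v = params.costs.transport_per_visit
        spec.ranges["transport_per_visit"] = (v, v)
        out = one_way_dsa(params, tm, lt, spec=spec)
        assert out.loc[0, "inmb_low"] == pytest.approx(base_inmb)
        assert out.loc[0, "inmb_high"] == pytest.approx(base_inmb)

    def test_wider_utility_range_widens_bar(self, male_inputs):
        params, tm, lt = male_inputs
        widths = []
        for rel in (0.02, 0.05, 0.10):
            spec = small_dsa_spec(("utility.aided.severe", "utility"))
            spec.rel_range = rel
            out = one_way_dsa(params, tm, lt, spec=spec)
            widths.append(out.loc[0, "width"])
        assert widths[0] < widths[1] < widths[2]

    def test_range_ends_respect_joint_invariants(self, male_inputs):
        # unaided mild * 1.2 = 0.96 would exceed the aided weight 0.93;
        # the high end must be pulled back to validity
        params, tm, lt = male_inputs
        spec = small_dsa_spec(("utility.unaided.mild", "utility"))
        out = one_way_dsa(params, tm, lt, spec=spec)
        # the low end 0.64 would undercut the moderate weight 0.65, so it is
        # pulled up to that bound
        assert out.loc[0, "high_value"] <= 0.93 + 1e-9
        assert out.loc[0, "low_value"] == pytest.approx(0.65, abs=1e-6)


class TestTornadoOrder:
    def test_descending_widths(self):
        df = pd.DataFrame(
            {
                "parameter": ["a", "b", "c"],
                "inmb_low": [0.0, 0.0, 0.0],
                "inmb_high": [5.0, 1.0, 3.0],
            }
        )
        out = tornado_order(df)
        assert out["parameter"].tolist() == ["a", "c", "b"]

    def test_ties_break_alphabetically(self):
        df = pd.DataFrame(
            {
                "parameter": ["zeta", "alpha", "mid"],
                "inmb_low": [0.0, 0.0, 0.0],
                "inmb_high": [2.0, 2.0, 2.0],
            }
        )
        assert tornado_order(df)["parameter"].tolist() == ["alpha", "mid", "zeta"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "parameter": [f"p{i}" for i in range(8)],
                "inmb_low": rng.normal(size=8),
                "inmb_high": rng.normal(size=8),
            }
        )
        ordered = tornado_order(df)
        shuffled = tornado_order(df.sample(frac=1, random_state=7))
        assert ordered["parameter"].tolist() == shuffled["parameter"].tolist()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tornado_order(pd.DataFrame(columns=["parameter", "inmb_low", "inmb_high"]))


class TestPsa:
    def test_zero_spread_reproduces_deterministic_run(self, male_inputs, base_inmb):
        params, tm, lt = male_inputs
        spec = PsaSpec(
            n_iterations=3, rel_se_probability=0.0, rel_se_cost=0.0, sigma_log_ratio=0.0
        )
        result = run_psa(params, tm, lt, spec, seed=11)
        a = run_arm(params, tm, lt, ArmKind.HA_PLUS_PPS)
        b = run_arm(params, tm, lt, ArmKind.NO_TREATMENT)
        det = compare(a, b)
        for d_cost, d_qaly in result.deltas:
            assert d_cost == pytest.approx(det.delta_cost, abs=1e-9)
            assert d_qaly == pytest.approx(det.delta_qaly, abs=1e-12)

    def test_seed_reproducibility(self, male_inputs):
        params, tm, lt = male_inputs
        spec = PsaSpec(n_iterations=12)
        r1 = run_psa(params, tm, lt, spec, seed=5)
        r2 = run_psa(params, tm, lt, spec, seed=5)
        r3 = run_psa(params, tm, lt, spec, seed=6)
        assert np.array_equal(r1.deltas, r2.deltas)
        assert not np.array_equal(r1.deltas, r3.deltas)

    def test_small_spread_concentrates_on_deterministic_value(self, male_inputs):
        params, tm, lt = male_inputs
        a = run_arm(params, tm, lt, ArmKind.HA_PLUS_PPS)
        b = run_arm(params, tm, lt, ArmKind.NO_TREATMENT)
        det = compare(a, b).delta_qaly
        spreads = []
        for se in (0.05, 0.005):
            spec = PsaSpec(
                n_iterations=25, rel_se_probability=se, rel_se_cost=se, sigma_log_ratio=se
            )
            r = run_psa(params, tm, lt, spec, seed=2)
            spreads.append(abs(r.deltas[:, 1].mean() - det))
        assert spreads[1] < spreads[0]
        assert spreads[1] < 0.01


class TestCeac:
    def test_counts_match_brute_force(self, male_inputs):
        params, tm, lt = male_inputs
        r = run_psa(params, tm, lt, PsaSpec(n_iterations=20), seed=9)
        grid = [0.0, 16265.0, 50000.0]
        curve = ceac(r, grid)
        for wtp, prob in zip(curve.wtp, curve.probability):
            count = sum(
                1 for d_cost, d_qaly in r.deltas if wtp * d_qaly - d_cost > 0
            )
            assert prob == pytest.approx(count / r.n)

    def test_dominant_draws_give_probability_one(self):
        from hacua.sensitivity import PsaResult

        deltas = np.column_stack([-np.ones(10), np.full(10, 0.2)])
        r = PsaResult(deltas=deltas, seed=0, spec_hash="x", arm_pair=(ArmKind.HA_PLUS_PPS, ArmKind.NO_TREATMENT))
        curve = ceac(r, [0, 1000, 1e6])
        assert np.all(curve.probability == 1.0)

    def test_zero_threshold_counts_cost_savings(self):
        from hacua.sensitivity import PsaResult

        rng = np.random.default_rng(0)
        deltas = np.column_stack([rng.normal(0, 1, 50), rng.normal(0, 1, 50)])
        r = PsaResult(deltas=deltas, seed=0, spec_hash="x", arm_pair=(ArmKind.HA_PLUS_PPS, ArmKind.NO_TREATMENT))
        curve = ceac(r, [0.0])
        assert curve.probability[0] == pytest.approx((deltas[:, 0] < 0).mean())

    def test_shuffle_invariance(self, male_inputs):
        from hacua.sensitivity import PsaResult

        params, tm, lt = male_inputs
        r = run_psa(params, tm, lt, PsaSpec(n_iterations=15), seed=4)
        shuffled = PsaResult(
            deltas=np.random.default_rng(1).permutation(r.deltas, axis=0),
            seed=r.seed, spec_hash=r.spec_hash, arm_pair=r.arm_pair,
        )
        grid = np.linspace(0, 40000, 9)
        assert np.array_equal(ceac(r, grid).probability, ceac(shuffled, grid).probability)


@pytest.fixture(scope="module")
def grid(male_inputs):
    params, tm, lt = male_inputs
    return run_scenarios(params, tm, lt)


class TestScenarios:
    def test_full_compliance_forces_uptake(self, male_inputs):
        params, _, _ = male_inputs
        p = apply_dropout_scenario(params, "no_dropout_full_compliance")
        for sev in ("mild", "moderate", "severe"):
            for arm in (ArmKind.HA_PLUS_PPS, ArmKind.HA_ALONE):
                assert uptake_split(p.pathway, sev, arm) == pytest.approx((1, 0, 0, 0))

    def test_grid_shape(self, grid):
        assert len(grid) == 4 * 3 * 3  # cost mixes x dropout scenarios x arm pairs
        assert set(grid["dropout_scenario"]) == {
            "current", "no_dropout_partial_compliance", "no_dropout_full_compliance",
        }

    def test_qaly_gain_monotone_in_uptake(self, grid):
        sub = grid[
            (grid["intervention"] == "ha_plus_pps")
            & (grid["comparator"] == "no_treatment")
            & (grid["cost_mix"] == "base_mix")
        ].set_index("dropout_scenario")["delta_qaly"]
        assert (
            sub["no_dropout_full_compliance"]
            >= sub["no_dropout_partial_compliance"]
            >= sub["current"]
        )

    def test_removing_dropout_raises_inmb(self, grid):
        sub = grid[
            (grid["intervention"] == "ha_plus_pps")
            & (grid["comparator"] == "no_treatment")
            & (grid["cost_mix"] == "base_mix")
        ].set_index("dropout_scenario")["inmb"]
        assert sub["current"] > 0  # positive per-user benefit in the base case
        assert sub["no_dropout_partial_compliance"] > sub["current"]

    def test_unknown_scenario_rejected(self, male_inputs):
        params, _, _ = male_inputs
        with pytest.raises(ValueError):
            apply_dropout_scenario(params, "no_such_scenario")
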