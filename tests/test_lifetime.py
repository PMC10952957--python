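"""Lifetime model: discounting, Markov engine, tree, PSA, scenarios, break-even."""

import numpy as np
import pandas as pd
import pytest

from incentives_cea import lifetime as lt


@pytest.fixture(scope="module")
def params():
    return lt.ModelParams()


@pytest.fixture(scope="module")
def det(params):
    return lt.run_deterministic(params)


class TestPrimitives:
    def test_gaming_adjustment_reproduces_published_deflations(self):
        assert lt.adjust_for_gaming(0.268, 0.11) == pytest.approx(0.239, abs=5e-4)
        assert lt.adjust_for_gaming(0.123, 0.20) == pytest.approx(0.098, abs=5e-4)
        assert lt.adjust_for_gaming(0.123, 0.11) == pytest.approx(0.109, abs=5e-4)
        assert lt.adjust_for_gaming(0.4, 0.0) == 0.4

    def test_discount_factor_closed_forms(self):
        assert lt.discount_factor(7, 0.0) == 1.0
        assert lt.discount_factor(1, 0.035) == pytest.approx(1 / 1.035)
        # constant stream of 1 for T years discounted = geometric series
        T, r = 25, 0.035
        total = sum(lt.discount_factor(t, r) for t in range(1, T + 1))
        closed = (1 - (1 + r) ** -T) / r
        assert total == pytest.approx(closed, rel=1e-12)

    def test_discount_rate_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            lt.discount_factor(1, -1.5)

    @pytest.mark.parametrize(
        "p,method,expected",
        [(0.0, "constant_hazard", 0.0), (0.5, "constant_hazard", 0.75),
         (0.3, "passthrough", 0.3)],
    )
    def test_relapse_extrapolation(self, p, method, expected):
        assert lt.extrapolate_relapse(p, method) == pytest.approx(expected)

    def test_relapse_fixed_injection_and_unknown_method(self):
        assert lt.extrapolate_relapse(0.2, "fixed", fixed_value=0.814) == 0.814
        with pytest.raises(ValueError):
            lt.extrapolate_relapse(0.2, "no_such")


class TestMarkovEngine:
    def test_single_alive_state_accrues_cycle_count(self):
        T = 10
        trans = np.ones((T, 1, 1))
        res = lt.run_markov(trans, np.array([1.0]), np.zeros((T, 1)),
                            np.ones((T, 1)), discount_rate=0.0, year_offset=0.0)
        assert res["qaly"] == pytest.approx(10.0)

    def test_all_dead_at_start_accrues_nothing(self):
        T = 5
        trans = np.zeros((T, 2, 2))
        trans[:, 0, 1] = 1.0  # alive -> dead immediately
        trans[:, 1, 1] = 1.0
        res = lt.run_markov(trans, np.array([0.0, 1.0]),
                            np.full((T, 2), 100.0) * [1, 0],
                            np.ones((T, 2)) * [1, 0], 0.0)
        assert res["cost"] == 0.0 and res["qaly"] == 0.0

    def test_constant_mortality_matches_geometric_life_expectancy(self):
        m, T = 0.2, 400
        trans = np.zeros((T, 2, 2))
        trans[:, 0] = [1 - m, m]
        trans[:, 1] = [0.0, 1.0]
        res = lt.run_markov(trans, np.array([1.0, 0.0]), np.zeros((T, 2)),
                            np.tile([1.0, 0.0], (T, 1)), 0.0, year_offset=0.0)
        # sum_{t>=0} (1-m)^t = 1/m
        assert res["qaly"] == pytest.approx(1 / m, rel=1e-6)

    def test_bad_transition_row_rejected(self):
        trans = np.ones((1, 2, 2)) * 0.4
        with pytest.raises(ValueError, match="sum to 1"):
            lt.run_markov(trans, np.array([1.0, 0.0]), np.zeros((1, 2)),
                          np.zeros((1, 2)), 0.0)

    def test_mass_conserved_and_no_negative_occupancy(self, params):
        for arm in ("incentives", "control"):
            model = lt.build_mother_model(params, arm)
            res = lt.run_markov(model["transitions"], model["start_occ"],
                                model["cost_rewards"], model["utility_rewards"],
                                params.discount_rate)
            sums = res["trace"].sum(axis=1)
            assert np.allclose(sums, params.cohort_size, rtol=1e-9)
            assert (res["trace"] >= -1e-12).all()

    def test_zero_discount_equals_straight_sum(self, params):
        model = lt.build_mother_model(params, "incentives")
        res = lt.run_markov(model["transitions"], model["start_occ"],
                            model["cost_rewards"], model["utility_rewards"], 0.0)
        manual = sum(
            float(res["trace"][t] @ model["utility_rewards"][t])
            for t in range(len(model["transitions"]))
        )
        assert res["qaly"] == pytest.approx(manual, rel=1e-12)


class TestPregnancyTree:
    def test_equal_quit_rates_give_zero_incrementals(self, params):
        p = params.copy()
        p.quit_rate = {"incentives": 0.2, "control": 0.2}
        p.intervention_cost = {"incentives": 100.0, "control": 100.0}
        a = lt.run_pregnancy_tree(p, "incentives")
        b = lt.run_pregnancy_tree(p, "control")
        assert a["mother_cost"] == pytest.approx(b["mother_cost"])
        assert a["adverse_live_births"] == pytest.approx(b["adverse_live_births"])

    def test_two_branch_enumeration(self):
        p = lt.ModelParams(
            cohort_size=100,
            quit_rate={"incentives": 0.5, "control": 0.1},
            intervention_cost={"incentives": 10.0, "control": 0.0},
            pregnancy_outcome_probs={
                "quit": {"normal": 1.0, "adverse_live": 0.0, "adverse_pregnancy": 0.0},
                "smoker": {"normal": 0.0, "adverse_live": 1.0, "adverse_pregnancy": 0.0},
            },
            pregnancy_outcome_cost_mother={"normal": 0.0, "adverse_live": 100.0, "adverse_pregnancy": 0.0},
        )
        tree = lt.run_pregnancy_tree(p, "incentives")
        # 50 smokers x £100 adverse cost + 100 x £10 intervention
        assert tree["mother_cost"] == pytest.approx(100 * 10.0 + 50 * 100.0)
        assert tree["adverse_live_births"] == pytest.approx(50.0)

    def test_higher_quit_rate_never_raises_adverse_counts(self, params):
        p = params.copy()
        counts = []
        for q in (0.1, 0.2, 0.3, 0.4):
            p.quit_rate["incentives"] = q
            t = lt.run_pregnancy_tree(p, "incentives")
            counts.append((t["adverse_live_births"], t["adverse_pregnancy_outcomes"]))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_outcome_probabilities_rejected(self, params):
        p = params.copy()
        p.pregnancy_outcome_probs["quit"]["normal"] = 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            lt.run_pregnancy_tree(p, "incentives")


class TestStructure:
    def test_combined_is_maternal_plus_infant_with_single_intervention_charge(self, det):
        r = det.set_index("section")
        for col in ("delta_cost", "delta_qaly"):
            assert r.loc["combined", col] == pytest.approx(
                r.loc["maternal_lifetime", col] + r.loc["infant_adulthood", col],
                rel=1e-12,
            )

    def test_dominance_label_iff_cost_saving_and_qaly_gaining(self, det):
        for _, row in det.iterrows():
            expect = row["delta_cost"] < 0 and row["delta_qaly"] > 0
            assert (row["label"] == "dominant") == expect

    def test_combined_delta_qaly_monotone_in_incentives_quit_rate(self, params):
        deltas = []
        for q in (0.15, 0.22, 0.268, 0.35):
            p = params.copy()
            p.quit_rate["incentives"] = q
            r = lt.run_deterministic(p).set_index("section")
            deltas.append(r.loc["combined", "delta_qaly"])
        assert all(a < b for a, b in zip(deltas, deltas[1:]))

    def test_identical_arms_give_zero_incrementals(self, params):
        p = params.copy()
        p.quit_rate["incentives"] = p.quit_rate["control"]
        p.intervention_cost["incentives"] = p.intervention_cost["control"]
        r = lt.run_deterministic(p).set_index("section")
        assert r["delta_cost"].abs().max() < 1e-9
        assert r["delta_qaly"].abs().max() < 1e-9

    def test_break_even_intervention_cost_exists_and_is_exact(self, params):
        be = lt.break_even_intervention_cost(params)
        assert be > params.intervention_cost["control"]
        p = params.copy()
        p.intervention_cost["incentives"] = be
        r = lt.run_deterministic(p).set_index("section")
        assert r.loc["combined", "delta_cost"] == pytest.approx(0.0, abs=1e-6)
        # just below break-even the strategy is dominant (QALY gain positive)
        p.intervention_cost["incentives"] = be - 1.0
        r = lt.run_deterministic(p).set_index("section")
        assert r.loc["combined", "label"] == "dominant"


class TestPsa:
    def test_degenerate_distributions_reproduce_deterministic_run(self, params):
        p = params.copy()
        p.quit_rate_se = {"incentives": 0.0, "control": 0.0}
        p.intervention_cost_se = {"incentives": 0.0, "control": 0.0}
        p.relapse_1yr_se = 0.0
        p.state_cost_cv = 0.0
        p.state_utility_se = 0.0
        det = lt.run_deterministic(p).set_index("section")
        psa = lt.run_psa(p, 5, seed=3)
        s = psa["samples"]["combined"]
        assert np.allclose(s["delta_cost"], det.loc["combined", "delta_cost"])
        assert np.allclose(s["delta_qaly"], det.loc["combined", "delta_qaly"])

    def test_seed_reproducible(self, params):
        a = lt.run_psa(params, 20, seed=9)["samples"]["combined"]
        b = lt.run_psa(params, 20, seed=9)["samples"]["combined"]
        pd.testing.assert_frame_equal(a, b)

    def test_probability_cost_effective_approaches_one_as_threshold_grows(self, params):
        psa = lt.run_psa(params, 100, seed=4)
        s = psa["samples"]["combined"]
        assert (s["delta_qaly"] > 0).all()
        lam = 10_000_000.0
        nmb = lam * s["delta_qaly"] - s["delta_cost"]
        assert (nmb > 0).all()

    def test_interval_halfwidth_shrinks_with_sample_size(self, params):
        """Monte-Carlo error of the mean Δcost scales like 1/sqrt(n)."""
        a = lt.run_psa(params, 100, seed=5)["samples"]["combined"]["delta_cost"]
        b = lt.run_psa(params, 400, seed=5)["samples"]["combined"]["delta_cost"]
        se_a = a.std(ddof=1) / np.sqrt(len(a))
        se_b = b.std(ddof=1) / np.sqrt(len(b))
        assert se_b == pytest.approx(se_a / 2.0, rel=0.35)

    def test_method_of_moments_families(self):
        a, b = lt.beta_mm(0.268, 0.020)
        assert a / (a + b) == pytest.approx(0.268)
        assert a * b / ((a + b) ** 2 * (a + b + 1)) == pytest.approx(0.020 ** 2)
        shape, scale = lt.gamma_mm(262.0, 11.7)
        assert shape * scale == pytest.approx(262.0)
        assert shape * scale ** 2 == pytest.approx(11.7 ** 2)
        assert lt.beta_mm(0.5, 0.0) is None
        with pytest.raises(ValueError, match="support"):
            lt.beta_mm(0.5, 0.6)


class TestScenarioRegistry:
    def test_substitutions(self, params):
        p = lt.scenario_params(params, "S1a")
        assert p.quit_rate["incentives"] == pytest.approx(0.268 * 0.89)
        assert p.quit_rate["control"] == pytest.approx(0.123 * 0.80)
        p = lt.scenario_params(params, "S3a")
        assert p.intervention_cost["incentives"] == 131.0
        assert p.quit_rate == {"incentives": 0.046, "control": 0.025}
        p = lt.scenario_params(params, "S3b")
        assert p.intervention_cost["incentives"] == 463.0
        assert p.quit_rate["incentives"] == 0.34
        assert p.quit_rate["control"] == params.quit_rate["control"]
        p = lt.scenario_params(params, "S4")
        assert p.relapse_1yr == 0.814
        with pytest.raises(ValueError):
            lt.scenario_params(params, "S9")

    def test_scenario_table_runs_and_labels(self, params):
        table = lt.run_all_scenarios(params, ("base", "S1a", "S4"))
        assert list(table["scenario"]) == ["base", "S1a", "S4"]
        for _, row in table.iterrows():
            expect = row["delta_cost"] < 0 and row["delta_qaly"] > 0
            assert (row["label"] == "dominant") == expect
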