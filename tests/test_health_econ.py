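import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialcea.data_model import EconConfig, TrialDataset, WAVES
from trialcea.health_econ import (
    bootstrap_cea,
    break_even_programme_price,
    ceac_curve,
    compute_qalys,
    cost_components,
    cost_participant,
    incremental_analysis,
    mnar_scenarios,
    one_way_sa,
    participant_totals,
    qalys_per_participant,
)

TIMES = [0.0, 0.1725, 0.6725, 2.1725]


def _totals(dc_cost, dc_qaly, pe_cost, pe_qaly, n=40):
    rows = []
    for arm, c, q in (("dCBT-I", dc_cost, dc_qaly), ("PE", pe_cost, pe_qaly)):
        for i in range(n):
            rows.append(
                {"participant_id": f"{arm}{i}", "arm": arm, "cost": c, "qaly": q}
            )
    return pd.DataFrame(rows)


class TestQALY:
    def test_constant_utility_times_horizon(self):
        assert compute_qalys([0.6] * 4, TIMES) == pytest.approx(0.6 * 2.1725)

    def test_two_point_trapezoid(self):
        assert compute_qalys([0.6, 0.8], [0.0, 1.0]) == pytest.approx(0.7)

    def test_missing_intermediate_wave_uses_observed_points(self):
        full = compute_qalys([0.6, np.nan, 0.6, 0.6], TIMES)
        assert full == pytest.approx(0.6 * 2.1725)

    def test_fewer_than_two_points_is_undefined(self):
        assert np.isnan(compute_qalys([0.6, np.nan, np.nan, np.nan], TIMES))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            compute_qalys([0.5, 0.6], [1.0, 1.0])

    @given(
        st.lists(st.floats(0.29, 1.0), min_size=4, max_size=4),
        st.lists(st.floats(0.29, 1.0), min_size=4, max_size=4),
        st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_trapezoid_linearity(self, u1, u2, lam):
        """QALY of a convex combination equals the combination of QALYs."""
        mix = [lam * a + (1 - lam) * b for a, b in zip(u1, u2)]
        assert compute_qalys(mix, TIMES) == pytest.approx(
            lam * compute_qalys(u1, TIMES) + (1 - lam) * compute_qalys(u2, TIMES),
            abs=1e-10,
        )

    def test_qaly_of_mean_trajectory_equals_mean_of_qalys(self, small_trial, econ_cfg):
        _, ds = small_trial
        per_person = qalys_per_participant(ds, econ_cfg)
        mean_traj = ds.wide("sf6d").mean(axis=0).to_numpy()
        assert compute_qalys(mean_traj, econ_cfg.times) == pytest.approx(
            per_person.mean(), abs=1e-10
        )


def _zero_use_trial():
    rows = []
    for arm in ("dCBT-I", "PE"):
        for w in WAVES:
            rows.append(
                {
                    "participant_id": f"{arm}-p", "arm": arm, "wave": w,
                    "sf6d": 0.6, "employed": 0,
                    "gp_visit": 0, "psychiatrist_visit": 0,
                    "specialist_visit": 0, "sleepmed_use": 0,
                }
            )
    return TrialDataset(pd.DataFrame(rows))


class TestCosts:
    def test_zero_resource_use_leaves_programme_cost_only(self, econ_cfg):
        ds = _zero_use_trial()
        entry_pe = cost_participant(ds, "PE-p", econ_cfg)
        assert entry_pe.total("societal") == pytest.approx(23.80)
        entry_dcbt = cost_participant(ds, "dCBT-I-p", econ_cfg)
        assert entry_dcbt.total("societal") == pytest.approx(70.16)
        assert entry_dcbt.total("societal") - entry_pe.total("societal") == pytest.approx(46.36)

    def test_hours_times_wage_currency_arithmetic(self, econ_cfg):
        # 1 h/week for 52 weeks at 350 NOK/h
        assert 52 * 350 / econ_cfg.nok_per_eur == pytest.approx(1847.7, abs=0.05)

    def test_perspective_masks_partition_societal_total(self, small_trial, econ_cfg):
        _, ds = small_trial
        comp = cost_components(ds, econ_cfg)
        societal = comp[["programme", "medical", "productivity", "out_of_pocket"]].sum(axis=1)
        totals = participant_totals(ds, econ_cfg, "societal")
        assert np.allclose(totals.set_index("participant_id")["cost"], societal)

    def test_patient_perspective_drops_exactly_the_non_patient_components(
        self, small_trial, econ_cfg
    ):
        _, ds = small_trial
        soc = participant_totals(ds, econ_cfg, "societal").set_index("participant_id")
        pat = participant_totals(ds, econ_cfg, "patient").set_index("participant_id")
        dropped = soc["cost"] - pat["cost"]
        assert np.allclose(dropped, soc["medical"] + soc["productivity"])

    def test_missing_unit_cost_is_config_error(self, small_trial):
        from trialcea.data_model import ConfigError

        _, ds = small_trial
        cfg = EconConfig()
        del cfg.unit_costs["gp_visit"]
        with pytest.raises(ConfigError, match="gp_visit"):
            cost_components(ds, cfg)


class TestIncrementalAndBootstrap:
    def test_printed_group_means_difference(self):
        inc = incremental_analysis(_totals(6183.0, 1.336, 6461.0, 1.310))
        assert inc.delta_cost == pytest.approx(-278.0)
        assert inc.delta_qaly == pytest.approx(0.026, abs=1e-9)

    def test_identical_arms_give_zero_increments(self):
        inc = incremental_analysis(_totals(100.0, 1.0, 100.0, 1.0))
        assert inc.delta_cost == pytest.approx(0.0, abs=1e-10)
        assert inc.delta_qaly == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_bootstrap_is_step_function(self, econ_cfg):
        tot = _totals(500.0, 1.2, 600.0, 1.1)  # every participant identical in arm
        ce = bootstrap_cea(tot, econ_cfg, B=50, seed=1)
        assert ce.quadrant == "dominant"
        assert (ce.replicates["delta_cost"] == -100.0).all()
        assert all(v == 1.0 for v in ce.ceac.values())  # dominant everywhere

    def test_ceac_boundary_identities(self, small_trial, econ_cfg):
        _, ds = small_trial
        tot = participant_totals(ds, econ_cfg)
        ce = bootstrap_cea(tot, econ_cfg, B=300, seed=5)
        reps = ce.replicates
        assert ce.ceac[0.0] == pytest.approx((reps["delta_cost"] <= 0).mean())
        lam_inf = 1e12
        big = ceac_curve(reps, [lam_inf])[lam_inf]
        frac_pos = (
            (reps["delta_qaly"] > 0)
            | ((reps["delta_qaly"] == 0) & (reps["delta_cost"] <= 0))
        ).mean()
        assert big == pytest.approx(frac_pos)

    def test_bootstrap_bit_reproducible(self, small_trial, econ_cfg):
        _, ds = small_trial
        tot = participant_totals(ds, econ_cfg)
        a = bootstrap_cea(tot, econ_cfg, B=100, seed=9)
        b = bootstrap_cea(tot, econ_cfg, B=100, seed=9)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_doubling_reps_shrinks_ceac_monte_carlo_error(self, small_trial, econ_cfg):
        _, ds = small_trial
        tot = participant_totals(ds, econ_cfg)
        lam = 30000.0

        def mc_sd(B, seeds):
            vals = [
                bootstrap_cea(tot, econ_cfg, B=B, seed=s).prob_cost_effective
                for s in seeds
            ]
            return np.std(vals)

        sd_small = mc_sd(100, range(20))
        sd_big = mc_sd(400, range(20, 40))
        # quadrupling B should roughly halve the MC SD
        assert sd_big < sd_small

    def test_nmb_arithmetic_on_published_values(self, econ_cfg):
        tot = _totals(6183.0, 1.336 + 0.025 - 0.026, 6461.0, 1.310)
        ce = bootstrap_cea(tot, econ_cfg, B=10, seed=1)
        assert ce.nmb(30000.0) == pytest.approx(30000 * 0.025 + 278.0, abs=1e-6)

    def test_b_below_one_rejected(self, econ_cfg):
        with pytest.raises(ValueError):
            bootstrap_cea(_totals(1.0, 1.0, 1.0, 1.0), econ_cfg, B=0)


class TestDeterministicSensitivity:
    def test_break_even_closed_form(self):
        assert break_even_programme_price(0.05, 30000.0, -100.0, 0.0) == pytest.approx(1600.0)
        assert break_even_programme_price(0.025, 30000.0, -324.36, 23.80) == pytest.approx(
            1098.16
        )

    def test_break_even_undefined_for_nonpositive_qaly_gain(self):
        with pytest.raises(ValueError):
            break_even_programme_price(0.0, 30000.0, 0.0, 0.0)

    def test_programme_price_at_break_even_gives_icer_equal_wtp(self, econ_cfg):
        tot = _totals(6183.0, 1.336, 6461.0, 1.310)
        sa = one_way_sa(tot, econ_cfg, "programme_cost_dCBT-I", values=[70.16])
        assert sa.threshold_defined
        fixed = one_way_sa(tot, econ_cfg, "programme_cost_dCBT-I", values=[sa.threshold])
        assert fixed.table["icer"].iloc[0] == pytest.approx(30000.0, rel=1e-9)

    def test_medical_uplift_threshold_fixed_point(self, small_trial, econ_cfg):
        _, ds = small_trial
        tot = participant_totals(ds, econ_cfg)
        sa = one_way_sa(tot, econ_cfg, "medical_costs_dCBT-I", values=[1.0, 1.5])
        if sa.threshold is not None:
            at = one_way_sa(
                tot, econ_cfg, "medical_costs_dCBT-I", values=[sa.threshold]
            )
            assert at.table["icer"].iloc[0] == pytest.approx(30000.0, rel=1e-6)

    def test_unknown_component_rejected(self, econ_cfg):
        with pytest.raises(ValueError):
            one_way_sa(_totals(1, 1, 1, 1), econ_cfg, "informal_care", values=[1.0])


class TestMNARScenarios:
    def test_null_scenario_reproduces_base_case(self, econ_cfg):
        tot = _totals(500.0, 1.2, 600.0, 1.1)
        base = bootstrap_cea(tot, econ_cfg, B=50, seed=2)
        grid = mnar_scenarios(tot, econ_cfg, qaly_cuts=(0.0,), cost_uplifts=(0.0,), B=50, seed=2)
        assert grid["delta_cost"].iloc[0] == pytest.approx(base.delta_cost)
        assert grid["delta_qaly"].iloc[0] == pytest.approx(base.delta_qaly)
        assert grid["prob_cost_effective"].iloc[0] == base.prob_cost_effective

    def test_cost_uplift_monotone_in_delta_cost(self, econ_cfg):
        tot = _totals(500.0, 1.2, 600.0, 1.1)
        grid = mnar_scenarios(
            tot, econ_cfg, qaly_cuts=(0.05,), cost_uplifts=(0.05, 0.10, 0.20), B=20, seed=2
        )
        assert grid["delta_cost"].is_monotonic_increasing

    def test_first_cell_losing_cost_effectiveness_matches_brute_force(
        self, small_trial, econ_cfg
    ):
        _, ds = small_trial
        tot = participant_totals(ds, econ_cfg)
        cuts, ups = (0.0, 0.05, 0.10), (0.0, 0.10, 0.20)
        grid = mnar_scenarios(tot, econ_cfg, qaly_cuts=cuts, cost_uplifts=ups, B=100, seed=4)

        def brute(q, c):
            mod = tot.copy()
            mask = mod["arm"] == "dCBT-I"
            mod.loc[mask, "qaly"] *= 1 - q
            mod.loc[mask, "cost"] *= 1 + c
            return bootstrap_cea(mod, econ_cfg, B=100, seed=4).prob_cost_effective

        for _, row in grid.iterrows():
            assert row["prob_cost_effective"] == pytest.approx(
                brute(row["qaly_cut"], row["cost_uplift"])
            )
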