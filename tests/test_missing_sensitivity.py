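import numpy as np
import pandas as pd
import pytest

from trialcea.change_models import fit_change_model
from trialcea.data_model import TrialDataset
from trialcea.missing_sensitivity import (
    PooledEstimate,
    mi_impute,
    pmm_weighted_estimate,
    pooled_change_contrast,
    rubin_pool,
    stratify_patterns,
    tipping_point,
)
from trialcea.synthetic_trial import (
    apply_dropout,
    generate_trial,
    planted_effect_config,
)


class TestRubinPool:
    def test_no_between_variance(self):
        r = rubin_pool([1.0, 1.0, 1.0], [0.04, 0.04, 0.04])
        assert r.estimate == 1.0
        assert r.between == 0.0
        assert r.total == pytest.approx(0.04)

    def test_hand_example(self):
        r = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert r.estimate == 2.0
        assert r.between == pytest.approx(1.0)
        assert r.total == pytest.approx(1.0 + (4.0 / 3.0), abs=1e-9)

    def test_permutation_invariance(self):
        a = rubin_pool([1.0, 2.0, 3.0, 4.0], [0.5, 0.6, 0.7, 0.8])
        b = rubin_pool([3.0, 1.0, 4.0, 2.0], [0.7, 0.5, 0.8, 0.6])
        assert a.estimate == b.estimate
        assert a.total == pytest.approx(b.total)
        assert a.p == pytest.approx(b.p)

    def test_pooled_estimate_is_mean(self):
        q = [0.3, -0.2, 0.8, 0.1, 0.4]
        r = rubin_pool(q, [0.1] * 5)
        assert r.estimate == pytest.approx(np.mean(q))

    def test_barnard_rubin_df_capped_by_complete_df(self):
        r = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], df_complete=50)
        assert r.df < 50

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            rubin_pool([1.0, 2.0], [1.0])


class TestPatternMixture:
    def test_stratum_weights_sum_to_one(self, small_trial_dropout):
        _, ds = small_trial_dropout
        for scheme in ("completeness", "completeness×arm"):
            strat = stratify_patterns(ds, "isi", scheme)
            assert sum(strat.weights.values()) == pytest.approx(1.0)

    def test_complete_definition_requires_both_followups(self, small_trial_dropout):
        _, ds = small_trial_dropout
        strat = stratify_patterns(ds, "isi")
        wide = ds.wide("isi")
        complete_ids = strat.assignment.index[strat.assignment == "complete"]
        assert wide.loc[complete_ids, ["6mo", "2yr"]].notna().all().all()

    def test_identical_stratum_estimates_average_to_themselves(self):
        # weighted average of equal estimates is that estimate, any weights
        est = [-4.0, -4.0]
        w = [0.6, 0.4]
        assert sum(wi * ei for wi, ei in zip(w, est)) == pytest.approx(-4.0)
        est = [-4.0, -2.0]
        assert sum(wi * ei for wi, ei in zip(w, est)) == pytest.approx(-3.2)

    def test_no_missingness_pmm_equals_primary_model(self, small_trial):
        _, ds = small_trial
        primary = fit_change_model(ds, "isi")
        rep = pmm_weighted_estimate(ds, "isi")
        # single "complete" stratum with weight 1
        assert rep.weights == {"complete": 1.0}
        for w in ("6mo", "2yr"):
            assert rep.weighted[w].estimate == pytest.approx(
                primary.contrasts[w].estimate, abs=1e-8
            )

    def test_pmm1_close_to_primary_under_mar(self, small_trial_dropout):
        _, ds = small_trial_dropout
        primary = fit_change_model(ds, "isi")
        rep = pmm_weighted_estimate(ds, "isi")
        # both consistent for the same estimand under MAR; one small trial so
        # allow a generous but bounded discrepancy
        assert rep.weighted["2yr"].estimate == pytest.approx(
            primary.contrasts["2yr"].estimate, abs=1.5
        )

    def test_pmm2_reports_four_strata(self, small_trial_dropout):
        _, ds = small_trial_dropout
        rep = pmm_weighted_estimate(ds, "isi", scheme="completeness×arm")
        assert len(rep.stratum_estimates) == 4
        assert set(rep.weighted) == {"6mo", "2yr"}


class TestMultipleImputation:
    def test_no_missing_values_returns_identical_datasets(self, small_trial):
        _, ds = small_trial
        out = mi_impute(ds, m=2, seed=5)
        for c in out:
            pd.testing.assert_frame_equal(c.df, ds.df)

    def test_pmm_never_invents_values(self, small_trial_dropout):
        _, ds = small_trial_dropout
        completed = mi_impute(ds, m=2, seed=7)
        for var in ("isi", "sf6d", "gp_visit"):
            orig = ds.wide(var)
            for c in completed:
                filled = c.wide(var)
                for wave in ("post", "6mo", "2yr"):
                    was_missing = orig[wave].isna()
                    if not was_missing.any():
                        continue
                    observed = set(orig[wave].dropna())
                    assert set(filled.loc[was_missing, wave]).issubset(observed)

    def test_seed_determinism(self, small_trial_dropout):
        _, ds = small_trial_dropout
        a = mi_impute(ds, m=2, seed=9)
        b = mi_impute(ds, m=2, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.df, y.df)

    def test_imputations_differ_between_draws(self, small_trial_dropout):
        _, ds = small_trial_dropout
        a, b = mi_impute(ds, m=2, seed=11)
        assert not a.df["isi"].equals(b.df["isi"])

    def test_pooled_mi_contrast_close_to_likelihood_estimate(self, small_trial_dropout):
        _, ds = small_trial_dropout
        direct = fit_change_model(ds, "isi").contrasts["2yr"]
        pooled = pooled_change_contrast(mi_impute(ds, m=10, seed=13), "isi", "2yr")
        assert pooled.estimate == pytest.approx(direct.estimate, abs=3 * direct.se)

    def test_mi_confidence_interval_coverage_under_mar(self):
        """Rubin-pooled 95% CIs cover the planted 2-year effect at the
        nominal rate over repeated MAR trials (scaled-down problem size)."""
        truth = -1.77
        hits = 0
        n_rep = 200
        for r in range(n_rep):
            cfg = planted_effect_config(
                seed=10_000 + r, n_per_arm={"dCBT-I": 150, "PE": 150}
            )
            ds = apply_dropout(generate_trial(cfg), cfg)
            completed = mi_impute(
                ds, m=10, seed=20_000 + r, variables=("isi",), iterations=5
            )
            ests, varis = [], []
            for c in completed:
                wide = c.wide("isi")
                arm = c.arm_of().reindex(wide.index)
                ch = wide["2yr"] - wide["baseline"]
                d = ch[arm == "dCBT-I"].mean() - ch[arm == "PE"].mean()
                v = ch[arm == "dCBT-I"].var() / (arm == "dCBT-I").sum() + ch[
                    arm == "PE"
                ].var() / (arm == "PE").sum()
                ests.append(d)
                varis.append(v)
            pooled = rubin_pool(ests, varis, df_complete=298)
            if pooled.ci_low <= truth <= pooled.ci_high:
                hits += 1
        assert 0.92 <= hits / n_rep <= 0.98


class TestTippingPoint:
    def test_zero_delta_reproduces_mar_estimate(self, small_trial_dropout):
        _, ds = small_trial_dropout
        tp = tipping_point(ds, "isi", delta_grid=np.arange(0, 1.01, 0.25), m=4, seed=3)
        assert tp.estimates[0] == pytest.approx(tp.mar_estimate)
        direct = fit_change_model(ds, "isi").contrasts["2yr"]
        assert tp.mar_estimate == pytest.approx(direct.estimate, abs=3 * direct.se)

    def test_estimates_attenuate_monotonically(self, small_trial_dropout):
        _, ds = small_trial_dropout
        tp = tipping_point(ds, "isi", delta_grid=np.arange(0, 3.01, 0.5), m=4, seed=3)
        sign = np.sign(tp.mar_estimate)
        assert np.all(np.diff(sign * tp.estimates) <= 1e-12)
        same_sign = np.sign(tp.estimates) == sign
        assert np.all(np.diff(np.abs(tp.estimates[same_sign])) <= 1e-12)

    def test_complete_data_is_delta_invariant(self, small_trial):
        _, ds = small_trial
        tp = tipping_point(ds, "isi", delta_grid=np.array([0.0, 1.0, 3.0]), m=2, seed=3)
        assert tp.imputed_fraction == 0.0
        assert np.allclose(tp.estimates, tp.estimates[0])
        # planted effect is significant on the full complete sample or not;
        # either way delta* cannot sit strictly inside the grid
        assert tp.delta_star in (None, 0.0)

    def test_attenuated_estimate_at_star_smaller_than_mar(self):
        cfg = planted_effect_config(seed=77)  # full sample size
        ds = apply_dropout(generate_trial(cfg), cfg)
        tp = tipping_point(ds, "isi", delta_grid=np.arange(0, 3.01, 0.1), m=4, seed=5)
        assert tp.delta_star is not None and tp.delta_star > 0
        assert abs(tp.estimate_at_star) < abs(tp.mar_estimate)

    def test_bad_grid_rejected(self, small_trial_dropout):
        _, ds = small_trial_dropout
        with pytest.raises(ValueError):
            tipping_point(ds, "isi", delta_grid=np.array([0.5, 0.2]), m=2)
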