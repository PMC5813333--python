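"""Composite level assignment and the proportional-odds hospital model."""

import numpy as np
import pandas as pd
import pytest

import hospbench as hb
from hospbench.ordinal import fit_proportional_odds, proportional_odds_loglik

from conftest import tiny_records


class TestLevelAssignment:
    @pytest.mark.parametrize(
        "died,long_los,readm,expected",
        [
            (0, 0, 0, 1),
            (0, 1, 0, 2),
            (0, 0, 1, 3),
            (0, 1, 1, 4),
            (1, 0, 0, 5),
            (1, 1, 0, 5),   # death dominates long LOS
        ],
    )
    def test_mapping(self, died, long_los, readm, expected):
        out = hb.assign_composite_level([died], [long_los], [readm])
        assert out.tolist() == [expected]

    def test_missing_readmission_for_deaths_is_level_5(self):
        out = hb.assign_composite_level(
            [1, 0], [1, 0], pd.array([pd.NA, 0], dtype="Int8")
        )
        assert out.tolist() == [5, 1]


class TestLoglik:
    def test_single_record_at_threshold_zero_gives_log_half(self):
        ll = proportional_odds_loglik([0.0], [], np.zeros((1, 0)), [1])
        assert ll == pytest.approx(np.log(0.5))

    def test_threshold_shift_changes_loglik(self):
        X = np.zeros((4, 0))
        lv = np.array([1, 2, 2, 3])
        a = proportional_odds_loglik([-0.5, 0.8], [], X, lv)
        b = proportional_odds_loglik([0.5, 1.8], [], X, lv)
        assert a != b

    def test_nonincreasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            proportional_odds_loglik([1.0, 0.5], [], np.zeros((1, 0)), [1])

    def test_fitted_optimum_beats_random_perturbations(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, (60, 1)).astype(float)
        lv = rng.integers(1, 4, 60)
        fit = fit_proportional_odds(X, lv, n_levels=3)
        best = proportional_odds_loglik(fit.thresholds, fit.beta, X, lv)
        for _ in range(100):
            d_th = rng.normal(0, 0.05, 2)
            th = np.sort(fit.thresholds + d_th)
            if th[1] - th[0] < 1e-6:
                continue
            ll = proportional_odds_loglik(th, fit.beta + rng.normal(0, 0.05, 1), X, lv)
            assert ll <= best + 1e-9


class TestFitter:
    def test_matches_brute_force_grid_oracle(self):
        # tiny instance: 2 hospitals, 30 records, 3 levels, one dummy covariate
        rng = np.random.default_rng(5)
        X = np.array([0] * 15 + [1] * 15, dtype=float).reshape(-1, 1)
        lv = rng.integers(1, 4, 30)
        fit = fit_proportional_odds(X, lv, n_levels=3)

        from scipy.optimize import minimize
        from scipy.stats import logistic

        def neg_ll(p):  # independent likelihood written from the definition
            t1, t2, b = p
            if t2 <= t1:
                return 1e9
            eta = X[:, 0] * b
            c1 = logistic.cdf(t1 - eta)
            c2 = logistic.cdf(t2 - eta)
            P = np.where(lv == 1, c1, np.where(lv == 2, c2 - c1, 1 - c2))
            return -np.sum(np.log(np.maximum(P, 1e-300)))

        best = None
        for t1 in np.linspace(-2, 2, 5):
            for dt in (0.5, 1.5):
                for b in (-1.0, 0.0, 1.0):
                    r = minimize(neg_ll, [t1, t1 + dt, b], method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12,
                                          "maxiter": 5000})
                    if best is None or r.fun < best.fun:
                        best = r
        ours = np.concatenate([fit.thresholds, fit.beta])
        assert np.max(np.abs(ours - best.x)) < 1e-4

    def test_agrees_with_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(6)
        n = 1500
        hosp = rng.integers(0, 3, n)
        sex = rng.integers(0, 2, n)
        eta = 0.4 * (hosp == 1) - 0.3 * (hosp == 2) + 0.25 * sex
        y = np.digitize(eta + rng.logistic(0, 1, n), [-1.0, 0.5, 1.5]) + 1
        X = np.column_stack([(hosp == 1), (hosp == 2), sex]).astype(float)
        fit = fit_proportional_odds(X, y, n_levels=4)
        om = OrderedModel(
            pd.Series(y).astype("category").cat.as_ordered(), X, distr="logit"
        ).fit(method="bfgs", disp=False)
        sm_beta = np.asarray(om.params)[:3]
        sm_th = om.model.transform_threshold_params(np.asarray(om.params)[3:])[1:-1]
        assert np.allclose(fit.beta, sm_beta, atol=2e-3)
        assert np.allclose(fit.thresholds, sm_th, atol=2e-3)
        assert np.allclose(fit.beta_se(), np.asarray(om.bse)[:3], rtol=1e-2)

    def test_two_identical_hospitals_have_near_zero_difference(self):
        cfg = hb.scenario_preset("null", n_hospitals=2, volume_range=(3000, 3000),
                                 seed=14)
        rec, _ = hb.generate_cohort(cfg)
        flags, _ = hb.long_los_flags(rec)
        lv = hb.assign_composite_level(rec["died"], flags, rec["readmitted_30d"])
        res = hb.HospitalOrdinalModel(rec, levels=lv).fit()
        assert abs(res.hospital_effects["coef"]).max() < 0.2

    def test_collapsing_middle_levels_brackets_thresholds(self, coupled_cohort):
        records, _, _ = coupled_cohort
        lv = hb.assign_composite_level(records["died"], records["long_los"],
                                       records["readmitted_30d"])
        full = hb.HospitalOrdinalModel(records, levels=lv).fit()
        collapsed_lv = np.where(lv == 1, 1, np.where(lv == 5, 3, 2))
        coll = hb.HospitalOrdinalModel(records, levels=collapsed_lv).fit()
        lo, hi = full.thresholds[0], full.thresholds[3]
        assert lo - 0.2 <= coll.thresholds[0] <= coll.thresholds[1] <= hi + 0.2
        assert coll.thresholds[0] == pytest.approx(lo, abs=0.2)
        assert coll.thresholds[1] == pytest.approx(hi, abs=0.2)

    def test_degenerate_levels_rejected(self):
        rec = tiny_records(n=40, seed=9)
        with pytest.raises(ValueError):
            hb.HospitalOrdinalModel(rec, levels=np.ones(40, dtype=int)).fit()

    def test_single_hospital_rejected(self):
        rec = tiny_records(n=40, seed=9, n_hospitals=1)
        with pytest.raises(ValueError):
            hb.HospitalOrdinalModel(rec, levels=np.ones(40, dtype=int))


class TestStandardization:
    def test_equal_coefficients_give_100(self):
        rates = hb.standardized_composite_rate({"a": 0.7, "b": 0.7, "c": 0.7})
        assert all(v == pytest.approx(100.0) for v in rates.values())

    def test_two_hospital_example(self):
        rates = hb.standardized_composite_rate({"a": 0.0, "b": np.log(4.0)})
        assert rates["a"] == pytest.approx(50.0)
        assert rates["b"] == pytest.approx(200.0)

    def test_geometric_mean_is_one(self, coupled_cohort):
        records, _, _ = coupled_cohort
        lv = hb.assign_composite_level(records["died"], records["long_los"],
                                       records["readmitted_30d"])
        res = hb.HospitalOrdinalModel(records, levels=lv).fit()
        rates = res.standardized_rates()["rate"].to_numpy()
        assert np.exp(np.mean(np.log(rates / 100.0))) == pytest.approx(1.0, abs=1e-9)

    def test_reference_choice_immaterial_after_centering(self, coupled_cohort):
        records, _, _ = coupled_cohort
        lv = hb.assign_composite_level(records["died"], records["long_los"],
                                       records["readmitted_30d"])
        hospitals = sorted(records["hospital_id"].unique())
        r1 = hb.HospitalOrdinalModel(records, levels=lv,
                                     reference=hospitals[0]).fit()
        r2 = hb.HospitalOrdinalModel(records, levels=lv,
                                     reference=hospitals[-1]).fit()
        a = r1.standardized_rates().set_index("hospital_id")["rate"]
        b = r2.standardized_rates().set_index("hospital_id")["rate"]
        assert np.allclose(a.to_numpy(), b.loc[a.index].to_numpy(), atol=0.05)

    def test_summary_contains_rates(self, coupled_cohort):
        records, _, _ = coupled_cohort
        lv = hb.assign_composite_level(records["died"], records["long_los"],
                                       records["readmitted_30d"])
        res = hb.HospitalOrdinalModel(records, levels=lv).fit()
        assert "std.rate" in res.summary()
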