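"""Case-mix modelling: age merging, elimination rules, calibration, oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import hospbench as hb
from hospbench.casemix import CaseMixLogit, merge_sparse_age_groups
from hospbench.design import Term, UnseenLevelError

from conftest import tiny_records


def _merge_map(event_counts, levels):
    """Build (age, events) series realising the given per-level event counts."""
    ages, events = [], []
    for lev, e in zip(levels, event_counts):
        n = max(e, 1) + 5
        ages += [lev] * n
        events += [1] * e + [0] * (n - e)
    age = pd.Series(ages)
    ev = pd.Series(events)
    return merge_sparse_age_groups(age, ev, min_events=10, levels=levels)


class TestAgeMerging:
    def test_no_group_below_threshold_keeps_identity(self):
        m = _merge_map([12, 11, 10], ["a", "b", "c"])
        assert m == {"a": "a", "b": "b", "c": "c"}

    def test_iterative_pairwise_merge_collapses_to_one(self):
        # [3,4,10]: a(3)->b gives [7,10]; merged(7)->c gives one band of 17
        m = _merge_map([3, 4, 10], ["a", "b", "c"])
        assert len(set(m.values())) == 1

    def test_all_zero_events_collapse_to_single_band(self):
        m = _merge_map([0, 0, 0], ["a", "b", "c"])
        assert len(set(m.values())) == 1

    def test_sparse_oldest_band_merges_downward(self):
        m = _merge_map([12, 30, 3], ["a", "b", "c"])
        assert m["a"] == "a" and m["b"] == m["c"]

    def test_partial_merge_keeps_enough_events(self):
        m = _merge_map([4, 8, 15, 20], ["a", "b", "c", "d"])
        merged = pd.Series([4, 8, 15, 20], index=["a", "b", "c", "d"]).groupby(
            pd.Series(m)
        ).sum()
        assert (merged >= 10).all()


class TestFitting:
    def test_intercept_only_is_logit_of_event_rate(self):
        rec = tiny_records(n=80, seed=3)
        res = CaseMixLogit(rec, "mortality", terms=[]).fit()
        rate = rec["died"].mean()
        assert res.params[0] == pytest.approx(logit(rate), abs=1e-9)

    def test_matches_independent_irls_to_1e6(self):
        # n=200, 3 covariates, no elimination: ML solutions must agree
        rng = np.random.default_rng(42)
        n = 200
        rec = tiny_records(n=n, seed=7)
        rec["sex"] = rng.integers(0, 2, n)
        rec["urgent_prior"] = rng.integers(0, 2, n)
        rec["elixhauser_count"] = rng.poisson(1.5, n)
        lp = -1.0 + 0.6 * rec["sex"] - 0.4 * rec["urgent_prior"] + 0.25 * rec["elixhauser_count"]
        rec["died"] = (rng.random(n) < expit(lp)).astype(np.int8)
        terms = [
            Term("sex", "binary", ("sex",)),
            Term("urgent_prior", "binary", ("urgent_prior",)),
            Term("elixhauser_count", "numeric", ("elixhauser_count",)),
        ]
        res = CaseMixLogit(rec, "mortality", terms=terms, elimination=False).fit()

        X = np.column_stack(
            [np.ones(n), rec["sex"], rec["urgent_prior"], rec["elixhauser_count"]]
        ).astype(float)
        y = rec["died"].to_numpy(dtype=float)
        beta = np.zeros(4)
        for _ in range(200):
            p = expit(X @ beta)
            W = p * (1 - p)
            z = X @ beta + (y - p) / np.maximum(W, 1e-12)
            new = np.linalg.solve((X * W[:, None]).T @ X, (X * W[:, None]).T @ z)
            if np.max(np.abs(new - beta)) < 1e-13:
                beta = new
                break
            beta = new
        assert np.max(np.abs(res.params - beta)) < 1e-6

    def test_calibration_identity_in_sample(self, coupled_cohort, coupled_models):
        records, _, _ = coupled_cohort
        from hospbench.casemix import outcome_series

        for (outcome, grp), res in coupled_models.items():
            if not res.converged or res.penalized:
                continue
            mask, y = outcome_series(records, outcome)
            sub = records.loc[mask & (records["group"] == grp)]
            p = res.predict(sub)
            observed = float(y.loc[sub.index].sum())
            assert p.sum() == pytest.approx(observed, rel=1e-6)

    def test_elimination_keeps_hierarchy_and_significance(self, coupled_models):
        for res in coupled_models.values():
            if res.intercept_only:
                continue
            retained = set(res.retained_terms)
            if "age_group:elixhauser_count" in retained:
                assert {"age_group", "elixhauser_count"} <= retained
            if "unplanned:transfer_in" in retained:
                assert {"unplanned", "transfer_in"} <= retained
            for term, p in res.term_pvalues.items():
                assert p < 0.1 + 1e-9, (res.outcome, term, p)

    def test_null_covariates_rarely_retained(self):
        # with zero planted covariate effects each term survives elimination
        # with probability near the 0.1 retention level
        retained = total = 0
        for s in range(5):
            cfg = hb.scenario_preset(
                "null", volume_range=(700, 700), n_hospitals=10, seed=60 + s
            )
            rec, _ = hb.generate_cohort(cfg)
            res = CaseMixLogit(rec, "mortality", group="general").fit()
            eliminable = [t for t in res.retained_terms if t != "Intercept"]
            retained += len(eliminable)
            total += 9  # candidate terms: 6 mains + year + 2 interactions
        assert 0.0 <= retained / total < 0.3

    def test_strong_age_effect_always_retained(self):
        cfg = hb.scenario_preset(
            "null", volume_range=(1500, 1500), n_hospitals=10, seed=91,
            casemix_effects=hb.CaseMixEffects(age_per_step=1.0),
        )
        rec, _ = hb.generate_cohort(cfg)
        res = CaseMixLogit(rec, "mortality", group="general").fit()
        assert "age_group" in res.retained_terms

    def test_sparse_group_gets_intercept_only(self):
        rec = tiny_records(n=20, seed=5)
        res = CaseMixLogit(rec, "mortality").fit()
        assert res.intercept_only

    def test_unseen_level_raises(self):
        cfg = hb.scenario_preset("null", volume_range=(300, 300), n_hospitals=4,
                                 seed=33)
        rec, _ = hb.generate_cohort(cfg)
        res = CaseMixLogit(rec, "mortality", elimination=False).fit()
        future = rec.head(5).assign(year=2099)
        with pytest.raises(UnseenLevelError):
            res.predict(future)

    def test_prediction_invariant_to_record_order(self, coupled_cohort):
        records, _, _ = coupled_cohort
        sub = records[records["group"] == "general"]
        res1 = CaseMixLogit(sub, "mortality").fit()
        shuffled = sub.sample(frac=1.0, random_state=0)
        res2 = CaseMixLogit(shuffled, "mortality").fit()
        p1 = res1.predict(sub).sort_index()
        p2 = res2.predict(sub).sort_index()
        assert np.allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-8)

    def test_summary_mentions_terms(self, coupled_models):
        res = next(iter(coupled_models.values()))
        text = res.summary()
        assert "Intercept" in text and "log-likelihood" in text
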