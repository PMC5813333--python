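"""Generator contracts: determinism, planted effects, marginal calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2

import hospbench as hb
from hospbench.config import ConfigurationError


def small_config(**kw):
    base = dict(
        n_hospitals=3,
        volume_range=(20, 40),
        groups=(hb.GroupSpec("g1", 0.1, 0.1, 1.5, 0.5),),
        years=(2010, 2011),
        seed=1,
    )
    base.update(kw)
    return hb.ScenarioConfig(**base)


class TestHospitalEffects:
    def test_zero_variances_give_exactly_zero_effects(self):
        eff = hb.generate_hospital_effects(small_config(n_hospitals=10))
        assert (eff[["eta_mort", "eta_readm", "eta_los"]].to_numpy() == 0).all()

    def test_same_seed_identical_effects(self):
        cfg = small_config(tau2_mort=0.2, tau2_readm=0.1, tau2_los=0.3, seed=9)
        a = hb.generate_hospital_effects(cfg)
        b = hb.generate_hospital_effects(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_effects_centered(self):
        cfg = small_config(n_hospitals=30, tau2_mort=0.2, tau2_readm=0.1,
                           tau2_los=0.3, seed=4)
        eff = hb.generate_hospital_effects(cfg)
        assert np.allclose(
            eff[["eta_mort", "eta_readm", "eta_los"]].mean(), 0, atol=1e-12
        )

    def test_variance_recovery_within_chi_square_bounds(self):
        # centered normal draws: sample variance ~ tau2 * chi2(n-1)/(n-1)
        n = 200
        cfg = small_config(n_hospitals=n, tau2_mort=0.25, seed=13)
        eff = hb.generate_hospital_effects(cfg)
        v = eff["eta_mort"].var(ddof=1)
        lo = 0.25 * chi2.ppf(0.005, n - 1) / (n - 1)
        hi = 0.25 * chi2.ppf(0.995, n - 1) / (n - 1)
        assert lo <= v <= hi

    def test_non_psd_correlation_rejected(self):
        bad = ((1.0, 0.99, -0.99), (0.99, 1.0, 0.99), (-0.99, 0.99, 1.0))
        with pytest.raises(ConfigurationError):
            small_config(tau2_mort=0.1, hospital_effect_correlation=bad).validate()

    def test_override_used_verbatim(self):
        ov = ((0.5, 0.0, -0.2), (0.1, 0.1, 0.1), (0.0, 0.0, 0.0))
        eff = hb.generate_hospital_effects(
            small_config(hospital_effects_override=ov)
        )
        assert eff["eta_mort"].tolist() == [0.5, 0.1, 0.0]


class TestCohort:
    def test_exact_record_count_for_fixed_volume(self):
        cfg = small_config(n_hospitals=2, volume_range=(10, 10))
        records, _ = hb.generate_cohort(cfg)
        assert len(records) == 20

    def test_same_seed_byte_identical_output(self, tmp_path):
        cfg = hb.scenario_preset("coupled", volume_range=(50, 80),
                                 n_hospitals=4, seed=2)
        r1, e1 = hb.generate_cohort(cfg)
        r2, e2 = hb.generate_cohort(cfg)
        pd.testing.assert_frame_equal(r1, r2)
        p1 = hb.write_cohort(r1, e1, cfg, tmp_path / "a")
        p2 = hb.write_cohort(r2, e2, cfg, tmp_path / "b")
        assert open(p1["cohort"], "rb").read() == open(p2["cohort"], "rb").read()
        assert open(p1["truth"], "rb").read() == open(p2["truth"], "rb").read()

    def test_readmission_missing_exactly_for_deaths(self):
        records, _ = hb.generate_cohort(
            small_config(volume_range=(200, 300), seed=3)
        )
        died = records["died"] == 1
        assert records.loc[died, "readmitted_30d"].isna().all()
        assert records.loc[~died, "readmitted_30d"].notna().all()

    def test_volumes_within_range(self):
        cfg = small_config(n_hospitals=6, volume_range=(30, 50), seed=8)
        records, _ = hb.generate_cohort(cfg)
        sizes = records.groupby("hospital_id").size()
        assert sizes.between(30, 50).all()

    def test_marginal_calibration_under_null(self):
        # with all effects zero the crude rates converge to the baselines
        cfg = hb.scenario_preset("null", seed=17)
        records, _ = hb.generate_cohort(cfg)
        assert abs(records["died"].mean() - 0.031) < 0.002
        surv = records[records["died"] == 0]
        assert abs(surv["readmitted_30d"].mean() - 0.078) < 0.004

    def test_los_positive_and_quartile_matches_closed_form(self):
        cfg = small_config(volume_range=(2000, 2000), seed=5)
        records, _ = hb.generate_cohort(cfg)
        assert (records["los_days"] > 0).all()
        q75 = cfg.groups[0].los_quantile(0.75)
        frac = (records["los_days"] > q75).mean()
        assert abs(frac - 0.25) < 0.02

    def test_early_death_redraw_shortens_death_los(self):
        cfg = hb.scenario_preset("stroke_like", volume_range=(500, 700), seed=6)
        records, _ = hb.generate_cohort(cfg)
        died = records["died"] == 1
        assert (
            np.log(records.loc[died, "los_days"]).mean()
            < np.log(records.loc[~died, "los_days"]).mean()
        )

    def test_roundtrip_through_csv(self, tmp_path):
        cfg = small_config(volume_range=(40, 60), seed=21)
        records, effects = hb.generate_cohort(cfg)
        paths = hb.write_cohort(records, effects, cfg, tmp_path)
        back = hb.read_cohort(paths["cohort"])
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), records.reset_index(drop=True),
            check_dtype=False, check_categorical=False,
        )


class TestPresets:
    def test_null_preset_is_fully_null(self):
        cfg = hb.scenario_preset("null")
        assert cfg.tau2_mort == cfg.tau2_readm == cfg.tau2_los == 0
        assert cfg.patient_coupling_mort_los == 0

    def test_strata_baselines(self):
        assert hb.scenario_preset("stroke_like").early_death_short_los
        assert hb.scenario_preset("stroke_like").groups[0].p_mortality == 0.136
        assert hb.scenario_preset("heart_failure_like").groups[0].p_readmission == 0.169

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(KeyError, match="null"):
            hb.scenario_preset("nope")

    def test_yaml_overrides(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            'preset: "null"\nn_hospitals: 4\nvolume_range: [10, 20]\nseed: 3\n'
        )
        cfg = hb.config_from_yaml(path)
        assert cfg.n_hospitals == 4 and cfg.volume_range == (10, 20)


@given(
    n_hospitals=st.integers(2, 4),
    seed=st.integers(0, 10_000),
    p_mort=st.floats(0.02, 0.4),
    tau2=st.floats(0.0, 0.4),
)
def test_generator_invariants_hold_for_random_configs(n_hospitals, seed, p_mort, tau2):
    cfg = hb.ScenarioConfig(
        n_hospitals=n_hospitals,
        volume_range=(5, 25),
        groups=(hb.GroupSpec("g", p_mort, 0.1, 1.4, 0.5),),
        years=(2010,),
        tau2_mort=tau2,
        seed=seed,
    )
    records, effects = hb.generate_cohort(cfg)
    assert (records["los_days"] > 0).all()
    assert records.loc[records["died"] == 1, "readmitted_30d"].isna().all()
    records2, effects2 = hb.generate_cohort(cfg)
    pd.testing.assert_frame_equal(records, records2)
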