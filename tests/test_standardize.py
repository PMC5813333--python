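"""Long-LOS rule, O/E ratios, patient-level ORs, hospital correlations."""

import numpy as np
import pandas as pd
import pytest

import hospbench as hb
from hospbench.standardize import nearest_rank

from conftest import tiny_records


def records_with_los(values, group="g"):
    rec = tiny_records(n=len(values), seed=1)
    rec["los_days"] = np.asarray(values, dtype=float)
    rec["group"] = group
    return rec


class TestLongLos:
    def test_upper_quartile_nearest_rank_of_eight(self):
        # nearest rank: ceil(0.75*8)=6th order statistic -> cutoff 6, flags {7,8}
        rec = records_with_los(range(1, 9))
        flags, rule = hb.long_los_flags(rec, 75)
        assert rule.cutoffs["g"] == 6
        assert flags.sum() == 2
        assert flags.mean() == 0.25

    def test_upper_decile_of_ten_flags_only_the_maximum(self):
        # ceil(0.9*10)=9th order statistic; only the largest value is above it
        rec = records_with_los(range(1, 11))
        flags, rule = hb.long_los_flags(rec, 90)
        assert rule.cutoffs["g"] == 9
        assert flags.sum() == 1

    def test_degenerate_distribution_flags_nothing(self):
        rec = records_with_los([4.0] * 12)
        flags, _ = hb.long_los_flags(rec, 75)
        assert flags.sum() == 0  # strict inequality

    def test_decile_flags_are_subset_of_quartile_flags(self, coupled_cohort):
        records, _, _ = coupled_cohort
        f75, _ = hb.long_los_flags(records, 75)
        f90, _ = hb.long_los_flags(records, 90)
        assert not (f90 & ~f75).any()

    def test_tiny_group_marked_low_confidence(self):
        rec = pd.concat(
            [records_with_los(range(1, 9), "big"),
             records_with_los([1.0, 2.0], "small")],
            ignore_index=True,
        )
        _, rule = hb.long_los_flags(rec, 75)
        assert rule.low_confidence == {"small"}

    def test_invalid_percentile_rejected(self, coupled_cohort):
        with pytest.raises(ValueError):
            hb.long_los_flags(coupled_cohort[0], 80)

    @pytest.mark.parametrize("values,pct,expected", [
        (list(range(1, 101)), 75, 75.0),
        ([5.0], 75, 5.0),
        ([1.0, 2.0, 3.0, 4.0], 90, 4.0),
    ])
    def test_nearest_rank_examples(self, values, pct, expected):
        assert nearest_rank(np.array(values), pct) == expected


class TestStandardizedRatio:
    @pytest.mark.parametrize("o,e,expected", [(50, 50, 100.0), (0, 12.3, 0.0),
                                              (15, 10, 150.0)])
    def test_ratio_arithmetic(self, o, e, expected):
        assert hb.standardized_ratio(o, e) == pytest.approx(expected)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            hb.standardized_ratio(3, 0.0)

    def test_whole_population_ratio_is_100(self, coupled_ratios):
        # sum(expected)=sum(observed) per model => all-hospitals ratio = 100
        g = coupled_ratios.groupby("outcome")
        overall = 100.0 * g["observed"].sum() / g["expected"].sum()
        assert np.allclose(overall.to_numpy(), 100.0, rtol=1e-6)

    def test_denominator_populations(self, coupled_ratios):
        pops = coupled_ratios.groupby("outcome")["denominator_population"].unique()
        assert pops["mortality"].tolist() == ["all"]
        assert pops["readmission"].tolist() == ["survivors"]
        assert pops["long_los"].tolist() == ["survivors"]


class TestPatientLevelOR:
    def test_two_by_two_closed_form(self):
        # exposed 20/100 events, unexposed 10/100 -> OR = (20*90)/(80*10) = 2.25
        n = 200
        rec = tiny_records(n=n, seed=2)
        exposure = pd.Series([1] * 100 + [0] * 100, index=rec.index)
        rec["died"] = np.array([1] * 20 + [0] * 80 + [1] * 10 + [0] * 90,
                               dtype=np.int8)
        res = hb.patient_level_or(rec, "mortality", adjusted=False,
                                  long_los=exposure)
        assert res.odds_ratio == pytest.approx(2.25, rel=1e-6)
        assert res.ci_low < 2.25 < res.ci_high

    def test_zero_cell_raises(self):
        rec = tiny_records(n=40, seed=3)
        exposure = pd.Series([1] * 20 + [0] * 20, index=rec.index)
        rec["died"] = np.array([0] * 20 + [1] * 10 + [0] * 10, dtype=np.int8)
        with pytest.raises(ValueError, match="zero cell"):
            hb.patient_level_or(rec, "mortality", adjusted=False, long_los=exposure)

    def test_adjusted_or_recovers_planted_coupling(self, coupled_cohort):
        # planted patient-level log-OR is ln(1.45) with confounding hospital
        # effects; the center+casemix adjusted estimate should cover it
        records, _, _ = coupled_cohort
        res = hb.patient_level_or(records, "mortality", adjusted=True)
        assert res.ci_low < 1.45 < res.ci_high or abs(res.odds_ratio - 1.45) < 0.12

    def test_readmission_restricted_to_survivors(self, coupled_cohort):
        records, _, _ = coupled_cohort
        res = hb.patient_level_or(records, "readmission", adjusted=False)
        assert res.n == int((records["died"] == 0).sum())


class TestHospitalCorrelations:
    def test_affine_relation_gives_unit_correlation(self):
        a = pd.Series([90.0, 100.0, 110.0, 120.0], index=list("abcd"))
        r, p = hb.hospital_correlations(a, 2 * a + 5)
        assert r == pytest.approx(1.0)
        r, _ = hb.hospital_correlations(a, -a)
        assert r == pytest.approx(-1.0)

    def test_too_few_hospitals_rejected(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            hb.hospital_correlations(a, a)

    def test_zero_variance_rejected(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        b = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        with pytest.raises(ValueError):
            hb.hospital_correlations(a, b)

    def test_independent_effects_correlation_near_zero(self):
        # null simulation: uncorrelated planted effects -> mean r ~ 0
        rs = []
        rng = np.random.default_rng(0)
        for _ in range(300):
            a = pd.Series(rng.normal(100, 10, 26))
            b = pd.Series(rng.normal(100, 10, 26))
            r, _ = hb.hospital_correlations(a, b)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05
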