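import numpy as np
import pytest
from lifelines.statistics import multivariate_logrank_test

from sspkit.clinical_survival import (
    clinical_by_subtype,
    filter_survival,
    ihc_surrogate,
    km_curve,
    logrank_test,
    marginal_summary,
    round_half_up,
)
from sspkit.core import SUBTYPES, ClinicalRecord, SurvivalRecord, ValidationError

from conftest import make_calls


def clin(sid, **kwargs):
    return ClinicalRecord(sample_id=sid, **kwargs)


# category x subtype counts for a 117-sample consistently-called cohort,
# subtype order LumA, LumB, Normal, Her2E, Basal
AGREED_COUNTS = {
    "er": {"positive": (35, 15, 2, 3, 0), "negative": (0, 1, 4, 18, 39)},
    "her2": {"over-expressed": (2, 5, 2, 18, 2), "not": (33, 11, 4, 3, 37)},
}


def build_agreed_cohort():
    """Calls + clinical records realizing the AGREED_COUNTS cross-tabs."""
    calls, clinical = [], []
    i = 0
    for er_level, er_row in AGREED_COUNTS["er"].items():
        for k, subtype in enumerate(SUBTYPES):
            for _ in range(er_row[k]):
                calls.append(make_calls([subtype], prefix=f"P{i}_")[0])
                clinical.append(clin(f"P{i}_0", er=er_level))
                i += 1
    return calls, clinical


class TestClinicalBySubtype:
    def test_er_cross_tab_counts(self):
        calls, clinical = build_agreed_cohort()
        tables = clinical_by_subtype(calls, clinical, features=["er"])
        counts = tables["er"]["counts"]
        assert counts.loc["positive", "Basal"] == 0
        assert counts.loc["negative", "Basal"] == 39
        assert counts.loc["positive", "LumA"] == 35
        assert tables["er"]["proportions"].loc["positive", "Basal"] == 0.0

    def test_her2_proportion_among_her2e(self):
        calls, clinical = [], []
        i = 0
        for level, row in AGREED_COUNTS["her2"].items():
            for k, subtype in enumerate(SUBTYPES):
                for _ in range(row[k]):
                    calls.append(make_calls([subtype], prefix=f"Q{i}_")[0])
                    clinical.append(clin(f"Q{i}_0", her2=level))
                    i += 1
        tables = clinical_by_subtype(calls, clinical, features=["her2"])
        assert tables["her2"]["counts"].loc["over-expressed", "Her2E"] == 18
        assert tables["her2"]["proportions"].loc["over-expressed", "Her2E"] == (
            pytest.approx(18 / 21)
        )

    def test_all_missing_feature(self):
        calls = make_calls(["LumA", "LumB"])
        clinical = [clin("S0"), clin("S1")]  # every feature NA
        tables = clinical_by_subtype(calls, clinical, features=["grade"])
        assert tables["grade"]["counts"].to_numpy().sum() == 0
        assert tables["grade"]["missing"].sum() == 2

    def test_unknown_feature_rejected(self):
        calls = make_calls(["LumA"])
        with pytest.raises(ValidationError, match="unknown clinical"):
            clinical_by_subtype(calls, [clin("S0")], features=["ki67"])

    def test_missing_clinical_record_rejected(self):
        calls = make_calls(["LumA"])
        with pytest.raises(ValidationError, match="without clinical"):
            clinical_by_subtype(calls, [], features=["er"])

    def test_unclassified_calls_excluded(self):
        calls = make_calls(["LumA", "Unclassified"])
        clinical = [clin("S0", er="positive"), clin("S1", er="positive")]
        tables = clinical_by_subtype(calls, clinical, features=["er"])
        assert tables["er"]["counts"].to_numpy().sum() == 1


class TestMarginalSummary:
    def test_half_of_44(self):
        records = [clin(f"S{i}", er="positive" if i < 22 else "negative")
                   for i in range(44)]
        out = marginal_summary(records, features=["er"])
        assert out["er"]["counts"]["positive"] == 22
        assert out["er"]["percent"]["positive"] == 50

    def test_single_category_is_100(self):
        records = [clin(f"S{i}", nodal="positive") for i in range(7)]
        out = marginal_summary(records, features=["nodal"])
        assert out["nodal"]["percent"]["positive"] == 100

    def test_rounding_half_up_43(self):
        # 73/168 = 0.43452... -> 43
        records = [clin(f"S{i}", lvi="positive" if i < 73 else "negative")
                   for i in range(168)]
        out = marginal_summary(records, features=["lvi"])
        assert out["lvi"]["percent"]["positive"] == 43

    def test_missing_excluded_from_denominator(self):
        records = [clin("S0", lvi="positive"), clin("S1", lvi="NA")]
        out = marginal_summary(records, features=["lvi"])
        assert out["lvi"]["n"] == 1
        assert out["lvi"]["missing"] == 1
        assert out["lvi"]["percent"]["positive"] == 100

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            marginal_summary([])

    @pytest.mark.parametrize("x,expected", [(0.5, 1), (1.5, 2), (58.5, 59),
                                            (59.4, 59), (42.5, 43)])
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestIhcSurrogate:
    def test_er_positive_dominates(self):
        assert ihc_surrogate(clin("s", er="positive", her2="over-expressed")) == (
            "luminal-like"
        )

    def test_triple_negative(self):
        assert ihc_surrogate(clin("s", er="negative", her2="not")) == (
            "triple-negative-like"
        )

    def test_her2_like(self):
        assert ihc_surrogate(clin("s", er="negative", her2="over-expressed")) == (
            "HER2-like"
        )

    def test_missing_er_unknown(self):
        assert ihc_surrogate(clin("s", her2="not")) == "unknown"

    def test_missing_her2_with_er_negative_unknown(self):
        assert ihc_surrogate(clin("s", er="negative")) == "unknown"


class TestKMCurve:
    def test_all_censored_is_flat_one(self):
        curve = km_curve([SurvivalRecord(f"S{i}", t, 0) for i, t in
                          enumerate([3.0, 5.0, 9.0])])
        assert (curve.survival == 1.0).all()
        assert curve.probability_at(100.0) == 1.0

    def test_hand_product_limit(self):
        # events at 1 and 3, censored at 2: S(1) = 2/3, S(3) = 0
        recs = [SurvivalRecord("a", 1.0, 1), SurvivalRecord("b", 2.0, 0),
                SurvivalRecord("c", 3.0, 1)]
        curve = km_curve(recs)
        assert curve.probability_at(1.0) == pytest.approx(2 / 3)
        assert curve.probability_at(3.0) == pytest.approx(0.0)

    def test_duplicate_event_times_single_step(self):
        recs = [SurvivalRecord("a", 2.0, 1), SurvivalRecord("b", 2.0, 1),
                SurvivalRecord("c", 5.0, 0)]
        curve = km_curve(recs)
        assert len(curve.times) == 2
        assert curve.probability_at(2.0) == pytest.approx(1 / 3)

    def test_monotone_starts_at_one(self):
        rng = np.random.default_rng(4)
        recs = [SurvivalRecord(f"S{i}", float(t), int(e)) for i, (t, e) in
                enumerate(zip(rng.exponential(20, 50), rng.integers(0, 2, 50)))]
        curve = km_curve(recs)
        assert curve.probability_at(0.0) == 1.0 or curve.times[0] == 0.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            km_curve([])


def make_group(times_events, prefix):
    return [SurvivalRecord(f"{prefix}{i}", t, e)
            for i, (t, e) in enumerate(times_events)]


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = [(1.0, 1), (2.0, 1), (3.0, 0)]
        stat, df, p = logrank_test([make_group(g, "a"), make_group(g, "b")])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_hand_built_risk_tables(self):
        # A: (1,event),(4,event); B: (2,event),(5,censored)
        # hand evaluation: U = 1/2 - 1/3 + 1/2 = 2/3,
        # V = 1/4 + 2/9 + 1/4 = 13/18, chi2 = (2/3)^2 / (13/18) = 8/13
        a = make_group([(1.0, 1), (4.0, 1)], "a")
        b = make_group([(2.0, 1), (5.0, 0)], "b")
        stat, df, p = logrank_test([a, b])
        assert stat == pytest.approx((2 / 3) ** 2 / (13 / 18), abs=1e-12)
        assert df == 1

    def test_matches_lifelines(self):
        rng = np.random.default_rng(8)
        groups = []
        for g in range(3):
            times = rng.exponential(15 * (g + 1), 25)
            cens = rng.uniform(0, 40, 25)
            obs = np.minimum(times, cens)
            groups.append(make_group(list(zip(obs, (times <= cens).astype(int))),
                                     f"g{g}"))
        stat, df, p = logrank_test(groups)
        all_t = np.concatenate([[r.time for r in g] for g in groups])
        all_e = np.concatenate([[r.event for r in g] for g in groups])
        all_g = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
        ref = multivariate_logrank_test(all_t, all_g, all_e)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)
        assert df == 2

    def test_five_groups_df_four(self):
        rng = np.random.default_rng(9)
        groups = [make_group([(float(t), 1) for t in rng.exponential(10, 5)], f"g{g}")
                  for g in range(5)]
        _, df, _ = logrank_test(groups)
        assert df == 4

    def test_zero_events_rejected(self):
        a = make_group([(1.0, 0), (2.0, 0)], "a")
        b = make_group([(3.0, 0)], "b")
        with pytest.raises(ValidationError, match="zero events"):
            logrank_test([a, b])

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            logrank_test([make_group([(1.0, 1)], "a")])

    def test_type_one_error_calibration(self):
        # equal-hazard exchangeable groups; quick version of the 1000-rep check
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 400
        for _ in range(reps):
            times = rng.exponential(20, 100)
            cens = rng.uniform(0, 60, 100)
            obs = np.minimum(times, cens)
            ev = (times <= cens).astype(int)
            a = make_group(list(zip(obs[:50], ev[:50])), "a")
            b = make_group(list(zip(obs[50:], ev[50:])), "b")
            if logrank_test([a, b])[2] < 0.05:
                rejections += 1
        assert 0.05 - 0.03 <= rejections / reps <= 0.05 + 0.03

    def test_power_under_hazard_ratio_three(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 300
        for _ in range(reps):
            t_a = rng.exponential(30, 20)
            t_b = rng.exponential(10, 20)  # hazard ratio 3
            cens_a = rng.uniform(0, 60, 20)
            cens_b = rng.uniform(0, 60, 20)
            a = make_group(list(zip(np.minimum(t_a, cens_a),
                                    (t_a <= cens_a).astype(int))), "a")
            b = make_group(list(zip(np.minimum(t_b, cens_b),
                                    (t_b <= cens_b).astype(int))), "b")
            if logrank_test([a, b])[2] < 0.05:
                rejections += 1
        assert rejections / reps >= 0.6


class TestFilterSurvival:
    def test_group_by_label_with_clinical_filter(self):
        calls = make_calls(["LumA", "LumB", "LumA", "Basal"])
        survival = [SurvivalRecord(f"S{i}", float(i + 1), 1) for i in range(4)]
        clinical = [clin("S0", er="positive"), clin("S1", er="positive"),
                    clin("S2", er="negative"), clin("S3", er="negative")]
        groups = filter_survival(calls, survival, clinical,
                                 clinical_filter={"er": "positive"})
        assert sorted(groups) == ["LumA", "LumB"]
        assert [r.sample_id for r in groups["LumA"]] == ["S0"]

    def test_label_restriction(self):
        calls = make_calls(["LumA", "LumB", "Basal"])
        survival = [SurvivalRecord(f"S{i}", 1.0, 0) for i in range(3)]
        groups = filter_survival(calls, survival, labels=["LumA", "LumB"])
        assert sorted(groups) == ["LumA", "LumB"]

    def test_filter_without_clinical_rejected(self):
        calls = make_calls(["LumA"])
        with pytest.raises(ValidationError, match="clinical"):
            filter_survival(calls, [], clinical_filter={"er": "positive"})
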