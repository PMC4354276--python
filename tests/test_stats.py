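import numpy as np
import pandas as pd
import pytest

from conftest import classical_mixed_anova_oracle
from visint.stats import (
    StudyAnalysis,
    closure_effect,
    facilitation_db,
    facilitation_table,
    filter_fixation,
    fisher_compare,
    mixed_anova,
    pearson_r,
    t_tests,
)


class TestFacilitation:
    def test_equal_thresholds_give_zero_db(self):
        assert facilitation_db(0.035, 0.035) == 0.0

    def test_halved_threshold_is_plus_six_db(self):
        assert facilitation_db(0.035, 0.0175) == pytest.approx(6.0206, abs=1e-3)

    def test_doubled_threshold_is_minus_six_db(self):
        assert facilitation_db(0.035, 0.070) == pytest.approx(-6.0206, abs=1e-3)

    def test_antisymmetry(self):
        assert facilitation_db(0.03, 0.05) == -facilitation_db(0.05, 0.03)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            facilitation_db(0.0, 0.035)

    def test_table_from_long_thresholds(self):
        thr = pd.DataFrame(
            [
                {"participant": "a", "group": "NT", "condition": "baseline",
                 "threshold": 0.04},
                {"participant": "a", "group": "NT", "condition": "0",
                 "threshold": 0.02},
                {"participant": "a", "group": "NT", "condition": "45",
                 "threshold": 0.04},
            ]
        )
        tab = facilitation_table(thr)
        assert len(tab) == 2
        row0 = tab[tab["offset"] == 0].iloc[0]
        assert row0["facilitation_db"] == pytest.approx(6.0206, abs=1e-3)
        assert tab[tab["offset"] == 45]["facilitation_db"].iloc[0] == 0.0

    def test_missing_baseline_rejected(self):
        thr = pd.DataFrame(
            [{"participant": "a", "group": "NT", "condition": "0",
              "threshold": 0.02}]
        )
        with pytest.raises(ValueError):
            facilitation_table(thr)


class TestFixationFilter:
    def make(self, deviations):
        return pd.DataFrame(
            {
                "participant": "p0",
                "gaze_deviation": deviations,
            }
        )

    def test_nothing_dropped_at_zero_deviation(self):
        kept, report = filter_fixation(self.make([0.0] * 5))
        assert len(kept) == 5
        assert report["retained_fraction"].iloc[0] == 1.0

    def test_boundary_is_inclusive(self):
        kept, report = filter_fixation(self.make([1.0, 1.5, 1.6]))
        assert list(kept["gaze_deviation"]) == [1.0, 1.5]
        assert report["n_dropped"].iloc[0] == 1

    def test_missing_gaze_retained_and_counted(self):
        kept, report = filter_fixation(self.make([np.nan, 2.0, 1.0]))
        assert len(kept) == 2
        assert report["n_missing_gaze"].iloc[0] == 1

    def test_retained_fraction_matches_gaze_law(self, nt_profile, rng):
        from visint.observer import sample_participant, sample_gaze

        part = sample_participant(nt_profile, rng)
        trials = pd.DataFrame(
            {
                "participant": "p0",
                "gaze_deviation": sample_gaze(part, rng, size=100_000),
            }
        )
        _, report = filter_fixation(trials)
        assert report["retained_fraction"].iloc[0] == pytest.approx(
            0.943, abs=0.01
        )


def long_table(y, groups, levels):
    rows = []
    for i in range(y.shape[0]):
        for j, lev in enumerate(levels):
            rows.append(
                {"participant": f"s{i}", "group": groups[i], "level": lev,
                 "y": y[i, j]}
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    @pytest.mark.parametrize("k,n_subj", [(2, 6), (4, 6), (4, 26)])
    def test_agrees_with_projection_oracle(self, k, n_subj, rng):
        y = rng.normal(size=(n_subj, k))
        groups = ["a"] * (n_subj // 2) + ["b"] * (n_subj - n_subj // 2)
        reports = mixed_anova(
            long_table(y, groups, list(range(k))),
            dv="y", within="level", subject="participant", between="group",
        )
        oracle = classical_mixed_anova_oracle(y, groups, k)
        for rep, key in zip(reports, ["between", "within", "interaction"]):
            assert rep.statistic == pytest.approx(oracle[key]["F"], abs=1e-8)
            assert rep.df == oracle[key]["df"]
            assert rep.effect_size == pytest.approx(oracle[key]["np2"], abs=1e-8)

    def test_df_match_the_two_by_four_design_with_26_subjects(self, rng):
        y = rng.normal(size=(26, 4))
        groups = ["NT"] * 13 + ["ASD"] * 13
        reports = mixed_anova(
            long_table(y, groups, [0, 15, 30, 45]),
            dv="y", within="level", subject="participant", between="group",
        )
        within = reports[1]
        assert within.df == (3, 72)
        between = reports[0]
        assert between.df == (1, 24)

    def test_scale_invariance(self, rng):
        y = rng.normal(size=(8, 3))
        groups = ["a"] * 4 + ["b"] * 4
        kwargs = dict(dv="y", within="level", subject="participant",
                      between="group")
        r1 = mixed_anova(long_table(y, groups, [1, 2, 3]), **kwargs)
        r2 = mixed_anova(long_table(10 * y, groups, [1, 2, 3]), **kwargs)
        for a, b in zip(r1, r2):
            assert a.statistic == pytest.approx(b.statistic, rel=1e-9)
            assert a.effect_size == pytest.approx(b.effect_size, rel=1e-9)

    def test_unbalanced_within_levels_rejected(self, rng):
        df = long_table(rng.normal(size=(4, 3)), ["a", "a", "b", "b"], [1, 2, 3])
        df = df.drop(index=0)
        with pytest.raises(ValueError):
            mixed_anova(df, dv="y", within="level", subject="participant",
                        between="group")


class TestTTests:
    def test_identical_pairs_give_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        [rep] = t_tests([("same", x, x.copy())], kind="paired")
        assert rep.statistic == 0.0
        assert rep.p == 1.0

    def test_paired_matches_hand_computation(self):
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 3.0, 4.0])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        [rep] = t_tests([("pair", x, y)], kind="paired")
        assert rep.statistic == pytest.approx(t_hand, rel=1e-12)
        assert rep.df == (2,)

    def test_bonferroni_quadruples_and_caps(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        [plain] = t_tests([("c", x, y)])
        [corr] = t_tests([("c", x, y)], bonferroni=4)
        assert corr.p == pytest.approx(min(1.0, plain.p * 4))
        [capped] = t_tests([("c", x, x + 1e-6 * y)], kind="paired",
                           bonferroni=1000)
        assert capped.p <= 1.0


class TestCorrelations:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pearson_r(x, x).statistic == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 7).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        r_hand = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert pearson_r(x, y).statistic == pytest.approx(r_hand, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_fisher_comparison_of_published_correlations(self):
        rep = fisher_compare(0.90, 13, 0.56, 13)
        assert round(rep.statistic, 2) == 1.88
        assert rep.p == pytest.approx(0.06, abs=0.005)

    def test_fisher_antisymmetry_and_null(self):
        assert fisher_compare(0.5, 10, 0.5, 20).statistic == 0.0
        a = fisher_compare(0.8, 15, 0.3, 12).statistic
        b = fisher_compare(0.3, 12, 0.8, 15).statistic
        assert a == pytest.approx(-b)

    def test_fisher_domain_errors(self):
        with pytest.raises(ValueError):
            fisher_compare(1.0, 10, 0.5, 10)
        with pytest.raises(ValueError):
            fisher_compare(0.5, 3, 0.5, 10)


class TestClosure:
    def make_tol(self, lines, square, groups):
        rows = []
        for i, (l, s, g) in enumerate(zip(lines, square, groups)):
            rows.append({"participant": f"p{i}", "group": g, "shape": "lines",
                         "tolerance": l})
            rows.append({"participant": f"p{i}", "group": g, "shape": "square",
                         "tolerance": s})
        return pd.DataFrame(rows)

    def test_identical_tolerances_give_zero_benefit(self):
        tol = self.make_tol([50, 48], [50, 48], ["NT", "NT"])
        summary = closure_effect(tol)
        assert summary["mean"].iloc[0] == 0.0

    def test_benefit_is_square_minus_lines(self):
        tol = self.make_tol([47.83, 47.83], [57.38, 57.38], ["NT", "NT"])
        summary = closure_effect(tol)
        assert summary["mean"].iloc[0] == pytest.approx(9.55, abs=1e-9)

    def test_missing_pair_excluded_with_report(self):
        tol = self.make_tol([50.0, 48.0], [55.0, 52.0], ["NT", "NT"])
        tol = tol.drop(index=3)  # p1 loses its square tolerance
        summary = closure_effect(tol)
        assert summary["n"].iloc[0] == 1
        assert summary.attrs["excluded"] == ["p1"]


class TestStudyAnalysis:
    def test_full_battery_on_a_small_study(self, nt_profile, asd_profile):
        from visint.runner import run_group_study

        study = run_group_study(
            {"NT": nt_profile, "ASD": asd_profile}, n_per_group=5, seed=3
        )
        report = StudyAnalysis(study).run()
        r = report.results
        assert {"baseline_ttest", "cf_anova", "cf_posthoc", "ci_anova",
                "closure", "ci_correlations", "fisher"} <= set(r)
        assert len(r["cf_anova"]) == 3
        assert len(r["cf_posthoc"]) == 4
        assert all(rep.correction for rep in r["cf_posthoc"])
        text = report.summary()
        assert "Contour integration" in text
        assert "closure benefit" in text
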