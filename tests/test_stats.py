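"""Statistical workflow: routing, post hocs, ROC orientation, Youden."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glottovib import (
    compare_groups,
    posthoc_pairwise,
    roc_analysis,
    run_study,
    youden_cutpoint,
    youden_index,
)
from glottovib.errors import ValidationError


def table_from(groups: dict[str, np.ndarray], parameter="x") -> pd.DataFrame:
    rows = []
    for g, vals in groups.items():
        rows += [{"diagnosis": g, parameter: v} for v in vals]
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_gaussian_groups_route_parametric(self):
        rng = np.random.default_rng(0)
        t = table_from({g: rng.normal(size=40) for g in "abc"})
        res = compare_groups(t, "x", ("a", "b", "c"))
        assert res.route == "parametric"
        assert res.test == "one-way ANOVA"

    def test_lognormal_groups_route_nonparametric(self):
        rng = np.random.default_rng(1)
        t = table_from({g: rng.lognormal(sigma=1.5, size=40) for g in "abc"})
        res = compare_groups(t, "x", ("a", "b", "c"))
        assert res.route == "nonparametric"
        assert res.test == "Kruskal-Wallis"

    def test_two_group_routes(self):
        rng = np.random.default_rng(2)
        t = table_from({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        assert compare_groups(t, "x", ("a", "b")).test == "T"
        t2 = table_from({"a": rng.lognormal(sigma=2, size=30),
                         "b": rng.lognormal(sigma=2, size=30)})
        assert compare_groups(t2, "x", ("a", "b")).test == "U Mann-Whitney"

    def test_large_shift_detected(self):
        rng = np.random.default_rng(3)
        t = table_from({"a": rng.normal(0, 1, 40), "b": rng.normal(3, 1, 40)})
        assert compare_groups(t, "x", ("a", "b")).p_value < 1e-3

    def test_well_separated_groups_agree_across_routes(self):
        import scipy.stats as sps

        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 40), rng.normal(4, 1, 40)
        assert sps.ttest_ind(a, b).pvalue < 0.001
        assert sps.mannwhitneyu(a, b, alternative="two-sided").pvalue < 0.001

    def test_tiny_group_rejected(self):
        t = table_from({"a": np.arange(2.0), "b": np.arange(10.0)})
        with pytest.raises(ValidationError):
            compare_groups(t, "x", ("a", "b"))


class TestPosthoc:
    def test_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(5)
        t = table_from({g: rng.lognormal(size=30) for g in "abc"})
        for res in posthoc_pairwise(t, "x", ("a", "b", "c"), "nonparametric"):
            assert res.adjusted_p >= res.p_value

    def test_identical_groups_rarely_flag_any_pair(self):
        rng = np.random.default_rng(6)
        clean = 0
        n_rep = 300
        for _ in range(n_rep):
            t = table_from({g: rng.lognormal(size=30) for g in "abc"})
            res = posthoc_pairwise(t, "x", ("a", "b", "c"), "nonparametric")
            clean += all(r.adjusted_p > 0.05 for r in res)
        assert clean / n_rep >= 0.93

    def test_single_shifted_group_isolated(self):
        rng = np.random.default_rng(7)
        t = table_from({
            "norm": rng.normal(0, 1, 50),
            "benign": rng.normal(0, 1, 85),
            "malignant": rng.normal(4, 1, 40),
        })
        res = {tuple(r.groups): r for r in
               posthoc_pairwise(t, "x", ("norm", "benign", "malignant"), "parametric")}
        assert res[("norm", "benign")].p_value > 0.05
        assert res[("norm", "malignant")].p_value < 1e-6
        assert res[("benign", "malignant")].p_value < 1e-6

    def test_fewer_than_three_groups_rejected(self):
        t = table_from({"a": np.arange(5.0), "b": np.arange(5.0)})
        with pytest.raises(ValidationError):
            posthoc_pairwise(t, "x", ("a", "b"), "parametric")


class TestRoc:
    def test_exhaustive_four_point_example(self):
        # controls {1,3}, cases {2,4}: 3 of 4 pairs concordant -> AUC 0.75
        r = roc_analysis(np.array([1.0, 3.0, 2.0, 4.0]), np.array([0, 0, 1, 1]), 1)
        assert r.orientation == "booster"
        assert r.auc == pytest.approx(0.75)
        cut = youden_cutpoint(r)
        assert cut.j == pytest.approx(0.5)

    def test_auc_equals_mannwhitney_u_statistic(self):
        import scipy.stats as sps

        rng = np.random.default_rng(8)
        for _ in range(50):
            n1, n0 = int(rng.integers(5, 51)), int(rng.integers(5, 51))
            vals = rng.normal(size=n1 + n0)
            labels = np.r_[np.ones(n1), np.zeros(n0)]
            r = roc_analysis(vals, labels, 1)
            u = sps.mannwhitneyu(vals[:n1], vals[n1:]).statistic / (n1 * n0)
            auc_booster = r.auc if r.orientation == "booster" else 1 - r.auc
            assert auc_booster == pytest.approx(u, abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        vals = rng.normal(size=60) + np.r_[np.ones(30), np.zeros(30)]
        labels = np.r_[np.ones(30), np.zeros(30)]
        r = roc_analysis(vals, labels, 1)
        assert r.auc == pytest.approx(roc_auc_score(labels, vals), abs=1e-12)

    def test_lower_cases_become_inhibitor(self):
        rng = np.random.default_rng(10)
        vals = np.r_[rng.normal(0, 1, 40), rng.normal(-2, 1, 40)]
        labels = np.r_[np.zeros(40), np.ones(40)]
        r = roc_analysis(vals, labels, 1)
        assert r.orientation == "inhibitor"
        assert r.auc > 0.5

    def test_negation_flips_orientation_keeps_auc(self):
        rng = np.random.default_rng(11)
        vals = np.r_[rng.normal(0, 1, 30), rng.normal(1.5, 1, 30)]
        labels = np.r_[np.zeros(30), np.ones(30)]
        a = roc_analysis(vals, labels, 1)
        b = roc_analysis(-vals, labels, 1)
        assert a.orientation != b.orientation
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.sum() in (0, 40):
            return
        a = roc_analysis(vals, labels, 1)
        b = roc_analysis(np.exp(vals) + vals**3, labels, 1)  # strictly monotone
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_ci_contains_auc_and_single_class_rejected(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=50)
        labels = np.r_[np.ones(25), np.zeros(25)]
        r = roc_analysis(vals, labels, 1)
        assert r.ci[0] <= r.auc <= r.ci[1]
        with pytest.raises(ValidationError):
            roc_analysis(vals, np.ones(50), 1)


class TestYouden:
    def test_identity_on_reported_operating_points(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            vals = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)
            if labels.sum() in (0, 40):
                continue
            cut = youden_cutpoint(roc_analysis(vals, labels, 1))
            assert cut.j == pytest.approx(
                youden_index(cut.sensitivity, cut.specificity), abs=1e-12
            )

    def test_exhaustive_threshold_search_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            vals = rng.normal(size=30)
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                continue
            r = roc_analysis(vals, labels, 1)
            cut = youden_cutpoint(r)
            sign = 1.0 if r.orientation == "booster" else -1.0
            cases, ctrls = sign * vals[labels == 1], sign * vals[labels == 0]
            best = max(
                np.mean(cases >= thr) + np.mean(ctrls < thr) - 1.0
                for thr in np.r_[sign * r.thresholds]
                if np.isfinite(thr)
            )
            best = max(best, 0.0)
            assert cut.j == pytest.approx(best, abs=1e-12)

    def test_perfect_separation_gives_unit_j(self):
        vals = np.r_[np.zeros(10), np.ones(10) + 5]
        labels = np.r_[np.zeros(10), np.ones(10)]
        cut = youden_cutpoint(roc_analysis(vals, labels, 1))
        assert cut.j == pytest.approx(1.0)


class TestRunStudy:
    def _null_cohort(self, rng):
        from glottovib.stv import PARAMETER_NAMES

        n = {"norm": 50, "benign": 85, "malignant": 40}
        rows = []
        for g, size in n.items():
            for _ in range(size):
                row = {"subject_id": "s", "diagnosis": g}
                for p in PARAMETER_NAMES:
                    if p in ("AmpInvolvedAvg", "AmpHealthyAvg"):
                        row[p] = np.nan if g == "norm" else rng.normal(4, 1)
                    else:
                        row[p] = rng.normal(10, 2)
                rows.append(row)
        return pd.DataFrame(rows)

    def test_report_structure(self):
        rng = np.random.default_rng(15)
        study = run_study(self._null_cohort(rng))
        assert len(study.omnibus) == 15  # 14 parameters + F0
        assert set(study.roc) == {"norm_vs_lesion", "benign_vs_malignant"}
        t = study.roc_table("benign_vs_malignant")
        assert list(t.columns)[:3] == ["Parameter", "Booster/Inhibitor", "AUC"]
        # per-fold amplitudes only defined where both classes carry values
        assert "AmpInvolvedAvg" not in set(
            study.roc_table("norm_vs_lesion")["Parameter"]
        )
        assert "AmpInvolvedAvg" in set(t["Parameter"])
        aucs = t["AUC"].to_numpy()
        assert np.all(np.diff(aucs) <= 1e-12)  # sorted descending

    def test_effect_free_cohort_shows_no_systematic_separation(self):
        """Under the null no parameter's variant-2 AUC CI excludes 0.5 more
        often than chance (individual CIs are at the 95% level, so a ~5%
        exclusion rate per parameter is expected)."""
        rng = np.random.default_rng(16)
        n_rep = 30
        exclusions: dict[str, int] = {}
        for _ in range(n_rep):
            study = run_study(self._null_cohort(rng))
            tab = study.roc_table("benign_vs_malignant")
            for _, row in tab.iterrows():
                excl = row["AUC lower 95%"] > 0.5
                exclusions[row["Parameter"]] = exclusions.get(row["Parameter"], 0) + excl
        worst = max(exclusions.values()) / n_rep
        assert worst <= 0.2
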