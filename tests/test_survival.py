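import itertools
import math

import numpy as np
import pandas as pd
import pytest

from splenomark.survival import (
    CutoffRule,
    bootstrap_ci,
    c_index_gain_test,
    cox_model,
    harrell_c,
    km_logrank,
    pearson_matrix,
    select_cutoff,
    stratify_3groups,
    subgroup_run,
    time_dependent_auc,
    analyze_endpoint,
)
from splenomark.synthetic_cohort import CohortSpec, simulate_cohort


class TestPearson:
    def test_self_and_negation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": -x, "c": x**2})
        m = pearson_matrix(df)
        assert m.loc["a", "a"] == pytest.approx(1.0)
        assert m.loc["a", "b"] == pytest.approx(-1.0)
        assert np.all(np.abs(m.values) <= 1 + 1e-12)
        np.testing.assert_allclose(m.values, m.values.T)

    def test_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.1])
        # textbook formula, computed independently
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        m = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        assert m.loc["x", "y"] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_matrix(df)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_matrix(pd.DataFrame({"a": [1.0, 2], "b": [3.0, 4]}))


class TestSelectCutoff:
    def test_median_rule(self):
        v = np.arange(1.0, 10.0)
        t = np.ones(9)
        e = np.zeros(9)
        assert select_cutoff(v, t, e, CutoffRule("f", "median")) == 5.0

    def test_fixed_rule(self):
        rule = CutoffRule("tmtv", "fixed", value=220.0)
        assert select_cutoff([1.0, 2.0], [1, 2], [0, 1], rule) == 220.0

    def test_fixed_requires_value(self):
        with pytest.raises(ValueError, match="explicit value"):
            CutoffRule("tmtv", "fixed")

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            select_cutoff([3.0, 3.0], [1, 2], [1, 0], CutoffRule("f", "median"))

    def test_youden_separable_marker(self):
        # events (by t=48) all have marker >= 10; survivors all < 10
        v = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        t = np.array([100.0, 90, 80, 120, 10, 20, 30, 12])
        e = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        cut = select_cutoff(v, t, e, CutoffRule("f", "youden", horizon=48.0))
        assert 4.0 <= cut < 10.0

    def test_youden_matches_exhaustive_scan(self, rng):
        n = 120
        v = rng.normal(size=n)
        t = rng.exponential(60 * np.exp(-0.8 * v))
        e = (rng.random(n) < 0.8).astype(int)
        rule = CutoffRule("f", "youden", horizon=40.0)
        cut = select_cutoff(v, t, e, rule)
        # independent naive scan with unweighted cases as a coarse oracle:
        # the IPCW-weighted optimum must be within one grid step of it
        case = (e == 1) & (t <= 40)
        control = t > 40
        grid = np.sort(np.unique(v))
        js = [np.mean(v[case] > c) + np.mean(v[control] <= c) - 1 for c in grid]
        naive = grid[int(np.argmax(js))]
        i_cut = int(np.searchsorted(grid, cut))
        i_naive = int(np.searchsorted(grid, naive))
        assert abs(i_cut - i_naive) <= 1


class TestKMLogrank:
    def test_no_events_reports_nan(self):
        res = km_logrank([5, 6, 7, 8], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert math.isnan(res.p_value)
        for curve in res.curves.values():
            assert np.all(curve["survival"] == 1.0)

    def test_identical_groups_p_one(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        g = ["a"] * 4 + ["b"] * 4
        res = km_logrank(t, e, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_patient_product_limit_hand_check(self):
        # group a: times 1,2+,3,4,4,5+ -> S = 5/6, 5/6, 0.625, 0.2083..., -
        t = [1, 2, 3, 4, 4, 5] + [10, 11]
        e = [1, 0, 1, 1, 1, 0] + [1, 0]
        g = ["a"] * 6 + ["b"] * 2
        res = km_logrank(t, e, g)
        curve = res.curves["a"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(5 / 6)
        assert curve.loc[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert curve.loc[4.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 3)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two non-empty groups"):
            km_logrank([1, 2], [1, 1], ["a", "a"])


class TestCoxModel:
    def test_null_covariate_hr_near_one(self, rng):
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(50, size=n)
        e = (rng.random(n) < 0.7).astype(int)
        fit = cox_model(pd.DataFrame({"x": x}), t, e)
        assert abs(fit.coef[0]) < 3 * fit.se[0]

    def test_recovers_true_hazard_ratio(self, rng):
        n = 1000
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-math.log(2.0) * x))
        e = np.ones(n, dtype=int)
        fit = cox_model(pd.DataFrame({"x": x}), t, e)
        assert abs(fit.hazard_ratios[0] - 2.0) / 2.0 < 0.10

    def test_summary_table(self, rng):
        n = 100
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        s = cox_model(df, rng.exponential(10, n), np.ones(n)).summary()
        assert list(s.index) == ["a", "b"]
        assert {"coef", "hr", "se", "p"} <= set(s.columns)


class TestHarrellC:
    def test_perfect_ranking(self):
        t = np.array([5.0, 4, 3, 2, 1])
        assert harrell_c(-t, t, np.ones(5)) == 1.0

    def test_random_marker_near_half(self, rng):
        n = 4000
        t = rng.exponential(10, n)
        assert abs(harrell_c(rng.normal(size=n), t, np.ones(n)) - 0.5) < 0.03

    def test_matches_exhaustive_pair_enumeration(self):
        t = np.array([2.0, 4.0, 3.0, 5.0, 1.0])
        e = np.array([1, 1, 0, 1, 1])
        risk = np.array([0.9, 0.3, 0.5, 0.1, 0.5])
        conc = comp = 0.0
        for i, j in itertools.permutations(range(5), 2):
            if not (e[i] and t[i] < t[j]):  # i must be the earlier event
                continue
            comp += 1
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] == risk[j]:
                conc += 0.5
        assert harrell_c(risk, t, e) == pytest.approx(conc / comp)

    def test_negation_complement(self, rng):
        n = 50
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.7).astype(int)
        risk = rng.normal(size=n)
        assert harrell_c(risk, t, e) == pytest.approx(1.0 - harrell_c(-risk, t, e))


class TestBootstrap:
    def test_mean_ci_matches_analytic(self):
        tab = pd.DataFrame({"x": np.arange(1.0, 101.0)})
        res = bootstrap_ci(lambda d: d["x"].mean(), tab, n_resamples=5000, seed=3)
        se = np.std(tab["x"], ddof=0) / 10.0
        assert res.lower[0] == pytest.approx(50.5 - 1.96 * se, abs=0.6)
        assert res.upper[0] == pytest.approx(50.5 + 1.96 * se, abs=0.6)

    def test_constant_statistic_zero_width(self):
        tab = pd.DataFrame({"x": np.arange(20.0)})
        res = bootstrap_ci(lambda d: 7.0, tab, n_resamples=200, seed=0)
        assert res.lower[0] == res.upper[0] == 7.0

    def test_seeded_determinism(self):
        tab = pd.DataFrame({"x": np.arange(50.0)})
        a = bootstrap_ci(lambda d: d["x"].median(), tab, n_resamples=300, seed=42)
        b = bootstrap_ci(lambda d: d["x"].median(), tab, n_resamples=300, seed=42)
        assert (a.lower[0], a.upper[0]) == (b.lower[0], b.upper[0])

    def test_failing_statistic_aborts(self):
        tab = pd.DataFrame({"x": np.arange(10.0)})

        def fragile(d):
            # fine on the full table, fails on (almost) every resample
            if d["x"].duplicated().any():
                raise RuntimeError("duplicate patient")
            return d["x"].mean()

        with pytest.raises(RuntimeError, match="failed"):
            bootstrap_ci(fragile, tab, n_resamples=100, seed=0)

    def test_minimum_resamples(self):
        with pytest.raises(ValueError, match=">= 100"):
            bootstrap_ci(lambda d: 0.0, pd.DataFrame({"x": [1.0]}), n_resamples=10)


class TestTimeDependentAUC:
    def test_independent_marker_near_half(self, rng):
        n = 3000
        t = rng.exponential(60, n)
        e = (rng.random(n) < 0.8).astype(int)
        auc = time_dependent_auc(rng.normal(size=n), t, e, horizon=40.0)
        assert abs(auc - 0.5) < 0.05

    def test_perfect_marker_near_one(self, rng):
        n = 300
        t = np.sort(rng.exponential(60, n))
        e = np.ones(n, dtype=int)
        auc = time_dependent_auc(-t, t, e, horizon=40.0)
        assert auc > 0.99

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            time_dependent_auc([1.0, 2.0], [100.0, 120.0], [1, 1], horizon=50.0)


class TestStratify3Groups:
    def test_quadrant_assignment(self):
        g = stratify_3groups(
            ["a", "b", "c"],
            tmtv_values=[100.0, 300.0, 300.0],
            feature_values=[20.0, 20.0, 40.0],
            tmtv_cutoff=220.0,
            feature_cutoff=32.43,
        )
        assert g.assignments == {"a": 0, "b": 1, "c": 2}
        assert g.n_groups == 3

    def test_missing_values_excluded(self):
        g = stratify_3groups(
            ["a", "b"], [100.0, np.nan], [20.0, 30.0], feature_cutoff=25.0
        )
        assert g.excluded == ["b"]
        assert list(g.assignments) == ["a"]


@pytest.fixture(scope="module")
def strong_cohort():
    spec = CohortSpec(n_patients=300, seed=77, betas={"tmtv_cm3": 0.5, "d_cm": 0.7})
    return simulate_cohort(spec).table


@pytest.fixture(scope="module")
def default_cohort():
    return simulate_cohort(CohortSpec(n_patients=250, seed=21)).table


class TestGainTest:
    def test_extended_equals_base_is_null(self, strong_cohort):
        res = c_index_gain_test(
            strong_cohort, ["tmtv_cm3"], ["tmtv_cm3"], "pfs_months", "pfs_event",
            n_resamples=200, seed=0,
        )
        assert res.delta_c == 0.0
        assert res.p_value == 1.0

    def test_true_second_feature_improves_c(self, strong_cohort):
        res = c_index_gain_test(
            strong_cohort, ["tmtv_cm3"], ["tmtv_cm3", "d_cm"], "pfs_months", "pfs_event",
            n_resamples=400, seed=1,
        )
        assert res.delta_c > 0
        assert res.p_value < 0.05
        assert res.ci_lower <= res.delta_c <= res.ci_upper

    def test_base_must_be_subset(self, strong_cohort):
        with pytest.raises(ValueError, match="contain the base"):
            c_index_gain_test(
                strong_cohort, ["d_cm"], ["tmtv_cm3"], "pfs_months", "pfs_event",
                n_resamples=200,
            )


class TestSubgroupAndEndpoint:
    def test_full_filter_identical_to_full_run(self, default_cohort):
        full = analyze_endpoint(default_cohort, "pfs", ["d_cm"], n_bootstrap=150, seed=0)
        sub = subgroup_run(
            default_cohort, np.ones(len(default_cohort), bool), "pfs", ["d_cm"],
            n_bootstrap=150, seed=0,
        )
        assert sub.c_index["point"] == pytest.approx(full.c_index["point"])
        assert sub.hazard_ratios["d_cm"]["hr"] == pytest.approx(full.hazard_ratios["d_cm"]["hr"])

    def test_no_invasion_subgroup_preserves_hr_direction(self, default_cohort):
        mask = ~default_cohort["invasion"].astype(bool)
        rep = subgroup_run(
            default_cohort, mask, "pfs", ["d_cm"], subset_label="no_invasion",
            n_bootstrap=150, seed=0,
        )
        assert rep.hazard_ratios["d_cm"]["hr"] > 1.0  # generator codes d_cm as risk
        assert rep.subset == "no_invasion"

    def test_tiny_subgroup_rejected(self, default_cohort):
        mask = np.zeros(len(default_cohort), bool)
        mask[:3] = True
        with pytest.raises(ValueError, match="patients"):
            subgroup_run(default_cohort, mask, "pfs", ["d_cm"])

    def test_report_invariants(self, default_cohort):
        rep = analyze_endpoint(
            default_cohort, "os", ["tmtv_cm3", "d_cm"], n_bootstrap=150, seed=5,
            km_feature="d_cm",
        )
        assert 0.5 <= rep.c_index["point"] <= 1.0
        assert rep.c_index["lo"] <= rep.c_index["point"] <= rep.c_index["hi"]
        for hr in rep.hazard_ratios.values():
            assert hr["lo"] <= hr["hr"] <= hr["hi"]
        assert 0.0 <= rep.td_auc["point"] <= 1.0
        assert rep.logrank_p is not None
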