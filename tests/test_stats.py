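"""Variance-gated ANOVA, FDR control, Tukey HSD, PCA and subsampling."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from dmta import reference
from dmta.errors import ParameterError
from dmta.stats_pipeline import (StatsConfig, annotate_bh, anova_oneway,
                                 anova_per_parameter, bh_adjust, fit_pca,
                                 full_analysis, group_summary,
                                 normality_check, project,
                                 select_pca_parameters, spearman_rank,
                                 subsample_compare, tukey_hsd)
from dmta.surface_io import ISO_PARAMETER_ORDER
from dmta.synthetic_data import make_parameter_table


def _frame(groups: dict) -> pd.DataFrame:
    rows = []
    for g, vals in groups.items():
        for v in vals:
            rows.append({"group": g, "y": float(v)})
    return pd.DataFrame(rows)


class TestNormalityCheck:
    def test_null_pvalues_are_uniform(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            df = _frame({"a": rng.standard_normal(30)})
            pvals.append(normality_check(df, "y")["a"])
        ks = st.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_detects_lognormal(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            df = _frame({"a": np.exp(rng.normal(0.0, 1.5, size=30))})
            if normality_check(df, "y")["a"] < 0.05:
                hits += 1
        assert hits >= 180  # power >= 90%

    def test_constant_group_flagged_not_crashed(self):
        df = _frame({"a": [1.0] * 10})
        with pytest.warns(RuntimeWarning, match="constant"):
            out = normality_check(df, "y")
        assert np.isnan(out["a"])

    def test_tiny_group_skipped(self):
        df = _frame({"a": [1.0, 2.0]})
        with pytest.warns(RuntimeWarning, match="n=2"):
            out = normality_check(df, "y")
        assert np.isnan(out["a"])


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        res = anova_oneway([np.array([1.0, 2.0, 3.0]),
                            np.array([1.0, 2.0, 3.0])])
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)
        assert not res.welch

    def test_textbook_three_group_fixture(self):
        # hand-computed: groups {2,3,4}, {4,5,6}, {6,7,8}; means 3,5,7;
        # SSbetween = 3*((3-5)^2+(5-5)^2+(7-5)^2) = 24 over df1 = 2
        # SSwithin  = 3 groups * 2 = 6 over df2 = 6
        # F = (24/2)/(6/6) = 12
        groups = [np.array([2.0, 3.0, 4.0]), np.array([4.0, 5.0, 6.0]),
                  np.array([6.0, 7.0, 8.0])]
        res = anova_oneway(groups)
        assert not res.welch
        assert res.F == pytest.approx(12.0, abs=1e-10)
        assert (res.df1, res.df2) == (2.0, 6.0)
        assert res.p == pytest.approx(float(st.f.sf(12.0, 2, 6)), abs=1e-12)

    def test_study_design_classic_degrees_of_freedom(self):
        # five groups of sizes 6,8,6,6,6 with homogeneous variances
        table = make_parameter_table(
            {"1": 6, "2a": 8, "2": 6, "3": 6, "4": 6}, seed=42)
        results = anova_per_parameter(table)
        classic = [r for r in results if not r.welch]
        assert classic, "expected at least one homoscedastic parameter"
        for r in classic:
            assert (r.df1, r.df2) == (4.0, 27.0)

    def test_welch_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        groups = [rng.normal(0, 1, 6), rng.normal(0.5, 2, 8),
                  rng.normal(1, 0.5, 6)]
        from dmta.stats_pipeline import _welch_anova
        F, df1, df2, p = _welch_anova(groups)
        df = pd.DataFrame({"y": np.concatenate(groups),
                           "g": ["a"] * 6 + ["b"] * 8 + ["c"] * 6})
        ref = pg.welch_anova(dv="y", between="g", data=df)
        assert F == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert df2 == pytest.approx(float(ref["ddof2"][0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)

    def test_welch_reduces_df2(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(0, s, n) for s, n in
                      [(0.2, 6), (3.0, 8), (1.0, 6)]]
            res = anova_oneway(groups)
            classic_df2 = float(sum(len(g) for g in groups) - len(groups))
            if res.welch:
                assert res.df2 < classic_df2

    def test_degenerate_zero_variance_flagged(self):
        res = anova_oneway([np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert "degenerate" in res.note
        assert np.isnan(res.F)


class TestBenjaminiHochberg:
    def test_published_pvalues_flag_exactly_four(self):
        names = list(reference.ANOVA_PVALUES)
        flags = bh_adjust([reference.ANOVA_PVALUES[n] for n in names],
                          fdr=0.05)
        flagged = {n for n, f in zip(names, flags) if f}
        assert flagged == set(reference.BH_SIGNIFICANT)
        assert flagged == {"Sds", "Sal", "Sdq", "Sdr"}

    def test_all_ones_flag_nothing(self):
        assert not bh_adjust([1.0] * 23).any()

    def test_step_up_monotone_in_fdr(self, rng):
        p = rng.uniform(0, 1, size=30)
        prev = bh_adjust(p, fdr=0.01)
        for fdr in (0.02, 0.05, 0.1, 0.2, 0.5):
            cur = bh_adjust(p, fdr=fdr)
            assert np.all(cur | ~prev)  # raising fdr never unflags
            prev = cur

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0,
                                allow_nan=False),
                     min_size=1, max_size=40),
           hst.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_naive_step_up_definition(self, pvals, fdr):
        m = len(pvals)
        order = sorted(range(m), key=lambda i: pvals[i])
        k = 0
        for rank, i in enumerate(order, start=1):
            if pvals[i] <= rank * fdr / m:
                k = rank
        expected = set(order[:k])
        flags = bh_adjust(pvals, fdr=fdr)
        assert {i for i, f in enumerate(flags) if f} == expected


class TestTukey:
    def test_identical_groups_adjusted_p_one(self):
        df = _frame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0],
                     "c": [9.0, 10.0, 11.0]})
        res = tukey_hsd(df, "y")
        pair = res.pairs[frozenset({"a", "b"})]
        assert pair["q"] == pytest.approx(0.0, abs=1e-12)
        assert pair["p_adj"] == pytest.approx(1.0, abs=1e-9)

    def test_overwhelming_shift_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = _frame({"a": rng.normal(0, 1, 6),
                         "b": rng.normal(0, 1, 6),
                         "c": rng.normal(10, 1, 6)})
            res = tukey_hsd(df, "y")
            ok = (res.pairs[frozenset({"a", "c"})]["p_adj"] < 0.001
                  and res.pairs[frozenset({"b", "c"})]["p_adj"] < 0.001
                  and res.pairs[frozenset({"a", "b"})]["p_adj"] > 0.001)
            hits += ok
        assert hits == 20

    def test_matches_studentized_range_distribution(self):
        df = _frame({"a": [2.1, 3.0, 2.5, 2.8], "b": [3.4, 3.9, 3.1, 3.6],
                     "c": [5.0, 5.5, 4.8, 5.2]})
        res = tukey_hsd(df, "y")
        vals = {g: df.loc[df.group == g, "y"].to_numpy()
                for g in ["a", "b", "c"]}
        ssw = sum(((v - v.mean()) ** 2).sum() for v in vals.values())
        dfw = 12 - 3
        s2 = ssw / dfw
        for ga, gb in [("a", "b"), ("a", "c"), ("b", "c")]:
            q = abs(vals[ga].mean() - vals[gb].mean()) / np.sqrt(
                s2 / 2 * (1 / len(vals[ga]) + 1 / len(vals[gb])))
            p_expected = float(st.studentized_range.sf(q, 3, dfw))
            assert res.pairs[frozenset({ga, gb})]["p_adj"] == \
                pytest.approx(p_expected, abs=1e-6)

    def test_singleton_group_excluded_with_warning(self):
        df = _frame({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0],
                     "solo": [5.0]})
        with pytest.warns(RuntimeWarning, match="solo"):
            res = tukey_hsd(df, "y")
        assert res.excluded_groups == ["solo"]
        assert frozenset({"a", "solo"}) not in res.pairs


class TestPca:
    def test_perfectly_correlated_pair_gives_single_component(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"Sq": x, "Sa": 3 * x + 1, "group": "g"})
        model = fit_pca(df, ["Sq", "Sa"])
        assert model.explained_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_uncorrelated_parameters_share_variance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((2000, 4)),
                          columns=["Sq", "Sal", "Sds", "Sdr"])
        model = fit_pca(df, ["Sq", "Sal", "Sds", "Sdr"])
        assert np.all(np.abs(model.explained_pct - 25.0) < 5.0)

    def test_full_reconstruction(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)),
                          columns=["Sq", "Sa", "Sal", "Sds", "Sk"])
        params = list(df.columns)
        model = fit_pca(df, params)
        Z = (df[params].to_numpy() - model.means) / model.sds
        back = model.scores @ model.loadings.T
        assert np.max(np.abs(back - Z)) < 1e-9
        assert model.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)
        # orthonormal loadings
        eye = model.loadings.T @ model.loadings
        assert np.max(np.abs(eye - np.eye(5))) < 1e-9

    def test_sign_convention_deterministic(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 3)),
                          columns=["Sq", "Sa", "Sal"])
        m1 = fit_pca(df, ["Sq", "Sa", "Sal"])
        m2 = fit_pca(df, ["Sq", "Sa", "Sal"])
        assert np.array_equal(m1.loadings, m2.loadings)
        for j in range(3):
            i = int(np.argmax(np.abs(m1.loadings[:, j])))
            assert m1.loadings[i, j] > 0

    def test_constant_parameter_named_in_error(self, rng):
        df = pd.DataFrame({"Sq": rng.normal(size=10),
                           "Sa": np.ones(10)})
        with pytest.raises(ParameterError, match="Sa"):
            fit_pca(df, ["Sq", "Sa"])


class TestProjection:
    def test_training_records_reproject_to_their_scores(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)),
                          columns=["Sq", "Sa", "Sal", "Sds"])
        model = fit_pca(df, list(df.columns))
        proj = project(model, df)
        assert np.max(np.abs(proj - model.scores)) < 1e-9

    def test_training_mean_projects_to_origin(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)),
                          columns=["Sq", "Sa", "Sal"])
        model = fit_pca(df, list(df.columns))
        mean_rec = pd.DataFrame([dict(zip(df.columns, model.means))])
        proj = project(model, mean_rec)
        assert np.max(np.abs(proj)) < 1e-12

    def test_projection_is_affine(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)),
                          columns=["Sq", "Sa", "Sal"])
        model = fit_pca(df, list(df.columns))
        x = df.iloc[[0]][list(df.columns)].to_numpy()
        a = 0.37
        blended = a * x + (1 - a) * model.means
        assert np.allclose(project(model, blended),
                           a * project(model, x), atol=1e-12)

    def test_projection_leaves_model_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 3)),
                          columns=["Sq", "Sa", "Sal"])
        model = fit_pca(df, list(df.columns))
        before = (model.means.copy(), model.sds.copy(),
                  model.loadings.copy(), model.scores.copy())
        project(model, df)
        assert np.array_equal(before[0], model.means)
        assert np.array_equal(before[1], model.sds)
        assert np.array_equal(before[2], model.loadings)
        assert np.array_equal(before[3], model.scores)

    def test_missing_parameter_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)),
                          columns=["Sq", "Sa", "Sal"])
        model = fit_pca(df, list(df.columns))
        with pytest.raises(ParameterError, match="Sal"):
            project(model, df[["Sq", "Sa"]])


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10, dtype=float)
        res = spearman_rank(x, x ** 3)
        assert res["rs"] == pytest.approx(1.0)
        res = spearman_rank(x, -np.exp(x / 3))
        assert res["rs"] == pytest.approx(-1.0)

    def test_all_tied_covariate_flagged(self):
        with pytest.warns(RuntimeWarning, match="all-tied"):
            res = spearman_rank(np.arange(8.0), np.ones(8))
        assert np.isnan(res["rs"])

    def test_permutation_p_is_seeded_and_sane(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(0, 0.5, size=20)
        r1 = spearman_rank(x, y, method="permutation", seed=1,
                           n_permutations=999)
        r2 = spearman_rank(x, y, method="permutation", seed=1,
                           n_permutations=999)
        assert r1 == r2
        assert r1["p"] < 0.05


class TestSubsampling:
    def test_deterministic_per_seed(self):
        t = make_parameter_table({"A": 6, "B": 18}, seed=0)
        a, b = t.subset(["A"]), t.subset(["B"])
        r1 = subsample_compare(a, b, k=6, reps=5, seed=3)
        r2 = subsample_compare(a, b, k=6, reps=5, seed=3)
        assert r1.per_rep == r2.per_rep

    def test_null_false_flag_rate_controlled(self):
        rates = []
        for seed in range(200):
            t = make_parameter_table({"A": 6, "B": 18}, seed=seed)
            a, b = t.subset(["A"]), t.subset(["B"])
            res = subsample_compare(a, b, k=6, reps=1, seed=seed)
            rates.append(len(res.per_rep[0]) / 23.0)
        assert np.mean(rates) <= 0.05 + 0.05

    def test_designed_effects_recovered(self):
        # 3-SD shifts: six-vs-six comparisons have per-parameter power
        # around 0.97 at the B-H-effective level, so >= 4/5 designed
        # parameters recover in well over 80% of repetitions
        designed = ["Sq", "Sds", "Sal", "Vmc", "Sk"]
        shift = {p: 3.0 for p in designed}
        hits = 0
        total = 0
        for seed in range(10):
            t = make_parameter_table({"A": 6, "B": 18},
                                     effects={"B": shift}, seed=seed)
            a, b = t.subset(["A"]), t.subset(["B"])
            res = subsample_compare(a, b, k=6, reps=4, seed=seed)
            for flagged in res.per_rep:
                total += 1
                hits += len(set(designed) & set(flagged)) >= 4
        assert hits / total >= 0.8

    def test_oversized_k_rejected(self):
        t = make_parameter_table({"A": 6, "B": 4}, seed=0)
        with pytest.raises(ParameterError):
            subsample_compare(t.subset(["A"]), t.subset(["B"]), k=6)


class TestGroupSummary:
    def test_hand_computed_ci(self):
        out = group_summary([1.0, 2.0, 3.0], ["g", "g", "g"])
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(0.57735, abs=1e-4)
        # t(0.975, df=2) = 4.3027
        assert row["ci_high"] - row["mean"] == pytest.approx(2.4841,
                                                             abs=1e-3)

    def test_grand_mean_of_equal_groups(self):
        out = group_summary([1, 2, 3, 7, 8, 9], list("aaabbb"))
        assert out.attrs["grand_mean"] == pytest.approx(5.0)
        assert out["mean"].mean() == pytest.approx(5.0)

    def test_ci_width_scales_with_sample_size(self):
        rng = np.random.default_rng(2)
        widths = {}
        for n in (40, 160):
            w = []
            for _ in range(200):
                vals = rng.normal(0, 1, n)
                out = group_summary(vals, ["g"] * n)
                w.append(out["ci_high"][0] - out["ci_low"][0])
            widths[n] = np.mean(w)
        assert widths[160] / widths[40] == pytest.approx(0.5, abs=0.05)


class TestSelectionAndFullAnalysis:
    def test_published_pairwise_tables_select_fourteen(self):
        sel = select_pca_parameters(reference.PAIRWISE_DIFFERENCES)
        assert sel == list(reference.PCA_SELECTED_PARAMETERS)
        assert len(sel) == 14
        assert set(sel) == {"Sq", "Sv", "Sz", "Sds", "Sal", "Vmp", "Vmc",
                            "Vvc", "Vvv", "Spk", "Sk", "Svk", "S5z", "Sa"}
        # the within-tooth pairs add nothing beyond the specimen pairs
        sel_no_2a = select_pca_parameters(reference.PAIRWISE_DIFFERENCES,
                                          exclude_groups=["2a"])
        assert sel_no_2a == sel

    def test_full_analysis_recovers_designed_structure(self):
        designed = {"Sq": 2.5, "Sds": -2.5, "Sal": 2.5, "Vmc": 2.5,
                    "Sk": 2.5}
        t = make_parameter_table(
            {"1": 6, "2": 6, "2a": 8, "3": 6, "4": 6, "5": 6},
            effects={"4": designed}, seed=3,
            diet_ranks={"1": 1, "2": 2, "3": 3, "4": 4})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = full_analysis(t)
        flagged = {r.parameter for r in report.anova if r.bh_significant}
        assert len(flagged & set(designed)) >= 4
        assert len(flagged - set(designed)) <= 1
        assert report.pca is not None
        assert len(report.projections) == 6
        assert report.pc1_anova.df1 == 4.0  # five individual specimens

    def test_full_analysis_deterministic(self):
        t = make_parameter_table({"1": 6, "2": 6, "3": 6, "4": 6}, seed=9,
                                 diet_ranks={"1": 1, "2": 2, "3": 3,
                                             "4": 4})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = full_analysis(t, StatsConfig(seed=5))
            r2 = full_analysis(t, StatsConfig(seed=5))
        assert r1.anova_table().equals(r2.anova_table())
        assert r1.scores.equals(r2.scores)

    def test_annotate_bh_attaches_flags(self):
        t = make_parameter_table({"A": 8, "B": 8}, seed=1)
        results = anova_per_parameter(t)
        annotate_bh(results)
        assert all(r.bh_significant is not None for r in results)
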