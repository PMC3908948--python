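"""CV, feature-wise ANOVAs, Storey q-values and the method-comparison report."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from lcmsnorm import (
    FeatureMatrix,
    SampleTable,
    case_control_anova,
    cv_per_feature,
    evaluation_report,
    qc_anova,
    storey_qvalues,
)
from lcmsnorm.evaluation import cv_summary
from lcmsnorm.exceptions import ValidationError


def fm_of(values):
    values = np.asarray(values, float)
    p, n = values.shape
    return FeatureMatrix(values, [f"f{i}" for i in range(p)],
                         [f"s{j}" for j in range(n)])


def fm_for(st, values):
    values = np.asarray(values, float)
    return FeatureMatrix(values, [f"f{i}" for i in range(values.shape[0])],
                         st.sample_ids)


def meta_qc_blocks(n_blocks=2, k=5):
    rows = []
    for b in range(n_blocks):
        for t in range(1, k + 1):
            rows.append({"sample_id": f"s{b * k + t - 1}", "analysis_order": t,
                         "batch": f"B{b + 1}", "experiment": "F", "group": "QC"})
    return SampleTable(pd.DataFrame(rows))


class TestCV:
    def test_constant_feature_zero(self):
        st = meta_qc_blocks(1, 4)
        cv = cv_per_feature(fm_of([[5.0, 5.0, 5.0, 5.0]]), st, "QC")
        assert cv.iloc[0] == 0.0

    def test_hand_example(self):
        st = meta_qc_blocks(1, 2)
        cv = cv_per_feature(fm_of([[8.0, 12.0]]), st, "QC")
        assert cv.iloc[0] == pytest.approx(np.sqrt(8) / 10)

    def test_scale_invariance(self):
        st = meta_qc_blocks(1, 5)
        vals = np.random.default_rng(0).uniform(1, 10, (3, 5))
        a = cv_per_feature(fm_of(vals), st, "QC")
        b = cv_per_feature(fm_of(7.0 * vals), st, "QC")
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_summary_counts(self):
        s = pd.Series([0.1, 0.2, 0.5, np.nan])
        out = cv_summary(s, threshold=0.3)
        assert out["n_below_threshold"] == 2
        assert out["median_cv"] == pytest.approx(0.2)


def brute_force_two_way_additive(D):
    """Explicit group-mean sums of squares for one J x K table."""
    J, K = D.shape
    grand = D.mean()
    ss_row = K * ((D.mean(axis=1) - grand) ** 2).sum()
    ss_col = J * ((D.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((D - grand) ** 2).sum()
    ss_err = ss_tot - ss_row - ss_col
    F = (ss_col / (K - 1)) / (ss_err / ((J - 1) * (K - 1)))
    return ss_col, ss_err, F


class TestQCAnova:
    def test_matches_brute_force_on_random_balanced_tables(self):
        rng = np.random.default_rng(1)
        st = meta_qc_blocks(2, 5)
        vals = rng.uniform(10, 100, (6, 10))
        res = qc_anova(fm_of(vals), st, log_transform=False)
        for i in range(6):
            D = vals[i].reshape(2, 5)
            ss_run, ss_err, F = brute_force_two_way_additive(D)
            assert res.table.loc[i, "ss_run"] == pytest.approx(ss_run, abs=1e-8)
            assert res.table.loc[i, "ss_err"] == pytest.approx(ss_err, abs=1e-8)
            assert res.table.loc[i, "F_zeta"] == pytest.approx(F, abs=1e-8)

    def test_batch_shift_leaves_f_unchanged(self):
        rng = np.random.default_rng(2)
        st = meta_qc_blocks(2, 5)
        vals = rng.uniform(10, 100, (4, 10))
        shifted = vals.copy()
        shifted[:, 5:] += 37.0  # pure batch offset: absorbed by the block effect
        f0 = qc_anova(fm_of(vals), st, log_transform=False).table["F_zeta"]
        f1 = qc_anova(fm_of(shifted), st, log_transform=False).table["F_zeta"]
        np.testing.assert_allclose(f0, f1, rtol=1e-8)

    def test_zero_run_effect_zero_f(self):
        st = meta_qc_blocks(2, 5)
        vals = np.tile([[10.0], [20.0]], (1, 10))
        vals[:, 5:] += 5.0  # batch effect only
        res = qc_anova(fm_of(vals), st, log_transform=False)
        np.testing.assert_allclose(res.table["F_zeta"], 0.0, atol=1e-10)
        np.testing.assert_allclose(res.table["p_zeta"], 1.0)

    def test_single_block_flagged(self):
        st = meta_qc_blocks(1, 5)
        res = qc_anova(fm_of(np.random.default_rng(3).uniform(1, 5, (2, 5))), st)
        assert "degenerate" in res.tag
        assert res.table["F_zeta"].isna().all()

    def test_unbalanced_rejected(self):
        rows = meta_qc_blocks(2, 5).table.iloc[:-1]
        st = SampleTable(rows)
        with pytest.raises(ValidationError, match="unbalanced"):
            qc_anova(fm_of(np.ones((2, 9)) + np.arange(9)), st)


def paired_meta(n_case=4, n_control=5):
    rows = []
    order = 1
    for e in ("F", "R"):
        order = 1
        for i in range(n_case + n_control):
            g = "case" if i < n_case else "control"
            rows.append({"sample_id": f"{e}{i}", "analysis_order": order,
                         "batch": "B1", "experiment": e, "group": g,
                         "subject": f"subj{i}"})
            order += 1
    return SampleTable(pd.DataFrame(rows))


class TestCaseControlAnova:
    def test_within_batch_matches_brute_force_group_means(self):
        rng = np.random.default_rng(4)
        st = paired_meta()
        vals = rng.uniform(10, 100, (3, 18))
        res = case_control_anova(fm_for(st, vals), st, "within_batch", batch="B1",
                                 log_transform=False)
        meta = st.table
        for i in range(3):
            df = meta.assign(y=vals[i])
            y = vals[i]
            grand = y.mean()
            gm = df.groupby("group")["y"].mean()
            me = df.groupby("experiment")["y"].mean()
            n_g = df.groupby("group")["y"].count() / 2  # subjects per group
            sub = df.groupby(["subject", "group"])["y"].mean().reset_index()
            ss_group = sum(2 * n_g[g] * (gm[g] - grand) ** 2 for g in gm.index)
            ss_subj = 2 * sum((r["y"] - gm[r["group"]]) ** 2
                              for _, r in sub.iterrows())
            ss_exp = sum(9 * (me[e] - grand) ** 2 for e in me.index)
            cell = df.groupby(["group", "experiment"])["y"].mean()
            ss_int = sum(n_g[g] * (m - gm[g] - me[e] + grand) ** 2
                         for (g, e), m in cell.items())
            ss_err = ((y - grand) ** 2).sum() - ss_group - ss_subj - ss_exp - ss_int
            L, G = 9, 2
            F_alpha = (ss_group / (G - 1)) / (ss_subj / (L - G))
            F_gamma = (ss_int / 1) / (ss_err / (L - G))
            assert res.table.loc[i, "ss_subject"] == pytest.approx(ss_subj, rel=1e-10)
            assert res.table.loc[i, "ss_err"] == pytest.approx(ss_err, rel=1e-10)
            assert res.table.loc[i, "F_alpha"] == pytest.approx(F_alpha, rel=1e-8)
            assert res.table.loc[i, "F_gamma"] == pytest.approx(F_gamma, rel=1e-8)

    def test_unpaired_subject_rejected(self):
        st = paired_meta()
        dropped = SampleTable(st.table.iloc[:-1])
        vals = np.random.default_rng(5).uniform(1, 10, (2, 17))
        with pytest.raises(ValidationError, match="subj8"):
            case_control_anova(fm_for(dropped, vals), dropped, "within_batch", batch="B1")

    def test_between_batch_matches_hand_two_way(self):
        # balanced 2 groups x 2 batches with 2 samples per cell
        rows = []
        sid = 0
        for b in ("B1", "B2"):
            order = 1
            for g in ("case", "control"):
                for _ in range(2):
                    rows.append({"sample_id": f"s{sid}", "analysis_order": order,
                                 "batch": b, "experiment": "F", "group": g})
                    sid += 1
                    order += 1
        st = SampleTable(pd.DataFrame(rows))
        y = np.array([[3.0, 5.0, 7.0, 9.0, 4.0, 6.0, 10.0, 14.0]])
        res = case_control_anova(fm_of(y), st, "between_batch", log_transform=False)
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = st.table.assign(y=y[0])
        m = ols("y ~ C(group) * C(batch)", data=df).fit()
        an = sm.stats.anova_lm(m, typ=2)
        mse = an.loc["Residual", "sum_sq"] / an.loc["Residual", "df"]
        assert res.table.loc[0, "F_alpha"] == pytest.approx(
            (an.loc["C(group)", "sum_sq"] / 1) / mse, rel=1e-8)
        assert res.table.loc[0, "F_gamma"] == pytest.approx(
            (an.loc["C(group):C(batch)", "sum_sq"] / 1) / mse, rel=1e-8)

    def test_null_pvalues_uniform(self):
        # no group effect: the group-test p-values should be uniform
        from scipy import stats

        rng = np.random.default_rng(6)
        st = paired_meta(10, 12)
        p = 500
        vals = np.exp(rng.normal(5, 1, (p, 1)) + rng.normal(0, 0.3, (p, 44)))
        res = case_control_anova(fm_for(st, vals), st, "within_batch", batch="B1")
        pa = res.table["p_alpha"].dropna().to_numpy()
        assert stats.kstest(pa, "uniform").pvalue > 0.01

    def test_non_proportional_cells_rejected(self):
        rows = []
        sid = 0
        for b, counts in [("B1", (3, 2)), ("B2", (2, 3))]:
            order = 1
            for g, c in zip(("case", "control"), counts):
                for _ in range(c):
                    rows.append({"sample_id": f"s{sid}", "analysis_order": order,
                                 "batch": b, "experiment": "F", "group": g})
                    sid += 1
                    order += 1
        st = SampleTable(pd.DataFrame(rows))
        with pytest.raises(ValidationError, match="proportional"):
            case_control_anova(fm_of(np.ones((2, 10)) + np.arange(10)), st,
                               "between_batch")


class TestStorey:
    def test_hand_example(self):
        q = storey_qvalues([0.01, 0.02, 0.9], lambda_=0.5)
        np.testing.assert_allclose(q, [0.02, 0.02, 0.6], atol=1e-12)

    def test_all_ones(self):
        np.testing.assert_allclose(storey_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_pi0_one_equals_bh_exactly(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 200)
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_monotone_in_p_and_order_invariant(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 100)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        perm = rng.permutation(100)
        np.testing.assert_array_equal(storey_qvalues(p[perm]), q[perm])

    def test_nan_propagates(self):
        q = storey_qvalues([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            storey_qvalues([])


class TestReport:
    def test_raw_vs_itself_identical_metrics(self, sim_small):
        _, fm, st, _ = sim_small
        rep = evaluation_report(fm, {"copy": fm}, st)
        a = rep.summary.set_index("method")
        assert a.loc["raw", "pct_qc_significant"] == a.loc["copy", "pct_qc_significant"]
        assert a.loc["raw", "median_qc_cv"] == a.loc["copy", "median_qc_cv"]

    def test_mismatched_shape_rejected(self, sim_small):
        _, fm, st, _ = sim_small
        small = fm.subset_features(np.arange(3))
        with pytest.raises(ValidationError, match="shape"):
            evaluation_report(fm, {"bad": small}, st)

    def test_report_writes_files(self, sim_small, tmp_path):
        _, fm, st, _ = sim_small
        rep = evaluation_report(fm, {}, st)
        rep.write(tmp_path / "report")
        assert (tmp_path / "report" / "report.tsv").exists()
        assert (tmp_path / "report" / "summary.json").exists()
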