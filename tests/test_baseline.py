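"""Hand-computed oracles and invariants for the nine normalization families."""

import numpy as np
import pandas as pd
import pytest

from lcmsnorm import (
    FeatureMatrix,
    SampleTable,
    internal_standard_normalize,
    loess_order_normalize,
    ma_normalize,
    median_scale,
    pretreat,
    qc_consistency_filter,
    quantile_normalize,
    stable_feature_normalize,
    tic_normalize,
)
from lcmsnorm.baseline import DEFAULT_SPAN_GRID, _loess_predict, _loo_span
from lcmsnorm.exceptions import DegenerateDataError, ValidationError


def fm_of(values, **kw):
    values = np.asarray(values, float)
    p, n = values.shape
    return FeatureMatrix(values, [f"f{i}" for i in range(p)],
                         [f"s{j}" for j in range(n)], **kw)


class TestTIC:
    def test_hand_example(self):
        # columns [2,6] and [4,12]: totals 8 and 16, mean 12 -> both [3,9]
        res = tic_normalize(fm_of([[2, 4], [6, 12]]))
        np.testing.assert_allclose(res.matrix.values, [[3, 3], [9, 9]])

    def test_identical_columns_unchanged(self):
        res = tic_normalize(fm_of([[1, 1], [5, 5]]))
        np.testing.assert_allclose(res.matrix.values, [[1, 1], [5, 5]])

    def test_column_sums_equal_after(self):
        rng = np.random.default_rng(0)
        fm = fm_of(rng.uniform(1, 100, (20, 6)))
        out = tic_normalize(fm).matrix.values
        sums = out.sum(axis=0)
        np.testing.assert_allclose(sums, sums[0], atol=1e-10)

    def test_zero_column_rejected(self):
        with pytest.raises(DegenerateDataError, match="s1"):
            tic_normalize(fm_of([[1, 0], [2, 0]]))

    def test_idempotent_and_scale_equivariant(self):
        rng = np.random.default_rng(1)
        fm = fm_of(rng.uniform(1, 100, (10, 5)))
        once = tic_normalize(fm).matrix
        twice = tic_normalize(once).matrix
        np.testing.assert_allclose(twice.values, once.values, atol=1e-8)
        scaled = tic_normalize(fm.copy_with(3.0 * fm.values)).matrix
        np.testing.assert_allclose(scaled.values, 3.0 * once.values, rtol=1e-10)


class TestMedianScale:
    def test_hand_example(self):
        # x_j=[2,8,18] vs ref [1,4,6]: ratios [2,2,3], median 2 -> [1,4,9]
        fm = fm_of(np.array([[1, 2], [4, 8], [6, 18]]))
        res = median_scale(fm, reference_policy="any_sample", reference_id="s0")
        np.testing.assert_allclose(res.matrix.values[:, 1], [1, 4, 9])
        np.testing.assert_allclose(res.matrix.values[:, 0], [1, 4, 6])

    def test_doubled_sample_maps_to_reference(self):
        ref = np.array([1.0, 4.0, 6.0])
        fm = fm_of(np.column_stack([ref, 2 * ref]))
        res = median_scale(fm, reference_policy="any_sample", reference_id="s0")
        np.testing.assert_allclose(res.matrix.values[:, 1], ref)

    def test_invert_flag(self):
        ref = np.array([1.0, 4.0, 6.0])
        fm = fm_of(np.column_stack([ref, 2 * ref]))
        res = median_scale(fm, reference_policy="any_sample", reference_id="s0",
                           invert=True)
        np.testing.assert_allclose(res.matrix.values[:, 1], ref)

    def test_min_missing_reference_choice(self):
        vals = np.array([[1.0, np.nan, 2.0], [2.0, 3.0, 4.0], [3.0, 4.0, 6.0]])
        res = median_scale(fm_of(vals), reference_policy="min_missing")
        assert res.parameters["reference"] == "s0"

    def test_mostly_missing_reference_rejected(self):
        vals = np.array([[np.nan, 1.0], [np.nan, 2.0], [3.0, 3.0]])
        with pytest.raises(DegenerateDataError, match="missing"):
            median_scale(fm_of(vals), reference_policy="any_sample", reference_id="s0")


class TestPretreat:
    def test_center(self):
        res = pretreat(fm_of([[1, 2, 3]]), "center")
        np.testing.assert_allclose(res.matrix.values, [[-1, 0, 1]])

    def test_range_hand_example(self):
        res = pretreat(fm_of([[2, 4, 6]]), "range")
        np.testing.assert_allclose(res.matrix.values, [[-0.5, 0, 0.5]])

    def test_pareto_default_vs_printed_form(self):
        fm = fm_of([[1.0, 2.0, 3.0]])
        sd = np.std([1, 2, 3], ddof=1)
        default = pretreat(fm, "pareto").matrix.values
        np.testing.assert_allclose(default, (np.array([[1, 2, 3]]) - 2) / np.sqrt(sd))
        printed = pretreat(fm, "pareto", strict_printed_form=True).matrix.values
        auto = pretreat(fm, "auto").matrix.values
        np.testing.assert_allclose(printed, auto)

    def test_vast_constant_row_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = pretreat(fm_of([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]), "vast")
        assert res.failed_features == ["f0"]
        np.testing.assert_allclose(res.matrix.values[0], [5, 5, 5])

    def test_log_with_zero_needs_offset(self):
        fm = fm_of([[0.0, 1.0, 2.0]])
        with pytest.raises(DegenerateDataError, match="offset"):
            pretreat(fm, "log")
        res = pretreat(fm, "log", log_offset=1.0)
        lx = np.log(np.array([0, 1, 2.0]) + 1)
        np.testing.assert_allclose(res.matrix.values, (lx - lx.mean())[None, :])


class TestInternalStandards:
    def test_constant_standard_is_identity(self):
        fm = fm_of([[5, 5, 5], [1, 2, 3]])
        res = internal_standard_normalize(fm, ["f0"], mode="single",
                                          reference_id="s0")
        np.testing.assert_allclose(res.matrix.values, fm.values)

    def test_doubled_standard_halves_sample(self):
        fm = fm_of([[5, 10], [4, 4]])
        res = internal_standard_normalize(fm, ["f0"], mode="single",
                                          reference_id="s0")
        np.testing.assert_allclose(res.matrix.values[:, 1], [5, 2])

    def test_nearest_assigns_by_rt(self):
        fm = fm_of([[5, 5], [7, 7], [1, 2]],
                   feature_rt=np.array([100.0, 500.0, 120.0]),
                   feature_mz=np.array([200.0, 300.0, 400.0]))
        res = internal_standard_normalize(fm, ["f0", "f1"], mode="nearest",
                                          reference_id="s0")
        assign = res.factors.set_index("feature_id")["standard"]
        assert assign["f2"] == "f0"

    def test_missing_standard_value_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValidationError, match="f0"):
            internal_standard_normalize(fm_of(vals), ["f0"])


class TestQuantile:
    def test_hand_example(self):
        res = quantile_normalize(fm_of(np.array([[1, 4], [2, 5], [3, 6.0]])))
        np.testing.assert_allclose(res.matrix.values,
                                   [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_columns_unchanged(self):
        fm = fm_of(np.array([[1, 1], [3, 3], [2, 2.0]]))
        res = quantile_normalize(fm)
        np.testing.assert_allclose(res.matrix.values, fm.values)

    def test_columns_share_sorted_multiset(self):
        rng = np.random.default_rng(2)
        fm = fm_of(rng.uniform(0, 50, (30, 5)))
        out = quantile_normalize(fm).matrix.values
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_array_equal(np.sort(out[:, j]), ref)

    def test_ties_get_mean_of_candidates(self):
        # column 0 has a tie at value 1 spanning the two smallest ranks
        fm = fm_of(np.array([[1, 10], [1, 20], [5, 30.0]]))
        out = quantile_normalize(fm).matrix.values
        assert out[0, 0] == out[1, 0]

    def test_missing_stays_missing(self):
        vals = np.array([[1.0, 4.0], [np.nan, 5.0], [3.0, 6.0]])
        out = quantile_normalize(fm_of(vals)).matrix.values
        assert np.isnan(out[1, 0]) and np.isfinite(out[1, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        fm = fm_of(rng.uniform(0, 50, (20, 4)))
        once = quantile_normalize(fm).matrix
        twice = quantile_normalize(once).matrix
        np.testing.assert_allclose(twice.values, once.values, atol=1e-8)


class TestMA:
    def test_reference_sample_unchanged(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 100, (30, 3))
        res = ma_normalize(fm_of(vals), reference_policy="sample", reference_id="s0")
        np.testing.assert_allclose(res.matrix.values[:, 0], vals[:, 0], rtol=1e-10)

    def test_constant_fold_change_removed(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(1, 100, 40)
        fm = fm_of(np.column_stack([ref, 3.0 * ref]))
        res = ma_normalize(fm, reference_policy="sample", reference_id="s0")
        np.testing.assert_allclose(res.matrix.values[:, 1], ref, rtol=1e-8)

    def test_corrected_m_has_zero_mean(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(1, 100, (50, 4))
        res = ma_normalize(fm_of(vals), regression="linear", reference_policy="mean")
        ref = np.mean(vals, axis=1)
        for j in range(4):
            m = np.log(res.matrix.values[:, j]) - np.log(ref)
            # residuals of least squares: mean zero
            assert abs(m.mean()) < 1e-8

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            ma_normalize(fm_of([[0.0, 1.0], [2.0, 3.0]]))

    def test_pairwise_converges(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(1, 100, (30, 4))
        res = ma_normalize(fm_of(vals), reference_policy="pairwise")
        assert res.parameters["iterations"] <= 50


class TestQCFilter:
    def _setup(self):
        rng = np.random.default_rng(8)
        # f0: stable in QC, variable in samples (keep); f1: noisy QC (drop)
        qc = np.column_stack([100 + rng.normal(0, 2, 4), rng.uniform(20, 300, 4)]).T
        smp = np.column_stack([rng.uniform(50, 200, 4), 100 + rng.normal(0, 5, 4)]).T
        fm = fm_of(np.hstack([qc, smp]))
        rows = [{"sample_id": f"s{j}", "analysis_order": j + 1, "batch": "B1",
                 "experiment": "F", "group": "QC" if j < 4 else "case"}
                for j in range(8)]
        return fm, SampleTable(pd.DataFrame(rows))

    def test_matches_brute_force(self):
        fm, st = self._setup()
        res = qc_consistency_filter(fm, st, TH1=0.3, TH2=2.0)
        qc_vals, s_vals = fm.values[:, :4], fm.values[:, 4:]
        for i, fid in enumerate(fm.feature_ids):
            cv_qc = np.std(qc_vals[i], ddof=1) / abs(np.mean(qc_vals[i]))
            cv_s = np.std(s_vals[i], ddof=1) / abs(np.mean(s_vals[i]))
            expect = (cv_qc < 0.3) and (cv_s > 2.0 * cv_qc)
            assert (fid in res.retained_feature_ids) == expect

    def test_c1_violation_removes_regardless(self):
        fm, st = self._setup()
        # TH1 below every QC CV: no feature can pass C1 whatever its CV_S
        with pytest.raises(DegenerateDataError):
            qc_consistency_filter(fm, st, TH1=1e-9, TH2=0.0)

    def test_th2_zero_reduces_to_c1(self):
        fm, st = self._setup()
        res = qc_consistency_filter(fm, st, TH1=10.0, TH2=0.0)
        cv_qc = res.factors["cv_qc"].to_numpy()
        assert res.factors["retained"].tolist() == (cv_qc < 10.0).tolist()


class TestStableFeatures:
    def test_identity_when_all_columns_identical(self):
        fm = fm_of(np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4)))
        res = stable_feature_normalize(fm, T_CV=np.inf)
        np.testing.assert_allclose(res.matrix.values, fm.values)

    def test_single_stable_feature_rule(self):
        # stable feature at 2x grand median in sample 1 -> sample divided by 2
        fm = fm_of(np.array([[10.0, 20.0], [1.0, 500.0]]))
        res = stable_feature_normalize(fm, T_CV=0.5)
        assert res.retained_feature_ids == ["f0"]
        grand = np.median([10.0, 20.0])
        np.testing.assert_allclose(res.matrix.values[:, 1],
                                   fm.values[:, 1] / 20.0 * grand)

    def test_infinite_threshold_is_median_scaling(self):
        rng = np.random.default_rng(9)
        fm = fm_of(rng.uniform(1, 100, (15, 4)))
        res = stable_feature_normalize(fm, T_CV=np.inf)
        med = np.median(fm.values, axis=0)
        expect = fm.values / med * np.median(med)
        np.testing.assert_allclose(res.matrix.values, expect, rtol=1e-10)

    def test_empty_stable_set_rejected(self):
        rng = np.random.default_rng(10)
        fm = fm_of(rng.uniform(1, 1000, (10, 5)))
        with pytest.raises(DegenerateDataError, match="T_CV"):
            stable_feature_normalize(fm, T_CV=1e-12)


class TestLoessOrder:
    def _meta(self, n=20, qc_every=2):
        rows = [{"sample_id": f"s{t - 1}", "analysis_order": t, "batch": "B1",
                 "experiment": "F", "group": "QC" if t % qc_every == 0 else "case"}
                for t in range(1, n + 1)]
        return SampleTable(pd.DataFrame(rows))

    def test_flat_qc_is_identity(self):
        st = self._meta()
        vals = np.full((3, 20), 50.0)
        res = loess_order_normalize(fm_of(vals), st, span=0.8, working_space="raw")
        np.testing.assert_allclose(res.matrix.values, vals, atol=1e-8)

    def test_linear_drift_removed(self):
        st = self._meta()
        t = np.arange(1, 21, dtype=float)
        vals = np.tile(10 + t, (2, 1))
        res = loess_order_normalize(fm_of(vals), st, span=1.0, qc_only=False,
                                    working_space="raw")
        out = res.matrix.values
        # corrected residuals constant across order
        assert np.ptp(out[0]) < 1e-6

    def test_loo_span_matches_exhaustive_grid(self):
        rng = np.random.default_rng(11)
        t = np.arange(1.0, 21.0, 2.0)
        x = np.sin(t / 5.0) + rng.normal(0, 0.1, len(t))
        best, sse = _loo_span(x, t, DEFAULT_SPAN_GRID)
        # brute force: recompute every span's LOO error independently
        brute = {}
        for span in DEFAULT_SPAN_GRID:
            if span * len(x) < 2:
                continue
            err = 0.0
            for k in range(len(x)):
                mask = np.arange(len(x)) != k
                err += (x[k] - _loess_predict(x[mask], t[mask], np.array([t[k]]),
                                              span)[0]) ** 2
            brute[span] = err
        assert best == min(brute, key=lambda sp: (brute[sp], sp))
        for sp in brute:
            np.testing.assert_allclose(sse[sp], brute[sp], rtol=1e-10)

    def test_too_few_qc_rejected(self):
        st = self._meta(6, qc_every=3)  # 2 QCs only
        with pytest.raises(DegenerateDataError):
            loess_order_normalize(fm_of(np.ones((2, 6))), st, span="cv")
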