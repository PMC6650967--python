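import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitphase import (GaitPhase, LabelSequence, goodness, goodness_band,
                       icc_a1, mt_cov, sample_metrics, timing_errors)

FS = 200.0


def seq(labels, fs=FS):
    return LabelSequence(np.asarray(labels, dtype=np.int8), fs)


def four_equal_phases(n_per_phase=50, n_strides=6):
    lab = np.tile(np.repeat([0, 1, 2, 3], n_per_phase), n_strides)
    return seq(lab)


class TestGoodness:
    @pytest.mark.parametrize("tpr,tnr,expect", [
        (1.0, 1.0, 0.0),
        (0.5, 0.5, math.sqrt(0.5)),
        (0.0, 0.0, math.sqrt(2.0)),
    ])
    def test_known_corners(self, tpr, tnr, expect):
        assert goodness(tpr, tnr) == pytest.approx(expect, abs=1e-12)

    def test_chance_level_rounds_to_point_seven(self):
        assert round(goodness(0.5, 0.5), 1) == 0.7

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            goodness(1.2, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_symmetric(self, a, b, c):
        assert goodness(a, b) == pytest.approx(goodness(b, a))
        lo, hi = sorted((a, c))
        assert goodness(hi, b) <= goodness(lo, b) + 1e-12

    def test_bands(self):
        assert goodness_band(0.1) == "optimum"
        assert goodness_band(0.5) == "good"
        assert goodness_band(math.sqrt(0.5)) == "random"
        assert goodness_band(1.0) == "bad"


class TestSampleMetrics:
    def test_perfect_prediction(self):
        ref = four_equal_phases()
        sc = sample_metrics(ref, ref)
        assert sc.macro_tpr == 1.0 and sc.macro_tnr == 1.0
        assert sc.accuracy_pct == 100.0
        assert sc.macro_g == 0.0

    def test_constant_classifier_scores_chance_floor(self):
        """A single-phase constant prediction over four equal phases scores
        25 % sensitivity and 75 % specificity."""
        ref = four_equal_phases()
        pred = seq(np.zeros(len(ref), dtype=int))
        sc = sample_metrics(pred, ref)
        assert sc.macro_tpr == pytest.approx(0.25, abs=1e-12)
        assert sc.macro_tnr == pytest.approx(0.75, abs=1e-12)
        assert goodness_band(sc.macro_g) == "bad"

    def test_shift_within_tolerance_keeps_full_sensitivity(self):
        ref = four_equal_phases()
        shift = 4  # 20 ms at 200 Hz < +-30 ms window
        pred = seq(np.roll(ref.labels, shift))
        sc = sample_metrics(pred, ref)
        assert all(v == 1.0 for v in sc.tpr.values())

    def test_zero_tolerance_reduces_to_exact_agreement(self):
        ref = four_equal_phases()
        pred = seq(np.roll(ref.labels, 2))
        sc = sample_metrics(pred, ref, tolerance_ms=0.0)
        agree = np.mean(pred.labels == ref.labels)
        assert sc.accuracy_pct == pytest.approx(agree * 100)
        for phase in GaitPhase:
            p = phase.name
            is_p = ref.labels == int(phase)
            tp = np.sum(is_p & (pred.labels == int(phase)))
            assert sc.tpr[p] == pytest.approx(tp / np.sum(is_p))

    def test_confusion_rows_sum_to_hundred(self):
        ref = four_equal_phases()
        rng = np.random.default_rng(0)
        pred = seq(rng.integers(0, 4, len(ref)))
        sc = sample_metrics(pred, ref)
        assert np.allclose(sc.confusion_pct.sum(axis=1), 100.0, atol=1e-6)

    def test_accuracy_invariant_under_consistent_relabeling(self):
        ref = four_equal_phases()
        rng = np.random.default_rng(1)
        pred = seq(rng.integers(0, 4, len(ref)))
        perm = np.array([2, 3, 0, 1])
        sc1 = sample_metrics(pred, ref)
        sc2 = sample_metrics(seq(perm[pred.labels]), seq(perm[ref.labels]))
        assert sc1.accuracy_pct == pytest.approx(sc2.accuracy_pct)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sample_metrics(seq([0, 1]), seq([0, 1, 2]))


class TestTimingErrors:
    def test_identical_sequences_have_zero_error(self):
        ref = four_equal_phases()
        rep = timing_errors(ref, ref)
        for p in ("HS", "FF", "HO", "SP"):
            assert np.allclose(rep.errors_ms[p], 0.0)
            assert rep.misses[p] == 0

    def test_uniform_shift_reported_everywhere(self):
        ref = four_equal_phases()
        pred = seq(np.roll(ref.labels, -4))  # 4 samples early = -20 ms
        rep = timing_errors(pred, ref)
        for p in ("FF", "HO", "SP"):
            assert np.allclose(rep.errors_ms[p], -20.0)

    def test_missing_onset_counted_per_phase(self):
        ref = four_equal_phases(n_per_phase=50, n_strides=4)
        lab = ref.labels.copy()
        # erase the second FF occurrence (absorb into HS)
        start = 200 + 50
        lab[start:start + 50] = 0
        rep = timing_errors(seq(lab), ref)
        assert rep.misses["FF"] == 1
        assert rep.misses["HO"] == 0 and rep.misses["SP"] == 0

    def test_antisymmetry(self):
        ref = four_equal_phases()
        rng = np.random.default_rng(2)
        pred = seq(np.roll(ref.labels, int(rng.integers(1, 6))))
        fwd = timing_errors(pred, ref)
        rev = timing_errors(ref, pred)
        for p in ("HS", "FF", "HO", "SP"):
            assert np.allclose(fwd.errors_ms[p], -rev.errors_ms[p])

    def test_rate_mismatch_rejected(self):
        with pytest.raises(ValueError):
            timing_errors(seq([0, 1], fs=100.0), seq([0, 1], fs=200.0))


class TestMtCov:
    def test_identical_strides_zero_cov(self):
        lab = np.concatenate([[3] * 5, np.tile(np.repeat([0, 1, 2, 3],
                                                         [20, 70, 50, 60]), 4), [0]])
        rep = mt_cov(seq(lab))
        assert rep.cov_pct["stride"] == pytest.approx(0.0, abs=1e-9)
        for p in ("HS", "FF", "HO", "SP"):
            assert rep.cov_pct[p] == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_stride_stats(self):
        # strides of 900 ms and 1100 ms at 200 Hz
        lab = np.concatenate([[3] * 5,
                              np.repeat([0, 1, 2, 3], [18, 63, 45, 54]),
                              np.repeat([0, 1, 2, 3], [22, 77, 55, 66]), [0]])
        rep = mt_cov(seq(lab))
        assert rep.mt_ms["stride"] == pytest.approx(1000.0)
        assert rep.cov_pct["stride"] == pytest.approx(14.1421, abs=1e-3)

    def test_cov_scale_invariant(self):
        lab1 = np.concatenate([[3] * 5,
                               np.repeat([0, 1, 2, 3], [18, 63, 45, 54]),
                               np.repeat([0, 1, 2, 3], [22, 77, 55, 66]), [0]])
        lab2 = np.repeat(lab1, 2)  # all durations doubled
        r1, r2 = mt_cov(seq(lab1)), mt_cov(seq(lab2))
        assert r1.cov_pct["stride"] == pytest.approx(r2.cov_pct["stride"])
        assert r2.mt_ms["stride"] == pytest.approx(2 * r1.mt_ms["stride"])

    def test_insufficient_strides_rejected(self):
        lab = np.concatenate([[3] * 5, np.repeat([0, 1, 2, 3], 20), [0]])
        with pytest.raises(ValueError):
            mt_cov(seq(lab))


class TestIcc:
    def test_identical_columns_give_one(self):
        data = np.tile(np.array([[1.0], [5.0], [9.0], [2.0]]), (1, 3))
        icc, band = icc_a1(data)
        assert icc == pytest.approx(1.0)
        assert band == "excellent"

    def test_fixed_matrix_matches_anova_hand_computation(self):
        """Two-way ANOVA computed longhand on a fixed 5x2 matrix."""
        data = np.array([[10.0, 14.0], [12.0, 15.0], [18.0, 25.0],
                         [8.0, 9.0], [20.0, 27.0]])
        n, k = data.shape
        grand = data.sum() / data.size
        ss_rows = sum(k * (row.mean() - grand) ** 2 for row in data)
        ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
        ss_tot = sum((v - grand) ** 2 for v in data.ravel())
        msr = ss_rows / (n - 1)
        msc = ss_cols / (k - 1)
        mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
        expect = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert icc_a1(data)[0] == pytest.approx(expect, abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(0)
        data = rng.normal(50, 10, (8, 3))
        df = pd.DataFrame({"targets": np.repeat(np.arange(8), 3),
                           "raters": np.tile(np.arange(3), 8),
                           "scores": data.ravel()})
        res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores")
        expect = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_a1(data)[0] == pytest.approx(expect, abs=1e-10)

    def test_large_offset_penalized_by_absolute_agreement(self):
        base = np.array([[10.0], [12.0], [18.0], [8.0], [20.0]])
        data = np.hstack([base, base + 50.0])
        icc, _ = icc_a1(data)
        assert icc < 0.5

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1, (500, 2))
        icc, band = icc_a1(data)
        assert abs(icc) < 0.1
        assert band == "poor"

    def test_degenerate_constant_matrix_returns_one(self):
        assert icc_a1(np.full((4, 2), 3.0))[0] == 1.0

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            icc_a1(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            icc_a1(np.array([[1.0, np.nan], [2.0, 3.0]]))
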