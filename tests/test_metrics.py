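"""Evaluation statistics against brute-force oracles.

Each metric is checked against an independent direct computation (explicit
sort/median, hand-counted rates, explicit two-way ANOVA sums of squares),
plus the documented invariances.  The ICC implementation is additionally
cross-checked against pingouin's two-way random absolute-agreement ICC.
"""

import numpy as np
import pytest

from spinesva.heatmaps import LandmarkPoint
from spinesva.metrics import (
    bland_altman,
    compute_sva,
    detection_curve,
    detection_rate,
    icc_two_way_random_absolute,
    mae_sva,
)
from spinesva.preprocess import ImageRecord


def _record(mmx=0.25, mmy=0.25, facing="right"):
    return ImageRecord(
        pixels=np.zeros((4, 4), np.float32),
        mm_per_pixel_x=mmx,
        mm_per_pixel_y=mmy,
        facing=facing,
    )


class TestComputeSva:
    def test_aligned_landmarks_give_zero(self):
        sva = compute_sva(LandmarkPoint(40, 10), LandmarkPoint(40, 90), _record())
        assert sva.value == 0.0

    def test_pixel_offset_times_scale(self):
        sva = compute_sva(LandmarkPoint(60, 10), LandmarkPoint(40, 90), _record(mmx=0.25))
        assert sva.value == pytest.approx(5.0)

    def test_facing_flip_negates_and_preserves_magnitude(self):
        c7, s1 = LandmarkPoint(60, 10), LandmarkPoint(40, 90)
        right = compute_sva(c7, s1, _record(facing="right"))
        left = compute_sva(c7, s1, _record(facing="left"))
        assert left.value == pytest.approx(-right.value)
        assert abs(left.value) == abs(right.value)


class TestMaeSva:
    def test_identical_sequences(self):
        s = mae_sva([1.0, -2.0, 3.0], [1.0, -2.0, 3.0])
        assert s.median_abs_error == 0.0
        assert s.outlier_count == 0

    def test_odd_length_median(self):
        s = mae_sva([0, 0, 0], [1, 2, 9])
        assert s.median_abs_error == 2.0
        assert s.outlier_count == 0

    def test_even_length_median_averages_central_pair(self):
        # absolute errors {1, 3, 11, 15}: median (3+11)/2 = 7; two above 10 mm
        s = mae_sva([0, 0, 0, 0], [1, 3, 11, 15])
        assert s.median_abs_error == 7.0
        assert s.outlier_count == 2
        assert s.outlier_fraction == pytest.approx(0.5)

    def test_matches_sort_oracle_on_random_inputs(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            a = rng.normal(size=n) * 20
            b = rng.normal(size=n) * 20
            s = mae_sva(a, b)
            errs = sorted(abs(x - y) for x, y in zip(a, b))
            mid = n // 2
            med = errs[mid] if n % 2 else (errs[mid - 1] + errs[mid]) / 2
            assert s.median_abs_error == pytest.approx(med)
            assert s.outlier_count == sum(e > 10 for e in errs)

    def test_global_sign_flip_invariance(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        assert mae_sva(a, b).median_abs_error == pytest.approx(
            mae_sva(-a, -b).median_abs_error
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae_sva([1.0], [1.0, 2.0])


class TestDetectionRate:
    def test_exact_matches_detect_at_any_threshold(self):
        pts = [LandmarkPoint(3, 4), LandmarkPoint(8, 1)]
        recs = [_record(), _record()]
        assert detection_rate(pts, pts, recs, 0.001) == 1.0

    def test_half_detected_counted_by_hand(self):
        true = [LandmarkPoint(0, 0), LandmarkPoint(0, 0)]
        pred = [LandmarkPoint(1, 0), LandmarkPoint(100, 0)]
        recs = [_record(mmx=1.0, mmy=1.0)] * 2
        assert detection_rate(true, pred, recs, 2.0) == 0.5

    def test_monotone_in_threshold_and_curve(self, rng):
        n = 25
        true = [LandmarkPoint(*rng.uniform(0, 100, 2)) for _ in range(n)]
        pred = [LandmarkPoint(t.x + rng.normal(0, 5), t.y + rng.normal(0, 5)) for t in true]
        recs = [_record(mmx=rng.uniform(0.5, 2), mmy=rng.uniform(0.5, 2)) for _ in range(n)]
        curve = detection_curve(true, pred, recs, [0.5, 1, 2, 5, 10, 1e9])
        assert list(curve.rates) == sorted(curve.rates)
        assert curve.rates[-1] == 1.0
        # per-axis mm conversion oracle at one threshold
        d = [
            np.hypot((t.x - p.x) * r.mm_per_pixel_x, (t.y - p.y) * r.mm_per_pixel_y)
            for t, p, r in zip(true, pred, recs)
        ]
        assert detection_rate(true, pred, recs, 5.0) == pytest.approx(np.mean(np.array(d) <= 5))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            detection_rate([LandmarkPoint(0, 0)], [], [], 1.0)


def _icc_oracle(x):
    """Explicit two-way ANOVA sums-of-squares ICC(A,1)."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_raters_give_one(self, rng):
        a = rng.normal(size=10)
        res = icc_two_way_random_absolute(np.column_stack([a, a]))
        assert res.estimate == pytest.approx(1.0)

    def test_constant_rater_shift_lowers_agreement(self, rng):
        a = rng.normal(size=20) * 10
        shifted = icc_two_way_random_absolute(np.column_stack([a, a + 5]))
        assert shifted.estimate < 1.0

    def test_adding_constant_to_all_cells_is_invariant(self, rng):
        x = rng.normal(size=(12, 3)) * 4 + rng.normal(size=(12, 1)) * 10
        r1 = icc_two_way_random_absolute(x)
        r2 = icc_two_way_random_absolute(x + 7.3)
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-10)

    def test_five_by_two_toy_table_matches_sums_of_squares_oracle(self):
        x = np.array([[1.0, 2.0], [3.0, 3.5], [5.0, 4.0], [7.0, 8.0], [9.0, 8.5]])
        res = icc_two_way_random_absolute(x)
        assert res.estimate == pytest.approx(_icc_oracle(x), abs=1e-12)

    def test_randomized_tables_match_oracle(self, rng):
        for _ in range(100):
            n, k = int(rng.integers(4, 20)), int(rng.integers(2, 5))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 3
            res = icc_two_way_random_absolute(x)
            assert res.estimate == pytest.approx(_icc_oracle(x), abs=1e-9)
            assert res.ci_low <= res.estimate <= res.ci_high

    def test_matches_pingouin_estimate_and_ci(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1)) * 2
        res = icc_two_way_random_absolute(x)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 3),
                "rater": np.tile(np.arange(3), 15),
                "score": x.ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        ref = table[table["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert res.estimate == pytest.approx(float(ref["ICC"]), abs=1e-6)
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        lo, hi = ref[ci_col]
        assert res.ci_low == pytest.approx(float(lo), abs=0.02)
        assert res.ci_high == pytest.approx(float(hi), abs=0.02)

    def test_degenerate_all_equal_flagged(self):
        res = icc_two_way_random_absolute(np.ones((5, 2)))
        assert res.estimate == 1.0 and res.degenerate

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            icc_two_way_random_absolute(np.ones((2, 2)))


class TestBlandAltman:
    def test_equal_sequences_all_zero(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_diff == 0 and res.sd_diff == 0
        assert res.loa_low == 0 and res.loa_high == 0

    def test_constant_offset(self):
        a = np.array([5.0, 6.0, 7.0])
        res = bland_altman(a, a - 2)
        assert res.mean_diff == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(0.0)
        assert (res.loa_low, res.loa_high) == (pytest.approx(2.0), pytest.approx(2.0))
        assert res.median_abs_diff == pytest.approx(2.0)

    def test_matches_direct_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            a, b = rng.normal(size=n) * 10, rng.normal(size=n) * 10
            res = bland_altman(a, b)
            d = a - b
            assert res.mean_diff == pytest.approx(d.mean())
            assert res.sd_diff == pytest.approx(d.std(ddof=1))
            assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
            assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
            assert res.median_abs_diff == pytest.approx(np.median(np.abs(d)))
            assert res.loa_low <= res.mean_diff <= res.loa_high

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0, 2.0])
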