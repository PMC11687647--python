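import math

import numpy as np
import pandas as pd
import pytest

from zipfadapt import (
    consistency_filter,
    curve_by_seniority,
    representative_cap,
    smooth_curve,
    trend_slope_bootstrap,
)


def make_log(rows):
    """rows: (user, label_id, seniority, distance)"""
    return pd.DataFrame(
        rows, columns=["user", "label_id", "seniority", "distance"]
    )


class TestConsistencyFilter:
    def test_identity_when_every_label_reaches_cap(self):
        df = make_log([("u", 1, s, 0.0) for s in (1, 2, 3)])
        out = consistency_filter(df, 3)
        pd.testing.assert_frame_equal(out, df)

    def test_drops_labels_that_peak_early(self):
        df = make_log(
            [("u", 1, 1, 0), ("u", 1, 2, 0), ("u", 1, 3, 0),
             ("v", 2, 1, 0), ("v", 2, 2, 0)]
        )
        out = consistency_filter(df, 3)
        assert set(out["label_id"]) == {1}

    def test_matches_set_comprehension_oracle(self):
        rng = np.random.default_rng(4)
        rows = []
        for label in range(1, 8):
            for user in "abc":
                top = int(rng.integers(1, 6))
                rows += [(user, label, s, 0.0) for s in range(1, top + 1)]
        df = make_log(rows)
        s_max = 4
        out = consistency_filter(df, s_max)
        expected = {
            label
            for label in df["label_id"].unique()
            if df[df.label_id == label]["seniority"].max() >= s_max
        }
        assert set(out["label_id"]) == expected

    def test_cap_beyond_observed_seniority_rejected(self):
        df = make_log([("u", 1, 1, 0.0)])
        with pytest.raises(ValueError):
            consistency_filter(df, 5)


class TestRepresentativeCap:
    def test_full_sample_has_zero_margin(self):
        df = make_log([(u, 1, s, 0.0) for u in "abcd" for s in (1, 2)])
        report = representative_cap(df)
        assert report.table.iloc[0]["margin_of_error"] == pytest.approx(0.0)
        assert report.table.iloc[1]["margin_of_error"] == pytest.approx(0.0)

    def test_cochran_fpc_formula_value(self):
        # N=1000 pairs at level 1, 516 reaching level 2, z=1.96 -> e ≈ 0.030
        rows = []
        for i in range(1000):
            rows.append((f"u{i}", i, 1, 0.0))
            if i < 516:
                rows.append((f"u{i}", i, 2, 0.0))
        report = representative_cap(make_log(rows), margin=0.03, confidence=0.95)
        e = report.table.set_index("level").loc[2, "margin_of_error"]
        assert e == pytest.approx(0.0300, abs=5e-4)

    def test_margin_decreases_with_sample_size(self):
        z = 1.96
        N = 1000
        es = [
            z * math.sqrt(0.25 / n) * math.sqrt((N - n) / (N - 1))
            for n in range(10, N + 1, 10)
        ]
        assert all(a >= b for a, b in zip(es, es[1:]))

    def test_cap_is_largest_contiguously_representative_level(self):
        rows = []
        for i in range(1000):
            top = 3 if i < 300 else (2 if i < 990 else 1)
            for s in range(1, top + 1):
                rows.append((f"u{i}", i, s, 0.0))
        report = representative_cap(make_log(rows), margin=0.03)
        # level 2 has n=990 (representative), level 3 only n=300 (e ≈ 0.047)
        assert report.s_max == 2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            representative_cap(make_log([("u", 1, 1, 0.0)]), margin=1.5)
        with pytest.raises(ValueError):
            representative_cap(make_log([]).astype({"seniority": int}))


class TestCurveBySeniority:
    def test_single_record_levels(self):
        df = make_log([("u", 1, 1, 5.0), ("u", 1, 2, 4.0), ("u", 1, 3, 3.0)])
        curve = curve_by_seniority(df, "distance")
        assert curve["mean"].tolist() == [5.0, 4.0, 3.0]
        assert curve["std"].tolist() == [0.0, 0.0, 0.0]
        assert curve["n"].tolist() == [1, 1, 1]

    def test_hand_computed_means_and_population_std(self):
        df = make_log(
            [("u", 1, 1, 1.0), ("v", 1, 1, 3.0), ("w", 1, 1, 5.0),
             ("u", 1, 2, 2.0), ("v", 1, 2, 2.0)]
        )
        curve = curve_by_seniority(df, "distance")
        assert curve.loc[0, "mean"] == pytest.approx(3.0)
        # population std of (1,3,5) = sqrt(8/3)
        assert curve.loc[0, "std"] == pytest.approx(math.sqrt(8 / 3))
        assert curve.loc[1, "std"] == pytest.approx(0.0)

    def test_invariant_to_record_order(self):
        rng = np.random.default_rng(0)
        df = make_log(
            [(f"u{i%4}", 1 + i % 3, 1 + i % 5, float(rng.normal())) for i in range(60)]
        )
        a = curve_by_seniority(df, "distance")
        b = curve_by_seniority(df.sample(frac=1, random_state=1), "distance")
        pd.testing.assert_frame_equal(a, b)

    def test_levels_with_no_records_are_gaps(self):
        df = make_log([("u", 1, 1, 1.0), ("u", 1, 5, 2.0)])
        curve = curve_by_seniority(df, "distance")
        assert curve["level"].tolist() == [1, 5]

    def test_unknown_column_rejected(self):
        with pytest.raises(ValueError):
            curve_by_seniority(make_log([("u", 1, 1, 0.0)]), "nope")


class TestSmoothCurve:
    def test_reproduces_polynomial_up_to_order(self):
        x = np.arange(15, dtype=float)
        y = 2.0 - 0.3 * x + 0.05 * x**2
        out = smooth_curve(y, window=11, polyorder=2)
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_constant_curve_unchanged(self):
        out = smooth_curve([4.2] * 12, window=5, polyorder=2)
        np.testing.assert_allclose(out, 4.2)

    def test_matches_windowed_least_squares_oracle(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0])
        out = smooth_curve(y, window=5, polyorder=2)
        # interior points: quadratic least squares on the centred window
        for i in range(2, 5):
            xs = np.arange(-2, 3, dtype=float)
            coef = np.polyfit(xs, y[i - 2 : i + 3], 2)
            assert out[i] == pytest.approx(np.polyval(coef, 0.0))
        # edges: polynomial fitted to the truncated end window
        head = np.polyfit(np.arange(5.0), y[:5], 2)
        assert out[0] == pytest.approx(np.polyval(head, 0.0))
        assert out[1] == pytest.approx(np.polyval(head, 1.0))

    @pytest.mark.parametrize("window, polyorder", [(4, 2), (3, 3), (9, 2)])
    def test_invalid_window_combinations_rejected(self, window, polyorder):
        with pytest.raises(ValueError):
            smooth_curve([1.0] * 7, window=window, polyorder=polyorder)


class TestTrendSlopeBootstrap:
    def test_constant_trajectories_give_zero_slope(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(40):
            d = float(rng.uniform(0, 3))
            rows += [(f"u{i}", 1, s, d) for s in range(1, 11)]
        tr = trend_slope_bootstrap(make_log(rows), max_level=10, n_boot=100, seed=0)
        assert tr.slope == pytest.approx(0.0, abs=1e-12)
        assert tr.covers_zero()

    def test_detects_a_real_decline(self):
        rows = []
        for i in range(40):
            rows += [(f"u{i}", 1, s, 10.0 - s + 0.01 * i) for s in range(1, 11)]
        tr = trend_slope_bootstrap(make_log(rows), max_level=10, n_boot=100, seed=0)
        assert tr.slope == pytest.approx(-1.0, abs=1e-9)
        assert not tr.covers_zero()

    def test_balanced_panel_restricts_to_full_trajectories(self):
        rows = [("u", 1, s, 1.0) for s in range(1, 6)]
        rows += [("v", 1, 1, 99.0)]  # short-lived pair, excluded when balanced
        tr = trend_slope_bootstrap(make_log(rows), max_level=5, n_boot=50, seed=0)
        assert tr.slope == pytest.approx(0.0, abs=1e-12)
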