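"""ICC(3,1), ratings, Bland-Altman and the table-level consistency wiring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from megconsist import (
    PairedMeasurements,
    bland_altman,
    distance_vs_icc,
    global_consistency,
    icc31,
    pearson,
    rate_icc,
    regional_consistency,
)
from megconsist.consistency import GLOBAL_MEASURES


def icc31_anova_oracle(a, b):
    """Independent route: regression-based two-way ANOVA decomposition.

    Fits the additive row+column model by least squares (dummy coding) and
    derives MSE from the residual sum of squares, instead of closed-form
    sums of squares.
    """
    n = a.size
    y = np.concatenate([a, b])
    rows = np.tile(np.arange(n), 2)
    cols = np.repeat([0, 1], n)
    x = np.zeros((2 * n, 1 + (n - 1) + 1))
    x[:, 0] = 1.0
    for i in range(n - 1):
        x[:, 1 + i] = (rows == i).astype(float) - (rows == n - 1).astype(float)
    x[:, -1] = cols - 0.5
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    mse = resid @ resid / ((n - 1) * (2 - 1))
    row_means = (a + b) / 2
    msr = 2 * np.sum((row_means - y.mean()) ** 2) / (n - 1)
    return (msr - mse) / (msr + mse)


class TestICC31:
    def test_identical_raters_give_one(self):
        v = np.array([3.0, 1.0, 4.0, 1.5])
        r = icc31(PairedMeasurements(v, v))
        assert r.icc == 1.0 and (r.ci_low, r.ci_high) == (1.0, 1.0)

    def test_additive_shift_ignored(self):
        v = np.array([3.0, 1.0, 4.0, 1.5])
        assert icc31(PairedMeasurements(v + 7, v)).icc == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        # MS_rows = 0 forces (0 - MSE) / (0 + MSE) = -1
        r = icc31(PairedMeasurements(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])))
        assert r.icc == pytest.approx(-1.0)
        assert r.rating == "poor" and r.not_reliable

    def test_matches_regression_anova_oracle(self, rng):
        for _ in range(100):
            a = rng.normal(size=20)
            b = 0.6 * a + 0.4 * rng.normal(size=20) + rng.normal() * 0.3
            mine = icc31(PairedMeasurements(a, b)).icc
            assert mine == pytest.approx(icc31_anova_oracle(a, b), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        for _ in range(10):
            a = rng.normal(size=15)
            b = 0.5 * a + rng.normal(size=15)
            mine = icc31(PairedMeasurements(a, b))
            df = pd.DataFrame(
                {
                    "t": np.tile(np.arange(15), 2),
                    "r": np.repeat(["A", "B"], 15),
                    "s": np.concatenate([a, b]),
                }
            )
            ref = pg.intraclass_corr(df, "t", "r", "s")
            row = ref[ref["Type"] == "ICC(C,1)"].iloc[0]
            assert mine.icc == pytest.approx(row["ICC"], abs=1e-10)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000),
           alpha=st.floats(0.1, 10), beta=st.floats(-5, 5))
    def test_affine_invariance(self, seed, alpha, beta):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=10)
        b = a + 0.5 * rng.normal(size=10)
        r1 = icc31(PairedMeasurements(a, b)).icc
        r2 = icc31(PairedMeasurements(alpha * a + beta, alpha * b + beta)).icc
        assert r2 == pytest.approx(r1, abs=1e-8)

    def test_ci_brackets_estimate(self, rng):
        for _ in range(20):
            a = rng.normal(size=12)
            b = 0.5 * a + rng.normal(size=12)
            r = icc31(PairedMeasurements(a, b))
            assert r.ci_low <= r.icc <= r.ci_high

    def test_constant_data_raises(self):
        with pytest.raises(ValueError, match="constant"):
            icc31(PairedMeasurements(np.ones(5), np.ones(5)))

    def test_too_few_items_raises(self):
        with pytest.raises(ValueError):
            icc31(PairedMeasurements(np.array([1.0, 2]), np.array([1.0, 2])))


class TestRating:
    @pytest.mark.parametrize(
        "value,label",
        [(0.85, "very good"), (0.80, "good"), (0.70, "good"), (0.60, "moderate"),
         (0.41, "moderate"), (0.40, "fair"), (0.21, "fair"), (0.20, "poor"),
         (-0.325, "poor")],
    )
    def test_band_edges(self, value, label):
        assert rate_icc(value) == label


class TestBlandAltman:
    def test_identical_pairs(self):
        v = np.array([1.0, 2, 3])
        ba = bland_altman(PairedMeasurements(v, v))
        assert ba.mean_diff == 0 and (ba.loa_low, ba.loa_high) == (0, 0)
        assert ba.n_outside == 0

    def test_constant_offset(self):
        a = np.array([2.0, 3, 4, 5])
        ba = bland_altman(PairedMeasurements(a, a - 1))
        assert ba.mean_diff == 1.0 and ba.sd_diff == 0.0
        assert (ba.loa_low, ba.loa_high) == (1.0, 1.0)

    def test_two_point_formula(self):
        ba = bland_altman(PairedMeasurements(np.array([0.0, 2.0]), np.zeros(2)))
        sd = np.sqrt(2)
        assert ba.mean_diff == 1.0
        assert ba.sd_diff == pytest.approx(sd)
        assert ba.loa_low == pytest.approx(1 - 1.96 * sd)
        assert ba.loa_high == pytest.approx(1 + 1.96 * sd)

    def test_limits_invariant_structure(self, rng):
        a = rng.normal(size=50)
        b = a + rng.normal(size=50)
        ba = bland_altman(PairedMeasurements(a, b))
        assert ba.loa_low == pytest.approx(ba.mean_diff - 1.96 * ba.sd_diff, abs=1e-12)
        assert ba.loa_high == pytest.approx(ba.mean_diff + 1.96 * ba.sd_diff, abs=1e-12)

    def test_large_sample_coverage(self):
        rng = np.random.default_rng(99)
        d = rng.normal(size=10_000)
        ba = bland_altman(PairedMeasurements(d, np.zeros_like(d)))
        inside = np.mean((d >= ba.loa_low) & (d <= ba.loa_high))
        assert 0.94 <= inside <= 0.96


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_anti_line(self):
        x = np.arange(10.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, _ = pearson(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        ref = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
        assert r == pytest.approx(ref, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(np.ones(5), np.arange(5.0))


def _regional_table(n_rois, n_epochs, clone=True, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for roi in range(1, n_rois + 1):
        base = rng.normal(size=n_epochs)
        other = base if clone else rng.normal(size=n_epochs)
        for e in range(n_epochs):
            for cond, vals in (("native", base), ("template", other)):
                rows.append(
                    {"subject": 0, "condition": cond, "roi": roi, "band": "theta",
                     "epoch": e, "measure": "power", "value": vals[e]}
                )
    return pd.DataFrame(rows)


class TestRegionalConsistency:
    def test_cloned_conditions_give_unit_icc(self):
        out = regional_consistency(_regional_table(6, 10, clone=True))
        assert len(out) == 6
        assert np.allclose(out["icc"], 1.0)

    def test_independent_noise_gives_null_iccs(self):
        out = regional_consistency(_regional_table(40, 200, clone=False, seed=1))
        near_zero = np.abs(out["icc"]) <= 0.2
        assert near_zero.mean() >= 0.95

    def test_output_one_row_per_roi_band_measure(self):
        df = _regional_table(4, 8)
        out = regional_consistency(df)
        assert set(out.columns) >= {"measure", "band", "roi", "icc", "ci_low",
                                    "ci_high", "rating"}
        assert len(out) == 4

    def test_misaligned_epochs_raise(self):
        df = _regional_table(2, 6)
        df = df[~((df.condition == "template") & (df.epoch == 3) & (df.roi == 1))]
        with pytest.raises(ValueError, match="misalignment"):
            regional_consistency(df)


def _global_table(n_subjects, identical=True, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for measure in GLOBAL_MEASURES:
        base = rng.normal(size=n_subjects)
        other = base if identical else base + 0.3 * rng.normal(size=n_subjects)
        for s in range(n_subjects):
            rows.append({"subject": s, "condition": "native", "band": "theta",
                         "measure": measure, "value": base[s]})
            rows.append({"subject": s, "condition": "template", "band": "theta",
                         "measure": measure, "value": other[s]})
    return pd.DataFrame(rows)


class TestGlobalConsistency:
    def test_identical_conditions(self):
        out = global_consistency(_global_table(8, identical=True))
        assert np.allclose(out["icc"], 1.0)
        assert np.allclose(out["loa_low"], 0.0) and np.allclose(out["loa_high"], 0.0)

    def test_covers_all_eight_measures(self):
        out = global_consistency(_global_table(8, identical=False))
        assert set(out["measure"]) == set(GLOBAL_MEASURES)
        assert len(out) == len(GLOBAL_MEASURES)


class TestDistanceVsICC:
    def test_negative_relation_detected(self, rng):
        d = rng.uniform(0, 30, size=30)
        icc = 1 - d / 40 + 0.05 * rng.normal(size=30)
        dist = pd.DataFrame({"band": "theta", "roi": np.arange(30), "distance_mm": d})
        iccs = pd.DataFrame({"band": "theta", "roi": np.arange(30), "icc": icc})
        out = distance_vs_icc(dist, iccs)
        assert out.iloc[0]["r"] < 0

    def test_constant_distances_skipped_with_warning(self):
        dist = pd.DataFrame({"band": "theta", "roi": [1, 2, 3], "distance_mm": 0.0})
        iccs = pd.DataFrame({"band": "theta", "roi": [1, 2, 3], "icc": [0.9, 0.8, 0.7]})
        with pytest.warns(UserWarning, match="skipped"):
            out = distance_vs_icc(dist, iccs)
        assert out.empty
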