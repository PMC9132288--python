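"""AoA50 fitting, meaning merges, frequencies, residualization, joins."""

import numpy as np
import pandas as pd
import pytest

from aoacorpus.norms import (
    CdiCurve,
    adjust_for_frequency,
    child_log_frequency,
    cdi_from_wide,
    fit_aoa50,
    fit_aoa50_table,
    join_norms,
    merge_test_meanings,
)


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def exact_curve(b0, b1, ages, n=1000):
    """Expected (non-integer) counts lying exactly on the logistic curve."""
    return CdiCurve(
        "w",
        tuple((a, p * n, n) for a, p in zip(ages, logistic(b0 + b1 * np.asarray(ages)))),
    )


class TestFitAoa50:
    def test_exact_curve_recovers_crossing_analytically(self):
        # logit(p) = -12 + 0.5*age crosses zero at age 24
        res = fit_aoa50(exact_curve(-12.0, 0.5, list(range(16, 31))))
        assert res.converged and res.excluded_reason == "none"
        assert res.aoa50_months == pytest.approx(24.0, abs=1e-6)
        assert res.slope == pytest.approx(0.5, abs=1e-6)

    def test_age_shift_equivariance(self):
        base = fit_aoa50(exact_curve(-12.0, 0.5, list(range(16, 31))))
        shifted = fit_aoa50(exact_curve(-12.0 - 0.5 * 3, 0.5, list(range(16, 31))))
        assert shifted.aoa50_months == pytest.approx(base.aoa50_months + 3.0, abs=1e-5)

    def test_never_said_word_excluded(self):
        curve = CdiCurve("w", tuple((a, 0, 50) for a in range(16, 31)))
        res = fit_aoa50(curve)
        assert np.isnan(res.aoa50_months)
        assert res.excluded_reason in ("no_convergence", "non_positive_slope", "out_of_range")

    def test_decreasing_curve_flagged_non_positive_slope(self):
        res = fit_aoa50(exact_curve(12.0, -0.5, list(range(16, 31))))
        assert res.excluded_reason == "non_positive_slope"
        assert np.isnan(res.aoa50_months)

    def test_out_of_range_crossing_excluded(self):
        # crossing at 120 months, far beyond the admissible window
        res = fit_aoa50(exact_curve(-12.0, 0.1, list(range(16, 31))))
        assert res.excluded_reason == "out_of_range"
        assert np.isnan(res.aoa50_months)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            CdiCurve("w", ((16.0, 5, 4), (17.0, 1, 4)))
        with pytest.raises(ValueError):
            CdiCurve("w", ((16.0, 1, 4),))  # one age only

    def test_simulated_recovery_within_one_month(self):
        # binomial draws around truth 24.0; scaled-down recovery check
        rng = np.random.default_rng(10)
        ages = np.arange(16.0, 31.0)
        hits = 0
        for _ in range(30):
            p = logistic(-12.0 + 0.5 * ages)
            n_say = rng.binomial(50, p)
            curve = CdiCurve("w", tuple(zip(ages, (int(x) for x in n_say), [50] * len(ages))))
            res = fit_aoa50(curve)
            if res.excluded_reason == "none" and abs(res.aoa50_months - 24.0) <= 1.0:
                hits += 1
        assert hits >= 28

    def test_table_fit_one_row_per_word(self):
        rows = []
        for word, b0 in (("a", -12.0), ("b", -10.0)):
            for age in range(16, 31):
                p = logistic(b0 + 0.5 * age)
                rows.append((word, age, int(round(p * 50)), 50))
        out = fit_aoa50_table(pd.DataFrame(rows, columns=["word", "age_months", "n_saying", "n_total"]))
        assert list(out["word"]) == ["a", "b"]
        assert out.loc[0, "aoa50_months"] < out.loc[1, "aoa50_months"] + 5


class TestCdiReshape:
    def test_wide_to_long_counts(self):
        wide = pd.DataFrame(
            {"word": ["dog"], "prop_16": [0.2], "n_16": [50], "prop_20": [0.6], "n_20": [40]}
        )
        long = cdi_from_wide(wide)
        assert len(long) == 2
        row16 = long[long["age_months"] == 16.0].iloc[0]
        assert row16["n_saying"] == 10 and row16["n_total"] == 50


class TestMergeTestMeanings:
    def test_minimum_grade_kept(self):
        df = pd.DataFrame(
            {"word": ["bank", "bank", "run", "run", "run", "cat"],
             "meaning": ["money", "river", "move", "manage", "stocking", "animal"],
             "grade": [4, 6, 2, 10, 13, 2]}
        )
        out = merge_test_meanings(df)
        assert out["bank"] == 4
        assert out["run"] == 2
        assert out["cat"] == 2

    def test_order_invariance(self):
        df = pd.DataFrame(
            {"word": ["run"] * 3, "meaning": ["a", "b", "c"], "grade": [13, 2, 10]}
        )
        assert merge_test_meanings(df)["run"] == merge_test_meanings(df.iloc[::-1])["run"]

    def test_inadmissible_grade_rejected(self):
        df = pd.DataFrame({"word": ["x"], "meaning": ["m"], "grade": [3]})
        with pytest.raises(ValueError, match="admissible"):
            merge_test_meanings(df)


class TestChildLogFrequency:
    def test_mean_of_bands_then_log(self):
        df = pd.DataFrame(
            {"word": ["a", "b", "c"],
             "freq_preschool": [10.0, 5.0, 0.0],
             "freq_primary": [30.0, 5.0, 0.0]}
        )
        out = child_log_frequency(df)
        assert out["a"] == pytest.approx(np.log(20.0))
        assert out["b"] == pytest.approx(np.log(5.0))
        assert np.isnan(out["c"])  # zero mean frequency has no log

    def test_negative_frequency_rejected(self):
        df = pd.DataFrame({"word": ["a"], "freq_preschool": [-1.0], "freq_primary": [2.0]})
        with pytest.raises(ValueError):
            child_log_frequency(df)


class TestAdjustForFrequency:
    def test_orthogonal_fixture_residuals_are_centered_aoa(self):
        # AoA exactly uncorrelated with frequency: slope 0, residual = AoA - mean
        lf = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        aoa = pd.Series([20.0, 24.0, 24.0, 20.0], index=list("abcd"))
        resid = adjust_for_frequency(aoa, lf)
        expected = aoa - aoa.mean()
        assert np.allclose(resid, expected, atol=1e-10)

    def test_residuals_orthogonal_to_regressor(self):
        rng = np.random.default_rng(2)
        idx = [f"w{i}" for i in range(500)]
        lf = pd.Series(rng.normal(3, 1, 500), index=idx)
        aoa = pd.Series(-2.0 * lf + rng.normal(24, 2, 500), index=idx)
        resid = adjust_for_frequency(aoa, lf)
        assert abs(resid.mean()) < 1e-10
        assert abs(np.corrcoef(resid, lf)[0, 1]) < 1e-10

    def test_known_slope_recovered(self):
        rng = np.random.default_rng(3)
        idx = [f"w{i}" for i in range(400)]
        lf = pd.Series(rng.normal(0, 1, 400), index=idx)
        noise = rng.normal(0, 1, 400)
        aoa = pd.Series(2.0 * lf + noise, index=idx)
        resid = adjust_for_frequency(aoa, lf)
        # implied slope = (aoa - resid - intercept)/lf; check via refit
        slope = np.polyfit(lf, aoa - resid, 1)[0]
        se = 1.0 / np.sqrt(400)  # noise sd 1, var(lf) ~ 1
        assert slope == pytest.approx(2.0, abs=2 * 2 * se)

    def test_subset_residuals_come_from_full_fit(self):
        # within a biased subset the residuals need not be orthogonal,
        # which is exactly what taking them from the full-set fit implies
        rng = np.random.default_rng(4)
        idx = [f"w{i}" for i in range(600)]
        lf = pd.Series(rng.normal(0, 1, 600), index=idx)
        aoa = pd.Series(-1.5 * lf + rng.normal(0, 1, 600), index=idx)
        resid = adjust_for_frequency(aoa, lf)
        subset = resid.nlargest(100).index  # selection correlated with the residual
        r_sub = np.corrcoef(resid[subset], lf[subset])[0, 1]
        r_full = np.corrcoef(resid, lf)[0, 1]
        assert abs(r_full) < 1e-10
        assert abs(r_sub) > 0.01

    def test_degenerate_inputs_rejected(self):
        idx = list("ab")
        with pytest.raises(ValueError):
            adjust_for_frequency(pd.Series([1.0, 2.0], index=idx), pd.Series([1.0, 2.0], index=idx))
        idx = list("abcd")
        with pytest.raises(ValueError, match="variance"):
            adjust_for_frequency(
                pd.Series([1.0, 2.0, 3.0, 4.0], index=idx),
                pd.Series([2.0, 2.0, 2.0, 2.0], index=idx),
            )


class TestJoinNorms:
    def test_complete_case_intersection(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"], name="x")
        b = pd.Series([4.0, 5.0, 6.0], index=["b", "c", "d"], name="y")
        out = join_norms({"x": a, "y": b}, required=["x", "y"])
        assert sorted(out.index) == ["b", "c"]

    def test_case_folding_joins_variants(self):
        a = pd.Series([1.0], index=["Ball"])
        b = pd.Series([2.0], index=["ball"])
        out = join_norms({"x": a, "y": b}, required=["x", "y"])
        assert list(out.index) == ["ball"]

    def test_duplicate_words_rejected_with_names(self):
        a = pd.Series([1.0, 2.0], index=["Ball", "ball"])
        with pytest.raises(ValueError, match="ball"):
            join_norms({"x": a})

    def test_staggered_missingness_matches_set_enumeration(self):
        rng = np.random.default_rng(5)
        words = [f"w{i}" for i in range(60)]
        sources = {}
        kept = {}
        for name in ("x", "y", "z"):
            chosen = sorted(rng.choice(words, size=40, replace=False))
            sources[name] = pd.Series(rng.normal(size=40), index=chosen)
            kept[name] = set(chosen)
        out = join_norms(sources, required=["x", "y", "z"])
        assert set(out.index) == kept["x"] & kept["y"] & kept["z"]
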