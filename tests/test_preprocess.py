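"""Preprocessing rules: transforms, filtering thresholds, frailty index,
telomere z-scores, covariate imputation and the landmark filter."""

import numpy as np
import pandas as pd
import pytest

from metaboaging.preprocess import (MetaboliteMatrix, PreprocessError,
                                    ProteinMatrix, compute_frailty_index,
                                    filter_proteins, impute_covariates,
                                    landmark_filter, prepare_telomere,
                                    transform_metabolites)


def _mm(arr, cols=None):
    df = pd.DataFrame(np.asarray(arr, float),
                      columns=cols or [f"m{j}" for j in
                                       range(np.asarray(arr).shape[1])])
    return MetaboliteMatrix(df, stage="raw")


class TestTransformMetabolites:
    def test_zero_maps_to_zero_before_standardization(self):
        # ln(0+1)=0: a column (0, e-1) becomes (0,1) pre z-score
        out = transform_metabolites(_mm([[0.0, 1.0], [np.e - 1, 2.0]]))
        expected = np.array([-1 / np.sqrt(2), 1 / np.sqrt(2)])
        np.testing.assert_allclose(out.values["m0"], expected, atol=1e-12)

    def test_mean_imputation_on_raw_scale(self):
        m = _mm([[1.0], [2.0], [np.nan]])
        out = transform_metabolites(m)
        # missing cell imputed to 1.5 before ln(x+1)
        logged = np.log1p([1.0, 2.0, 1.5])
        z = (logged - logged.mean()) / logged.std(ddof=1)
        np.testing.assert_allclose(out.values["m0"], z, atol=1e-12)

    def test_columns_are_unit_variance_zero_mean(self, small_cohort):
        _, cohort, _ = small_cohort
        out = transform_metabolites(MetaboliteMatrix(cohort.metabolites))
        assert out.stage == "transformed"
        np.testing.assert_allclose(out.values.mean(), 0, atol=1e-8)
        np.testing.assert_allclose(out.values.std(ddof=1), 1, atol=1e-8)

    def test_rezscoring_is_idempotent(self):
        out = transform_metabolites(_mm([[0.0, 3], [1.0, 5], [4.0, 9]]))
        v = out.values
        again = (v - v.mean()) / v.std(ddof=1)
        np.testing.assert_allclose(v, again, atol=1e-12)

    def test_zero_variance_column_names_culprit(self):
        with pytest.raises(PreprocessError, match="m1"):
            transform_metabolites(_mm([[1.0, 2.0], [3.0, 2.0]], ["m0", "m1"]))

    def test_negative_raw_rejected(self):
        with pytest.raises(PreprocessError, match="0"):
            transform_metabolites(_mm([[-1.0], [1.0]]))

    def test_wrong_stage_rejected(self):
        m = _mm([[1.0], [2.0]])
        m.stage = "transformed"
        with pytest.raises(PreprocessError):
            transform_metabolites(m)


class TestFilterProteins:
    def test_threshold_is_strictly_greater(self):
        n = 100
        vals = np.random.default_rng(0).normal(size=(n, 2))
        df = pd.DataFrame(vals, columns=["keep30", "drop31"])
        df.iloc[:30, 0] = np.nan    # exactly 30% missing -> kept
        df.iloc[:31, 1] = np.nan    # 31% missing -> dropped
        out = filter_proteins(ProteinMatrix(df))
        assert list(out.values.columns) == ["keep30"]

    def test_counts_of_retained_columns(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 10)),
                          columns=[f"p{j}" for j in range(10)])
        for j in (2, 5, 7):
            df.iloc[:20, j] = np.nan     # 40% missing
        out = filter_proteins(ProteinMatrix(df))
        assert out.values.shape[1] == 7

    def test_no_missing_only_zscored(self, rng):
        df = pd.DataFrame(rng.normal(loc=5, size=(40, 3)))
        df.columns = ["a", "b", "c"]
        out = filter_proteins(ProteinMatrix(df))
        np.testing.assert_allclose(out.values.mean(), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(ddof=1), 1, atol=1e-10)
        assert out.stage == "standardized"

    def test_retention_matches_bruteforce_on_random_masks(self, rng):
        for _ in range(25):
            n, p = rng.integers(10, 40), rng.integers(2, 8)
            df = pd.DataFrame(rng.normal(size=(n, p)),
                              columns=[f"p{j}" for j in range(p)])
            mask = rng.uniform(size=(n, p)) < rng.uniform(0, 0.5)
            df = df.mask(mask)
            thr = float(rng.uniform(0.05, 0.5))
            expected = [c for c in df.columns
                        if df[c].isna().sum() / n <= thr
                        and df[c].dropna().nunique() > 1]
            if not expected:
                with pytest.raises(PreprocessError):
                    filter_proteins(ProteinMatrix(df), max_missing=thr)
                continue
            try:
                out = filter_proteins(ProteinMatrix(df), max_missing=thr)
            except PreprocessError:
                continue   # zero-variance survivor column
            assert list(out.values.columns) == expected

    def test_all_dropped_errors(self):
        df = pd.DataFrame({"a": [np.nan] * 8 + [1.0, 2.0]})
        with pytest.raises(PreprocessError):
            filter_proteins(ProteinMatrix(df), max_missing=0.3)


class TestFrailtyIndex:
    def _items(self, row, n=49):
        return pd.DataFrame([row + [0.0] * (n - len(row))])

    def test_proportion_of_deficits(self):
        items = self._items([1.0] * 10)
        out = compute_frailty_index(items)
        assert out["fi"].iloc[0] == pytest.approx(10 / 49)

    def test_observed_item_denominator(self):
        row = [1.0] * 9 + [np.nan] * 4 + [0.0] * 36
        out = compute_frailty_index(pd.DataFrame([row]))
        assert out["fi"].iloc[0] == pytest.approx(9 / 45)

    def test_fixed_denominator_option(self):
        row = [1.0] * 9 + [np.nan] * 4 + [0.0] * 36
        out = compute_frailty_index(pd.DataFrame([row]), denominator="fixed")
        assert out["fi"].iloc[0] == pytest.approx(9 / 49)

    def test_ten_missing_items_excluded(self):
        row = [np.nan] * 10 + [1.0] * 39
        out = compute_frailty_index(pd.DataFrame([row]))
        assert bool(out["excluded"].iloc[0])
        assert np.isnan(out["fi"].iloc[0])

    def test_nine_missing_items_retained(self):
        row = [np.nan] * 9 + [1.0] * 40
        out = compute_frailty_index(pd.DataFrame([row]))
        assert not bool(out["excluded"].iloc[0])

    def test_bounds_and_column_order_invariance(self, rng):
        items = pd.DataFrame(rng.integers(0, 2, size=(30, 49)).astype(float))
        a = compute_frailty_index(items)["fi"]
        b = compute_frailty_index(items[items.columns[::-1]])["fi"]
        np.testing.assert_allclose(a, b)
        assert ((a >= 0) & (a <= 1)).all()
        assert compute_frailty_index(items * 0)["fi"].eq(0).all()
        assert compute_frailty_index((items * 0) + 1)["fi"].eq(1).all()

    def test_wrong_width_errors_unless_overridden(self):
        items = pd.DataFrame(np.zeros((3, 20)))
        with pytest.raises(PreprocessError):
            compute_frailty_index(items)
        out = compute_frailty_index(items, n_items=20)
        assert out["fi"].eq(0).all()


class TestTelomere:
    def test_closed_form_two_values(self):
        z = prepare_telomere(pd.Series([1.0, np.e]))
        np.testing.assert_allclose(z, [-1 / np.sqrt(2), 1 / np.sqrt(2)],
                                   atol=1e-12)

    def test_output_centered(self, small_cohort):
        _, cohort, _ = small_cohort
        z = prepare_telomere(cohort.telomere_raw)
        assert abs(z.mean()) < 1e-10

    def test_nonpositive_rejected(self):
        with pytest.raises(PreprocessError):
            prepare_telomere(pd.Series([1.0, 0.0]))

    def test_constant_rejected(self):
        with pytest.raises(PreprocessError):
            prepare_telomere(pd.Series([2.0, 2.0, 2.0]))


class TestImputeCovariates:
    def test_low_rate_continuous_median(self):
        c = pd.DataFrame({"x": [1.0, 2.0, 3.0, 100.0] + [5.0] * 96})
        c.loc[0, "x"] = np.nan   # 1% missing
        out = impute_covariates(c, categorical=[])
        assert out.table["x"].iloc[0] == c["x"].median(skipna=True)
        assert out.audit["x"]["method"] == "median"

    def test_high_rate_categorical_missing_level(self):
        vals = ["a"] * 46 + ["b"] * 46 + [np.nan] * 8
        c = pd.DataFrame({"g": vals})
        out = impute_covariates(c, categorical=["g"])
        assert (out.table["g"] == "missing").sum() == 8
        assert out.audit["g"]["method"] == "missing_category"

    def test_high_rate_continuous_indicator(self):
        x = np.arange(100, dtype=float)
        x[:8] = np.nan
        out = impute_covariates(pd.DataFrame({"x": x}), categorical=[])
        assert "x_missing" in out.table
        assert out.table["x_missing"].sum() == 8
        assert out.table["x"].isna().sum() == 0

    def test_no_missing_is_identity(self):
        c = pd.DataFrame({"x": [1.0, 2.0], "g": ["a", "b"]})
        out = impute_covariates(c)
        pd.testing.assert_frame_equal(out.table, c)

    def test_entirely_missing_errors(self):
        with pytest.raises(PreprocessError, match="x"):
            impute_covariates(pd.DataFrame({"x": [np.nan, np.nan]}))


class TestLandmarkFilter:
    def _out(self):
        return pd.DataFrame({
            "entry_age": [50.0, 51, 52, 53],
            "time": [0.5, 0.5, 2.0, 0.9],
            "event": [1, 0, 1, 1]})

    def test_early_events_removed_early_censorings_kept(self):
        out = landmark_filter(self._out(), years=1.0)
        assert list(out.index) == [1, 2]

    def test_no_early_events_identity(self):
        df = self._out()
        df["time"] = [1.5, 0.5, 2.0, 1.9]
        out = landmark_filter(df, years=1.0)
        pd.testing.assert_frame_equal(out, df)

    def test_nonpositive_time_rejected(self):
        df = self._out()
        df.loc[0, "time"] = 0.0
        with pytest.raises(PreprocessError):
            landmark_filter(df)
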