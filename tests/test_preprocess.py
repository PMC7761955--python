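import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metabopanel import (
    PreprocessConfig,
    compute_rsd,
    filter_by_missingness,
    filter_by_qc_cv,
    impute_half_min,
    log2_transform,
    normalize_median,
    preprocess_pipeline,
)
from metabopanel.preprocess import PreprocessError

from conftest import make_meta, make_table


def bio_meta(n_bio, n_qc=0):
    ids = [f"s{i}" for i in range(n_bio)] + [f"q{i}" for i in range(n_qc)]
    groups = ["normal"] * n_bio + ["qc"] * n_qc
    return ids, make_meta(ids, groups=groups)


class TestMissingnessFilter:
    def test_boundary_20_percent_removed(self):
        # missing in exactly 2 of 10 biological samples -> >= threshold, removed
        vals = np.ones((2, 10))
        vals[0, :2] = 0.0
        _, meta = bio_meta(10)
        out = filter_by_missingness(make_table(vals), meta, threshold=0.20)
        assert out.n_features == 1

    def test_below_threshold_retained(self):
        vals = np.ones((1, 10))
        vals[0, 0] = 0.0          # 10% missing
        _, meta = bio_meta(10)
        out = filter_by_missingness(make_table(vals), meta, threshold=0.20)
        assert out.n_features == 1

    def test_no_zeros_identity(self):
        vals = np.arange(1, 13, dtype=float).reshape(3, 4)
        _, meta = bio_meta(4)
        out = filter_by_missingness(make_table(vals), meta, 0.20)
        assert out.n_features == 3

    def test_qc_samples_not_in_denominator(self):
        # feature missing only in QCs passes
        vals = np.ones((1, 6))
        vals[0, 4:] = 0.0
        ids, meta = bio_meta(4, n_qc=2)
        out = filter_by_missingness(make_table(vals, samples=ids), meta, 0.20)
        assert out.n_features == 1

    def test_no_biological_samples_errors(self):
        ids, meta = bio_meta(0, n_qc=3)
        with pytest.raises(PreprocessError):
            filter_by_missingness(make_table(np.ones((1, 3)), samples=ids), meta, 0.2)


class TestQcCvFilter:
    def qc_table(self, qc_values):
        ids, meta = bio_meta(2, n_qc=len(qc_values))
        vals = np.concatenate([[100.0, 100.0], qc_values])[None, :]
        return make_table(vals, samples=ids), meta

    def test_zero_variance_retained(self):
        table, meta = self.qc_table([100.0, 100.0, 100.0])
        assert filter_by_qc_cv(table, meta, 0.30).n_features == 1

    def test_cv_50_percent_removed(self):
        # sd=50, mean=100 -> CV 50%
        table, meta = self.qc_table([50.0, 100.0, 150.0])
        assert filter_by_qc_cv(table, meta, 0.30).n_features == 0

    def test_cv_exactly_30_percent_retained(self):
        # strict inequality: CV == 30.0% stays
        qc = np.array([100.0 - 30.0, 100.0, 100.0 + 30.0]) / np.sqrt(
            ((np.array([70, 100, 130]) - 100.0) ** 2).sum() / 2
        ) * 30.0
        # construct directly: values with sd/mean exactly 0.3
        base = np.array([70.0, 100.0, 130.0])
        scale = 0.30 / (np.std(base, ddof=1) / np.mean(base))
        qc = 100.0 + (base - 100.0) * scale
        table, meta = self.qc_table(qc)
        cv = np.std(qc, ddof=1) / np.mean(qc)
        assert cv == pytest.approx(0.30, abs=1e-12)
        assert filter_by_qc_cv(table, meta, 0.30).n_features == 1

    def test_insufficient_qc_values_removed_separately(self):
        from metabopanel.preprocess import PreprocessReport

        ids, meta = bio_meta(2, n_qc=3)
        vals = np.array([[10.0, 10.0, 5.0, 0.0, 0.0]])   # only 1 QC observation
        report = PreprocessReport()
        out = filter_by_qc_cv(make_table(vals, samples=ids), meta, 0.30, report=report)
        assert out.n_features == 0
        assert report.removed_qc_insufficient == 1
        assert report.removed_qc_cv == 0

    def test_no_qc_samples_instructs_explicit_skip(self):
        _, meta = bio_meta(3)
        with pytest.raises(PreprocessError, match="skip"):
            filter_by_qc_cv(make_table(np.ones((1, 3))), meta, 0.30)


class TestImputation:
    def test_half_minimum_positive(self):
        out = impute_half_min(make_table([[0.0, 4.0, 8.0]]))
        assert out.values.tolist() == [[2.0, 4.0, 8.0]]

    def test_no_zeros_identity(self):
        table = make_table([[1.0, 2.0, 3.0]])
        out = impute_half_min(table)
        assert np.array_equal(out.values, table.values)

    def test_all_zero_feature_errors_with_name(self):
        with pytest.raises(PreprocessError, match="1.0000_100.0000"):
            impute_half_min(make_table([[0.0, 0.0, 0.0]]))

    @given(
        st.lists(st.floats(0.5, 1e6), min_size=2, max_size=8),
        st.integers(0, 7),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_imputed_value_is_exactly_half_feature_minimum(self, vals, zero_at):
        zero_at = zero_at % len(vals)
        row = list(vals)
        row[zero_at] = 0.0
        if all(v == 0 for v in row):
            return
        out = impute_half_min(make_table([row]))
        minimum = min(v for v in row if v > 0)
        assert out.values[0, zero_at] == minimum / 2.0


class TestNormalization:
    def test_reference_is_median_of_medians(self):
        # sample medians 1, 10, 100 -> all medians become 10
        vals = np.array([[0.5, 5.0, 50.0], [1.0, 10.0, 100.0], [2.0, 20.0, 200.0]])
        out = normalize_median(make_table(vals))
        np.testing.assert_allclose(np.median(out.values, axis=0), 10.0)

    def test_two_sample_scale_factors(self):
        vals = np.array([[5.0, 10.0], [10.0, 20.0], [20.0, 40.0]])   # medians 10, 20
        out = normalize_median(make_table(vals))
        np.testing.assert_allclose(out.values[:, 0], vals[:, 0] * 1.5)
        np.testing.assert_allclose(out.values[:, 1], vals[:, 1] * 0.75)

    def test_equal_medians_identity(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        out = normalize_median(make_table(vals))
        np.testing.assert_allclose(out.values, vals)


class TestLog2:
    def test_values(self):
        out = log2_transform(make_table([[8.0, 1.0]]))
        assert out.values.tolist() == [[3.0, 0.0]]

    def test_zero_violates_contract(self):
        with pytest.raises(PreprocessError):
            log2_transform(make_table([[1.0, 0.0]]))


class TestRsd:
    def make(self, qc_vals):
        ids, meta = bio_meta(2, n_qc=len(qc_vals))
        vals = np.concatenate([[1.0, 1.0], qc_vals])[None, :]
        return make_table(vals, samples=ids), meta

    def test_constant_qc_zero_rsd(self):
        table, meta = self.make([100.0, 100.0, 100.0])
        assert compute_rsd(table, meta, table.labels[0]) == 0.0

    def test_hand_computed_50_percent(self):
        table, meta = self.make([50.0, 100.0, 150.0])
        assert compute_rsd(table, meta, table.labels[0]) == pytest.approx(50.0)

    def test_single_qc_value_errors(self):
        table, meta = self.make([100.0, 0.0, 0.0])
        with pytest.raises(PreprocessError):
            compute_rsd(table, meta, table.labels[0])

    @given(st.floats(1e-3, 1e5))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_scale_invariance(self, c):
        table, meta = self.make([50.0, 100.0, 150.0])
        scaled, _ = self.make([50.0 * c, 100.0 * c, 150.0 * c])
        assert compute_rsd(scaled, meta, scaled.labels[0]) == pytest.approx(
            compute_rsd(table, meta, table.labels[0]), rel=1e-9
        )


class TestPipeline:
    def constructed_fixture(self):
        """3 features fail the 80% rule, 2 fail the QC CV filter."""
        rng = np.random.default_rng(0)
        n_bio, n_qc = 10, 4
        ids, meta = bio_meta(n_bio, n_qc=n_qc)
        vals = rng.uniform(50, 150, size=(12, n_bio + n_qc))
        # pooled-QC columns: low dispersion around the feature mean
        vals[:, n_bio:] = vals[:, :n_bio].mean(axis=1, keepdims=True) * rng.normal(
            1.0, 0.02, size=(12, n_qc)
        )
        for i in range(3):                      # >= 20% missing among bio
            vals[i, :2] = 0.0
        for i in (3, 4):                        # QC CV far above 30%
            vals[i, n_bio:] = [10.0, 200.0, 10.0, 200.0]
        vals[5, 3] = 0.0                        # one zero: imputed, not filtered
        return make_table(vals, samples=ids), meta

    def test_filter_counts_match_construction(self):
        table, meta = self.constructed_fixture()
        out, report = preprocess_pipeline(table, meta, PreprocessConfig())
        assert report.removed_missingness == 3
        assert report.removed_qc_cv == 2
        assert out.n_features == 12 - 5
        assert report.n_features_out == 7

    def test_sample_medians_equalized_pre_log(self):
        table, meta = self.constructed_fixture()
        out, report = preprocess_pipeline(table, meta, PreprocessConfig())
        medians = np.median(np.exp2(out.values), axis=0)
        np.testing.assert_allclose(medians, report.reference_median, rtol=1e-9)

    def test_imputation_does_not_change_filter_decisions(self):
        table, meta = self.constructed_fixture()
        cfg = PreprocessConfig()
        filtered = filter_by_qc_cv(
            filter_by_missingness(table, meta, cfg.missing_fraction_threshold),
            meta,
            cfg.qc_cv_threshold,
        )
        imputed_first = impute_half_min(table)
        refiltered = filter_by_qc_cv(
            filter_by_missingness(imputed_first, meta, cfg.missing_fraction_threshold),
            meta,
            cfg.qc_cv_threshold,
        )
        # imputing before filtering may only keep extra features, never lose
        # ones that pass on raw data: the filters act on pre-imputation zeros
        assert set(filtered.labels) <= set(refiltered.labels)

    def test_rerun_is_deterministic(self, tmp_path):
        table, meta = self.constructed_fixture()
        out1, _ = preprocess_pipeline(table, meta, PreprocessConfig())
        out2, _ = preprocess_pipeline(table, meta, PreprocessConfig())
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        out1.intensities.to_csv(p1)
        out2.intensities.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()
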