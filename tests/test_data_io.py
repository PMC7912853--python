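import numpy as np
import pytest

from rwrfuse import (
    FeatureMatrix,
    align_samples,
    filter_missingness,
    impute_missing,
    normalize_features,
    preprocess,
    read_feature_matrix,
    read_survival,
    write_feature_matrix,
)


def write(tmp_path, text, name="m.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFeatureMatrix:
    def test_parses_missing_cell(self, tmp_path):
        p = write(tmp_path, "id\ts1\ts2\nf1\t1.0\t2.0\nf2\t\t4.0\nf3\t5.0\t6.0\n")
        m = read_feature_matrix(p)
        assert m.feature_ids == ["f1", "f2", "f3"]
        assert m.sample_ids == ["s1", "s2"]
        assert np.isnan(m.values).sum() == 1
        assert np.isnan(m.values[1, 0])

    def test_orientation_transpose_identity(self, tmp_path):
        p1 = write(tmp_path, "id\ts1\ts2\nf1\t1\t2\nf2\t3\t4\n", "a.tsv")
        p2 = write(tmp_path, "id\tf1\tf2\ns1\t1\t3\ns2\t2\t4\n", "b.tsv")
        m1 = read_feature_matrix(p1)
        m2 = read_feature_matrix(p2, orientation="samples-by-features")
        np.testing.assert_array_equal(m1.values, m2.values)
        assert m1.sample_ids == m2.sample_ids

    def test_round_trip(self, tmp_path, small_matrix):
        p = tmp_path / "rt.tsv"
        write_feature_matrix(small_matrix, p)
        m = read_feature_matrix(p)
        np.testing.assert_allclose(m.values, small_matrix.values, rtol=1e-12)
        assert m.feature_ids == small_matrix.feature_ids
        assert m.sample_ids == small_matrix.sample_ids

    def test_duplicate_ids_rejected(self, tmp_path):
        p = write(tmp_path, "id\ts1\ts1\nf1\t1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_feature_matrix(p)

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = write(tmp_path, "id\ts1\ts2\nf1\t1\tbogus\n")
        with pytest.raises(ValueError, match="f1.*s2"):
            read_feature_matrix(p)

    def test_na_token_case_insensitive(self, tmp_path):
        p = write(tmp_path, "id\ts1\ts2\nf1\tNA\tNa\n")
        m = read_feature_matrix(p)
        assert np.isnan(m.values).all()


class TestAlignSamples:
    def test_intersection(self):
        a = FeatureMatrix(np.ones((2, 3)), ["f1", "f2"], ["A", "B", "C"])
        b = FeatureMatrix(np.ones((2, 3)), ["f1", "f2"], ["B", "C", "D"])
        out = align_samples([a, b])
        assert [m.sample_ids for m in out] == [["B", "C"], ["B", "C"]]

    def test_columns_reordered_consistently(self, rng):
        vals = rng.normal(size=(3, 4))
        a = FeatureMatrix(vals, ["f1", "f2", "f3"], ["A", "B", "C", "D"])
        b = FeatureMatrix(vals[:, [3, 2, 1, 0]], ["f1", "f2", "f3"], ["D", "C", "B", "A"])
        out = align_samples([a, b])
        np.testing.assert_array_equal(out[0].values, out[1].values)

    def test_shared_count_on_generated_ids(self, rng):
        ids = [f"s{i}" for i in range(100)]
        def layer(drop):
            keep = [s for s in ids if s not in drop]
            return FeatureMatrix(np.ones((2, len(keep))), ["f1", "f2"], keep)
        # three layers each missing a different 8-id slice: 76 shared
        out = align_samples([layer(ids[0:8]), layer(ids[8:16]), layer(ids[16:24])])
        assert all(m.n_samples == 76 for m in out)

    def test_empty_intersection_raises(self):
        a = FeatureMatrix(np.ones((1, 2)), ["f"], ["A", "B"])
        b = FeatureMatrix(np.ones((1, 2)), ["f"], ["C", "D"])
        with pytest.raises(ValueError, match="no sample"):
            align_samples([a, b])


class TestFilterMissingness:
    def test_no_missing_is_noop(self, rng):
        m = FeatureMatrix(rng.normal(size=(4, 5)), list("abcd"), list("vwxyz"))
        out = filter_missingness(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_sample_over_20pct_missing_dropped(self):
        vals = np.ones((10, 3))
        vals[:3, 0] = np.nan  # sample 0: 30% missing
        m = FeatureMatrix(vals, [f"f{i}" for i in range(10)], ["s0", "s1", "s2"])
        out = filter_missingness(m)
        assert out.sample_ids == ["s1", "s2"]

    def test_hand_enumerated_5x5(self):
        # feature f0 missing in 3/5 samples (60%); sample s0 missing 2/5 features (40%)
        vals = np.ones((5, 5))
        vals[0, [1, 2, 3]] = np.nan
        vals[1, 0] = np.nan
        vals[2, 0] = np.nan
        m = FeatureMatrix(vals, [f"f{i}" for i in range(5)], [f"s{j}" for j in range(5)])
        out = filter_missingness(m)
        assert out.values.shape == (4, 4)
        assert "s0" not in out.sample_ids and "f0" not in out.feature_ids

    def test_idempotent(self, rng):
        vals = rng.normal(size=(10, 10))
        mask = rng.random((10, 10)) < 0.15
        vals[mask] = np.nan
        m = FeatureMatrix(vals, [f"f{i}" for i in range(10)], [f"s{j}" for j in range(10)])
        once = filter_missingness(m)
        twice = filter_missingness(once)
        np.testing.assert_array_equal(once.values, twice.values)


class TestImputeMissing:
    def test_mean_of_observed(self):
        m = FeatureMatrix(np.array([[1.0, 3.0, np.nan]]), ["f"], ["a", "b", "c"])
        out = impute_missing(m)
        assert out.values[0, 2] == 2.0

    def test_observed_cells_unchanged(self, rng):
        vals = rng.normal(size=(8, 12))
        mask = rng.random((8, 12)) < 0.1
        masked = vals.copy()
        masked[mask] = np.nan
        m = FeatureMatrix(masked, [f"f{i}" for i in range(8)], [f"s{j}" for j in range(12)])
        out = impute_missing(m)
        np.testing.assert_array_equal(out.values[~mask], vals[~mask])
        # imputed cells equal per-feature observed means
        means = np.nanmean(masked, axis=1)
        rows, cols = np.nonzero(mask)
        np.testing.assert_allclose(out.values[rows, cols], means[rows], rtol=1e-12)

    def test_fully_missing_feature_raises(self):
        m = FeatureMatrix(np.array([[np.nan, np.nan]]), ["f"], ["a", "b"])
        with pytest.raises(ValueError, match="no observed value"):
            impute_missing(m)


class TestNormalizeFeatures:
    def test_zero_mean_unit_sd(self, rng):
        m = FeatureMatrix(rng.normal(2, 5, size=(6, 20)), [f"f{i}" for i in range(6)],
                          [f"s{j}" for j in range(20)])
        out = normalize_features(m)
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=1), 1, atol=1e-10)

    def test_idempotent_on_standardized(self, rng):
        m = FeatureMatrix(rng.normal(size=(3, 50)), list("abc"), [f"s{j}" for j in range(50)])
        once = normalize_features(m)
        twice = normalize_features(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_feature_dropped(self):
        vals = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        m = FeatureMatrix(vals, ["f1", "f2"], ["a", "b", "c"])
        out = normalize_features(m)
        assert out.feature_ids == ["f1"]


class TestPreprocessChain:
    def test_end_state_invariants(self, rng):
        layers = []
        for li in range(3):
            vals = rng.normal(size=(15, 30))
            mask = rng.random(vals.shape) < 0.05
            vals[mask] = np.nan
            ids = [f"s{j}" for j in range(li, 30)]  # staggered sample sets
            layers.append(FeatureMatrix(vals[:, :len(ids)], [f"l{li}f{i}" for i in range(15)], ids))
        out = preprocess(layers)
        ids0 = out[0].sample_ids
        for m in out:
            assert m.sample_ids == ids0
            assert not np.isnan(m.values).any()
            np.testing.assert_allclose(m.values.mean(axis=1), 0, atol=1e-10)
            np.testing.assert_allclose(m.values.std(axis=1), 1, atol=1e-10)


def test_read_survival(tmp_path):
    p = tmp_path / "surv.tsv"
    p.write_text("sample_id\ttime\tevent\ns1\t10\t1\ns2\t20\t0\n")
    s = read_survival(p)
    assert s.sample_ids == ["s1", "s2"]
    np.testing.assert_array_equal(s.event, [1, 0])
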