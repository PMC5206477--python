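import math

import numpy as np
import pytest

from dosepred.data_io import (
    EmptyDatasetError,
    ExpressionDataset,
    NoResponseError,
    SeriesMatrixError,
    preprocess,
    read_series_matrix,
    read_tsv,
    split_train_test,
    write_tsv,
)
from tests.conftest import SERIES_MATRIX_OK


class TestSeriesMatrix:
    def test_parses_shape_and_orientation(self, series_matrix_file):
        ds = read_series_matrix(series_matrix_file(), dose=[1.0, 2.0, 3.0])
        assert ds.X.shape == (3, 4)  # samples x probes (transposed)
        assert ds.gene_ids == ["probe_a", "probe_b", "probe_c", "probe_d"]
        assert ds.sample_ids == ["GSM1", "GSM2", "GSM3"]
        # file stores probes as rows: probe_a row becomes column 0
        np.testing.assert_allclose(ds.X[:, 0], [1.0, 2.0, 3.0])

    def test_null_cell_becomes_missing_marker(self, series_matrix_file):
        text = SERIES_MATRIX_OK.replace('"probe_b"\t4.0', '"probe_b"\tnull')
        ds = read_series_matrix(series_matrix_file(text), dose=[1, 2, 3])
        assert np.isnan(ds.X).sum() == 1
        assert math.isnan(ds.X[0, 1])

    def test_row_width_mismatch_raises_structural_error(self, series_matrix_file):
        text = SERIES_MATRIX_OK.replace(
            '"probe_c"\t7.0\t8.0\t9.0', '"probe_c"\t7.0\t8.0\t9.0\t99.0'
        )
        with pytest.raises(SeriesMatrixError, match="probe_c"):
            read_series_matrix(series_matrix_file(text), dose=[1, 2, 3])

    def test_missing_table_markers_raise(self, series_matrix_file):
        text = SERIES_MATRIX_OK.replace("!series_matrix_table_end\n", "")
        with pytest.raises(SeriesMatrixError):
            read_series_matrix(series_matrix_file(text), dose=[1, 2, 3])

    def test_dose_from_characteristics_key(self, series_matrix_file):
        ds = read_series_matrix(series_matrix_file(), dose_key="dose")
        np.testing.assert_allclose(ds.y, [1.5, 3.0, 6.0])

    def test_no_response_mapping_is_explicit_error(self, series_matrix_file):
        with pytest.raises(NoResponseError, match="no response"):
            read_series_matrix(series_matrix_file())
        with pytest.raises(NoResponseError):
            read_series_matrix(series_matrix_file(), dose_key="concentration")


class TestPreprocess:
    def _ds(self, X, n=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        return ExpressionDataset(
            sample_ids=[f"s{i}" for i in range(n)],
            gene_ids=[f"g{j}" for j in range(X.shape[1])],
            X=X,
            y=np.arange(n, dtype=float),
        )

    def test_log2_with_pseudocount(self):
        ds = self._ds([[1.0], [3.0], [7.0]])
        out = preprocess(ds, already_log2=False)
        np.testing.assert_allclose(out.X[:, 0], [1.0, 2.0, 3.0])

    def test_negative_values_floored_before_log(self):
        ds = self._ds([[-5.0], [0.0], [1.0]])
        out = preprocess(ds, already_log2=False)
        np.testing.assert_allclose(out.X[:, 0], [0.0, 0.0, 1.0])

    def test_high_missingness_gene_dropped(self):
        X = np.ones((10, 2))
        X[:3, 0] = np.nan  # 30% missing > 20% threshold
        out = preprocess(self._ds(X), already_log2=True, max_missing_fraction=0.2)
        assert out.gene_ids == ["g1"]

    def test_surviving_missing_cell_imputed_with_median(self):
        X = np.column_stack([np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10.0])])
        X[0, 0] = np.nan
        out = preprocess(self._ds(X), already_log2=True, max_missing_fraction=0.2)
        # observed median of {2..10} is 6
        assert out.X[0, 0] == 6.0
        assert not np.isnan(out.X).any()

    def test_fully_missing_gene_always_dropped(self):
        X = np.ones((5, 2))
        X[:, 0] = np.nan
        out = preprocess(self._ds(X), already_log2=True, max_missing_fraction=1.0)
        assert out.gene_ids == ["g1"]

    def test_all_genes_dropped_raises(self):
        X = np.full((5, 2), np.nan)
        with pytest.raises(EmptyDatasetError):
            preprocess(self._ds(X), already_log2=True, max_missing_fraction=0.2)

    def test_idempotent_on_clean_log2_data(self, small_dataset):
        once = preprocess(small_dataset, already_log2=True)
        twice = preprocess(once, already_log2=True)
        np.testing.assert_array_equal(once.X, twice.X)


class TestSplit:
    @pytest.mark.parametrize("n,expected_train", [(10, 7), (69, 48), (20, 14)])
    def test_split_sizes_round_half_away(self, rng, n, expected_train):
        ds = ExpressionDataset(
            sample_ids=[f"s{i}" for i in range(n)],
            gene_ids=["g0"],
            X=rng.standard_normal((n, 1)),
            y=rng.standard_normal(n),
        )
        pair = split_train_test(ds, 0.7, seed=3)
        assert pair.train.n_samples == expected_train
        assert pair.test.n_samples == n - expected_train

    def test_same_seed_gives_identical_partition(self, small_dataset):
        a = split_train_test(small_dataset, 0.7, seed=11)
        b = split_train_test(small_dataset, 0.7, seed=11)
        assert a.train.sample_ids == b.train.sample_ids
        assert a.test.sample_ids == b.test.sample_ids

    def test_partitions_exhaustive_and_disjoint_over_many_seeds(self, small_dataset):
        full = set(small_dataset.sample_ids)
        for seed in range(1000):
            pair = split_train_test(small_dataset, 0.7, seed=seed)
            tr, te = set(pair.train.sample_ids), set(pair.test.sample_ids)
            assert tr.isdisjoint(te)
            assert tr | te == full

    def test_too_small_dataset_rejected(self, rng):
        ds = ExpressionDataset(
            sample_ids=["a", "b", "c"],
            gene_ids=["g"],
            X=rng.standard_normal((3, 1)),
            y=np.zeros(3),
        )
        with pytest.raises(ValueError):
            split_train_test(ds, 0.7, seed=0)


def test_tsv_round_trip_bit_exact(tmp_path, rng):
    X = rng.standard_normal((8, 5))
    X[2, 3] = np.nan
    ds = ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(8)],
        gene_ids=[f"gene_{j}" for j in range(5)],
        X=X,
        y=rng.standard_normal(8) * 9.59 + 13.6,
    )
    path = tmp_path / "ds.tsv"
    write_tsv(ds, path)
    back = read_tsv(path)
    assert back.sample_ids == ds.sample_ids
    assert back.gene_ids == ds.gene_ids
    np.testing.assert_array_equal(back.X, ds.X)
    np.testing.assert_array_equal(back.y, ds.y)
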