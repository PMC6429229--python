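"""Descriptor filters, scaling convention, splits and the activity threshold."""

import numpy as np
import pytest

import btlqsar as bq
from btlqsar.data import ACTIVE, INACTIVE
from btlqsar import preprocess as prep


def _matrix(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"d{j}" for j in range(values.shape[1])]
    ids = [f"c{i}" for i in range(values.shape[0])]
    return bq.DescriptorMatrix(ids, names, values)


class TestAutoscale:
    def test_fit_gives_zero_mean_unit_sd(self, tiny_dataset):
        scaled, params = bq.autoscale(tiny_dataset.descriptors)
        np.testing.assert_allclose(scaled.values.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(scaled.values.std(axis=0, ddof=0), 1, atol=1e-10)

    def test_applying_fitted_params_is_idempotent_with_fit(self, tiny_dataset):
        scaled, params = bq.autoscale(tiny_dataset.descriptors)
        reapplied, _ = bq.autoscale(tiny_dataset.descriptors, params)
        np.testing.assert_array_equal(scaled.values, reapplied.values)

    def test_two_row_column_population_sd_convention(self):
        # column (1, 3): mean 2, population SD 1, so the scaled values are
        # exactly (-1, +1) — the sample-SD convention would give ±1/√2
        X = _matrix([[1.0], [3.0]])
        scaled, params = bq.autoscale(X)
        np.testing.assert_allclose(scaled.values.ravel(), [-1.0, 1.0], atol=1e-12)
        assert params.ddof == 0

    def test_zero_variance_column_raises(self):
        X = _matrix([[1.0, 2.0], [1.0, 3.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            bq.autoscale(X)


class TestVarianceAndCorrelationFilters:
    def test_constant_column_removed_others_kept(self):
        X = _matrix(np.column_stack([np.ones(5), np.arange(5)]), ["const", "ramp"])
        out = bq.drop_zero_variance(X)
        assert out.names == ["ramp"]

    def test_no_constant_columns_identity(self, tiny_dataset):
        out = bq.drop_zero_variance(tiny_dataset.descriptors)
        assert out.names == tiny_dataset.descriptors.names

    def test_tiny_variance_removed_at_tolerance(self):
        rng = np.random.default_rng(0)
        tiny = 1.0 + rng.normal(0, 1e-7, 20)  # variance ~1e-14 < 1e-12
        X = _matrix(np.column_stack([tiny, rng.normal(size=20)]), ["tiny", "ok"])
        assert bq.drop_zero_variance(X).names == ["ok"]

    def test_all_constant_raises(self):
        with pytest.raises(ValueError):
            bq.drop_zero_variance(_matrix(np.ones((4, 2))))

    def test_duplicate_column_earlier_survives(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        X = _matrix(np.column_stack([a, a.copy(), rng.normal(size=30)]),
                    ["a", "a_copy", "b"])
        assert bq.drop_intercorrelated(X).names == ["a", "b"]

    def test_generator_blocks_one_survivor_each(self, tiny_dataset):
        out = bq.drop_intercorrelated(tiny_dataset.descriptors)
        for block in tiny_dataset.correlation_blocks:
            survivors = [n for n in out.names if n in block]
            assert len(survivors) == 1

    def test_survivors_pairwise_below_threshold(self, tiny_dataset):
        out = bq.drop_intercorrelated(tiny_dataset.descriptors, threshold=0.9)
        corr = np.corrcoef(out.values, rowvar=False)
        off = np.abs(corr[~np.eye(out.n_descriptors, dtype=bool)])
        assert off.max() <= 0.9

    def test_orthogonal_columns_identity(self):
        X = _matrix(np.eye(4))
        assert bq.drop_intercorrelated(X).names == X.names


class TestKohonenReduce:
    def test_single_neuron_single_descriptor(self, tiny_dataset):
        kept = bq.kohonen_reduce(tiny_dataset.descriptors, grid=(1, 1), seed=0)
        assert len(kept) == 1

    def test_identical_columns_never_both_retained(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        X = _matrix(
            np.column_stack([a, a.copy()] + [rng.normal(size=40) for _ in range(6)])
        )
        kept = bq.kohonen_reduce(X, grid=(2, 3), seed=0)
        assert not ({"d0", "d1"} <= set(kept))

    def test_correlation_blocks_at_most_one_member(self):
        ds = bq.generate_btl_like_dataset(
            bq.SyntheticSpec(n_compounds=80, n_descriptors=35, n_informative=5,
                             correlation_block_size=3, seed=9)
        )
        assert len(ds.correlation_blocks) == 10
        kept = set(bq.kohonen_reduce(ds.descriptors, grid=(4, 5), seed=0))
        for block in ds.correlation_blocks:
            assert len(kept & set(block)) <= 1

    def test_oversized_grid_warns(self, tiny_dataset):
        with pytest.warns(UserWarning):
            bq.kohonen_reduce(tiny_dataset.descriptors, grid=(10, 10), seed=0)


class TestSplitDataset:
    @pytest.mark.parametrize("method", ["random", "som"])
    def test_75_25_of_120_gives_90_30(self, method):
        ds = bq.generate_btl_like_dataset(bq.SyntheticSpec(seed=1))
        split = bq.split_dataset(ds.descriptors, ds.activities, (0.75, 0.25),
                                 method, seed=0)
        assert len(split.train_ids) == 90
        assert len(split.validation_ids) == 30

    @pytest.mark.parametrize("method", ["random", "som"])
    def test_three_way_disjoint_exhaustive(self, method):
        ds = bq.generate_btl_like_dataset(bq.SyntheticSpec(seed=1))
        split = bq.split_dataset(ds.descriptors, ds.activities,
                                 (0.60, 0.25, 0.15), method, seed=0)
        parts = [split.train_ids, split.test_ids, split.validation_ids]
        flat = [i for p in parts for i in p]
        assert len(flat) == 120
        assert set(flat) == set(ds.descriptors.ids)

    def test_fixed_seed_reproducible(self, tiny_dataset):
        a = bq.split_dataset(tiny_dataset.descriptors, tiny_dataset.activities,
                             (0.75, 0.25), "random", seed=5)
        b = bq.split_dataset(tiny_dataset.descriptors, tiny_dataset.activities,
                             (0.75, 0.25), "random", seed=5)
        assert a.train_ids == b.train_ids and a.validation_ids == b.validation_ids

    def test_stratified_split_preserves_class_ratio(self):
        ds = bq.generate_btl_like_dataset(bq.SyntheticSpec(seed=4))
        split = bq.split_dataset(ds.descriptors, ds.activities, (0.75, 0.25),
                                 "random", seed=1)
        tr = ds.activities.select_compounds(split.train_ids)
        # 50/120 actives → 37.5 expected in a 90-compound training set
        assert abs(tr.n_active - 37.5) <= 1

    def test_bad_fractions_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            bq.split_dataset(tiny_dataset.descriptors, tiny_dataset.activities,
                             (0.7, 0.2), "random", seed=0)


class TestActivityThreshold:
    @pytest.mark.parametrize(
        "pki,expected",
        [(1.31, ACTIVE), (1.3, INACTIVE), (-0.5, INACTIVE), (5.0, ACTIVE)],
    )
    def test_strict_threshold(self, pki, expected):
        assert bq.classify_by_threshold(pki) == expected

    def test_missing_value_raises(self):
        with pytest.raises(ValueError):
            bq.classify_by_threshold(float("nan"))
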