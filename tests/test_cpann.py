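"""Counter-propagation network: training rule, winner lookup, AD gating."""

import numpy as np
import pytest

import btlqsar as bq
from btlqsar import cpann as _cp
from btlqsar import preprocess as prep
from btlqsar import som
from btlqsar.data import ACTIVE, INACTIVE


def _dm(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"d{j}" for j in range(values.shape[1])]
    return bq.DescriptorMatrix([f"c{i}" for i in range(values.shape[0])], names, values)


class TestTrainingRule:
    def test_single_vector_full_rate_overwrites_winner(self):
        # one epoch, one training vector, η=1, single neuron (winner-only):
        # w ← w + 1·(x−w) lands exactly on the vector and the output weight
        # exactly on the target
        x = np.array([[2.0, -1.0, 0.5]])
        W, U, _ = som.train_som(x, rows=1, cols=1, epochs=1,
                                eta_max=1.0, eta_min=1.0, seed=0,
                                targets=np.array([[0.7]]))
        np.testing.assert_allclose(W[0], x[0], atol=1e-12)
        np.testing.assert_allclose(U[0, 0], 0.7, atol=1e-12)

    def test_retrain_same_seed_identical(self, tiny_dataset):
        cfg = _cp.CpannConfig(grid_rows=5, grid_cols=5, epochs=20, seed=3)
        y = tiny_dataset.activities.binary()
        a = _cp.train_cpann(tiny_dataset.descriptors, y, cfg)
        b = _cp.train_cpann(tiny_dataset.descriptors, y, cfg)
        np.testing.assert_array_equal(a.kohonen_weights, b.kohonen_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)
        assert a.ed_crt == b.ed_crt

    def test_noise_free_separable_training_accuracy(self):
        # memorization check: noise-free separable classes, 8×8 map,
        # 200 epochs, sharp learning rates
        ds = bq.generate_btl_like_dataset(
            bq.SyntheticSpec(n_compounds=60, n_descriptors=20, n_informative=5,
                             noise_sd=0.0, nonlinearity_weight=0.0, seed=3)
        )
        X = prep.drop_intercorrelated(prep.drop_zero_variance(ds.descriptors))
        model = _cp.train_cpann(
            X, ds.activities.binary(),
            _cp.CpannConfig(grid_rows=8, grid_cols=8, epochs=200,
                            eta_max=0.8, eta_min=0.05, seed=1),
        )
        pred = _cp.predict_cpann(model, X)
        acc = np.mean(pred["label"].to_numpy() == np.array(ds.activities.labels))
        assert acc >= 0.95

    def test_noise_free_regression_fit_quality_and_monotone_rmse(self):
        ds = bq.generate_btl_like_dataset(
            bq.SyntheticSpec(n_descriptors=40, n_informative=5, noise_sd=0.0,
                             nonlinearity_weight=0.0, seed=3)
        )
        X = ds.descriptors.select_descriptors(ds.true_support)
        model = _cp.train_cpann(X, ds.activities.pki, _cp.CpannConfig(seed=2),
                                task="regression")
        pred = _cp.predict_cpann(model, X)["pKi"].to_numpy()
        r2 = np.corrcoef(pred, ds.activities.pki)[0, 1] ** 2
        assert r2 >= 0.9
        # epoch-block mean RMSE decreases to a plateau
        h = np.array(model.rmse_history)
        blocks = h.reshape(5, -1).mean(axis=1)
        assert np.all(np.diff(blocks) <= 1e-9)

    def test_empty_or_nonfinite_input_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            _cp.train_cpann(_dm(np.empty((0, 3))), [], _cp.CpannConfig(seed=0))
        bad = tiny_dataset.descriptors
        values = bad.values.copy()
        values[0, 0] = np.nan
        with pytest.raises(ValueError):
            _cp.train_cpann(bq.DescriptorMatrix(bad.ids, bad.names, values),
                            tiny_dataset.activities.binary(), _cp.CpannConfig(seed=0))


class TestFindWinner:
    def test_exact_neuron_distance_zero(self, tiny_dataset):
        model = _cp.train_cpann(tiny_dataset.descriptors,
                                tiny_dataset.activities.binary(),
                                _cp.CpannConfig(grid_rows=4, grid_cols=4,
                                                epochs=10, seed=0))
        j, d = _cp.find_winner(model, model.kohonen_weights[7])
        assert j == 7 and d == 0.0

    def test_tie_broken_to_lowest_row_major_index(self):
        weights = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0]])
        j, d = som.find_winner(weights, np.zeros(2))  # first two equidistant
        assert j == 0 and d == pytest.approx(1.0)

    def test_agrees_with_exhaustive_scan(self, tiny_dataset):
        model = _cp.train_cpann(tiny_dataset.descriptors,
                                tiny_dataset.activities.binary(),
                                _cp.CpannConfig(grid_rows=6, grid_cols=5,
                                                epochs=15, seed=1))
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=model.kohonen_weights.shape[1])
            j, d = _cp.find_winner(model, x)
            dists = [np.linalg.norm(w - x) for w in model.kohonen_weights]
            assert j == int(np.argmin(dists))
            assert d == pytest.approx(min(dists))

    def test_dimension_mismatch_raises(self, tiny_dataset):
        model = _cp.train_cpann(tiny_dataset.descriptors,
                                tiny_dataset.activities.binary(),
                                _cp.CpannConfig(grid_rows=3, grid_cols=3,
                                                epochs=5, seed=0))
        with pytest.raises(ValueError):
            _cp.find_winner(model, np.zeros(3))


class TestPredictAndDomain:
    @pytest.fixture()
    def model_and_data(self, tiny_dataset):
        model = _cp.train_cpann(tiny_dataset.descriptors,
                                tiny_dataset.activities.binary(),
                                _cp.CpannConfig(grid_rows=5, grid_cols=5,
                                                epochs=30, seed=4))
        return model, tiny_dataset

    def test_training_compounds_always_in_domain(self, model_and_data):
        model, ds = model_and_data
        pred = _cp.predict_cpann(model, ds.descriptors)
        assert pred["ad_flag"].all()
        # ED_crt is attained by at least one training compound
        assert pred["distance"].max() == pytest.approx(model.ed_crt)

    def test_boundary_score_called_active(self):
        X = _dm(np.random.default_rng(0).normal(size=(10, 2)))
        model = _cp.train_cpann(X, np.ones(10) * 0.5,
                                _cp.CpannConfig(grid_rows=2, grid_cols=2,
                                                epochs=5, seed=0))
        model.output_weights[:] = 0.5
        pred = _cp.predict_cpann(model, X)
        assert (pred["label"] == ACTIVE).all()

    def test_far_query_out_of_domain(self, model_and_data):
        model, ds = model_and_data
        far = bq.DescriptorMatrix(["far"], ds.descriptors.names,
                                  ds.descriptors.values[:1] + 100.0)
        assert not _cp.predict_cpann(model, far)["ad_flag"].iloc[0]

    def test_in_domain_fraction_monotone_in_ed_crt(self, model_and_data):
        model, ds = model_and_data
        scr = bq.generate_screening_set(200, ds, seed=9)
        fractions = []
        for factor in [1.0, 0.75, 0.5, 0.25, 0.1]:
            lowered = _cp.CpannModel(
                model.kohonen_weights, model.output_weights,
                model.descriptor_names, model.scaling,
                model.ed_crt * factor, model.task, model.config,
            )
            fractions.append(_cp.predict_cpann(lowered, scr)["ad_flag"].mean())
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestSerialization:
    def test_json_round_trip(self, tiny_dataset, tmp_path):
        model = _cp.train_cpann(tiny_dataset.descriptors,
                                tiny_dataset.activities.binary(),
                                _cp.CpannConfig(grid_rows=4, grid_cols=4,
                                                epochs=10, seed=2))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = _cp.CpannModel.from_json(path)
        np.testing.assert_array_equal(loaded.kohonen_weights, model.kohonen_weights)
        np.testing.assert_array_equal(loaded.output_weights, model.output_weights)
        assert loaded.ed_crt == model.ed_crt
        assert loaded.config == model.config
        assert loaded.to_json() == model.to_json()
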