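import numpy as np
import pytest

from nullelab.chem import MoleculeState
from nullelab.qsar import (
    DescriptorFeaturizer,
    EmbeddingFeaturizer,
    FAMILIES,
    ModelSpec,
    MorganFeaturizer,
    QsarDataset,
    TrainedQsarModel,
    crossval_benchmark,
    featurize_set,
    predict,
    train,
)
from nullelab.synthetic import SurrogateSpec, gen_property_labels, surrogate_targets

PLANTED = (0.5, 0.01, -0.02, 0.1)  # intercept + coefficients on (MW, TPSA, HBD)


def linear_dataset(library, noise_sd=0.0, seed=0):
    spec = SurrogateSpec(name="linear_descriptor", coefficients=PLANTED,
                         noise_sd=noise_sd, seed=seed)
    y = surrogate_targets(library, spec)
    return QsarDataset(
        ids=[f"m{i}" for i in range(len(library))],
        smiles=[s.structure for s in library],
        y=y,
        endpoint="binding_energy",
    )


class TestFeaturizers:
    def test_duplicates_get_identical_rows(self, small_library):
        X = featurize_set(["CCO", "OCC", "CCN"])
        assert np.array_equal(X[0], X[1]) and not np.array_equal(X[0], X[2])

    def test_row_count_and_width(self, small_library):
        feat = MorganFeaturizer(n_bits=256)
        X = featurize_set(small_library, feat)
        assert X.shape == (len(small_library), 256)

    def test_invalid_state_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            featurize_set(["CCO", "x&y", "CCN"])

    def test_embedding_contract(self, small_library):
        feat = EmbeddingFeaturizer(dim=16).fit(small_library)
        X = feat.transform(small_library[:5])
        assert X.shape == (5, 16)
        again = feat.transform(small_library[:5])
        assert np.array_equal(X, again)
        # aliases of the same molecule featurize identically
        alias = feat.transform(["OCC"])
        assert np.array_equal(alias, feat.transform(["CCO"]))


class TestTrain:
    def test_linear_family_recovers_planted_coefficients(self, small_library):
        data = linear_dataset(small_library)
        model = train(ModelSpec(family="linear"), data, featurizer=DescriptorFeaturizer())
        coef = model.model.coef_
        # features are (mw, tpsa, hbd, ...): planted weights on the first three, 0 beyond
        assert np.allclose(coef[:3], PLANTED[1:], atol=1e-6)
        assert np.allclose(coef[3:], 0.0, atol=1e-6)
        assert model.model.intercept_ == pytest.approx(PLANTED[0], abs=1e-6)
        mse = float(np.mean((model.predict(data.smiles) - data.y) ** 2))
        assert mse < 1e-8

    def test_unrestricted_tree_memorizes(self, small_library):
        data = linear_dataset(small_library, noise_sd=0.1)
        model = train(ModelSpec(family="tree"), data)
        assert float(np.mean((model.predict(data.smiles) - data.y) ** 2)) == pytest.approx(0.0, abs=1e-12)

    def test_constant_target_tree(self, small_library):
        data = QsarDataset(
            ids=[f"m{i}" for i in range(10)],
            smiles=[s.structure for s in small_library[:10]],
            y=np.full(10, 2.0),
            endpoint="cns_mpo",
        )
        model = train(ModelSpec(family="tree"), data)
        assert np.allclose(model.predict(data.smiles), 2.0)

    def test_seeded_reproducibility(self, small_library):
        data = linear_dataset(small_library, noise_sd=0.2)
        spec = ModelSpec(family="feedforward", hidden_layers=(16, 8), epochs=50)
        a = train(spec, data, seed=7).predict(data.smiles)
        b = train(spec, data, seed=7).predict(data.smiles)
        assert np.array_equal(a, b)

    def test_empty_dataset_rejected(self):
        data = QsarDataset(ids=[], smiles=[], y=np.array([]), endpoint="cns_mpo")
        with pytest.raises(ValueError, match="empty"):
            train(ModelSpec(family="linear"), data)

    def test_log_transform_on_half_time_endpoint(self, small_library):
        spec = SurrogateSpec(name="motif_potency", seed=3)
        data = gen_property_labels(small_library, spec)
        model = train(ModelSpec(family="tree"), data)
        assert model.log_target
        # back-transformed predictions reproduce the positive labels
        assert np.allclose(model.predict(data.smiles), data.y, rtol=1e-9)


class TestPredict:
    def test_memorizing_tree_returns_training_targets(self, small_library):
        data = linear_dataset(small_library, noise_sd=0.3, seed=5)
        model = train(ModelSpec(family="tree"), data)
        assert np.allclose(predict(model, data.smiles), data.y)

    def test_batch_order_preserved(self, small_library):
        data = linear_dataset(small_library)
        model = train(ModelSpec(family="linear"), data, featurizer=DescriptorFeaturizer())
        batch = [small_library[i].structure for i in (3, 0, 7)]
        single = [float(predict(model, [s])[0]) for s in batch]
        assert np.allclose(predict(model, batch), single)

    def test_smiles_alias_invariance(self, small_library):
        data = linear_dataset(small_library)
        model = train(ModelSpec(family="forest"), data)
        assert predict(model, ["OCC"])[0] == predict(model, ["CCO"])[0]


class TestSerialization:
    def test_round_trip(self, tmp_path, small_library):
        data = linear_dataset(small_library, noise_sd=0.1)
        model = train(ModelSpec(family="forest"), data, seed=3)
        path = tmp_path / "model.joblib"
        model.save(path)
        back = TrainedQsarModel.load(path)
        assert back.endpoint == model.endpoint and back.seed == 3
        assert np.allclose(back.predict(data.smiles), model.predict(data.smiles))


class TestCrossvalBenchmark:
    def test_matrix_shape_and_memorizing_tree(self, small_library):
        data = linear_dataset(small_library, noise_sd=0.2)
        specs = [ModelSpec(family=f, hidden_layers=(16, 8), epochs=30) for f in FAMILIES]
        result = crossval_benchmark(specs, [data], k=3, seed=0)
        assert set(result.table) == {(f, "binding_energy") for f in FAMILIES}
        for v in result.table.values():
            assert v["train_mse"] >= 0 and v["test_mse"] >= 0
        tree = result.table[("tree", "binding_energy")]
        assert tree["train_mse"] == pytest.approx(0.0, abs=1e-12)
        assert tree["train_mse"] <= tree["test_mse"]

    def test_noiseless_linear_generalizes(self, small_library):
        data = linear_dataset(small_library)
        result = crossval_benchmark(
            [ModelSpec(family="linear")], [data], k=3, seed=0,
            featurizer=DescriptorFeaturizer(),
        )
        assert result.table[("linear", "binding_energy")]["test_mse"] < 1e-6

    def test_row_order_invariance(self, small_library):
        data = linear_dataset(small_library, noise_sd=0.2)
        perm = np.random.default_rng(0).permutation(len(data))
        shuffled = QsarDataset(
            ids=[data.ids[i] for i in perm],
            smiles=[data.smiles[i] for i in perm],
            y=data.y[perm],
            endpoint=data.endpoint,
        )
        a = crossval_benchmark([ModelSpec(family="linear")], [data], k=3, seed=0)
        b = crossval_benchmark([ModelSpec(family="linear")], [shuffled], k=3, seed=0)
        ka, kb = ("linear", "binding_energy"), ("linear", "binding_energy")
        assert a.table[ka]["test_mse"] == pytest.approx(b.table[kb]["test_mse"], rel=0.5)

    def test_k_larger_than_n_rejected(self, small_library):
        data = linear_dataset(small_library[:4])
        with pytest.raises(ValueError):
            crossval_benchmark([ModelSpec(family="linear")], [data], k=10)

    def test_csv_matrix_layout(self, tmp_path, small_library):
        data = linear_dataset(small_library, noise_sd=0.1)
        result = crossval_benchmark([ModelSpec(family="linear"), ModelSpec(family="tree")],
                                    [data], k=3, seed=0)
        path = tmp_path / "bench.csv"
        result.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        assert list(df.index) == ["linear", "tree"]
        assert set(df.columns) == {"binding_energy_train", "binding_energy_test"}
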