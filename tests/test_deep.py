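import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

import painfeat as pf
from painfeat import deep

# Published layer recipes the builders must reproduce exactly.
MLP_TABLE = [
    ("Flatten", {}),
    ("Dropout", {"rate": 0.1}),
    ("Dense", {"units": 250, "activation": None}),
    ("Dropout", {"rate": 0.1}),
    ("Dense", {"units": 100, "activation": None}),
    ("Dense", {"units": 2, "activation": "softmax"}),
]
CNN_TABLE = [
    ("Conv", {"filters": 16, "kernel": 7, "stride": 2, "activation": "relu"}),
    ("MaxPool", {"size": 4}),
    ("Dropout", {"rate": 0.1}),
    ("Conv", {"filters": 16, "kernel": 7, "stride": 2, "activation": "relu"}),
    ("MaxPool", {"size": 4}),
    ("Dropout", {"rate": 0.1}),
    ("Flatten", {}),
    ("Dense", {"units": 100, "activation": None}),
    ("Dense", {"units": 2, "activation": "softmax"}),
]
CONVLSTM_TABLE = [
    ("ConvLSTM", {"filters": 32, "kernel": 11, "stride": 8,
                  "activation": "tanh", "recurrent_activation": "hard_sigmoid"}),
    ("Dropout", {"rate": 0.1}), ("BatchNorm", {}), ("MaxPool", {"size": 4}),
    ("ConvLSTM", {"filters": 16, "kernel": 7, "stride": 8,
                  "activation": "tanh", "recurrent_activation": "hard_sigmoid"}),
    ("Dropout", {"rate": 0.1}), ("BatchNorm", {}), ("MaxPool", {"size": 4}),
    ("ConvLSTM", {"filters": 8, "kernel": 3, "stride": 2,
                  "activation": "tanh", "recurrent_activation": "hard_sigmoid"}),
    ("Dropout", {"rate": 0.1}), ("BatchNorm", {}), ("MaxPool", {"size": 4}),
    ("Flatten", {}), ("Dropout", {"rate": 0.1}),
    ("Dense", {"units": 100, "activation": "relu"}),
    ("Dense", {"units": 2, "activation": "softmax"}),
]
CAE_TABLE = [
    ("Conv", {"filters": 64, "kernel": 7, "stride": 1, "activation": "relu"}),
    ("MaxPool", {"size": 4}),
    ("Conv", {"filters": 32, "kernel": 11, "stride": 1, "activation": "relu"}),
    ("MaxPool", {"size": 4}),
    ("Conv", {"filters": 16, "kernel": 11, "stride": 1, "activation": "relu"}),
    ("MaxPool", {"size": 4}),
    ("UpSampling", {"size": 4}),
    ("Conv", {"filters": 16, "kernel": 11, "stride": 1, "activation": "relu"}),
    ("UpSampling", {"size": 4}),
    ("Conv", {"filters": 32, "kernel": 11, "stride": 1, "activation": "relu"}),
    ("UpSampling", {"size": 4}),
    ("Conv", {"filters": 64, "kernel": 7, "stride": 1, "activation": "relu"}),
    ("Conv", {"filters": 1, "kernel": 1, "stride": 1, "activation": None}),
]


class TestArchitectureConformance:
    @pytest.mark.parametrize("name,shape,table", [
        ("mlp", (2560, 1), MLP_TABLE),
        ("cnn", (2560, 1), CNN_TABLE),
        ("convlstm", (4, 640, 1), CONVLSTM_TABLE),
        ("cae", (2560, 1), CAE_TABLE),
    ])
    def test_layer_by_layer_audit(self, name, shape, table):
        spec, _ = pf.build_architecture(name, shape)
        assert spec.layers == table

    def test_mlp_feature_length_is_100(self):
        spec, model = pf.build_architecture("mlp", (2560, 1))
        fe = pf.truncate_to_extractor(model, spec)
        out = fe(np.zeros((2, 2560, 1)))
        assert out.shape == (2, 100)

    @pytest.mark.parametrize("t,expected", [(2560, 640), (1408, 352)])
    def test_cae_bottleneck_size(self, t, expected):
        # three pools of 4 reduce T by 64; 16 bottleneck channels
        spec, model = pf.build_architecture("cae", (t, 1))
        fe = pf.truncate_to_extractor(model, spec)
        assert fe(np.zeros((1, t, 1))).shape == (1, expected)

    def test_cae_reconstruction_shape_matches_input(self):
        _, model = pf.build_architecture("cae", (2560, 1))
        x = np.zeros((2, 2560, 1))
        assert model.forward(x).shape == x.shape

    def test_convlstm_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            pf.reshape_for_convlstm(np.zeros((1407, 1)))


class TestReshape:
    @pytest.mark.parametrize("t,expected", [(1408, (4, 352, 1, 1)),
                                            (2560, (4, 640, 1, 1))])
    def test_published_shapes(self, t, expected):
        assert pf.reshape_for_convlstm(np.zeros((t, 1))).shape == expected

    def test_split_then_concatenate_is_identity(self):
        x = np.random.default_rng(0).random((64, 2))
        tensor = pf.reshape_for_convlstm(x)
        np.testing.assert_array_equal(deep.unsplit_convlstm(tensor), x)


def toy_two_class(n=40, t=64, seed=0):
    """Two Gaussian-bump classes, linearly separable."""
    rng = np.random.default_rng(seed)
    grid = np.arange(t)
    x = np.empty((n, t, 1), dtype=np.float32)
    y = np.tile([0, 1], n // 2)
    for i, label in enumerate(y):
        center = t // 4 if label == 0 else 3 * t // 4
        x[i, :, 0] = np.exp(-0.5 * ((grid - center) / 5.0) ** 2) \
            + 0.05 * rng.normal(size=t)
    return x, y


class TestTraining:
    def test_supervised_loss_decreases_on_separable_toy_data(self):
        x, y = toy_two_class()
        _, model = pf.build_architecture("mlp", (64, 1))
        cfg = pf.TrainConfig(learning_rate=1e-3, epochs=20, rng_seed=0)
        _, history = pf.train_supervised(model, x, y, cfg)
        assert history[-1] < history[0]

    def test_zero_epochs_is_a_no_op(self):
        x, y = toy_two_class()
        _, model = pf.build_architecture("mlp", (64, 1))
        before = [p.copy() for p, _ in model.params_and_grads()]
        _, history = pf.train_supervised(model, x, y,
                                         pf.TrainConfig(epochs=0))
        assert history == []
        for b, (p, _) in zip(before, model.params_and_grads()):
            np.testing.assert_array_equal(b, p)

    def test_fixed_seed_reproduces_loss_history(self):
        x, y = toy_two_class()
        histories = []
        for _ in range(2):
            _, model = pf.build_architecture("cnn", (64, 1), rng_seed=3)
            _, h = pf.train_supervised(model, x, y,
                                       pf.TrainConfig(epochs=3, rng_seed=3))
            histories.append(h)
        assert histories[0] == histories[1]

    def test_single_class_rejected(self):
        x, _ = toy_two_class()
        _, model = pf.build_architecture("mlp", (64, 1))
        with pytest.raises(ValueError):
            pf.train_supervised(model, x, np.zeros(len(x), dtype=int),
                                pf.TrainConfig(epochs=1))

    def test_cae_learns_constant_windows(self):
        x = np.full((16, 64, 1), 0.5, dtype=np.float32)
        _, model = pf.build_architecture("cae", (64, 1))
        cfg = pf.TrainConfig(learning_rate=1e-2, epochs=30, rng_seed=0)
        _, history = pf.train_cae(model, x, cfg)
        assert history[-1] < history[0]
        assert history[-1] < 1e-3

    def test_untrained_encoder_still_yields_finite_vectors(self):
        spec, model = pf.build_architecture("cae", (64, 1))
        fe = pf.truncate_to_extractor(model, spec)
        out = fe(np.random.default_rng(0).random((3, 64, 1)))
        assert out.shape[0] == 3
        assert np.all(np.isfinite(out))


class TestExtractor:
    def test_extractor_is_pure(self):
        x, y = toy_two_class()
        spec, model = pf.build_architecture("cnn", (64, 1))
        pf.train_supervised(model, x, y, pf.TrainConfig(epochs=2))
        fe = pf.truncate_to_extractor(model, spec)
        np.testing.assert_array_equal(fe(x[:4]), fe(x[:4]))

    def test_trained_mlp_features_beat_random_projection(self):
        """On separable data an RF on learned features outperforms an RF on
        an equal-width random linear projection."""
        x, y = toy_two_class(n=60, seed=1)
        spec, model = pf.build_architecture("mlp", (64, 1), rng_seed=0)
        pf.train_supervised(model, x, y,
                            pf.TrainConfig(learning_rate=1e-3, epochs=30,
                                           rng_seed=0))
        fe = pf.truncate_to_extractor(model, spec)
        rng = np.random.default_rng(99)
        proj = rng.normal(size=(64, 100))
        flat = x[:, :, 0]

        def cv_accuracy(features):
            accs = []
            for fold in range(3):
                test = np.arange(len(y)) % 3 == fold
                rf = RandomForestClassifier(n_estimators=50, random_state=0)
                rf.fit(features[~test], y[~test])
                accs.append(np.mean(rf.predict(features[test]) == y[test]))
            return np.mean(accs)

        assert cv_accuracy(fe(x)) >= cv_accuracy(flat @ proj)
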