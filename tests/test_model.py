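"""Architecture contracts: shapes, heads, fusion, masking, gradient flow."""

import numpy as np
import pytest

from cogfuse.embeddings import EmbeddingSpec
from cogfuse.model import (
    CNN_KERNELS,
    FusionClassifier,
    HyperPoint,
    ModelSpec,
    assemble,
    predict_multilabel,
)
from cogfuse.training import encode_dataset

HYPER = HyperPoint(lstm_dim=64, dense_dim=8, batch=20, lr=1e-3)


def make_spec(**kwargs):
    base = dict(embedding=EmbeddingSpec.of("random"), n_classes=2, hyper=HYPER)
    base.update(kwargs)
    return ModelSpec(**base)


def batch_for(ds, spec, idx=None):
    data = encode_dataset(ds.records, spec, n_classes=2 if ds.task != "relation_detection" else 11)
    idx = np.arange(len(data)) if idx is None else np.asarray(idx)
    return data, data.take(idx, spec)


class TestHyperPoint:
    def test_values_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            HyperPoint(lstm_dim=100)
        with pytest.raises(ValueError):
            HyperPoint(lr=0.02)

    def test_kernel_ensemble_is_fixed(self):
        assert CNN_KERNELS == (1, 4, 7)


class TestSpecs:
    def test_cognitive_dims(self):
        assert make_spec(cognitive_input="eeg").cognitive_dim == 105
        assert make_spec(cognitive_input="noise").cognitive_dim == 105
        assert make_spec(cognitive_input="gaze").cognitive_dim == 5
        assert make_spec(cognitive_input="none").cognitive_dim == 0

    def test_band_streams(self):
        four = make_spec(cognitive_input="eeg",
                         eeg_bands=("theta", "alpha", "beta", "gamma"))
        assert [n for n, _ in four.cognitive_streams] == ["theta", "alpha", "beta", "gamma"]
        wide = make_spec(cognitive_input="eeg", band_fusion="concat",
                         eeg_bands=("theta", "alpha", "beta", "gamma"))
        assert wide.cognitive_streams == [("theta+alpha+beta+gamma", 420)]

    def test_invalid_choices_rejected(self):
        for bad in (
            dict(cognitive_input="fmri"),
            dict(fusion="average"),
            dict(head="linear"),
            dict(eeg_component="transformer"),
        ):
            with pytest.raises(ValueError):
                make_spec(**bad)


class TestForwardContracts:
    def test_softmax_scores_sum_to_one(self, tiny_binary_dataset):
        spec = make_spec(cognitive_input="eeg", eeg_bands=("theta",))
        _, batch = batch_for(tiny_binary_dataset, spec, idx=range(8))
        model = assemble(spec, 5000, 10, seed=0)
        probs = model.predict_proba(batch)
        assert probs.shape == (8, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_sigmoid_head_independent_scores(self, tiny_relation_dataset):
        spec = make_spec(cognitive_input="eeg", head="sigmoid", n_classes=11)
        _, batch = batch_for(tiny_relation_dataset, spec, idx=range(6))
        model = assemble(spec, 5000, 10, seed=0)
        probs = model.predict_proba(batch)
        assert probs.shape == (6, 11)
        assert np.all((probs > 0) & (probs < 1))

    def test_head_ranges_over_random_draws(self):
        # normalization/range holds for arbitrary weights and inputs
        rng = np.random.default_rng(0)
        for trial in range(100):
            spec = make_spec(head="softmax" if trial % 2 == 0 else "sigmoid", n_classes=3)
            model = assemble(spec, 50, 6, seed=trial)
            batch = {
                "token_ids": rng.integers(0, 50, size=(2, 6)),
                "mask": np.ones((2, 6)),
                "cog": {},
            }
            probs = model.predict_proba(batch)
            if spec.head == "softmax":
                np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
            else:
                assert np.all((probs > 0) & (probs < 1))

    @pytest.mark.parametrize("fusion", ["concat", "add", "subtract", "max"])
    def test_fusion_variants_forward(self, tiny_binary_dataset, fusion):
        spec = make_spec(cognitive_input="eeg", eeg_bands=("theta",), fusion=fusion)
        _, batch = batch_for(tiny_binary_dataset, spec, idx=range(4))
        model = assemble(spec, 5000, 10, seed=1)
        assert model.predict_proba(batch).shape == (4, 2)

    def test_gaze_tower_consumes_five_dims(self, tiny_binary_dataset):
        spec = make_spec(cognitive_input="gaze")
        data, batch = batch_for(tiny_binary_dataset, spec, idx=range(4))
        assert data.cog["gaze"].shape[2] == 5
        model = assemble(spec, 5000, 10, seed=1)
        assert model.predict_proba(batch).shape == (4, 2)

    def test_convolutional_tower_branches(self, tiny_binary_dataset):
        spec = make_spec(cognitive_input="eeg", eeg_bands=("theta",),
                         eeg_component="convolutional",
                         hyper=HyperPoint(cnn_filters=16, dense_dim=8))
        data, batch = batch_for(tiny_binary_dataset, spec, idx=range(4))
        model = assemble(spec, 5000, data.pad_len, seed=1)
        tower = model.cog_towers[0][1]
        assert len(tower.convs) == 3
        assert {w.data.shape[0] for w, _ in tower.convs} == set(CNN_KERNELS)
        # branch concatenation carries 3 x filters channels
        assert sum(w.data.shape[2] for w, _ in tower.convs) == 48
        assert model.predict_proba(batch).shape == (4, 2)

    def test_conv_output_width_independent_of_content(self, tiny_binary_dataset):
        spec = make_spec(cognitive_input="eeg", eeg_component="convolutional")
        data, batch = batch_for(tiny_binary_dataset, spec)
        model = assemble(spec, 5000, data.pad_len, seed=0)
        h = model.forward(batch)
        assert h.data.shape == (len(data), 2)


class TestMasking:
    def test_padding_invariance_recurrent(self, tiny_binary_dataset):
        spec = make_spec(cognitive_input="eeg", eeg_bands=("theta",))
        data, batch = batch_for(tiny_binary_dataset, spec, idx=range(5))
        model = assemble(spec, 5000, data.pad_len, seed=3)
        out_a = model.forward(batch).data
        wider = {
            "token_ids": np.pad(batch["token_ids"], ((0, 0), (0, 4))),
            "mask": np.pad(batch["mask"], ((0, 0), (0, 4))),
            "cog": {"theta": np.pad(batch["cog"]["theta"], ((0, 0), (0, 4), (0, 0)))},
        }
        out_b = model.forward(wider).data
        np.testing.assert_allclose(out_a, out_b, atol=1e-12)

    def test_all_pad_sentence_deterministic(self):
        spec = make_spec()
        model = assemble(spec, 50, 6, seed=0)
        batch = {"token_ids": np.zeros((2, 6), dtype=int), "mask": np.zeros((2, 6)), "cog": {}}
        out1 = model.forward(batch).data
        out2 = model.forward(batch).data
        np.testing.assert_array_equal(out1, out2)
        np.testing.assert_allclose(out1[0], out1[1])


class TestGradientFlow:
    def test_training_step_updates_both_towers(self, tiny_binary_dataset):
        spec = make_spec(cognitive_input="eeg", eeg_bands=("theta",))
        data, batch = batch_for(tiny_binary_dataset, spec, idx=range(10))
        model = assemble(spec, 5000, data.pad_len, seed=2)
        loss = model.loss(batch, np.random.default_rng(0), training=True)
        for p in model.parameters():
            p.grad = None
        loss.backward()
        text_norm = sum(np.abs(p.grad).sum() for p in model.text_tower.parameters())
        cog_norm = sum(np.abs(p.grad).sum() for p in model.cog_towers[0][1].parameters())
        assert text_norm > 0
        assert cog_norm > 0


class TestMultilabelDecision:
    def test_threshold_rule(self):
        assert predict_multilabel([0.9, 0.2, 0.6], 0.5) == {0, 2}

    def test_empty_set_allowed(self):
        assert predict_multilabel([0.1, 0.2], 0.5) == set()

    def test_threshold_monotonicity(self, rng):
        scores = rng.random(11)
        low, high = predict_multilabel(scores, 0.3), predict_multilabel(scores, 0.7)
        assert high <= low

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            predict_multilabel([0.5], 1.0)
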