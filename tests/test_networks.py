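"""Architecture specs, parameter audits, prediction and embedding contracts."""

import numpy as np
import pytest

from sincvoice import nnet
from sincvoice.networks import (
    NetworkSpec,
    build_model,
    compact_sincnet_spec,
    count_learnable_params,
    default_cnn1d_spec,
    default_cnn2d_spec,
    default_sincnet_spec,
    extract_embedding,
    predict_chunk,
)


class TestDefaultSpecs:
    def test_sincnet_head_matches_class_count(self):
        assert default_sincnet_spec(4).n_classes == 4

    def test_sincnet_front_end_has_160_learnable_scalars(self):
        spec = default_sincnet_spec(2)
        fe = spec.front_end
        assert fe["kind"] == "sinc"
        assert 2 * fe["n_filters"] == 160
        assert fe["kernel"] == 251

    def test_sincnet_and_cnn1d_differ_only_in_front_end(self):
        a = default_sincnet_spec(3).to_dict()
        b = default_cnn1d_spec(3).to_dict()
        del a["front_end"], b["front_end"]
        assert a == b

    def test_sincnet_stack_dimensions(self):
        spec = default_sincnet_spec(2)
        assert spec.conv_layers == [(60, 5, 1), (60, 5, 1)]
        assert spec.fc_layers == [2048, 2048, 2048]
        assert spec.dropout_conv == [0.5, 0.5]
        assert spec.dropout_fc == [0.3, 0.3, 0.3]

    def test_cnn1d_front_end_learnable_scalars(self):
        fe = default_cnn1d_spec(2).front_end
        assert fe["n_filters"] * fe["kernel"] == 20080  # plus bias terms

    def test_cnn2d_structure(self):
        spec = default_cnn2d_spec(2)
        assert [c for c, _k, _s in spec.conv_layers] == [80, 60, 60]
        assert spec.dropout_fc == [0.3, 0.2, 0.2]
        assert spec.dropout_conv == [0.0, 0.5, 0.4]
        assert spec.front_end["kind"] == "conv2d-spectrogram"

    def test_binary_head(self):
        assert default_cnn1d_spec(2).n_classes == 2

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            default_sincnet_spec(1)

    def test_yaml_roundtrip(self):
        spec = default_cnn2d_spec(3)
        again = NetworkSpec.from_yaml(spec.to_yaml())
        assert again.to_dict() == spec.to_dict()


class TestParameterAudit:
    @pytest.mark.parametrize("factory", [default_sincnet_spec, default_cnn1d_spec,
                                         default_cnn2d_spec])
    def test_built_model_matches_symbolic_count(self, factory):
        spec = factory(4)
        model = build_model(spec, seed=0)
        assert model.n_params == count_learnable_params(spec)

    def test_sinc_front_end_parameter_budget(self):
        model = build_model(default_sincnet_spec(4), seed=0)
        front = model.front
        assert sum(p.value.size for p in front.params()) == 160

    def test_compact_model_matches_symbolic_count(self):
        spec = compact_sincnet_spec(4)
        assert build_model(spec, seed=1).n_params == count_learnable_params(spec)


@pytest.fixture(scope="module")
def tiny_model():
    """A 4-filter miniature for fast inference contracts."""
    spec = compact_sincnet_spec(3)
    spec.front_end = dict(spec.front_end, n_filters=4, kernel=31)
    spec.conv_layers = [(4, 5, 1)]
    spec.pool_size = [4, 4]
    spec.fc_layers = [16]
    spec.dropout_conv = [0.2]
    spec.dropout_fc = [0.1]
    spec.chunk_s = 0.05
    return build_model(spec, seed=3)


class TestPredictChunk:
    def test_posterior_sums_to_one(self, tiny_model):
        rng = np.random.default_rng(0)
        chunk = rng.standard_normal(tiny_model.spec.chunk_len)
        probs = predict_chunk(tiny_model, chunk)
        assert probs.shape == (3,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(probs >= 0)

    def test_inference_is_deterministic(self, tiny_model):
        chunk = np.random.default_rng(1).standard_normal(tiny_model.spec.chunk_len)
        p1 = predict_chunk(tiny_model, chunk)
        p2 = predict_chunk(tiny_model, chunk)
        assert np.array_equal(p1, p2)

    def test_zero_chunk_near_uniform_posterior(self, tiny_model):
        probs = predict_chunk(tiny_model, np.zeros(tiny_model.spec.chunk_len))
        assert np.all(np.abs(probs - 1.0 / 3.0) < 0.05)

    def test_wrong_length_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            predict_chunk(tiny_model, np.zeros(10))

    def test_nonfinite_input_rejected(self, tiny_model):
        bad = np.zeros(tiny_model.spec.chunk_len)
        bad[0] = np.nan
        with pytest.raises(ValueError):
            predict_chunk(tiny_model, bad)


class TestEmbedding:
    def test_dimension_matches_last_fc_width(self, tiny_model):
        chunk = np.random.default_rng(2).standard_normal(tiny_model.spec.chunk_len)
        emb = extract_embedding(tiny_model, chunk)
        assert emb.shape == (16,)
        assert np.all(np.isfinite(emb))

    def test_default_embedding_width_is_2048(self):
        assert default_sincnet_spec(2).fc_layers[-1] == 2048

    def test_head_applied_to_embedding_reproduces_posterior(self, tiny_model):
        chunk = np.random.default_rng(3).standard_normal(tiny_model.spec.chunk_len)
        emb = extract_embedding(tiny_model, chunk)
        logits = tiny_model.head.forward(emb[None, :], train=False)
        assert np.allclose(nnet.softmax(logits)[0], predict_chunk(tiny_model, chunk))

    def test_distinct_posteriors_imply_distinct_embeddings(self, tiny_model):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(tiny_model.spec.chunk_len)
        b = rng.standard_normal(tiny_model.spec.chunk_len)
        if not np.allclose(predict_chunk(tiny_model, a), predict_chunk(tiny_model, b)):
            assert not np.allclose(extract_embedding(tiny_model, a),
                                   extract_embedding(tiny_model, b))


class TestGradients:
    def test_sinc_cutoff_gradients_match_numerical(self, tiny_model):
        """Autograd vs central differences on the 4-filter miniature."""
        model = tiny_model
        rng = np.random.default_rng(5)
        x = rng.standard_normal((4, model.spec.chunk_len))
        y = np.array([0, 1, 2, 0])
        # move cutoff parameters off the |x| kink at zero, where the
        # two-sided difference quotient vanishes by symmetry
        model.front.raw_low.value += 2.0
        model.front.raw_band.value += 2.0

        def loss_now():
            loss, _ = nnet.softmax_xent(model.forward_logits(x, train=False), y)
            return loss

        for p in model.params():
            p.zero_grad()
        loss, dlogits = nnet.softmax_xent(model.forward_logits(x, train=False), y)
        model.backward(dlogits)
        front = model.front
        eps = 1e-5
        for par in (front.raw_low, front.raw_band):
            for i in range(2):
                orig = par.value[i]
                par.value[i] = orig + eps
                lp = loss_now()
                par.value[i] = orig - eps
                lm = loss_now()
                par.value[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert par.grad[i] == pytest.approx(numeric, rel=1e-4, abs=1e-10)

    def test_gradients_reach_cutoffs_on_random_batch(self, tiny_model):
        model = tiny_model
        rng = np.random.default_rng(6)
        x = rng.standard_normal((8, model.spec.chunk_len))
        y = rng.integers(0, 3, size=8)
        for p in model.params():
            p.zero_grad()
        _, dlogits = nnet.softmax_xent(model.forward_logits(x, train=True), y)
        model.backward(dlogits)
        front = model.front
        assert np.all(np.isfinite(front.raw_low.grad))
        assert np.all(np.isfinite(front.raw_band.grad))
        assert np.any(front.raw_low.grad != 0)
        assert np.any(front.raw_band.grad != 0)


def test_cnn2d_forward_shapes_and_posterior():
    spec = default_cnn2d_spec(3)
    spec.fc_layers = [32, 32, 32]  # keep the audit structure, desk-scale width
    model = build_model(spec, seed=7)
    assert model.n_params == count_learnable_params(spec)
    chunk = np.random.default_rng(8).standard_normal(spec.chunk_len)
    probs = predict_chunk(model, chunk)
    assert probs.shape == (3,)
    assert probs.sum() == pytest.approx(1.0, abs=1e-6)
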