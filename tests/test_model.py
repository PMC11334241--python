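"""Siamese network shape contracts, loss analytics, stop-gradient."""

import numpy as np
import pytest

from siamquality import nn
from siamquality.model import (ModelConfig, SiamQualityNet, load_checkpoint,
                               negative_cosine, pair_loss, save_checkpoint)


def unit(v):
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


class TestShapes:
    def test_tiny_encoder_output_dim(self, tiny_model):
        h = tiny_model.eval().encode(np.random.default_rng(0).random(1200))
        assert h.shape == (1, 64)

    def test_projection_and_prediction_dims(self, tiny_model):
        out = tiny_model.eval()(np.random.default_rng(0).random((3, 1200)))
        assert out.h.shape == (3, 64)
        assert out.z.shape == (3, 32)
        assert out.p.shape == (3, 32)

    def test_predictor_is_endomorphic(self, tiny_model):
        """Equal input/output dims: the predictor can be applied twice."""
        z = nn.Tensor(np.random.default_rng(1).random((2, 32)))
        tiny_model.eval()
        p = tiny_model.predict(tiny_model.predict(z))
        assert p.shape == (2, 32)

    def test_wrong_input_length_names_expectation(self, tiny_model):
        with pytest.raises(ValueError, match="1200"):
            tiny_model.encode(np.zeros(800))

    def test_batched_encode_equals_stacked_singles(self, tiny_model):
        rng = np.random.default_rng(2)
        X = rng.random((4, 1200))
        tiny_model.eval()
        batched = tiny_model.encode(X).data
        singles = np.concatenate([tiny_model.encode(x).data for x in X])
        assert np.allclose(batched, singles, atol=1e-10)

    def test_eval_mode_is_deterministic(self, tiny_model):
        x = np.random.default_rng(3).random(1200)
        tiny_model.eval()
        assert np.array_equal(tiny_model.encode(x).data,
                              tiny_model.encode(x).data)

    def test_bottleneck_variant_builds_and_has_expected_feature_dim(self):
        config = ModelConfig(encoder_variant="resnet50_1d", input_length=240)
        assert config.feature_dim == 2048
        model = SiamQualityNet(config, seed=0).eval()
        h = model.encode(np.random.default_rng(0).random((1, 240)))
        assert h.shape == (1, 2048)

    def test_incompatible_feature_dim_rejected(self):
        with pytest.raises(ValueError, match="feature_dim"):
            ModelConfig(encoder_variant="tiny_1d", feature_dim=128)


class TestNegativeCosine:
    def test_identical_directions_give_minus_one(self):
        v = unit([1.0, 2.0, 3.0])
        assert float(negative_cosine(v, 2.5 * v).data) == pytest.approx(-1.0)

    def test_orthogonal_vectors_give_zero(self):
        assert float(negative_cosine([1.0, 0.0], [0.0, 5.0]).data) == pytest.approx(0.0)

    def test_matches_arithmetic_oracle_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            p, z = rng.normal(size=3), rng.normal(size=3)
            expect = -np.dot(p, z) / (np.linalg.norm(p) * np.linalg.norm(z))
            assert float(negative_cosine(p, z).data) == pytest.approx(expect, abs=1e-6)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            negative_cosine([0.0, 0.0], [1.0, 1.0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        p, z = rng.normal(size=8), rng.normal(size=8)
        base = float(negative_cosine(p, z).data)
        assert float(negative_cosine(7.3 * p, z).data) == pytest.approx(base)
        assert float(negative_cosine(p, 0.01 * z).data) == pytest.approx(base)

    def test_no_gradient_flows_into_z(self):
        p = nn.Tensor(np.array([1.0, 2.0]), requires_grad=True)
        z = nn.Tensor(np.array([3.0, 1.0]), requires_grad=True)
        negative_cosine(p, z).backward()
        assert p.grad is not None
        assert z.grad is None


def _outputs(p, z):
    from siamquality.model import SiamOutputs
    return SiamOutputs(h=nn.Tensor(np.zeros(2)), z=nn.Tensor(np.atleast_2d(z)),
                       p=nn.Tensor(np.atleast_2d(p)))


class TestPairLoss:
    def test_perfect_alignment_reaches_minus_two(self):
        a, b = unit([1.0, 1.0, 0.0]), unit([0.0, 1.0, 1.0])
        loss = pair_loss(_outputs(p=a, z=b), _outputs(p=b, z=a))
        assert float(loss.data) == pytest.approx(-2.0)

    def test_mutually_orthogonal_vectors_give_zero(self):
        e = np.eye(4)
        loss = pair_loss(_outputs(p=e[0], z=e[1]), _outputs(p=e[2], z=e[3]))
        assert float(loss.data) == pytest.approx(0.0)

    def test_half_scale_reproduces_averaged_form(self):
        rng = np.random.default_rng(6)
        og = _outputs(p=rng.normal(size=5), z=rng.normal(size=5))
        ob = _outputs(p=rng.normal(size=5), z=rng.normal(size=5))
        full = float(pair_loss(og, ob, scale=1.0).data)
        half = float(pair_loss(og, ob, scale=0.5).data)
        assert half == pytest.approx(full / 2.0)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            og = _outputs(p=rng.normal(size=4), z=rng.normal(size=4))
            ob = _outputs(p=rng.normal(size=4), z=rng.normal(size=4))
            ab = float(pair_loss(og, ob).data)
            ba = float(pair_loss(ob, og).data)
            assert ab == pytest.approx(ba)
            assert -2.0 <= ab <= 2.0

    def test_stop_gradient_contract_on_projections(self):
        rng = np.random.default_rng(8)
        og = _outputs(p=rng.normal(size=4), z=rng.normal(size=4))
        ob = _outputs(p=rng.normal(size=4), z=rng.normal(size=4))
        for o in (og, ob):
            o.p.requires_grad = True
            o.z.requires_grad = True
        pair_loss(og, ob, stop_gradient=True).backward()
        assert og.p.grad is not None and ob.p.grad is not None
        assert og.z.grad is None and ob.z.grad is None
        # ablation switch: gradients reach z when stop-gradient is disabled
        pair_loss(og, ob, stop_gradient=False).backward()
        assert og.z.grad is not None and ob.z.grad is not None


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tiny_model, tmp_path):
        x = np.random.default_rng(9).random((2, 1200))
        tiny_model.eval()
        expect = tiny_model(x)
        save_checkpoint(tiny_model, tmp_path / "ck.npz")
        loaded = load_checkpoint(tmp_path / "ck.npz").eval()
        got = loaded(x)
        assert np.array_equal(got.h.data, expect.h.data)
        assert np.array_equal(got.p.data, expect.p.data)

    def test_config_mismatch_detected(self, tiny_model, tmp_path):
        save_checkpoint(tiny_model, tmp_path / "ck.npz")
        with pytest.raises(ValueError, match="config"):
            load_checkpoint(tmp_path / "ck.npz",
                            expect_config=ModelConfig(projection_dim=16))
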