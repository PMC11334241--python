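"""Pretraining mechanics: curriculum consumption, determinism, diagnostics,
and the fine-tuning freeze contract."""

import numpy as np
import pytest

from siamquality.experiments import make_hr_noise_segments
from siamquality.model import ModelConfig, SiamQualityNet
from siamquality.pairing import find_pairs
from siamquality.train import (FinetuneConfig, PretrainConfig,
                               collapse_diagnostic, embed_segments, finetune,
                               pretrain)


@pytest.fixture(scope="module")
def small_pairs():
    segs = make_hr_noise_segments(seed=9, reps=6)
    return find_pairs(segs), segs


class TestPretrain:
    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            pretrain([], config=PretrainConfig())

    def test_identical_seeds_give_bitwise_identical_traces(self, small_pairs):
        pairs, _ = small_pairs
        cfg = PretrainConfig(epochs=2, batch_size=8, seed=5)
        _, t1 = pretrain(pairs, config=cfg)
        _, t2 = pretrain(pairs, config=cfg)
        assert t1.step_losses == t2.step_losses
        assert t1.epoch_dispersion == t2.epoch_dispersion

    def test_strict_sort_consumes_batches_in_nondecreasing_c(self, small_pairs):
        pairs, _ = small_pairs
        cfg = PretrainConfig(epochs=2, batch_size=4,
                             curriculum_mode="strict_sort", seed=0)
        _, trace = pretrain(pairs, config=cfg)
        per_epoch = len(trace.batch_mean_c) // 2
        for e in range(2):
            cs = trace.batch_mean_c[e * per_epoch:(e + 1) * per_epoch]
            assert all(b >= a - 1e-12 for a, b in zip(cs, cs[1:]))

    def test_loss_stays_within_bounds(self, small_pairs):
        pairs, _ = small_pairs
        _, trace = pretrain(pairs, config=PretrainConfig(epochs=2, seed=3))
        assert all(-2.0 - 1e-9 <= l <= 2.0 + 1e-9 for l in trace.step_losses)

    def test_weight_sharing_single_parameter_store(self, small_pairs):
        """Both branches read the same Tensor objects at every step."""
        pairs, _ = small_pairs
        model, _ = pretrain(pairs[:8], config=PretrainConfig(epochs=1, seed=0))
        og, ob = model.forward_pair(pairs[0].good.samples, pairs[0].bad.samples)
        # same model object serves both branches; parameters are shared by identity
        assert model.parameters() == model.parameters()


class TestCollapseDiagnostic:
    def test_identical_embeddings_score_zero(self):
        emb = np.tile([1.0, 2.0, 3.0], (10, 1))
        assert collapse_diagnostic(emb) == pytest.approx(0.0, abs=1e-12)

    def test_random_unit_vectors_score_near_inverse_sqrt_dim(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(1000, 32))
        expect = 1.0 / np.sqrt(32)
        assert abs(collapse_diagnostic(emb) - expect) <= 0.3 * expect

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            collapse_diagnostic(np.ones((1, 8)))


@pytest.fixture(scope="module")
def hr_data():
    segs = make_hr_noise_segments(seed=21, reps=4)
    X = np.stack([s.samples for s in segs])
    y = np.array([s.meta["hr_bpm"] for s in segs])
    return X, y


class TestFinetune:
    def test_fine_tune_last_freezes_encoder(self, hr_data):
        X, y = hr_data
        model = SiamQualityNet(ModelConfig(), seed=2)
        before = [p.data.copy() for p in model.encoder.parameters()]
        task, _ = finetune(model, X, y, FinetuneConfig(
            strategy="fine_tune_last", epochs=3, seed=2))
        after = [p.data for p in task.encoder_model.encoder.parameters()]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_fine_tune_all_moves_encoder(self, hr_data):
        X, y = hr_data
        model = SiamQualityNet(ModelConfig(), seed=2)
        before = [p.data.copy() for p in model.encoder.parameters()]
        task, _ = finetune(model, X[:32], y[:32], FinetuneConfig(
            strategy="fine_tune_all", epochs=1, seed=2))
        after = [p.data for p in task.encoder_model.encoder.parameters()]
        assert not all(np.array_equal(a, b) for a, b in zip(before, after))
        # and the caller's model is untouched
        assert all(np.array_equal(a, p.data)
                   for a, p in zip(before, model.encoder.parameters()))

    def test_label_task_mismatch_rejected(self, hr_data):
        X, y = hr_data
        model = SiamQualityNet(ModelConfig(), seed=0)
        with pytest.raises(ValueError, match="integer"):
            finetune(model, X[:8], y[:8].astype(float),
                     FinetuneConfig(task_kind="classification", head_dim=2))

    def test_in_domain_strategy_requires_pairs(self, hr_data):
        X, y = hr_data
        model = SiamQualityNet(ModelConfig(), seed=0)
        with pytest.raises(ValueError, match="pairs"):
            finetune(model, X[:8], y[:8], FinetuneConfig(
                strategy="in_domain_pretrain_then_last", epochs=1))

    def test_classification_head_learns_clean_vs_noisy(self):
        """Binary classification smoke test on an easy separable task."""
        segs = make_hr_noise_segments(seed=33, reps=8,
                                      noise_levels=(0.0, 0.7))
        X = np.stack([s.samples for s in segs])
        labels = (np.array([s.meta["noise_level"] for s in segs]) > 0).astype(int)
        model = SiamQualityNet(ModelConfig(), seed=1)
        _, f1_val = finetune(model, X, labels, FinetuneConfig(
            strategy="fine_tune_last", task_kind="classification", head_dim=2,
            epochs=20, seed=1), X_val=X, y_val=labels)
        assert f1_val > 0.8
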