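"""Metric oracles and artifact-tolerance curve correctness."""

import numpy as np
import pytest
from sklearn.metrics import f1_score, mean_absolute_error

from siamquality.evaluate import (ConfusionCounts, at_curve, f1,
                                  latent_diagnostics, mae)


class TestMAE:
    def test_hand_worked_example(self):
        assert mae([70, 80], [72, 77]) == pytest.approx(2.5)

    def test_perfect_predictions(self):
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_symmetry_and_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            a, b = rng.normal(size=n), rng.normal(size=n)
            assert mae(a, b) == pytest.approx(mean_absolute_error(a, b))
            assert mae(a, b) == mae(b, a)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mae([], [])
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])


class TestF1:
    def test_perfect_classifier(self):
        assert f1(ConfusionCounts(tp=5, fp=0, fn=0))[0] == 1.0

    def test_hand_worked_example(self):
        score, precision, recall = f1(ConfusionCounts(tp=2, fp=1, fn=1))
        assert precision == pytest.approx(2 / 3)
        assert recall == pytest.approx(2 / 3)
        assert score == pytest.approx(2 / 3)

    def test_zero_rule(self):
        assert f1(ConfusionCounts(tp=0, fp=3, fn=2))[0] == 0.0

    def test_against_sklearn_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            counts = ConfusionCounts(
                tp=int(np.sum((y_pred == 1) & (y_true == 1))),
                fp=int(np.sum((y_pred == 1) & (y_true == 0))),
                fn=int(np.sum((y_pred == 0) & (y_true == 1))),
                tn=int(np.sum((y_pred == 0) & (y_true == 0))))
            assert f1(counts)[0] == pytest.approx(
                f1_score(y_true, y_pred, zero_division=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0)


def brute_force_at_curve(quality, y_true, y_pred, metric_name, thresholds):
    """Independent filter-and-score loop."""
    sizes, metrics = [], []
    for u in thresholds:
        sel = [i for i, q in enumerate(quality) if q <= u]
        sizes.append(len(sel))
        if not sel:
            metrics.append(np.nan)
        elif metric_name == "MAE":
            metrics.append(np.mean([abs(y_true[i] - y_pred[i]) for i in sel]))
        else:
            yt = np.asarray([y_true[i] for i in sel])
            yp = np.asarray([y_pred[i] for i in sel])
            metrics.append(f1_score(yt, yp, zero_division=0))
    return sizes, metrics


class TestATCurve:
    def test_hand_worked_example(self):
        """Qualities {.1,.5,.9} / errors {1,2,3}: MAE 1 at u=.2, 2 at u=1."""
        curve = at_curve([0.1, 0.5, 0.9], [0.0, 0.0, 0.0], [1.0, 2.0, 3.0],
                         "MAE", thresholds=[0.2, 1.0])
        assert list(curve.subgroup_sizes) == [1, 3]
        assert curve.subgroup_metric[0] == pytest.approx(1.0)
        assert curve.subgroup_metric[1] == pytest.approx(2.0)

    def test_uniform_zero_quality_gives_constant_curve(self):
        curve = at_curve(np.zeros(5), np.arange(5.0), np.arange(5.0) + 1.0)
        assert np.all(curve.subgroup_sizes == 5)
        assert np.allclose(curve.subgroup_metric, 1.0)

    @pytest.mark.parametrize("metric_name", ["MAE", "F1"])
    def test_matches_brute_force_on_random_inputs(self, metric_name):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            q = rng.uniform(size=n)
            if metric_name == "MAE":
                yt, yp = rng.normal(size=n), rng.normal(size=n)
            else:
                yt = rng.integers(0, 2, size=n).astype(float)
                yp = rng.integers(0, 2, size=n).astype(float)
            thresholds = np.sort(rng.uniform(size=int(rng.integers(2, 8))))
            curve = at_curve(q, yt, yp, metric_name, thresholds)
            sizes, metrics = brute_force_at_curve(q, yt, yp, metric_name,
                                                  thresholds)
            assert list(curve.subgroup_sizes) == sizes
            assert np.allclose(curve.subgroup_metric, metrics, equal_nan=True)

    def test_cumulative_invariants(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 50))
            q, yt, yp = rng.uniform(size=n), rng.normal(size=n), rng.normal(size=n)
            curve = at_curve(q, yt, yp)
            assert np.all(np.diff(curve.subgroup_sizes) >= 0)
            assert curve.subgroup_sizes[-1] == n
            assert curve.subgroup_metric[-1] == pytest.approx(mae(yt, yp))

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            at_curve([0.1, 0.2], [1.0], [1.0, 2.0])

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            at_curve([0.1], [1.0], [1.0], thresholds=[0.5, 0.2])


class TestLatentDiagnostics:
    def test_ideal_clustering_gives_unit_gap(self):
        emb = np.vstack([np.tile([1.0, 0.0], (4, 1)),
                         np.tile([0.0, 1.0], (4, 1))])
        labels = [60] * 4 + [90] * 4
        out = latent_diagnostics(emb, labels)
        assert out.gap == pytest.approx(1.0)
        assert out.silhouette > 0.9

    def test_identical_embeddings_give_zero_gap(self):
        emb = np.tile([1.0, 2.0], (6, 1))
        out = latent_diagnostics(emb, [60, 60, 60, 90, 90, 90])
        assert out.gap == pytest.approx(0.0)

    def test_gap_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        emb = rng.normal(size=(12, 5))
        labels = rng.choice([60, 90, 120], size=12)
        while len(np.unique(labels)) < 2:
            labels = rng.choice([60, 90, 120], size=12)
        out = latent_diagnostics(emb, labels)
        unit = emb / np.linalg.norm(emb, axis=1, keepdims=True)
        within, between = [], []
        for i in range(12):
            for j in range(12):
                if i == j:
                    continue
                s = float(unit[i] @ unit[j])
                (within if labels[i] == labels[j] else between).append(s)
        assert out.gap == pytest.approx(np.mean(within) - np.mean(between))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            latent_diagnostics(np.eye(3), [60, 60, 60])
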