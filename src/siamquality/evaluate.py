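"""Task metrics, the artifact-tolerance curve, and latent-space diagnostics.

The artifact-tolerance (AT) curve assesses robustness across signal
quality: for each quality threshold u in an ascending grid, the *cumulative*
subgroup of test samples with artifact fraction <= u is scored with the
task metric (MAE or F1).  The threshold 1.0 subgroup is the whole test
set, so the curve's top point equals the overall metric; threshold 0
scores only the cleanest samples.  Subgroup sizes are reported alongside
the metric so the quality distribution of the test set is visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ATCurve",
    "mae",
    "f1",
    "at_curve",
    "latent_diagnostics",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class ATCurve:
    """Cumulative-subgroup metric curve over quality thresholds."""

    thresholds: np.ndarray
    subgroup_sizes: np.ndarray
    subgroup_metric: np.ndarray       # NaN marks an empty subgroup
    metric_name: str

    def to_records(self) -> list[dict]:
        return [{"threshold": float(u), "n": int(n), self.metric_name:
                 (None if np.isnan(m) else float(m))}
                for u, n, m in zip(self.thresholds, self.subgroup_sizes,
                                   self.subgroup_metric)]


def mae(y_true, y_pred) -> float:
    """Mean absolute error (1/n) sum |y_i - yhat_i|."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.mean(np.abs(y_true - y_pred)))


def f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """F1 = 2PR/(P+R) with P = TP/(TP+FP), R = TP/(TP+FN).

    Returns (f1, precision, recall).  Degenerate zero-rule: with tp = 0,
    F1 (and any undefined precision/recall) is 0.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    if precision + recall == 0.0:
        return 0.0, precision, recall
    return 2 * precision * recall / (precision + recall), precision, recall


def _score(metric_name: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if metric_name == "MAE":
        return mae(y_true, y_pred)
    if metric_name == "F1":
        yt = y_true.astype(int)
        yp = y_pred.astype(int)
        counts = ConfusionCounts(
            tp=int(np.sum((yp == 1) & (yt == 1))),
            fp=int(np.sum((yp == 1) & (yt == 0))),
            fn=int(np.sum((yp == 0) & (yt == 1))),
            tn=int(np.sum((yp == 0) & (yt == 0))))
        return f1(counts)[0]
    raise ValueError(f"unknown metric {metric_name!r}")


def at_curve(per_sample_quality, y_true, y_pred, metric_name: str = "MAE",
             thresholds=DEFAULT_THRESHOLDS) -> ATCurve:
    """Compute the artifact-tolerance curve.

    ``per_sample_quality`` holds each test sample's artifact fraction;
    the subgroup at threshold u is every sample with quality <= u.  Empty
    subgroups get size 0 and a NaN metric.
    """
    q = np.asarray(per_sample_quality, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if not (q.shape == y_true.shape == y_pred.shape):
        raise ValueError("quality, targets and predictions must align")
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size == 0 or np.any(np.diff(thresholds) < 0) \
            or thresholds.min() < 0 or thresholds.max() > 1:
        raise ValueError("thresholds must be ascending within [0, 1]")
    sizes = np.zeros(thresholds.size, dtype=int)
    metrics = np.full(thresholds.size, np.nan)
    for i, u in enumerate(thresholds):
        sel = q <= u
        sizes[i] = int(sel.sum())
        if sizes[i] > 0:
            metrics[i] = _score(metric_name, y_true[sel], y_pred[sel])
    return ATCurve(thresholds=thresholds, subgroup_sizes=sizes,
                   subgroup_metric=metrics, metric_name=metric_name)


@dataclass
class LatentSummary:
    within_group_similarity: float
    between_group_similarity: float
    gap: float
    silhouette: float
    n_groups: int


def latent_diagnostics(embeddings: np.ndarray, hr_labels,
                       noise_levels=None) -> LatentSummary:
    """Quantify clustering of embeddings by physiological state.

    Reports the mean cosine similarity between embeddings sharing a heart
    rate (across noise levels), the mean similarity between different
    heart rates, their gap, and a silhouette score (cosine distance, HR
    as the grouping label).  Requires at least two HR groups.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    hr_labels = np.asarray(hr_labels)
    if embeddings.ndim != 2 or embeddings.shape[0] != hr_labels.shape[0]:
        raise ValueError("embeddings and labels must align")
    groups = np.unique(hr_labels)
    if groups.size < 2:
        raise ValueError("need at least two heart-rate groups")

    norms = np.linalg.norm(embeddings, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = embeddings / norms
    sims = unit @ unit.T
    same = hr_labels[:, None] == hr_labels[None, :]
    off_diag = ~np.eye(len(unit), dtype=bool)
    within_sel = same & off_diag
    if noise_levels is not None:
        # the robustness claim is about *across-noise* neighbours: restrict
        # within-group pairs to members with different noise levels
        noise = np.asarray(noise_levels)
        diff_noise = noise[:, None] != noise[None, :]
        if not (within_sel & diff_noise).any():
            raise ValueError("no across-noise pairs within any group")
        within_sel &= diff_noise
    within = float(sims[within_sel].mean())
    between = float(sims[~same].mean())

    from sklearn.metrics import silhouette_score
    sil = float(silhouette_score(unit, hr_labels, metric="cosine"))
    return LatentSummary(within_group_similarity=within,
                         between_group_similarity=between,
                         gap=within - between, silhouette=sil,
                         n_groups=int(groups.size))
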