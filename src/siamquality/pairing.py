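"""Temporal-quality pairing and curriculum ordering.

The pairing rule: every *anchor* segment (artifact fraction ``y`` at or
below the anchor threshold, 0 by default) is paired with the same
patient's low-quality segment (``y > 0.2``) inside a 5-minute window that
lies at the greatest temporal distance from the anchor.  Each pair
carries a curriculum difficulty ``c = |y_bad - y_good|``; training
consumes pairs in ascending ``c``, either by a strict stable sort or in
equal-width difficulty buckets shuffled internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import LabeledSegment

__all__ = [
    "PairingConfig",
    "QualityPair",
    "find_pairs",
    "curriculum_measure",
    "curriculum_order",
]


@dataclass(frozen=True)
class PairingConfig:
    """Thresholds for the pair search.

    ``window_seconds`` is the half-width of the two-sided temporal search
    window (5 minutes); candidates must have ``y > low_quality_threshold``
    and anchors ``y <= anchor_threshold``.  ``selection`` picks the
    candidate rule: ``"max_abs_dt"`` (greatest temporal distance, the
    default) or ``"max_index"`` (latest candidate timestamp).
    """

    window_seconds: float = 300.0
    low_quality_threshold: float = 0.2
    anchor_threshold: float = 0.0
    selection: str = "max_abs_dt"

    def __post_init__(self):
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        for name in ("low_quality_threshold", "anchor_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.selection not in ("max_abs_dt", "max_index"):
            raise ValueError(f"unknown selection rule {self.selection!r}")


@dataclass(eq=False)
class QualityPair:
    """One (high-quality anchor, low-quality neighbour) training pair."""

    good: LabeledSegment
    bad: LabeledSegment
    c: float

    def __post_init__(self):
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c={self.c} outside [0, 1]")


def curriculum_measure(y1: float, y2: float) -> float:
    """Curriculum difficulty C(x1, x2) = |y1 - y2|, symmetric, in [0, 1]."""
    if not (0.0 <= y1 <= 1.0 and 0.0 <= y2 <= 1.0):
        raise ValueError("artifact fractions must lie in [0, 1]")
    return abs(y1 - y2)


def find_pairs(segments: list[LabeledSegment],
               config: PairingConfig | None = None) -> list[QualityPair]:
    """Pair every anchor with its most temporally distant low-quality neighbour.

    The search is restricted to segments of the same patient.  Ties in
    temporal distance are broken by the later timestamp, then the higher
    ``y``.  Anchors without any candidate yield no pair; a low-quality
    segment may serve several anchors.
    """
    config = config or PairingConfig()
    for s in segments:
        if s.t is None or s.y is None:
            raise ValueError(f"segment {s.segment_id} missing t or y")

    by_patient: dict[str, list[LabeledSegment]] = {}
    for s in segments:
        by_patient.setdefault(s.patient_id, []).append(s)

    pairs: list[QualityPair] = []
    for plist in by_patient.values():
        anchors = [s for s in plist if s.y <= config.anchor_threshold]
        lows = [s for s in plist if s.y > config.low_quality_threshold]
        for a in anchors:
            cands = [s for s in lows
                     if s is not a and abs(s.t - a.t) < config.window_seconds]
            if not cands:
                continue
            if config.selection == "max_abs_dt":
                best = max(cands, key=lambda s: (abs(s.t - a.t), s.t, s.y))
            else:  # literal "max index": latest candidate timestamp
                best = max(cands, key=lambda s: (s.t, s.y))
            pairs.append(QualityPair(good=a, bad=best,
                                     c=curriculum_measure(a.y, best.y)))
    return pairs


def curriculum_order(pairs: list[QualityPair], mode: str = "staged_buckets",
                     n_buckets: int = 5, seed: int = 0) -> list[QualityPair]:
    """Order pairs for curriculum training, easiest (smallest c) first.

    ``strict_sort`` performs a stable ascending sort on ``c``.
    ``staged_buckets`` partitions [0, 1] into ``n_buckets`` equal-width
    difficulty bins, consumes bins in ascending order, and shuffles within
    each bin with ``seed`` — preserving the curriculum trend while keeping
    stochasticity inside each stage.  ``shuffled_control`` is a plain
    seeded shuffle (no curriculum), for ablation.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    if mode == "strict_sort":
        return sorted(pairs, key=lambda p: p.c)
    if mode == "shuffled_control":
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(pairs))
        return [pairs[i] for i in order]
    if mode != "staged_buckets":
        raise ValueError(f"unknown curriculum mode {mode!r}")
    if n_buckets < 1:
        raise ValueError("n_buckets must be >= 1")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, 1.0, n_buckets + 1)
    out: list[QualityPair] = []
    for b in range(n_buckets):
        lo, hi = edges[b], edges[b + 1]
        bucket = [p for p in pairs
                  if (lo <= p.c < hi) or (b == n_buckets - 1 and p.c == hi)]
        order = rng.permutation(len(bucket))
        out.extend(bucket[i] for i in order)
    return out
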