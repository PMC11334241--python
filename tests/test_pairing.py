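"""Pair search against a brute-force oracle, plus curriculum ordering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_segments
from siamquality.pairing import (PairingConfig, QualityPair, curriculum_measure,
                                 curriculum_order, find_pairs)
from siamquality.preprocess import LabeledSegment


def brute_force_pairs(segments, config):
    """Independent enumeration of every (anchor, candidate) combination."""
    out = []
    for a in segments:
        if a.y > config.anchor_threshold:
            continue
        best = None
        for s in segments:
            if s is a or s.patient_id != a.patient_id:
                continue
            if s.y <= config.low_quality_threshold:
                continue
            if abs(s.t - a.t) >= config.window_seconds:
                continue
            key = (abs(s.t - a.t), s.t, s.y)
            if best is None or key > best[0]:
                best = (key, s)
        if best is not None:
            out.append((a.segment_id, best[1].segment_id,
                        abs(a.y - best[1].y)))
    return sorted(out)


def seg(sid, pid, t, y):
    return LabeledSegment(samples=np.zeros(4), y=y, t=t, patient_id=pid,
                          segment_id=sid)


class TestFindPairs:
    def test_worked_example_picks_most_distant_candidate(self):
        segs = [seg("a", "p", 0.0, 0.0), seg("b", "p", 60.0, 0.1),
                seg("c", "p", 120.0, 0.3), seg("d", "p", 280.0, 0.5)]
        pairs = find_pairs(segs)
        assert len(pairs) == 1
        assert pairs[0].bad.segment_id == "d"
        assert pairs[0].c == pytest.approx(0.5)

    def test_anchor_without_candidates_yields_nothing(self):
        segs = [seg("a", "p", 0.0, 0.0), seg("b", "p", 60.0, 0.15)]
        assert find_pairs(segs) == []

    def test_window_is_strict_and_two_sided(self):
        segs = [seg("a", "p", 300.0, 0.0), seg("b", "p", 0.0, 0.9),
                seg("c", "p", 600.0, 0.9), seg("d", "p", 1.0, 0.5)]
        pairs = find_pairs(segs)
        # b and c sit exactly 300 s away (excluded); d at 299 s wins
        assert len(pairs) == 1 and pairs[0].bad.segment_id == "d"

    def test_pairs_stay_within_patient(self):
        segs = [seg("a", "p1", 0.0, 0.0), seg("b", "p2", 10.0, 0.9)]
        assert find_pairs(segs) == []

    def test_max_index_option_matches_literal_rule(self):
        segs = [seg("a", "p", 100.0, 0.0), seg("b", "p", 0.0, 0.9),
                seg("c", "p", 150.0, 0.3)]
        prose = find_pairs(segs)   # |dt|: b at 100 beats c at 50
        literal = find_pairs(segs, PairingConfig(selection="max_index"))
        assert prose[0].bad.segment_id == "b"
        assert literal[0].bad.segment_id == "c"   # latest timestamp

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force_oracle_on_random_toys(self, trial):
        rng = np.random.default_rng(1000 + trial)
        segs = random_segments(rng, int(rng.integers(2, 51)))
        config = PairingConfig()
        got = sorted((p.good.segment_id, p.bad.segment_id, p.c)
                     for p in find_pairs(segs, config))
        assert got == brute_force_pairs(segs, config)

    def test_emitted_pairs_satisfy_all_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            segs = random_segments(rng, 40)
            for p in find_pairs(segs):
                assert p.good.patient_id == p.bad.patient_id
                assert abs(p.bad.t - p.good.t) < 300.0
                assert p.good.y <= 0.0
                assert p.bad.y > 0.2
                assert p.c == pytest.approx(abs(p.bad.y - p.good.y))

    def test_pair_count_bounded_by_anchor_count(self):
        rng = np.random.default_rng(8)
        segs = random_segments(rng, 50)
        anchors = sum(1 for s in segs if s.y <= 0.0)
        assert len(find_pairs(segs)) <= anchors
        clean_only = [s for s in segs if s.y <= 0.2]
        assert find_pairs(clean_only) == []


class TestCurriculumMeasure:
    def test_examples(self):
        assert curriculum_measure(0.0, 0.5) == 0.5
        assert curriculum_measure(0.3, 0.3) == 0.0

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_symmetry_and_range(self, a, b):
        assert curriculum_measure(a, b) == curriculum_measure(b, a)
        assert 0.0 <= curriculum_measure(a, b) <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            curriculum_measure(-0.1, 0.5)


def _toy_pairs(c_values):
    return [QualityPair(good=seg(f"g{i}", "p", 0.0, 0.0),
                        bad=seg(f"b{i}", "p", 10.0, 0.5), c=c)
            for i, c in enumerate(c_values)]


class TestCurriculumOrder:
    def test_strict_sort_orders_ascending_and_is_stable(self):
        pairs = _toy_pairs([0.4, 0.1, 0.9])
        assert [p.c for p in curriculum_order(pairs, "strict_sort")] == [0.1, 0.4, 0.9]
        sorted_in = _toy_pairs([0.1, 0.4, 0.9])
        assert curriculum_order(sorted_in, "strict_sort") == sorted_in

    @pytest.mark.parametrize("trial", range(100))
    def test_bucket_separation_and_reproducibility(self, trial):
        rng = np.random.default_rng(2000 + trial)
        pairs = _toy_pairs(rng.uniform(0, 1, size=int(rng.integers(5, 40))))
        out1 = curriculum_order(pairs, "staged_buckets", n_buckets=5, seed=trial)
        out2 = curriculum_order(pairs, "staged_buckets", n_buckets=5, seed=trial)
        assert out1 == out2
        assert sorted(id(p) for p in out1) == sorted(id(p) for p in pairs)
        # non-adjacent bucket separation: every pair two buckets apart is ordered
        buckets = [min(int(p.c * 5), 4) for p in out1]
        for i, bi in enumerate(buckets):
            for j, bj in enumerate(buckets):
                if bj >= bi + 2:
                    assert out1[i].c < out1[j].c

    def test_bucket_means_non_decreasing(self):
        rng = np.random.default_rng(3)
        pairs = _toy_pairs(rng.uniform(0, 1, size=50))
        out = curriculum_order(pairs, "staged_buckets", n_buckets=5, seed=0)
        buckets = {}
        for p in out:
            buckets.setdefault(min(int(p.c * 5), 4), []).append(p.c)
        means = [np.mean(buckets[k]) for k in sorted(buckets)]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            curriculum_order([], "strict_sort")
        with pytest.raises(ValueError):
            curriculum_order(_toy_pairs([0.5]), "staged_buckets", n_buckets=0)
        with pytest.raises(ValueError):
            curriculum_order(_toy_pairs([0.5]), "nonsense")
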