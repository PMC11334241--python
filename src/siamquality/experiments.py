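"""Desk-scale experiments exercising the full method on synthetic PPG.

These are scaled-down counterparts of the evaluations a practitioner
would run on real data: a latent-robustness experiment
(does pretraining cluster same-heart-rate segments across noise levels?)
and a heart-rate regression task comparing fine-tuning strategies.  Both
are deterministic given their seed and small enough for minutes-scale
CPU runs; the test suite and the acceptance script call them directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelConfig, SiamQualityNet
from .pairing import find_pairs
from .preprocess import LabeledSegment, minmax_normalize
from .simulate import NoiseSpec, inject_noise, simulate_clean_ppg
from .train import (FinetuneConfig, PretrainConfig, TrainingTrace,
                    embed_segments, finetune, pretrain)

__all__ = [
    "make_hr_noise_segments",
    "clean_noisy_gap",
    "RobustnessResult",
    "representation_robustness",
    "make_hr_task_corpus",
    "FinetuneComparison",
    "finetune_strategy_comparison",
]

SEGMENT_SECONDS = 30.0
FS = 40.0


def make_hr_noise_segments(seed: int, heart_rates=(60.0, 90.0, 120.0),
                           noise_levels=(0.0, 0.3, 0.7), reps: int = 40,
                           motion_window_fraction: float = 0.5
                           ) -> list[LabeledSegment]:
    """Segments on a (heart rate x motion-noise level) grid.

    One synthetic patient per heart rate; clean and noisy segments
    alternate in time so every clean segment has in-window low-quality
    neighbours.  Each segment's metadata records its heart rate and noise
    level; ``y`` is the ground-truth artifact fraction (roughly
    ``motion_window_fraction x level``).
    """
    segs: list[LabeledSegment] = []
    for pi, hr in enumerate(heart_rates):
        pid = f"hr{int(hr)}"
        t, k = 0.0, 0
        for _ in range(reps):
            for lvl in noise_levels:
                s0 = seed * 100_000 + pi * 1000 + k
                clean = simulate_clean_ppg(hr, SEGMENT_SECONDS, FS, seed=s0)
                if lvl > 0:
                    rec = inject_noise(clean, FS, NoiseSpec(
                        motion_level=lvl,
                        motion_window_fraction=motion_window_fraction),
                        seed=s0)
                    x, y = rec.samples, float(rec.artifact_mask.mean())
                else:
                    x, y = clean, 0.0
                segs.append(LabeledSegment(
                    samples=minmax_normalize(x), y=y, t=t, patient_id=pid,
                    segment_id=f"{pid}-s{k:04d}",
                    meta={"hr_bpm": hr, "noise_level": lvl}))
                t += SEGMENT_SECONDS
                k += 1
    return segs


def clean_noisy_gap(embeddings: np.ndarray, hr_labels: np.ndarray,
                    noise_levels: np.ndarray) -> tuple[float, float, float]:
    """Within-HR vs between-HR mean cosine similarity over clean/noisy pairs.

    Both statistics are computed over the same pair composition — one
    clean member, one noisy member — so they differ only in whether the
    heart rates match.  Returns (within, between, gap).
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = emb / norms
    sims = unit @ unit.T
    hr = np.asarray(hr_labels)
    nz = np.asarray(noise_levels)
    same = hr[:, None] == hr[None, :]
    cross = (nz[:, None] == 0) ^ (nz[None, :] == 0)   # exactly one clean
    off = ~np.eye(len(hr), dtype=bool)
    within = float(sims[same & cross & off].mean())
    between = float(sims[~same & cross].mean())
    return within, between, within - between


@dataclass
class RobustnessResult:
    trained_within: float
    trained_between: float
    trained_gap: float
    untrained_gap: float
    final_dispersion: float
    trace: TrainingTrace
    n_pairs: int


def representation_robustness(seed: int, reps: int = 40, epochs: int = 5
                              ) -> RobustnessResult:
    """Pretrain on quality pairs and measure latent heart-rate clustering.

    The central robustness claim at desk scale: after pretraining, the
    encoder representation of a clean segment should be closer to noisy
    segments of the *same* heart rate than to clean/noisy segments of
    different heart rates — and more so than for an untrained encoder
    with the same initialization seed.
    """
    segs = make_hr_noise_segments(seed, reps=reps)
    pairs = find_pairs(segs)
    model, trace = pretrain(
        pairs, config=PretrainConfig(epochs=epochs, seed=seed))
    X = np.stack([s.samples for s in segs])
    hr = np.array([s.meta["hr_bpm"] for s in segs])
    nz = np.array([s.meta["noise_level"] for s in segs])
    w, b, gap = clean_noisy_gap(embed_segments(model, X), hr, nz)
    untrained = SiamQualityNet(ModelConfig(), seed=seed)
    _, _, gap0 = clean_noisy_gap(embed_segments(untrained, X), hr, nz)
    return RobustnessResult(trained_within=w, trained_between=b,
                            trained_gap=gap, untrained_gap=gap0,
                            final_dispersion=trace.epoch_dispersion[-1],
                            trace=trace, n_pairs=len(pairs))


def make_hr_task_corpus(seed: int, n_patients: int = 20,
                        segments_per_patient: int = 10,
                        hr_range=(55.0, 115.0), noisy_fraction: float = 0.5,
                        clean_only: bool = False) -> list[LabeledSegment]:
    """Patient-structured corpus for heart-rate regression.

    Each patient has a fixed heart rate (the regression target, stored in
    segment metadata) and an alternating clean/noisy segment sequence, so
    the same corpus supports quality pairing and supervised fine-tuning.
    """
    rng = np.random.default_rng(seed)
    segs: list[LabeledSegment] = []
    for p in range(n_patients):
        hr = float(rng.uniform(*hr_range))
        pid = f"t{seed}-p{p:03d}"
        t = 0.0
        for k in range(segments_per_patient):
            s0 = int(rng.integers(2 ** 31))
            clean = simulate_clean_ppg(hr, SEGMENT_SECONDS, FS, seed=s0)
            noisy = (not clean_only) and k % 2 == 1 \
                and rng.uniform() < 2 * noisy_fraction
            if noisy:
                lvl = float(rng.uniform(0.5, 0.9))
                rec = inject_noise(clean, FS, NoiseSpec(
                    motion_level=lvl, motion_window_fraction=0.5), seed=s0)
                x, y = rec.samples, float(rec.artifact_mask.mean())
            else:
                x, y = clean, 0.0
            segs.append(LabeledSegment(
                samples=minmax_normalize(x), y=y, t=t, patient_id=pid,
                segment_id=f"{pid}-s{k:03d}", meta={"hr_bpm": hr}))
            t += SEGMENT_SECONDS
    return segs


@dataclass
class FinetuneComparison:
    mae_all: float
    mae_last: float
    encoder_unchanged_last: bool
    n_train: int
    n_test: int


def finetune_strategy_comparison(seed: int, pretrain_epochs: int = 3,
                                 finetune_epochs: int = 20
                                 ) -> FinetuneComparison:
    """Compare fine-tune-all vs fine-tune-last on held-out clean segments.

    Both strategies start from the same quality-pair-pretrained encoder
    and the same seed; the test set contains clean segments from unseen
    patients.  Also verifies the freeze contract: fine-tune-last leaves
    every encoder parameter bit-identical.
    """
    train_segs = make_hr_task_corpus(seed)
    test_segs = make_hr_task_corpus(seed + 500, n_patients=8,
                                    segments_per_patient=8, clean_only=True)
    pairs = find_pairs(train_segs)
    model, _ = pretrain(pairs, config=PretrainConfig(
        epochs=pretrain_epochs, seed=seed))

    Xtr = np.stack([s.samples for s in train_segs])
    ytr = np.array([s.meta["hr_bpm"] for s in train_segs])
    Xte = np.stack([s.samples for s in test_segs])
    yte = np.array([s.meta["hr_bpm"] for s in test_segs])

    results = {}
    enc_ok = True
    for strategy in ("fine_tune_all", "fine_tune_last"):
        before = [p.data.copy() for p in model.encoder.parameters()]
        fc = FinetuneConfig(strategy=strategy, epochs=finetune_epochs,
                            seed=seed)
        _, mae_val = finetune(model, Xtr, ytr, fc, X_val=Xte, y_val=yte)
        after = [p.data for p in model.encoder.parameters()]
        unchanged = all(np.array_equal(a, b) for a, b in zip(before, after))
        if not unchanged:   # the caller's model must never be mutated
            enc_ok = False
        results[strategy] = mae_val
    return FinetuneComparison(mae_all=results["fine_tune_all"],
                              mae_last=results["fine_tune_last"],
                              encoder_unchanged_last=enc_ok,
                              n_train=len(train_segs), n_test=len(test_segs))
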