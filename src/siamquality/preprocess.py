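"""Segmentation, downsampling and normalization of continuous recordings.

The preprocessing contract: a continuous recording is cut into
non-overlapping fixed-length windows (30 s by default, trailing remainder
dropped), each window is downsampled to the target rate (40 Hz by
default, anti-alias filtered first) and min-max normalized to [0, 1].
The ground-truth artifact fraction ``y`` of a window is the flagged
fraction of the recording's artifact mask over that window, computed at
the original sampling rate before any resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import RecordingWithTruth

__all__ = [
    "RawSegment",
    "LabeledSegment",
    "segment_recording",
    "downsample",
    "minmax_normalize",
    "label_segments",
    "preprocess_recording",
]

SEGMENT_SECONDS = 30.0
TARGET_FS = 40.0


@dataclass(eq=False)
class RawSegment:
    """An unprocessed window cut from a recording."""

    samples: np.ndarray
    mask: np.ndarray | None
    fs: float
    t: float                 # window start, seconds from recording start
    patient_id: str
    index: int


@dataclass(eq=False)
class LabeledSegment:
    """A normalized fixed-length window with its artifact fraction.

    Attributes
    ----------
    samples : normalized waveform, min 0 / max 1 for non-constant input.
    y : artifact fraction in [0, 1] (0 = clean).
    t : collection time, seconds from recording start.
    patient_id, segment_id : identifiers.
    """

    samples: np.ndarray
    y: float
    t: float
    patient_id: str
    segment_id: str
    fs: float = TARGET_FS
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.y <= 1.0:
            raise ValueError(f"y={self.y} outside [0, 1]")


def segment_recording(rec: RecordingWithTruth,
                      segment_seconds: float = SEGMENT_SECONDS) -> list[RawSegment]:
    """Cut a recording into consecutive non-overlapping windows.

    A trailing remainder shorter than ``segment_seconds`` is dropped.  A
    recording shorter than one window yields an empty list.
    """
    if segment_seconds <= 0:
        raise ValueError("segment_seconds must be positive")
    win = int(round(segment_seconds * rec.fs))
    n_seg = rec.samples.size // win
    out = []
    for k in range(n_seg):
        sl = slice(k * win, (k + 1) * win)
        out.append(RawSegment(
            samples=rec.samples[sl].copy(),
            mask=None if rec.artifact_mask is None else rec.artifact_mask[sl].copy(),
            fs=rec.fs,
            t=rec.start_time + k * segment_seconds,
            patient_id=rec.patient_id,
            index=k))
    return out


def downsample(samples: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias filter then decimate to ``fs_out``.

    For integer decimation factors a zero-phase Butterworth low-pass with
    cutoff 0.45 x fs_out is applied before taking every ``fs_in/fs_out``-th
    sample; non-integer ratios go through polyphase resampling.  Output
    length is ``round(len(samples) * fs_out / fs_in)``.
    """
    if fs_out > fs_in or fs_out <= 0:
        raise ValueError(f"need fs_in >= fs_out > 0, got {fs_in}, {fs_out}")
    samples = np.asarray(samples, dtype=np.float64)
    if fs_in == fs_out:
        return samples.copy()
    factor = fs_in / fs_out
    if abs(factor - round(factor)) < 1e-9:
        factor = int(round(factor))
        sos = sps.butter(8, 0.45 * fs_out / (fs_in / 2.0), output="sos")
        filtered = sps.sosfiltfilt(sos, samples)
        return filtered[::factor].copy()
    # non-integer ratio: rational polyphase resampling
    from fractions import Fraction
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(samples, frac.numerator, frac.denominator)


def minmax_normalize(samples: np.ndarray) -> np.ndarray:
    """Map to [0, 1] via (x - min)/(max - min); constant input maps to zeros."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("cannot normalize an empty sequence")
    lo, hi = samples.min(), samples.max()
    if hi == lo:
        return np.zeros_like(samples)
    return (samples - lo) / (hi - lo)


def label_segments(segments: list[RawSegment],
                   rec: RecordingWithTruth | None = None,
                   labels: dict[int, float] | None = None,
                   target_fs: float = TARGET_FS) -> list[LabeledSegment]:
    """Downsample, normalize and attach artifact fractions to raw segments.

    ``y`` comes from the segment's own slice of the ground-truth mask, or
    from an external ``labels`` mapping (segment index -> y).  Missing
    labels raise an error naming the affected segments.
    """
    out = []
    missing = []
    for seg in segments:
        if labels is not None and seg.index in labels:
            y = float(labels[seg.index])
        elif seg.mask is not None:
            y = float(np.mean(seg.mask))
        else:
            missing.append(seg.index)
            continue
        x = downsample(seg.samples, seg.fs, target_fs)
        x = minmax_normalize(x)
        out.append(LabeledSegment(
            samples=x, y=y, t=seg.t, patient_id=seg.patient_id,
            segment_id=f"{seg.patient_id}-s{seg.index:05d}", fs=target_fs,
            meta={} if rec is None else dict(rec.meta)))
    if missing:
        raise ValueError(f"no artifact labels for segments {missing}")
    return out


def preprocess_recording(rec: RecordingWithTruth,
                         segment_seconds: float = SEGMENT_SECONDS,
                         target_fs: float = TARGET_FS) -> list[LabeledSegment]:
    """Full pipeline for one recording: segment, downsample, normalize, label."""
    return label_segments(segment_recording(rec, segment_seconds), rec=rec,
                          target_fs=target_fs)
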