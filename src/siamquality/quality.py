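"""Heuristic stand-in signal-quality assessment.

Real deployments of quality-paired pretraining rely on learned PPG
quality models (a binary high/low classifier plus an artifact
segmentation network).  Those models are not reproducible here, so this
module provides a documented rule-based stand-in that (a) estimates a
per-sample artifact mask and hence an artifact percentage, and (b) turns
it into a binary high/low label.  Pairing and training default to
simulator ground truth; this module is exercised separately and only
needs to *rank* segments by corruption correctly, not match any learned
model's accuracy.

Three rules are evaluated over sliding windows and OR-ed together:

1. **flatline** — windowed standard deviation below a threshold relative
   to the segment's range (sensor dropout, clipping plateaus);
2. **amplitude excursion** — windowed peak-to-peak above a multiple of
   the *median* window peak-to-peak (motion bursts).  The median-relative
   form is used because on a clean quasi-periodic segment every window
   spans nearly the full segment range, so a fraction-of-segment-range
   rule cannot separate bursts from beats;
3. **spectral implausibility** — dominant non-DC frequency of a window
   outside the plausible heart-rate band 0.5-3.7 Hz (30-222 beats/min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QualityParams", "QualityAssessment", "estimate_artifact_mask", "assess"]


@dataclass(frozen=True)
class QualityParams:
    """Thresholds for the rule-based artifact detector."""

    window_seconds: float = 2.0
    hop_seconds: float = 0.5
    flatline_rel_std: float = 0.01      # windowed std / segment ptp
    excursion_ratio: float = 2.0        # window ptp / median window ptp
    hr_band_hz: tuple[float, float] = (0.5, 3.7)
    anchor_threshold: float = 0.0       # y_estimate <= this -> "high" quality


@dataclass
class QualityAssessment:
    binary_label: str                   # "high" | "low"
    mask_estimate: np.ndarray
    y_estimate: float


def estimate_artifact_mask(segment: np.ndarray, fs: float,
                           params: QualityParams | None = None) -> np.ndarray:
    """Per-sample boolean artifact estimate for one segment.

    The segment must be at least two window lengths long (>= 2 s x fs by
    default).  Flags from overlapping windows are OR-ed at sample
    resolution.
    """
    params = params or QualityParams()
    segment = np.asarray(segment, dtype=np.float64)
    win = int(round(params.window_seconds * fs))
    if segment.size < 2 * win:
        raise ValueError(
            f"segment too short: {segment.size} samples < {2 * win}")
    hop = max(1, int(round(params.hop_seconds * fs)))
    seg_ptp = float(np.ptp(segment))
    if seg_ptp == 0.0:
        return np.ones(segment.size, dtype=bool)   # constant segment: all flatline

    starts = list(range(0, segment.size - win + 1, hop))
    if starts[-1] != segment.size - win:
        starts.append(segment.size - win)
    windows = np.stack([segment[s:s + win] for s in starts])
    stds = windows.std(axis=1)
    ptps = np.ptp(windows, axis=1)
    med_ptp = float(np.median(ptps))

    flat = stds < params.flatline_rel_std * seg_ptp
    excur = ptps > params.excursion_ratio * max(med_ptp, 1e-12)

    # dominant non-DC frequency per window
    spec = np.abs(np.fft.rfft(windows - windows.mean(axis=1, keepdims=True),
                              axis=1))
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    spec[:, 0] = 0.0
    dom = freqs[spec.argmax(axis=1)]
    lo, hi = params.hr_band_hz
    implausible = (dom < lo) | (dom > hi)

    flagged = flat | excur | implausible
    mask = np.zeros(segment.size, dtype=bool)
    for s, f in zip(starts, flagged):
        if f:
            mask[s:s + win] = True
    return mask


def assess(segment: np.ndarray, fs: float,
           params: QualityParams | None = None) -> QualityAssessment:
    """Full assessment: mask estimate, artifact percentage, binary label."""
    params = params or QualityParams()
    mask = estimate_artifact_mask(segment, fs, params)
    y = float(np.mean(mask))
    label = "high" if y <= params.anchor_threshold else "low"
    return QualityAssessment(binary_label=label, mask_estimate=mask, y_estimate=y)
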