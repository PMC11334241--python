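"""Synthetic PPG generation with labelled artifacts.

A photoplethysmogram is modelled as a train of double-bump pulses (a
systolic peak followed by a smaller diastolic/dicrotic bump, each a
Gaussian in time), one pulse per cardiac cycle.  Three noise families can
be injected on top of a clean waveform:

* **drift** — slow baseline wander in the 0.05-0.5 Hz band, a global
  confounder;
* **powerline** — a mains-frequency sinusoid (50 or 60 Hz), also global;
* **motion** — localized high-amplitude bursts emulating motion artifacts.

Only motion bursts count as *artifacts*: the per-sample boolean
``artifact_mask`` marks exactly the burst samples, and the ground-truth
artifact fraction ``y`` of any window is the flagged fraction of that
window.  Drift and powerline distort the signal everywhere and are
recorded in metadata, not in the mask — an artifact fraction only makes
sense for corruption that is localizable within a window.

Noise levels are dimensionless in [0, 1] and scale each component's
amplitude linearly relative to the clean signal's peak-to-peak range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

__all__ = [
    "BeatTemplateParams",
    "NoiseSpec",
    "ArtifactSchedule",
    "RecordingWithTruth",
    "simulate_clean_ppg",
    "inject_noise",
    "make_corpus",
]


@dataclass(frozen=True)
class BeatTemplateParams:
    """Shape of a single PPG pulse: two Gaussians per beat.

    Times are seconds after the beat onset; amplitudes are arbitrary units.
    """

    systolic_amplitude: float = 1.0
    systolic_width: float = 0.08
    systolic_offset: float = 0.15
    diastolic_amplitude: float = 0.45
    diastolic_offset: float = 0.42
    diastolic_width: float = 0.12

    def __post_init__(self):
        if min(self.systolic_width, self.diastolic_width) <= 0:
            raise ValueError("template widths must be positive")
        if self.diastolic_offset <= 0 or self.diastolic_offset >= 60.0 / 30.0:
            raise ValueError(
                "diastolic_offset must lie in (0, beat period at 30 bpm)")
        if min(self.systolic_amplitude, self.diastolic_amplitude) <= 0:
            raise ValueError("template amplitudes must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels for one injection pass; levels are fractions in [0, 1]."""

    drift_level: float = 0.0
    motion_level: float = 0.0
    powerline_level: float = 0.0
    mains_hz: float = 60.0
    motion_window_fraction: float = 0.5

    def __post_init__(self):
        for name in ("drift_level", "motion_level", "powerline_level",
                     "motion_window_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ArtifactSchedule:
    """Block-level artifact plan used by :func:`make_corpus`.

    Each 30 s block of a recording is independently selected as an artifact
    block with probability ``p_segment``; selected blocks receive motion
    bursts at a level drawn uniformly from ``level_range`` covering
    ``window_fraction`` x level of the block.  ``drift_level`` and
    ``powerline_level`` apply globally to the whole recording.
    """

    p_segment: float = 0.4
    level_range: tuple[float, float] = (0.3, 0.8)
    window_fraction: float = 1.0
    drift_level: float = 0.1
    powerline_level: float = 0.0
    block_seconds: float = 30.0

    def __post_init__(self):
        if not 0.0 <= self.p_segment <= 1.0:
            raise ValueError("p_segment outside [0, 1]")
        lo, hi = self.level_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("level_range must satisfy 0 <= lo <= hi <= 1")


@dataclass(eq=False)
class RecordingWithTruth:
    """A continuous recording plus the per-sample artifact ground truth."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    artifact_mask: np.ndarray = None
    patient_id: str = "p000"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.samples.shape, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != self.samples.shape:
            raise ValueError("artifact_mask length must match samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def simulate_clean_ppg(hr_bpm: float, duration_s: float, fs: float,
                       template: BeatTemplateParams | None = None,
                       hr_jitter: float = 0.02,
                       seed: int = 0) -> np.ndarray:
    """Simulate an artifact-free PPG waveform.

    Parameters
    ----------
    hr_bpm : heart rate in beats/min, within [30, 220].
    duration_s, fs : recording length (s) and sampling rate (Hz, >= 20).
    template : pulse-shape parameters; default is a generic adult pulse.
    hr_jitter : fractional standard deviation of beat-to-beat interval
        variability (0 gives an exactly periodic waveform).
    seed : RNG seed for the jitter sequence.

    Returns
    -------
    ndarray of ``round(duration_s * fs)`` samples.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if fs < 20:
        raise ValueError("fs must be at least 20 Hz")
    if not 30 <= hr_bpm <= 220:
        raise ValueError("hr_bpm must lie in [30, 220]")
    if hr_jitter < 0:
        raise ValueError("hr_jitter must be non-negative")
    template = template or BeatTemplateParams()

    rng = np.random.default_rng(seed)
    period = 60.0 / hr_bpm
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # beat onsets: start one period early so edge beats contribute their tails
    onsets = []
    t_beat = -period
    while t_beat < duration_s + period:
        onsets.append(t_beat)
        iv = period
        if hr_jitter > 0:
            iv = period * (1.0 + hr_jitter * float(rng.standard_normal()))
            iv = max(iv, 0.3 * period)
        t_beat += iv
    onsets = np.asarray(onsets)

    # each beat only contributes within +/- 6 sigma of its two bumps
    lead = template.systolic_offset - 6.0 * template.systolic_width
    trail = template.diastolic_offset + 6.0 * template.diastolic_width
    out = np.zeros(n)
    for onset in onsets:
        i0 = max(0, int(np.ceil((onset + lead) * fs)))
        i1 = min(n, int(np.floor((onset + trail) * fs)) + 1)
        if i1 <= i0:
            continue
        dt = t[i0:i1] - onset
        out[i0:i1] += (template.systolic_amplitude
                       * np.exp(-0.5 * ((dt - template.systolic_offset)
                                        / template.systolic_width) ** 2)
                       + template.diastolic_amplitude
                       * np.exp(-0.5 * ((dt - template.diastolic_offset)
                                        / template.diastolic_width) ** 2))
    return out


def _colored_noise(n: int, fs: float, band: tuple[float, float],
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to ``band`` (Hz)."""
    x = rng.standard_normal(n)
    lo, hi = band
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    if lo <= 0:
        sos = sps.butter(2, hi / nyq, btype="low", output="sos")
    else:
        sos = sps.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
    y = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y ** 2))
    return y / rms if rms > 0 else y


def _place_bursts(n: int, fs: float, target_fraction: float,
                  rng: np.random.Generator,
                  burst_seconds: tuple[float, float] = (0.5, 2.0)) -> np.ndarray:
    """Place non-overlapping bursts covering ~target_fraction of n samples."""
    mask = np.zeros(n, dtype=bool)
    if target_fraction <= 0:
        return mask
    target = int(round(target_fraction * n))
    attempts = 0
    while mask.sum() < target and attempts < 10 * n:
        attempts += 1
        dur = int(rng.uniform(*burst_seconds) * fs)
        dur = max(1, min(dur, target - int(mask.sum())))
        if dur >= n:
            start = 0
        else:
            start = int(rng.integers(0, n - dur))
        if mask[start:start + dur].any():
            continue
        mask[start:start + dur] = True
    return mask


def inject_noise(clean: np.ndarray, fs: float, spec: NoiseSpec,
                 seed: int = 0) -> RecordingWithTruth:
    """Add drift, powerline and motion-burst noise to a clean waveform.

    Motion bursts cover approximately ``motion_window_fraction x
    motion_level`` of the samples and are the only component recorded in
    the artifact mask.  With all levels zero the input is returned
    bit-exactly with an all-false mask.
    """
    clean = np.asarray(clean, dtype=np.float64)
    if clean.size == 0:
        raise ValueError("clean signal must be non-empty")
    if fs <= 0:
        raise ValueError("fs must be positive")

    n = clean.size
    rng = np.random.default_rng(seed)
    out = clean.copy()
    mask = np.zeros(n, dtype=bool)
    ptp = float(np.ptp(clean))
    if ptp == 0.0:
        ptp = 1.0  # flat input: fall back to unit amplitude scaling

    if spec.drift_level > 0:
        drift = _colored_noise(n, fs, (0.05, 0.5), rng)
        out = out + spec.drift_level * ptp * drift

    if spec.powerline_level > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        out = out + spec.powerline_level * ptp * np.sin(
            2 * np.pi * spec.mains_hz * t + phase)

    if spec.motion_level > 0 and spec.motion_window_fraction > 0:
        frac = spec.motion_window_fraction * spec.motion_level
        mask = _place_bursts(n, fs, frac, rng)
        if mask.any():
            burst = _colored_noise(n, fs, (0.0, min(10.0, 0.45 * fs)), rng)
            # bursts are large relative to the pulse amplitude so that they
            # both look like motion artifacts and are detectable
            out = out + mask * (0.5 + 1.5 * spec.motion_level) * ptp * burst

    return RecordingWithTruth(
        samples=out, fs=fs, artifact_mask=mask,
        meta={"noise_spec": asdict(spec), "seed": seed})


def make_corpus(n_patients: int, recording_minutes: float, fs: float = 240.0,
                hr_range: tuple[float, float] = (50.0, 120.0),
                artifact_schedule: ArtifactSchedule | None = None,
                template: BeatTemplateParams | None = None,
                seed: int = 0) -> list[RecordingWithTruth]:
    """Generate one continuous recording per synthetic patient.

    Each recording interleaves clean 30 s blocks with artifact blocks per
    ``artifact_schedule``.  When the schedule injects any artifacts
    (``p_segment > 0``), the first block is forced clean and the second is
    forced to carry artifacts, guaranteeing at least one (clean anchor,
    within-5-min low-quality neighbour) pair per patient.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if recording_minutes < 1:
        raise ValueError("recording_minutes must be >= 1")
    if hr_range is None or len(hr_range) != 2 or hr_range[0] > hr_range[1]:
        raise ValueError("hr_range must be a (low, high) interval")
    schedule = artifact_schedule if artifact_schedule is not None else ArtifactSchedule()

    master = np.random.default_rng(seed)
    recordings = []
    for p in range(n_patients):
        prng = np.random.default_rng(master.integers(2 ** 31))
        hr = float(prng.uniform(*hr_range))
        duration = recording_minutes * 60.0
        x = simulate_clean_ppg(hr, duration, fs, template=template,
                               hr_jitter=0.02,
                               seed=int(prng.integers(2 ** 31)))
        n = x.size
        ptp = float(np.ptp(x))
        mask = np.zeros(n, dtype=bool)

        # global confounders
        if schedule.drift_level > 0:
            x = x + schedule.drift_level * ptp * _colored_noise(
                n, fs, (0.05, 0.5), prng)
        if schedule.powerline_level > 0:
            t = np.arange(n) / fs
            x = x + schedule.powerline_level * ptp * np.sin(
                2 * np.pi * 60.0 * t + prng.uniform(0, 2 * np.pi))

        # block-level motion artifacts
        block = int(round(schedule.block_seconds * fs))
        n_blocks = n // block
        block_levels = np.zeros(n_blocks)
        for b in range(n_blocks):
            if schedule.p_segment <= 0:
                continue
            hit = prng.uniform() < schedule.p_segment
            if b == 0:
                hit = False   # guaranteed clean anchor
            elif b == 1:
                hit = True    # guaranteed nearby low-quality neighbour
            if hit:
                block_levels[b] = prng.uniform(*schedule.level_range)
        for b, level in enumerate(block_levels):
            if level == 0:
                continue
            sl = slice(b * block, (b + 1) * block)
            seg = x[sl]
            bmask = _place_bursts(seg.size, fs,
                                  schedule.window_fraction * level, prng)
            burst = _colored_noise(seg.size, fs, (0.0, min(10.0, 0.45 * fs)),
                                   prng)
            x[sl] = seg + bmask * (0.5 + 1.5 * level) * ptp * burst
            mask[sl] = bmask

        recordings.append(RecordingWithTruth(
            samples=x, fs=fs, start_time=0.0, artifact_mask=mask,
            patient_id=f"p{p:03d}",
            meta={"hr_bpm": hr, "schedule": asdict(schedule), "seed": seed}))
    return recordings
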