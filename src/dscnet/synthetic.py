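"""Synthetic two-class resting-state EEG generator.

The generator emulates the eyes-closed, oscillation-dominated regime of a
resting-state addiction-screening cohort: every channel carries 1/f-shaped
("pink") Gaussian background noise, and a shared band-limited oscillation
(alpha band by default) is mixed into all channels with fixed per-subject
mixing weights.  The two classes differ only in the oscillation's band
power: class 1 carries ``power_ratio`` times the band power of class 0.
Subjects within a class get a log-normal amplitude multiplier so that
subject-wise train/test splits are genuinely harder than segment-wise ones.

Optionally a 50 Hz mains component and a slow (< 0.5 Hz) drift can be added,
so that the notch/band-pass/resampling chain has realistic work to do on the
"raw" 1,000 Hz recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import EEGRecord, SegmentSet

__all__ = ["SyntheticSpec", "generate_dataset", "generate_raw_recording"]

# Oscillation RMS relative to the broadband background RMS for class 0.  At
# this level the oscillation dominates the target band (pink background holds
# only a few percent of its power in a 4 Hz alpha band), so the measured
# class-1/class-0 band-power ratio tracks power_ratio closely.
_OSC_RMS_FACTOR = 1.0
_SUBJECT_SIGMA = 0.1  # log-normal sd of the per-subject amplitude multiplier
_LINE_FREQ = 50.0  # Hz mains
_DRIFT_FREQ = 0.25  # Hz, below the 0.5 Hz band-pass edge


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the simulated cohort."""

    n_subjects_per_class: int = 20
    segments_per_subject: int = 50
    n_channels: int = 8
    sampling_rate: float = 128.0
    segment_length: int = 256
    target_band: tuple[float, float] = (8.0, 12.0)
    power_ratio: float = 2.0
    noise_floor: float = 1.0
    line_noise_amplitude: float = 0.0
    drift_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("n_subjects_per_class must be positive")
        if self.segments_per_subject < 1:
            raise ValueError("segments_per_subject must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.segment_length < 1:
            raise ValueError("segment_length must be positive")
        low, high = self.target_band
        if not (0.0 < low < high < self.sampling_rate / 2.0):
            raise ValueError(
                f"target_band {self.target_band} must lie inside (0, Nyquist={self.sampling_rate / 2})"
            )
        if self.power_ratio < 1.0:
            raise ValueError("power_ratio must be >= 1")
        if self.segment_length < 2 * self.sampling_rate / low:
            raise ValueError(
                "segment_length too short: need at least two cycles of the slowest "
                f"target component ({2 * self.sampling_rate / low:.0f} samples)"
            )
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise along the last axis, unit RMS."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # Flat below 1 Hz to avoid a divergent DC term.
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec *= scale
    out = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt(np.mean(out**2, axis=-1, keepdims=True))
    return out / np.maximum(rms, 1e-30)


def _band_oscillation(rng: np.random.Generator, n: int, fs: float,
                      band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited noise: white noise band-passed into ``band``."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    # Pad so filter transients do not bias the segment.
    pad = min(4 * n, int(4 * fs))
    x = rng.standard_normal(n + 2 * pad)
    y = signal.sosfiltfilt(sos, x)[pad:pad + n]
    rms = np.sqrt(np.mean(y**2))
    return y / max(rms, 1e-30)


def _subject_params(rng: np.random.Generator, spec: SyntheticSpec) -> tuple[np.ndarray, float]:
    """Per-subject channel mixing weights and amplitude multiplier."""
    mixing = rng.uniform(0.5, 1.5, size=spec.n_channels)
    amp = float(np.exp(rng.normal(0.0, _SUBJECT_SIGMA)))
    return mixing, amp


def generate_dataset(spec: SyntheticSpec) -> SegmentSet:
    """Simulate the full labeled cohort as ready-to-train segments.

    Returns a :class:`SegmentSet` with ``2 * n_subjects_per_class *
    segments_per_subject`` segments of shape (C, 1, T).  Labels are balanced
    exactly; each subject has a single, consistent label; identical
    (spec, seed) pairs yield bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_seg_total = 2 * spec.n_subjects_per_class * spec.segments_per_subject
    segments = np.empty(
        (n_seg_total, spec.n_channels, 1, spec.segment_length), dtype=np.float64
    )
    labels = np.empty(n_seg_total, dtype=np.int64)
    subject_ids = np.empty(n_seg_total, dtype=object)

    osc_rms = _OSC_RMS_FACTOR * spec.noise_floor
    i = 0
    for label in (0, 1):
        class_amp = osc_rms * (np.sqrt(spec.power_ratio) if label == 1 else 1.0)
        for s in range(spec.n_subjects_per_class):
            mixing, subj_amp = _subject_params(rng, spec)
            sid = f"C{label}S{s:03d}"
            for _ in range(spec.segments_per_subject):
                seg = _make_segment(rng, spec, mixing, class_amp * subj_amp)
                segments[i, :, 0, :] = seg
                labels[i] = label
                subject_ids[i] = sid
                i += 1
    return SegmentSet(
        segments=segments,
        labels=labels,
        subject_ids=subject_ids.astype(str),
        sampling_rate=spec.sampling_rate,
    )


def _make_segment(rng: np.random.Generator, spec: SyntheticSpec,
                  mixing: np.ndarray, osc_amp: float) -> np.ndarray:
    """One (C, T) segment: pink background plus shared mixed oscillation."""
    bg = spec.noise_floor * _pink_noise(
        rng, (spec.n_channels, spec.segment_length), spec.sampling_rate
    )
    osc = _band_oscillation(rng, spec.segment_length, spec.sampling_rate, spec.target_band)
    seg = bg + osc_amp * mixing[:, None] * osc[None, :]
    if spec.line_noise_amplitude > 0 and _LINE_FREQ < spec.sampling_rate / 2:
        t = np.arange(spec.segment_length) / spec.sampling_rate
        phase = rng.uniform(0, 2 * np.pi)
        seg += spec.line_noise_amplitude * np.sin(2 * np.pi * _LINE_FREQ * t + phase)[None, :]
    if spec.drift_amplitude > 0:
        t = np.arange(spec.segment_length) / spec.sampling_rate
        phase = rng.uniform(0, 2 * np.pi)
        seg += spec.drift_amplitude * np.sin(2 * np.pi * _DRIFT_FREQ * t + phase)[None, :]
    return seg


def generate_raw_recording(spec: SyntheticSpec, label: int = 0,
                           subject_id: str | None = None) -> EEGRecord:
    """One continuous unsegmented recording for exercising the preprocessing chain.

    Duration is ``segments_per_subject * segment_length`` samples at
    ``spec.sampling_rate`` (typically 1,000 Hz for "raw" input).  Line noise
    and drift components are included at the amplitudes given in the spec.
    """
    spec.validate()
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng(spec.seed)
    n = spec.segments_per_subject * spec.segment_length
    mixing, subj_amp = _subject_params(rng, spec)
    osc_amp = _OSC_RMS_FACTOR * spec.noise_floor * subj_amp
    if label == 1:
        osc_amp *= np.sqrt(spec.power_ratio)

    bg = spec.noise_floor * _pink_noise(rng, (spec.n_channels, n), spec.sampling_rate)
    osc = _band_oscillation(rng, n, spec.sampling_rate, spec.target_band)
    data = bg + osc_amp * mixing[:, None] * osc[None, :]
    t = np.arange(n) / spec.sampling_rate
    if spec.line_noise_amplitude > 0 and _LINE_FREQ < spec.sampling_rate / 2:
        phase = rng.uniform(0, 2 * np.pi)
        data += spec.line_noise_amplitude * np.sin(2 * np.pi * _LINE_FREQ * t + phase)[None, :]
    if spec.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        data += spec.drift_amplitude * np.sin(2 * np.pi * _DRIFT_FREQ * t + phase)[None, :]

    return EEGRecord(
        data=data,
        sampling_rate=spec.sampling_rate,
        subject_id=subject_id or f"C{label}S000",
        label=label,
    )
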