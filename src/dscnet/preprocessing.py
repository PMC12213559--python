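"""Signal conditioning chain: notch, band-pass, resample, re-reference,
segmentation, and the per-time-point standardization.

All filters are zero-phase (forward-backward) IIR filters: a 2nd-order notch
with quality factor 30 for mains rejection and a 4th-order Butterworth for
the band-pass.  Resampling is polyphase at the exact rational ratio (e.g.
16/125 for 1,000 -> 128 Hz) so no cumulative drift is introduced.

Standardization follows the dataset-level per-time-point recipe: for every
segment the cross-channel mean and standard deviation are computed at each
time point, these per-segment curves are averaged over the (training) set to
give global mu(t) and sigma(t), and every sample is transformed as
(x - mu(t)) / sigma(t).  A plain pooled per-time-point dialect is available
via ``mode="global"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .data import EEGRecord, SegmentSet

__all__ = [
    "StandardizationStats",
    "notch_filter",
    "bandpass_filter",
    "resample",
    "rereference",
    "segment",
    "fit_standardization",
    "standardize",
    "remove_artifacts_ica",
    "preprocess_record",
]

NOTCH_Q = 30.0
BANDPASS_ORDER = 4
SIGMA_FLOOR = 1e-8


@dataclass
class StandardizationStats:
    """Global per-time-point mean and standard deviation curves."""

    mu: np.ndarray  # (T,)
    sigma: np.ndarray  # (T,)
    epsilon: float = SIGMA_FLOOR
    mode: str = "per_segment_average"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D arrays of equal length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma entries must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def notch_filter(rec: EEGRecord, freq: float = 50.0) -> EEGRecord:
    """Zero-phase narrow-band rejection of a mains component."""
    if not 0 < freq < rec.sampling_rate / 2:
        raise ValueError(
            f"notch frequency {freq} Hz must lie in (0, Nyquist={rec.sampling_rate / 2})"
        )
    b, a = signal.iirnotch(freq, NOTCH_Q, fs=rec.sampling_rate)
    out = signal.filtfilt(b, a, rec.data, axis=-1)
    return rec.copy_with(out)


def bandpass_filter(rec: EEGRecord, low: float = 0.5, high: float = 64.0) -> EEGRecord:
    """Zero-phase Butterworth band-pass, removing drift and high-frequency noise."""
    if not 0 < low < high < rec.sampling_rate / 2:
        raise ValueError(
            f"band edges ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist={rec.sampling_rate / 2}"
        )
    sos = signal.butter(BANDPASS_ORDER, (low, high), btype="bandpass",
                        fs=rec.sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(out)


def resample(rec: EEGRecord, target_rate: float) -> EEGRecord:
    """Polyphase rational-rate resampling with built-in anti-alias filtering.

    Output length is round(samples * target_rate / sampling_rate).
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == rec.sampling_rate:
        return rec.copy_with(rec.data.copy())
    ratio = Fraction(target_rate / rec.sampling_rate).limit_denominator(10_000)
    out = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=-1)
    n_expected = int(round(rec.n_samples * target_rate / rec.sampling_rate))
    if out.shape[-1] > n_expected:
        out = out[..., :n_expected]
    elif out.shape[-1] < n_expected:  # pad by edge value; off-by-one at most
        pad = n_expected - out.shape[-1]
        out = np.concatenate([out, np.repeat(out[..., -1:], pad, axis=-1)], axis=-1)
    return rec.copy_with(out, sampling_rate=float(target_rate))


def rereference(rec: EEGRecord, ref_channels: list[str],
                drop_refs: bool = True) -> EEGRecord:
    """Subtract the per-sample mean of the reference electrodes (e.g. A1/A2).

    Reference channels are dropped afterwards by default since they become
    linearly dependent on the rest.
    """
    if not ref_channels:
        raise ValueError("at least one reference channel required")
    missing = [c for c in ref_channels if c not in rec.channel_names]
    if missing:
        raise ValueError(f"unknown reference channel(s): {missing}")
    idx = [rec.channel_names.index(c) for c in ref_channels]
    ref = rec.data[idx].mean(axis=0, keepdims=True)
    out = rec.data - ref
    names = list(rec.channel_names)
    if drop_refs:
        keep = [i for i in range(rec.n_channels) if i not in idx]
        out = out[keep]
        names = [names[i] for i in keep]
    return rec.copy_with(out, channel_names=names)


def remove_artifacts_ica(rec: EEGRecord, n_components: int | None = None,
                         drop_components: list[int] | None = None,
                         seed: int = 0) -> EEGRecord:
    """Optional ICA artifact-removal stage.

    Decomposes the recording with FastICA, zeroes the listed independent
    components (chosen by the caller — no automatic artifact detection), and
    reconstructs the signal.  Delegates entirely to the established FastICA
    implementation; with ``drop_components`` empty this is a (lossy only up
    to rank) round-trip.
    """
    from sklearn.decomposition import FastICA

    ica = FastICA(n_components=n_components, random_state=seed, max_iter=500,
                  whiten="unit-variance")
    sources = ica.fit_transform(rec.data.T)  # (samples, components)
    if drop_components:
        sources[:, list(drop_components)] = 0.0
    out = ica.inverse_transform(sources).T
    return rec.copy_with(out)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment(rec: EEGRecord, length: int, stride: int | None = None) -> SegmentSet:
    """Fixed-length windowing into (N, C, 1, length) segments.

    N = floor((samples - length) / stride) + 1; the trailing remainder is
    dropped.  Every segment inherits the record's label and subject ID.
    """
    if stride is None:
        stride = length
    if length < 1 or length > rec.n_samples:
        raise ValueError(
            f"segment length {length} must be in [1, {rec.n_samples}]"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = (rec.n_samples - length) // stride + 1
    segs = np.stack([rec.data[:, i * stride:i * stride + length] for i in range(n)])
    return SegmentSet(
        segments=segs[:, :, None, :],
        labels=np.full(n, rec.label, dtype=np.int64),
        subject_ids=np.full(n, rec.subject_id, dtype=object).astype(str),
        sampling_rate=rec.sampling_rate,
    )


def concatenate_sets(sets: list[SegmentSet]) -> SegmentSet:
    """Stack several segment sets (e.g. one per subject) into one."""
    if not sets:
        raise ValueError("nothing to concatenate")
    rates = {s.sampling_rate for s in sets}
    if len(rates) != 1:
        raise ValueError(f"mixed sampling rates: {sorted(rates)}")
    return SegmentSet(
        segments=np.concatenate([s.segments for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        subject_ids=np.concatenate([s.subject_ids for s in sets]),
        sampling_rate=sets[0].sampling_rate,
    )


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def fit_standardization(train: SegmentSet, epsilon: float = SIGMA_FLOOR,
                        mode: str = "per_segment_average") -> StandardizationStats:
    """Fit global per-time-point mu/sigma on a (training) segment set.

    ``per_segment_average`` (default): each segment's cross-channel mean and
    std are computed per time point, and mu/sigma are the averages of those
    curves over segments.  ``global``: plain pooled per-time-point statistics
    over all segments and channels.
    """
    if len(train) < 1:
        raise ValueError("cannot fit standardization on an empty set")
    x = train.segments[:, :, 0, :]  # (N, C, T)
    if mode == "per_segment_average":
        mu = x.mean(axis=1).mean(axis=0)
        sigma = x.std(axis=1).mean(axis=0)
    elif mode == "global":
        mu = x.mean(axis=(0, 1))
        sigma = x.std(axis=(0, 1))
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    return StandardizationStats(mu=mu, sigma=np.maximum(sigma, epsilon),
                                epsilon=epsilon, mode=mode)


def standardize(x: SegmentSet, stats: StandardizationStats) -> SegmentSet:
    """Apply (value - mu(t)) / max(sigma(t), epsilon) to every sample."""
    if stats.mu.shape[0] != x.segment_length:
        raise ValueError(
            f"stats fitted for T={stats.mu.shape[0]} but segments have T={x.segment_length}"
        )
    denom = np.maximum(stats.sigma, stats.epsilon)
    out = (x.segments - stats.mu[None, None, None, :]) / denom[None, None, None, :]
    return SegmentSet(out, x.labels.copy(), x.subject_ids.copy(), x.sampling_rate)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def preprocess_record(rec: EEGRecord, notch: float | None = 50.0,
                      band: tuple[float, float] | None = (0.5, 64.0),
                      target_rate: float | None = 128.0,
                      ref_channels: list[str] | None = None,
                      segment_length: int = 256,
                      stride: int | None = None) -> SegmentSet:
    """Run the conditioning chain on one recording and window it.

    Every stage is individually skippable by passing ``None``.  Order:
    notch -> band-pass -> resample -> re-reference -> segment.
    Standardization is fitted separately (on the training split) via
    :func:`fit_standardization`.
    """
    if notch is not None:
        rec = notch_filter(rec, notch)
    if band is not None:
        rec = bandpass_filter(rec, *band)
    if target_rate is not None:
        rec = resample(rec, target_rate)
    if ref_channels:
        rec = rereference(rec, ref_channels)
    return segment(rec, segment_length, stride)
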