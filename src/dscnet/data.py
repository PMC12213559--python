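"""Core in-memory containers for multichannel EEG.

Two units of data flow through the package:

* :class:`EEGRecord` — one subject's continuous multichannel recording
  (channels x samples) with its sampling rate, subject identity and binary
  class label.  This is what the preprocessing chain operates on.
* :class:`SegmentSet` — a stack of fixed-length segments with shape
  (N x C x 1 x T); the dataset unit consumed by the model and the
  training/evaluation machinery.  The singleton height axis is kept
  explicitly so that segments read as single-row "images" for the 1 x k
  temporal convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecord", "SegmentSet"]


@dataclass
class EEGRecord:
    """One subject's raw or preprocessed multichannel EEG signal."""

    data: np.ndarray  # (channels, samples)
    sampling_rate: float  # Hz
    subject_id: str = "S0"
    label: int = 0  # {0, 1}
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"EEGRecord data must be 2-D (channels x samples), got shape {self.data.shape}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("EEGRecord needs at least one channel and one sample")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def copy_with(self, data: np.ndarray, sampling_rate: float | None = None,
                  channel_names: list[str] | None = None) -> "EEGRecord":
        """New record with replaced signal, inheriting identity metadata."""
        return EEGRecord(
            data=data,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            subject_id=self.subject_id,
            label=self.label,
            channel_names=list(self.channel_names) if channel_names is None else channel_names,
        )


@dataclass
class SegmentSet:
    """Stack of fixed-length EEG segments: the dataset unit.

    ``segments`` has shape (N, C, 1, T); ``labels`` and ``subject_ids`` are
    aligned 1:1 with the leading axis.
    """

    segments: np.ndarray  # (N, C, 1, T)
    labels: np.ndarray  # (N,) in {0, 1}
    subject_ids: np.ndarray  # (N,) strings
    sampling_rate: float

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments)
        if self.segments.ndim != 4 or self.segments.shape[2] != 1:
            raise ValueError(
                f"segments must have shape (N, C, 1, T), got {self.segments.shape}"
            )
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=str)
        n = self.segments.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("segments, labels and subject_ids must have equal length")
        if n and not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary {0, 1}")
        if n and not np.all(np.isfinite(self.segments)):
            raise ValueError("segments contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[1]

    @property
    def segment_length(self) -> int:
        return self.segments.shape[3]

    def subset(self, indices: np.ndarray) -> "SegmentSet":
        indices = np.asarray(indices, dtype=np.int64)
        return SegmentSet(
            segments=self.segments[indices],
            labels=self.labels[indices],
            subject_ids=self.subject_ids[indices],
            sampling_rate=self.sampling_rate,
        )

    def subjects(self) -> np.ndarray:
        """Unique subject IDs, in order of first appearance."""
        _, first = np.unique(self.subject_ids, return_index=True)
        return self.subject_ids[np.sort(first)]
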