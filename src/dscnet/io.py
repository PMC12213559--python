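"""Readers/writers, run configuration and logging.

Three on-disk surfaces:

* a generic single-file HDF5 container for :class:`SegmentSet` /
  :class:`EEGRecord` (datasets ``data``, ``labels``, ``subject_ids``;
  ``sampling_rate`` attribute) — the package's native interchange format;
* the public alcoholism-trial text dialect (comment headers introduced by
  ``#`` followed by whitespace-separated ``trial  channel  sample  value``
  records), with the stated filtering rules: position channels X, Y and nd
  are excluded, "err"-marked trials and empty files are rejected with
  distinguishable reason codes;
* a MAT-file shim for per-subject recordings stored as MATLAB arrays.

``RunConfig`` is the full nested configuration tree (simulation,
preprocessing stages, model, training, split); it round-trips losslessly
through YAML and rejects unknown keys with the offending field path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .data import EEGRecord, SegmentSet
from .model import ModelConfig
from .synthetic import SyntheticSpec
from .training import TrainConfig

__all__ = [
    "UCITrialRecord", "UCITrialRejected", "UCIParseError",
    "read_uci_trial", "to_segmentset",
    "save_segmentset", "load_segmentset", "save_record", "load_record",
    "read_mat_record",
    "PreprocessingConfig", "SplitConfig", "RunConfig",
    "load_config", "save_config", "setup_logging",
]

EXCLUDED_CHANNELS = ("X", "Y", "nd")
UCI_SAMPLING_RATE = 256.0


# ---------------------------------------------------------------------------
# Public trial text dialect
# ---------------------------------------------------------------------------

class UCIParseError(ValueError):
    """Malformed trial stream; carries the offending line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class UCITrialRejected(Exception):
    """Trial excluded by a stated filtering rule (not a parse failure)."""

    def __init__(self, reason: str, message: str = ""):
        super().__init__(message or reason)
        self.reason = reason  # "trial_error" | "empty_file"


@dataclass
class UCITrialRecord:
    subject_id: str
    trial_number: int
    condition: str  # stimulus/matching condition from the header
    group_label: int  # 1 = alcoholic, 0 = control
    sampling_rate: float
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0


def read_uci_trial(stream) -> UCITrialRecord:
    """Parse one trial file from the public alcoholism EEG text dialect.

    ``stream`` is an iterable of lines (an open text file works).  Position
    channels X, Y and nd are dropped; a trial whose condition header carries
    an "err" marker raises :class:`UCITrialRejected` with reason
    ``trial_error``; an empty stream raises it with ``empty_file``; any
    malformed line raises :class:`UCIParseError` naming the line number.
    """
    subject_id = ""
    group_label = 0
    condition = ""
    trial_number = -1
    samples: dict[str, dict[int, float]] = {}
    saw_content = False

    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        saw_content = True
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if line_no == 1 or (not subject_id and body.endswith(".rd")):
                token = body.split()[0] if body else ""
                subject_id = token.removesuffix(".rd")
                # naming convention: 4th character 'a' = alcoholic, 'c' = control
                if len(subject_id) >= 4 and subject_id[3] in ("a", "c"):
                    group_label = 1 if subject_id[3] == "a" else 0
            elif "trial" in body and "chan" not in body:
                cond_part, _, trial_part = body.partition(", trial")
                condition = cond_part.strip()
                if "err" in condition.lower().split():
                    raise UCITrialRejected(
                        "trial_error", f"trial marked with an error condition: {condition!r}"
                    )
                try:
                    trial_number = int(trial_part.strip() or trial_number)
                except ValueError:
                    pass
            continue
        parts = line.split()
        if len(parts) != 4:
            raise UCIParseError(line_no, f"expected 4 fields, got {len(parts)}: {line!r}")
        try:
            trial = int(parts[0])
            chan = parts[1]
            idx = int(parts[2])
            value = float(parts[3])
        except ValueError as exc:
            raise UCIParseError(line_no, f"cannot parse record {line!r}: {exc}") from None
        if trial_number < 0:
            trial_number = trial
        samples.setdefault(chan, {})[idx] = value

    if not saw_content:
        raise UCITrialRejected("empty_file", "stream contains no data")
    if not samples:
        raise UCIParseError(0, "stream has headers but no sample records")

    channels: dict[str, np.ndarray] = {}
    lengths = set()
    for chan, vals in samples.items():
        if chan in EXCLUDED_CHANNELS:
            continue
        arr = np.empty(len(vals))
        order = sorted(vals)
        if order != list(range(len(vals))):
            raise UCIParseError(0, f"channel {chan!r} has non-contiguous sample indices")
        for i in order:
            arr[i] = vals[i]
        channels[chan] = arr
        lengths.add(len(arr))
    if len(lengths) > 1:
        raise UCIParseError(0, f"retained channels have unequal sample counts: {sorted(lengths)}")
    return UCITrialRecord(
        subject_id=subject_id or "unknown",
        trial_number=trial_number,
        condition=condition,
        group_label=group_label,
        sampling_rate=UCI_SAMPLING_RATE,
        channels=channels,
    )


def to_segmentset(records: list) -> SegmentSet:
    """Stack trials/recordings into the (N, C, 1, T) dataset container.

    Accepts :class:`UCITrialRecord` or :class:`EEGRecord` items (each
    becomes one segment); channel counts and lengths must be homogeneous.
    Labels and subject IDs are preserved 1:1 with input order.
    """
    if not records:
        raise ValueError("no records to stack")
    arrays, labels, sids, rates = [], [], [], set()
    for rec in records:
        if isinstance(rec, UCITrialRecord):
            arrays.append(np.stack(list(rec.channels.values())))
            labels.append(rec.group_label)
            sids.append(rec.subject_id)
            rates.add(rec.sampling_rate)
        elif isinstance(rec, EEGRecord):
            arrays.append(rec.data)
            labels.append(rec.label)
            sids.append(rec.subject_id)
            rates.add(rec.sampling_rate)
        else:
            raise TypeError(f"unsupported record type {type(rec).__name__}")
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"heterogeneous record shapes: {sorted(shapes)}")
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates: {sorted(rates)}")
    data = np.stack(arrays)[:, :, None, :]
    return SegmentSet(data, np.asarray(labels), np.asarray(sids, dtype=str),
                      sampling_rate=rates.pop())


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_segmentset(path, ss: SegmentSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "segmentset"
        f.attrs["sampling_rate"] = ss.sampling_rate
        f.create_dataset("data", data=ss.segments)
        f.create_dataset("labels", data=ss.labels)
        f.create_dataset("subject_ids",
                         data=np.asarray(ss.subject_ids, dtype="S"))


def load_segmentset(path) -> SegmentSet:
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "segmentset":
            raise ValueError(f"{path} is not a segment-set container")
        return SegmentSet(
            segments=f["data"][()],
            labels=f["labels"][()],
            subject_ids=f["subject_ids"][()].astype(str),
            sampling_rate=float(f.attrs["sampling_rate"]),
        )


def save_record(path, rec: EEGRecord) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "record"
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["label"] = rec.label
        f.create_dataset("data", data=rec.data)
        f.create_dataset("channel_names",
                         data=np.asarray(rec.channel_names, dtype="S"))


def load_record(path) -> EEGRecord:
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "record":
            raise ValueError(f"{path} is not a recording container")
        return EEGRecord(
            data=f["data"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            subject_id=str(f.attrs["subject_id"]),
            label=int(f.attrs["label"]),
            channel_names=[c.decode() for c in f["channel_names"][()]],
        )


def read_mat_record(path, var_name: str | None = None,
                    sampling_rate: float | None = None,
                    subject_id: str = "S0", label: int = 0) -> EEGRecord:
    """Interoperability shim for per-subject MATLAB array files.

    Loads the named 2-D variable (or the first 2-D numeric one found) as a
    (channels x samples) signal; the sampling rate is taken from an ``fs``
    or ``srate`` scalar if present, else must be passed explicitly.
    """
    from scipy.io import loadmat

    mat = loadmat(path)
    data = None
    if var_name is not None:
        if var_name not in mat:
            raise KeyError(f"variable {var_name!r} not in {path}")
        data = np.asarray(mat[var_name])
    else:
        for key, value in mat.items():
            if key.startswith("__"):
                continue
            arr = np.asarray(value)
            if arr.ndim == 2 and arr.size > 1 and np.issubdtype(arr.dtype, np.number):
                data = arr
                break
        if data is None:
            raise ValueError(f"no 2-D numeric array found in {path}")
    if sampling_rate is None:
        for key in ("fs", "srate", "sampling_rate"):
            if key in mat:
                sampling_rate = float(np.asarray(mat[key]).ravel()[0])
                break
    if sampling_rate is None:
        raise ValueError("sampling_rate not found in the file; pass it explicitly")
    return EEGRecord(data=data, sampling_rate=sampling_rate,
                     subject_id=subject_id, label=label)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessingConfig:
    notch: float | None = 50.0
    band_low: float | None = 0.5
    band_high: float | None = 64.0
    resample_to: float | None = 128.0
    ref_channels: tuple[str, ...] = ()
    segment_length: int = 256
    stride: int | None = None
    standardization_mode: str = "per_segment_average"


@dataclass(frozen=True)
class SplitConfig:
    mode: str = "subject_wise"
    train_fraction: float = 0.8


@dataclass(frozen=True)
class RunConfig:
    """Full nested configuration tree for a reproducible run."""

    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "runs"
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    split: SplitConfig = field(default_factory=SplitConfig)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _from_dict(cls, payload: dict, path: str = ""):
    """Strict dataclass construction: unknown keys are rejected with their path."""
    if not isinstance(payload, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping, "
                         f"got {type(payload).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(payload) - set(fields))
    if unknown:
        raise ValueError(f"unknown config key(s) at {path or '<root>'}: {unknown}")
    kwargs = {}
    for name, value in payload.items():
        f = fields[name]
        sub = f"{path}.{name}" if path else name
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[name] = _from_dict(f.type, value, sub)
        elif name in _NESTED_SECTIONS:
            kwargs[name] = _from_dict(_NESTED_SECTIONS[name], value, sub)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config at {path or '<root>'}: {exc}") from exc


_NESTED_SECTIONS = {
    "synthetic": SyntheticSpec,
    "preprocessing": PreprocessingConfig,
    "model": ModelConfig,
    "training": TrainConfig,
    "split": SplitConfig,
}


def load_config(path) -> RunConfig:
    with open(path) as f:
        payload = yaml.safe_load(f) or {}
    return _from_dict(RunConfig, payload)


def save_config(path, cfg: RunConfig) -> None:
    """Write the config with every default materialized explicitly."""
    payload = json.loads(json.dumps(asdict(cfg)))  # tuples -> lists, plain types
    with open(path, "w") as f:
        yaml.safe_dump(payload, f, sort_keys=False)


def setup_logging(level: str = "INFO", seed: int | None = None,
                  config_hash: str | None = None) -> logging.Logger:
    """Structured run logger stamped with the global seed and config hash."""
    logger = logging.getLogger("dscnet")
    logger.setLevel(getattr(logging, level.upper()))
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    if seed is not None or config_hash is not None:
        logger.info("run stamp: seed=%s config=%s", seed, config_hash)
    return logger
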