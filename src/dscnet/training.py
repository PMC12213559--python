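"""Subject-aware splitting, training loop, confusion-count metrics and the
ablation grid runner.

Two split modes are provided.  ``per_subject_segments`` puts 80% of every
subject's segments in the training set (the permissive reading of an
80/20-per-subject protocol); ``subject_wise`` assigns whole subjects to one
side only, stratified by class — the strict, leakage-free reading, and the
default for every end-to-end claim in this package.

Metrics are the four standard confusion-count quantities: Accuracy =
(TP+TN)/(TP+TN+FP+FN), Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F1 = 2PR/(P+R); computed per class and aggregated by support-weighted
(default) and macro averaging.  A zero denominator yields 0 for the
affected class metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .autodiff import Tensor, Adam
from .data import SegmentSet
from .model import ModelConfig, ParameterStore, forward_core, _lift_params

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "EvalReport",
    "TrainingDivergedError",
    "make_split",
    "compute_metrics",
    "train",
    "evaluate",
    "run_ablation",
    "metrics_table",
    "ABLATION_VARIANTS",
    "TABLES_GRID",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    mode: str  # "per_subject_segments" or "subject_wise"
    train_fraction: float
    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray

    def describe(self) -> str:
        return (f"{self.mode}(train_fraction={self.train_fraction}, seed={self.seed}, "
                f"n_train={len(self.train_indices)}, n_test={len(self.test_indices)})")


def make_split(data: SegmentSet, mode: str = "subject_wise",
               train_fraction: float = 0.8, seed: int = 0) -> SplitPlan:
    """Deterministic train/test partition of a segment set.

    ``per_subject_segments``: floor(train_fraction * n_i) of each subject's
    segments go to train, the rest to test.  ``subject_wise``: whole
    subjects are assigned, stratified by class, so that the train and test
    subject sets are provably disjoint.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(data) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []

    if mode == "per_subject_segments":
        for sid in data.subjects():
            idx = np.flatnonzero(data.subject_ids == sid)
            idx = idx[rng.permutation(len(idx))]
            n_train = int(np.floor(train_fraction * len(idx)))
            n_train = min(n_train, len(idx) - 1)  # keep the test side nonempty
            train_idx.extend(idx[:n_train])
            test_idx.extend(idx[n_train:])
    elif mode == "subject_wise":
        for label in (0, 1):
            mask = data.labels == label
            if not mask.any():
                continue
            subs = pd.unique(data.subject_ids[mask])
            if len(subs) < 2:
                raise ValueError(
                    f"subject_wise split needs >= 2 subjects in class {label}, "
                    f"got {len(subs)}"
                )
            subs = subs[rng.permutation(len(subs))]
            n_train = int(np.floor(train_fraction * len(subs)))
            n_train = min(max(n_train, 1), len(subs) - 1)
            train_subs = set(subs[:n_train])
            for i in np.flatnonzero(mask):
                (train_idx if data.subject_ids[i] in train_subs else test_idx).append(i)
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    plan = SplitPlan(mode=mode, train_fraction=train_fraction, seed=seed,
                     train_indices=np.sort(np.asarray(train_idx, dtype=np.int64)),
                     test_indices=np.sort(np.asarray(test_idx, dtype=np.int64)))
    _check_split(plan, data)
    return plan


def _check_split(plan: SplitPlan, data: SegmentSet) -> None:
    n = len(data)
    joined = np.concatenate([plan.train_indices, plan.test_indices])
    if len(joined) != n or len(np.unique(joined)) != n:
        raise AssertionError("split indices must be disjoint and cover the dataset")
    if plan.mode == "subject_wise":
        tr = set(data.subject_ids[plan.train_indices])
        te = set(data.subject_ids[plan.test_indices])
        if tr & te:
            raise AssertionError(f"subject leakage across the split: {sorted(tr & te)}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion counts and derived metrics for a binary task.

    ``tp/tn/fp/fn`` are counted with class 1 as positive; ``per_class``
    holds the one-vs-rest precision/recall/F1 of both classes.  The headline
    accuracy/precision/recall/f1 use the configured averaging (support-
    weighted by default); macro values are always included.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict = field(default_factory=dict)
    averaging: str = "weighted"
    split: str = ""
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    def row(self, name: str) -> dict:
        """Percentage row in the standard table column layout."""
        return {
            "Methods": name,
            "Accuracy (%)": round(100 * self.accuracy, 2),
            "Precision (%)": round(100 * self.precision, 2),
            "Recall (%)": round(100 * self.recall, 2),
            "F1-score (%)": round(100 * self.f1, 2),
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(y_true, y_pred, split: str = "", seed: int = 0) -> EvalReport:
    """Accuracy/precision/recall/F1 from confusion counts, per class and averaged."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal-length nonempty 1-D arrays")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.all(np.isin(arr, (0, 1))):
            raise ValueError(f"{name} must contain only binary labels 0/1")

    per_class = {}
    supports = {}
    for cls in (0, 1):
        tp = int(np.sum((y_pred == cls) & (y_true == cls)))
        fp = int(np.sum((y_pred == cls) & (y_true != cls)))
        fn = int(np.sum((y_pred != cls) & (y_true == cls)))
        tn = int(np.sum((y_pred != cls) & (y_true != cls)))
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * p * r, p + r)
        per_class[cls] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
                          "precision": p, "recall": r, "f1": f1,
                          "support": tp + fn}
        supports[cls] = tp + fn

    n = len(y_true)
    accuracy = float(np.mean(y_true == y_pred))
    w = {cls: supports[cls] / n for cls in (0, 1)}
    weighted = {m: sum(w[c] * per_class[c][m] for c in (0, 1))
                for m in ("precision", "recall", "f1")}
    macro = {m: 0.5 * sum(per_class[c][m] for c in (0, 1))
             for m in ("precision", "recall", "f1")}

    pos = per_class[1]
    return EvalReport(
        tp=pos["tp"], tn=pos["tn"], fp=pos["fp"], fn=pos["fn"],
        accuracy=accuracy,
        precision=weighted["precision"], recall=weighted["recall"], f1=weighted["f1"],
        macro_precision=macro["precision"], macro_recall=macro["recall"],
        macro_f1=macro["f1"],
        per_class=per_class, split=split, seed=seed,
    )


def metrics_table(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """Variant-name x metric table, percentages with two decimals."""
    return pd.DataFrame([rep.row(name) for name, rep in reports.items()])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.loss != "cross_entropy":
            raise ValueError("only cross-entropy loss is supported")


def _cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    onehot[np.arange(len(y)), y] = 1.0
    picked = (logits * onehot).sum(axis=1)
    return (logits.logsumexp(axis=1) - picked).mean()


class _SGD:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.params = params
        self.lr = lr

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            if g is not None:
                self.params[k] -= self.lr * g


def train(model_cfg: ModelConfig, train_data: SegmentSet, train_cfg: TrainConfig,
          val_data: SegmentSet | None = None,
          store: ParameterStore | None = None,
          ) -> tuple[ParameterStore, dict[str, list[float]]]:
    """Minimize cross-entropy over the training segments.

    Fully seeded: parameter initialization and the per-epoch shuffling both
    derive from ``train_cfg.seed``, so identical inputs yield bit-identical
    final parameters.  Raises :class:`TrainingDivergedError` on a
    non-finite loss.
    """
    if len(train_data) == 0:
        raise ValueError("training data is empty")
    if store is None:
        store = ParameterStore.initialize(model_cfg, seed=train_cfg.seed)
    opt = (Adam(store.params, lr=train_cfg.learning_rate)
           if train_cfg.optimizer == "adam"
           else _SGD(store.params, lr=train_cfg.learning_rate))
    shuffle_rng = np.random.default_rng(train_cfg.seed + 1)

    x_all = np.ascontiguousarray(train_data.segments[:, :, 0, :], dtype=np.float32)
    y_all = train_data.labels
    n = len(train_data)
    history: dict[str, list[float]] = {"loss": [], "train_accuracy": []}
    if val_data is not None:
        history["val_accuracy"] = []
    best_val, stale = -np.inf, 0

    for _epoch in range(train_cfg.epochs):
        perm = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = perm[start:start + train_cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            tp = _lift_params(store, requires_grad=True)
            logits = forward_core(Tensor(xb), model_cfg, tp, store, train=True)
            loss = _cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {_epoch}: {loss.data}"
                )
            loss.backward()
            opt.step({k: t.grad for k, t in tp.items()})
            epoch_loss += float(loss.data) * len(idx)
            correct += int(np.sum(np.argmax(logits.data, axis=1) == yb))
        history["loss"].append(epoch_loss / n)
        history["train_accuracy"].append(correct / n)
        if val_data is not None:
            rep = evaluate(store, model_cfg, val_data)
            history["val_accuracy"].append(rep.accuracy)
            if train_cfg.early_stop_patience is not None:
                if rep.accuracy > best_val + 1e-12:
                    best_val, stale = rep.accuracy, 0
                else:
                    stale += 1
                    if stale >= train_cfg.early_stop_patience:
                        break
    return store, history


def evaluate(store: ParameterStore, model_cfg: ModelConfig, test_data: SegmentSet,
              batch_size: int = 256, aggregate: str = "segment",
              split: str = "", seed: int = 0) -> EvalReport:
    """Forward pass + argmax + confusion-count metrics (deterministic).

    ``aggregate="subject_vote"`` replaces each subject's segment predictions
    with their majority vote (ties toward class 0) before scoring, one
    prediction per segment so supports are unchanged.
    """
    if len(test_data) == 0:
        raise ValueError("evaluation data is empty")
    x_all = np.ascontiguousarray(test_data.segments[:, :, 0, :], dtype=np.float32)
    preds = np.empty(len(test_data), dtype=np.int64)
    tp = _lift_params(store, requires_grad=False)
    for start in range(0, len(test_data), batch_size):
        xb = x_all[start:start + batch_size]
        logits = forward_core(Tensor(xb), model_cfg, tp, store, train=False)
        preds[start:start + len(xb)] = np.argmax(logits.data, axis=1)
    if aggregate == "subject_vote":
        for sid in test_data.subjects():
            mask = test_data.subject_ids == sid
            vote = 1 if preds[mask].mean() > 0.5 else 0
            preds[mask] = vote
    elif aggregate != "segment":
        raise ValueError(f"unknown aggregation {aggregate!r}")
    return compute_metrics(test_data.labels, preds, split=split, seed=seed)


# ---------------------------------------------------------------------------
# Ablation grid
# ---------------------------------------------------------------------------

# Row layout of the five ablation tables: embedding on/off, standard vs
# depthwise-separable convolution, DAFM off / 4 levels / 2 levels, CoT
# on/off, and one/two/three stage-2 rounds.  Rows with an empty override are
# the full default model and share one trained instance.
ABLATION_VARIANTS: dict[str, dict] = {
    "w/o embedding": {"use_embedding": False},
    "w embedding": {},
    "SC": {"conv_type": "sc"},
    "DSC": {},
    "w/o DAFM": {"use_dafm": False},
    "w DAFM (n_levels = 4)": {"n_levels": 4},
    "w DAFM (n_levels = 2)": {},
    "w/o CoT module": {"use_cot": False},
    "One": {"rounds": 1},
    "Two": {},
    "Three": {"rounds": 3},
}

# The ten-variant grid covering all table toggles (the full model appears
# once, as "w embedding"; "DSC", "w DAFM (n_levels = 2)" and "Two" alias it).
TABLES_GRID: list[str] = [
    "w/o embedding", "w embedding", "SC", "w/o DAFM", "w DAFM (n_levels = 4)",
    "w DAFM (n_levels = 2)", "w/o CoT module", "One", "Two", "Three",
]


def run_ablation(grid: list[str], data: SegmentSet, model_cfg: ModelConfig,
                 train_cfg: TrainConfig, split_mode: str = "subject_wise",
                 train_fraction: float = 0.8, seed: int = 0,
                 ) -> tuple[pd.DataFrame, dict[str, EvalReport]]:
    """Train and evaluate every named variant under one split and seed.

    Variants whose configurations coincide (the full model under its
    different table row names) are trained once and share the result.
    Returns the metrics table in the standard column layout plus the full
    per-variant reports.
    """
    unknown = [g for g in grid if g not in ABLATION_VARIANTS]
    if unknown:
        raise ValueError(f"unknown ablation variant(s): {unknown}; "
                         f"known: {sorted(ABLATION_VARIANTS)}")
    plan = make_split(data, mode=split_mode, train_fraction=train_fraction, seed=seed)
    train_set = data.subset(plan.train_indices)
    test_set = data.subset(plan.test_indices)

    cache: dict[str, EvalReport] = {}
    reports: dict[str, EvalReport] = {}
    for name in grid:
        cfg = model_cfg.with_overrides(**ABLATION_VARIANTS[name])
        key = json.dumps(asdict(cfg), sort_keys=True)
        if key not in cache:
            store, _ = train(cfg, train_set, train_cfg)
            cache[key] = evaluate(store, cfg, test_set,
                                  split=plan.describe(), seed=train_cfg.seed)
        reports[name] = cache[key]
    return metrics_table(reports), reports
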