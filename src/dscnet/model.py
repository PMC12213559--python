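"""DSCnet: multi-angle temporal-convolutional EEG classifier.

The architecture runs in three stages over feature maps of shape
(channels x 1 x time):

* **Stage 1 — hybrid representation.**  An embedding of three same-padded
  1x3 convolutions (each followed by batch normalization and GELU) runs in
  parallel with a 1x1-convolution skip path; their sum (a residual block) is
  concatenated along the channel axis with a 1x1-projected copy of the raw
  input, doubling the embedding width.

* **Stage 2 — multi-angle rounds.**  Each round applies a depthwise
  separable convolution (local view), then in parallel a directional
  adaptive feature modulation operator (DAFM, global view) and a contextual
  attention block (CoT, static + dynamic view); the two branch outputs are
  summed elementwise and max-pooled along time.  DAFM splits channels into
  ``n_levels`` scales, applies 1x3 depthwise convolutions at progressively
  down-sampled temporal resolutions (nearest-neighbor up-sampling restores
  length), fuses the scales with a 1x1 convolution, and gates the input
  multiplicatively through a GELU of the fused map.  CoT forms a static
  context K1 by grouped 1xk convolution, derives per-position attention over
  each k-neighborhood from two stacked 1x1 convolutions on [K1, x], applies
  it to a 1x1-convolved value map to get the dynamic context K2, and returns
  K1 + K2.

* **Stage 3 — classifier.**  Global average pooling over time followed by
  two 1x1 convolutions; argmax over the class scores gives the prediction.

Every operation is exposed both as a plain-array function (for inspection
and oracle testing) and through the differentiable core used in training.
Ablation variants — no embedding, standard instead of depthwise-separable
convolution, DAFM/CoT removal, different ``n_levels`` and round counts —
are plain configuration toggles.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "ModelConfig",
    "ParameterStore",
    "embed",
    "depthwise_separable_conv",
    "dafm",
    "cot_attention",
    "stage2_round",
    "classify",
    "forward",
    "predict",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "model_summary",
]

CHECKPOINT_VERSION = 1
BN_EPS = 1e-5
BN_MOMENTUM = 0.1
# Width of the intermediate attention embedding in CoT, as a fraction of the
# 2C-channel [K1, Q] concatenation (reduction factor 4, per the CoT lineage).
COT_REDUCTION = 4


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Every architecture hyperparameter, fixed or open.

    Fixed by design: two scale levels inside DAFM, two stage-2 rounds and
    1x3 kernels.  Widths, the CoT kernel/grouping, pooling sizes and the
    classifier head are open choices with CPU-friendly defaults.
    """

    in_channels: int = 32
    embed_width: int = 16
    stage2_width: int = 32
    n_levels: int = 2
    dafm_pool: int = 2
    cot_kernel: int = 3
    cot_groups: int = 4
    rounds: int = 2
    maxpool_size: int = 2
    classifier_hidden: int = 64
    n_classes: int = 2
    activation: str = "gelu"
    # Ablation / dialect toggles
    use_embedding: bool = True
    conv_type: str = "dsc"  # "dsc" (depthwise separable) or "sc" (standard)
    use_dafm: bool = True
    use_cot: bool = True
    dafm_pool_mode: str = "max"  # or "avg"
    embed_raw_copy: bool = False  # concat raw input instead of 1x1 projection

    def __post_init__(self) -> None:
        counts = {
            "in_channels": self.in_channels, "embed_width": self.embed_width,
            "stage2_width": self.stage2_width, "n_levels": self.n_levels,
            "dafm_pool": self.dafm_pool, "cot_kernel": self.cot_kernel,
            "cot_groups": self.cot_groups, "rounds": self.rounds,
            "maxpool_size": self.maxpool_size,
            "classifier_hidden": self.classifier_hidden,
            "n_classes": self.n_classes,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be a positive count, got {v}")
        if self.stage2_width % self.n_levels:
            raise ValueError("stage2_width must be divisible by n_levels")
        if self.stage2_width % self.cot_groups:
            raise ValueError("stage2_width must be divisible by cot_groups")
        if self.cot_kernel % 2 != 1:
            raise ValueError("cot_kernel must be odd (same-padding)")
        if self.conv_type not in ("dsc", "sc"):
            raise ValueError("conv_type must be 'dsc' or 'sc'")
        if self.dafm_pool_mode not in ("max", "avg"):
            raise ValueError("dafm_pool_mode must be 'max' or 'avg'")
        if self.activation != "gelu":
            raise ValueError("only the GELU activation is supported")

    @property
    def hybrid_channels(self) -> int:
        """Channel count entering stage 2."""
        if not self.use_embedding:
            return self.in_channels
        if self.embed_raw_copy:
            return self.embed_width + self.in_channels
        return 2 * self.embed_width

    def with_overrides(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

class ParameterStore:
    """Named collection of weights, biases and normalization buffers."""

    def __init__(self, params: dict[str, np.ndarray],
                 buffers: dict[str, np.ndarray],
                 init_scheme: str = "fan_in_normal", seed: int = 0):
        self.params = params
        self.buffers = buffers
        self.init_scheme = init_scheme
        self.seed = seed

    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy(self) -> "ParameterStore":
        return ParameterStore(
            {k: v.copy() for k, v in self.params.items()},
            {k: v.copy() for k, v in self.buffers.items()},
            self.init_scheme, self.seed,
        )

    @staticmethod
    def initialize(cfg: ModelConfig, seed: int = 0,
                   dtype=np.float32) -> "ParameterStore":
        """Kaiming fan-in normal kernels, zero biases, unit BN scale."""
        rng = np.random.default_rng(seed)
        params: dict[str, np.ndarray] = {}
        buffers: dict[str, np.ndarray] = {}

        def conv(name: str, c_out: int, c_in_g: int, k: int) -> None:
            # Fan-in-scaled normal kernels with unit gain: the multiplicative
            # DAFM gating makes activation variance roughly quadratic in the
            # per-layer gain, so the usual ReLU gain of sqrt(2) is too hot.
            fan_in = c_in_g * k
            params[f"{name}.w"] = rng.normal(
                0.0, np.sqrt(1.0 / fan_in), size=(c_out, c_in_g, k)
            ).astype(dtype)
            params[f"{name}.b"] = np.zeros(c_out, dtype=dtype)

        def bn(name: str, c: int) -> None:
            params[f"{name}.gamma"] = np.ones(c, dtype=dtype)
            params[f"{name}.beta"] = np.zeros(c, dtype=dtype)
            buffers[f"{name}.running_mean"] = np.zeros(c, dtype=dtype)
            buffers[f"{name}.running_var"] = np.ones(c, dtype=dtype)

        c, e, w = cfg.in_channels, cfg.embed_width, cfg.stage2_width
        if cfg.use_embedding:
            conv("embed.conv1", e, c, 3)
            bn("embed.bn1", e)
            conv("embed.conv2", e, e, 3)
            bn("embed.bn2", e)
            conv("embed.conv3", e, e, 3)
            bn("embed.bn3", e)
            conv("embed.skip", e, c, 1)
            if not cfg.embed_raw_copy:
                conv("embed.proj", e, c, 1)

        c_in = cfg.hybrid_channels
        for r in range(cfg.rounds):
            p = f"round{r}"
            if cfg.conv_type == "dsc":
                conv(f"{p}.dw", c_in, 1, 3)  # depthwise: groups = c_in
                conv(f"{p}.pw", w, c_in, 1)
            else:
                conv(f"{p}.sc", w, c_in, 3)
            if cfg.use_dafm:
                cl = w // cfg.n_levels
                for lvl in range(cfg.n_levels):
                    conv(f"{p}.dafm.dw{lvl}", cl, 1, 3)
                conv(f"{p}.dafm.fuse", w, w, 1)
            if cfg.use_cot:
                k = cfg.cot_kernel
                mid = max(2 * w // COT_REDUCTION, 4)
                conv(f"{p}.cot.key", w, w // cfg.cot_groups, k)
                conv(f"{p}.cot.att1", mid, 2 * w, 1)
                conv(f"{p}.cot.att2", w * k, mid, 1)
                conv(f"{p}.cot.value", w, w, 1)
            c_in = w

        conv("cls.fc1", cfg.classifier_hidden, w, 1)
        conv("cls.fc2", cfg.n_classes, cfg.classifier_hidden, 1)
        return ParameterStore(params, buffers, seed=seed)


def count_parameters(cfg: ModelConfig) -> int:
    """Total learnable scalar count for a configuration."""
    return ParameterStore.initialize(cfg, seed=0).n_parameters()


# ---------------------------------------------------------------------------
# Differentiable core
# ---------------------------------------------------------------------------

def _lift_params(store: ParameterStore, requires_grad: bool) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=requires_grad) for k, v in store.params.items()}


def _batchnorm(x: Tensor, tp: dict[str, Tensor], store: ParameterStore,
               name: str, train: bool) -> Tensor:
    gamma = tp[f"{name}.gamma"].reshape(1, -1, 1)
    beta = tp[f"{name}.beta"].reshape(1, -1, 1)
    if train:
        mu = x.mean(axis=(0, 2), keepdims=True)
        var = (x - mu).pow(2).mean(axis=(0, 2), keepdims=True)
        rm = store.buffers[f"{name}.running_mean"]
        rv = store.buffers[f"{name}.running_var"]
        rm *= 1.0 - BN_MOMENTUM
        rm += BN_MOMENTUM * mu.data.reshape(-1).astype(rm.dtype)
        rv *= 1.0 - BN_MOMENTUM
        rv += BN_MOMENTUM * var.data.reshape(-1).astype(rv.dtype)
        xhat = (x - mu) / (var + BN_EPS).sqrt()
    else:
        rm = store.buffers[f"{name}.running_mean"][None, :, None]
        rv = store.buffers[f"{name}.running_var"][None, :, None]
        xhat = (x - rm) * (1.0 / np.sqrt(rv + BN_EPS))
    return xhat * gamma + beta


def _embed_core(x: Tensor, cfg: ModelConfig, tp: dict[str, Tensor],
                store: ParameterStore, train: bool) -> Tensor:
    h = x
    for i in (1, 2, 3):
        h = h.conv1d(tp[f"embed.conv{i}.w"], tp[f"embed.conv{i}.b"])
        h = _batchnorm(h, tp, store, f"embed.bn{i}", train).gelu()
    skip = x.conv1d(tp["embed.skip.w"], tp["embed.skip.b"])
    res = h + skip
    if cfg.embed_raw_copy:
        return concat([res, x], axis=1)
    proj = x.conv1d(tp["embed.proj.w"], tp["embed.proj.b"])
    return concat([res, proj], axis=1)


def _local_conv_core(x: Tensor, cfg: ModelConfig, tp: dict[str, Tensor],
                     prefix: str) -> Tensor:
    if cfg.conv_type == "dsc":
        c = x.shape[1]
        h = x.conv1d(tp[f"{prefix}.dw.w"], tp[f"{prefix}.dw.b"], groups=c)
        return h.conv1d(tp[f"{prefix}.pw.w"], tp[f"{prefix}.pw.b"])
    return x.conv1d(tp[f"{prefix}.sc.w"], tp[f"{prefix}.sc.b"])


def _dafm_core(x: Tensor, cfg: ModelConfig, tp: dict[str, Tensor],
               prefix: str) -> Tensor:
    n, c, t = x.shape
    if c % cfg.n_levels:
        raise ValueError(f"channels {c} not divisible by n_levels={cfg.n_levels}")
    if t < cfg.dafm_pool:
        raise ValueError(f"time length {t} shorter than dafm_pool={cfg.dafm_pool}")
    cl = c // cfg.n_levels
    branches = []
    for lvl in range(cfg.n_levels):
        xi = x.narrow(1, lvl * cl, cl)
        w, b = tp[f"{prefix}.dw{lvl}.w"], tp[f"{prefix}.dw{lvl}.b"]
        if lvl == 0:
            branches.append(xi.conv1d(w, b, groups=cl))
            continue
        factor = min(cfg.dafm_pool**lvl, t)
        down = xi.maxpool1d(factor) if cfg.dafm_pool_mode == "max" else xi.avgpool1d(factor)
        h = down.conv1d(w, b, groups=cl)
        up = h.upsample_nearest(factor)
        branches.append(up.pad_right_edge(t - up.shape[-1]))
    fused = concat(branches, axis=1).conv1d(
        tp[f"{prefix}.fuse.w"], tp[f"{prefix}.fuse.b"]
    )
    return fused.gelu() * x


def _cot_core(x: Tensor, cfg: ModelConfig, tp: dict[str, Tensor],
              prefix: str) -> Tensor:
    n, c, t = x.shape
    if c % cfg.cot_groups:
        raise ValueError(f"channels {c} not divisible by cot_groups={cfg.cot_groups}")
    k = cfg.cot_kernel
    k1 = x.conv1d(tp[f"{prefix}.key.w"], tp[f"{prefix}.key.b"], groups=cfg.cot_groups)
    qk = concat([k1, x], axis=1)
    a = qk.conv1d(tp[f"{prefix}.att1.w"], tp[f"{prefix}.att1.b"]).gelu()
    a = a.conv1d(tp[f"{prefix}.att2.w"], tp[f"{prefix}.att2.b"])
    attn = a.reshape(n, c, k, t).softmax(axis=2)
    v = x.conv1d(tp[f"{prefix}.value.w"], tp[f"{prefix}.value.b"])
    k2 = (attn * v.unfold1d(k)).sum(axis=2)
    return k1 + k2


def _round_core(x: Tensor, cfg: ModelConfig, tp: dict[str, Tensor],
                prefix: str) -> Tensor:
    if x.shape[-1] < cfg.maxpool_size:
        raise ValueError(
            f"time length {x.shape[-1]} shorter than maxpool_size={cfg.maxpool_size}"
        )
    h = _local_conv_core(x, cfg, tp, prefix)
    branches = []
    if cfg.use_dafm:
        branches.append(_dafm_core(h, cfg, tp, f"{prefix}.dafm"))
    if cfg.use_cot:
        branches.append(_cot_core(h, cfg, tp, f"{prefix}.cot"))
    s = branches[0] if branches else h
    for extra in branches[1:]:
        s = s + extra
    return s.maxpool1d(cfg.maxpool_size)


def _classify_core(x: Tensor, tp: dict[str, Tensor]) -> Tensor:
    gap = x.mean(axis=2, keepdims=True)
    h = gap.conv1d(tp["cls.fc1.w"], tp["cls.fc1.b"]).gelu()
    out = h.conv1d(tp["cls.fc2.w"], tp["cls.fc2.b"])
    return out.reshape(out.shape[0], out.shape[1])


def forward_core(x: Tensor, cfg: ModelConfig, tp: dict[str, Tensor],
                 store: ParameterStore, train: bool = False) -> Tensor:
    """Full differentiable forward pass on a (N, C, T) tensor."""
    if x.shape[1] != cfg.in_channels:
        raise ValueError(
            f"input has {x.shape[1]} channels, config expects {cfg.in_channels}"
        )
    if x.shape[-1] < cfg.maxpool_size**cfg.rounds:
        raise ValueError(
            f"time length {x.shape[-1]} too short for {cfg.rounds} rounds of "
            f"max pooling by {cfg.maxpool_size}"
        )
    h = _embed_core(x, cfg, tp, store, train) if cfg.use_embedding else x
    for r in range(cfg.rounds):
        h = _round_core(h, cfg, tp, f"round{r}")
    return _classify_core(h, tp)


# ---------------------------------------------------------------------------
# Plain-array operation surface
# ---------------------------------------------------------------------------

def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """(C, 1, T) or (N, C, 1, T) feature map -> (N, C, T), single? flag."""
    x = np.asarray(x)
    if x.ndim == 3 and x.shape[1] == 1:
        return x[None, :, 0, :], True
    if x.ndim == 4 and x.shape[2] == 1:
        return x[:, :, 0, :], False
    raise ValueError(
        f"expected a (C, 1, T) or (N, C, 1, T) feature map, got shape {x.shape}"
    )


def _from_batch(y: np.ndarray, single: bool) -> np.ndarray:
    out = y[:, :, None, :]
    return out[0] if single else out


def _run(op, x: np.ndarray, cfg: ModelConfig, store: ParameterStore) -> np.ndarray:
    xb, single = _as_batch(x)
    tp = _lift_params(store, requires_grad=False)
    out = op(Tensor(xb), tp)
    return _from_batch(out.data, single)


def embed(x: np.ndarray, cfg: ModelConfig, store: ParameterStore) -> np.ndarray:
    """Stage-1 hybrid representation (residual embedding ++ projected input)."""
    return _run(lambda t, tp: _embed_core(t, cfg, tp, store, train=False), x, cfg, store)


def depthwise_separable_conv(x: np.ndarray, cfg: ModelConfig,
                             store: ParameterStore, round_index: int = 0) -> np.ndarray:
    """Per-channel 1x3 convolution then 1x1 cross-channel mixing."""
    return _run(lambda t, tp: _local_conv_core(t, cfg, tp, f"round{round_index}"),
                x, cfg, store)


def dafm(x: np.ndarray, cfg: ModelConfig, store: ParameterStore,
         round_index: int = 0) -> np.ndarray:
    """Directional adaptive feature modulation (GELU-gated multi-scale map)."""
    return _run(lambda t, tp: _dafm_core(t, cfg, tp, f"round{round_index}.dafm"),
                x, cfg, store)


def cot_attention(x: np.ndarray, cfg: ModelConfig, store: ParameterStore,
                  round_index: int = 0) -> np.ndarray:
    """Contextual attention: static grouped-conv context + dynamic context."""
    return _run(lambda t, tp: _cot_core(t, cfg, tp, f"round{round_index}.cot"),
                x, cfg, store)


def stage2_round(x: np.ndarray, cfg: ModelConfig, store: ParameterStore,
                 round_index: int = 0) -> np.ndarray:
    """One multi-angle round: local conv -> DAFM + CoT -> sum -> max pool."""
    return _run(lambda t, tp: _round_core(t, cfg, tp, f"round{round_index}"),
                x, cfg, store)


def classify(x: np.ndarray, cfg: ModelConfig, store: ParameterStore) -> np.ndarray:
    """Global average pooling and the two-layer 1x1 head; returns class scores."""
    xb, single = _as_batch(x)
    tp = _lift_params(store, requires_grad=False)
    out = _classify_core(Tensor(xb), tp).data
    return out[0] if single else out


def forward(x: np.ndarray, cfg: ModelConfig, store: ParameterStore) -> np.ndarray:
    """Full inference pass; returns (n_classes,) or (N, n_classes) scores."""
    xb, single = _as_batch(x)
    tp = _lift_params(store, requires_grad=False)
    out = forward_core(Tensor(xb), cfg, tp, store, train=False).data
    return out[0] if single else out


def predict(x: np.ndarray, cfg: ModelConfig, store: ParameterStore) -> np.ndarray:
    """Argmax labels; ties break toward the lower class index."""
    scores = forward(x, cfg, store)
    return np.argmax(scores, axis=-1)


# ---------------------------------------------------------------------------
# Checkpointing and summaries
# ---------------------------------------------------------------------------

def save_checkpoint(path, store: ParameterStore, cfg: ModelConfig) -> None:
    """Single-file container for parameters + buffers + config (bit-exact)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = CHECKPOINT_VERSION
        f.attrs["config"] = json.dumps(asdict(cfg))
        f.attrs["init_scheme"] = store.init_scheme
        f.attrs["seed"] = store.seed
        gp = f.create_group("params")
        for k, v in store.params.items():
            gp.create_dataset(k, data=v)
        gb = f.create_group("buffers")
        for k, v in store.buffers.items():
            gb.create_dataset(k, data=v)


def load_checkpoint(path) -> tuple[ParameterStore, ModelConfig]:
    import h5py

    with h5py.File(path, "r") as f:
        if int(f.attrs["format_version"]) != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {f.attrs['format_version']}")
        cfg = ModelConfig(**json.loads(f.attrs["config"]))
        params = {k: f["params"][k][()] for k in f["params"]}
        buffers = {k: f["buffers"][k][()] for k in f["buffers"]}
        store = ParameterStore(params, buffers,
                               init_scheme=str(f.attrs["init_scheme"]),
                               seed=int(f.attrs["seed"]))
    return store, cfg


def model_summary(cfg: ModelConfig) -> str:
    """Layer table with shapes and the total learnable parameter count."""
    store = ParameterStore.initialize(cfg, seed=0)
    buf = io.StringIO()
    buf.write(f"{'parameter':<28}{'shape':<18}{'count':>10}\n")
    buf.write("-" * 56 + "\n")
    for k, v in store.params.items():
        buf.write(f"{k:<28}{str(v.shape):<18}{v.size:>10}\n")
    buf.write("-" * 56 + "\n")
    buf.write(f"{'total':<46}{store.n_parameters():>10}\n")
    return buf.getvalue()
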