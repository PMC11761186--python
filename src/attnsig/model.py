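"""Attention-augmented convolutional survival classifier.

The network is a four-stage convolutional backbone with two interpolation
attention modules. Attention module 1 gates the stage-1 feature map with a
spatial signal derived from stage 2; module 2 gates stage 3 with a signal
from stage 4. Each module projects the deeper feature map to a single
channel (1x1 convolution), squashes it through a sigmoid, bilinearly
upsamples it to the shallower map's grid, scales the shallow features by
the gate and global-average-pools the result. The pooled attention vectors
are concatenated with the backbone's output vector and fed through a
three-layer fully connected head (128/32/2 units, ReLU + dropout 0.2)
ending in a softmax.

With the ``resnet101-like`` backbone (stage widths 256/512/1024/2048,
backbone output 1000) the concatenated vector is 1000 + 256 + 1024 = 2280
wide. A ``tiny`` backbone (8/16/32/64, output 50; concat width 90) keeps
the same topology at a scale trainable on one CPU.

Training minimises the focal loss (mean of -alpha * (1-p_t)^gamma * ln p_t).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn.layers import (
    DTYPE, Module, Conv2d, BatchNorm2d, ReLU, Sigmoid, Linear, Dropout,
    GlobalAvgPool, Sequential, upsample_bilinear, bilinear_matrices,
)

#: Backbone registry: stem (channels, kernel, stride) or None, per-stage
#: output channels, per-stage strides, and backbone output width.
BACKBONES: dict[str, dict] = {
    "resnet101-like": {
        "stem": (64, 7, 4),
        "stages": (256, 512, 1024, 2048),
        "strides": (1, 2, 2, 2),
        "out": 1000,
    },
    "tiny": {
        "stem": None,
        "stages": (8, 16, 32, 64),
        "strides": (2, 2, 2, 2),
        "out": 50,
    },
}


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``stage_channels``/``backbone_out`` default to the registry entry for
    ``backbone`` and may be overridden for custom desk-scale variants.
    """

    input_size: int = 1024
    batch_size: int = 6
    backbone: str = "resnet101-like"
    stage_channels: tuple[int, int, int, int] | None = None
    stage_strides: tuple[int, int, int, int] | None = None
    stem: tuple[int, int, int] | None | str = "auto"
    backbone_out: int | None = None
    head_widths: tuple[int, ...] = (128, 32, 2)
    dropout_rate: float = 0.2
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ConfigurationError(
                f"unknown backbone {self.backbone!r}; known: {sorted(BACKBONES)}")
        spec = BACKBONES[self.backbone]
        if self.stage_channels is None:
            self.stage_channels = tuple(spec["stages"])
        if self.stage_strides is None:
            self.stage_strides = tuple(spec["strides"])
        if self.stem == "auto":
            self.stem = spec["stem"]
        if self.backbone_out is None:
            self.backbone_out = spec["out"]
        if self.head_widths[-1] != 2:
            raise ConfigurationError("head must end in 2 output units")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if any(c <= 0 for c in self.stage_channels) or self.backbone_out <= 0:
            raise ConfigurationError("channel widths must be positive")
        if self.pretrained:
            raise ConfigurationError(
                "no pretrained weight source is bundled; load weights with "
                "load_checkpoint() instead of pretrained=True")

    @property
    def concat_width(self) -> int:
        """Width of the vector fed to the head: backbone output plus the
        stage-1 and stage-3 pooled attention vectors."""
        return self.backbone_out + self.stage_channels[0] + self.stage_channels[2]

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size, "batch_size": self.batch_size,
            "backbone": self.backbone, "stage_channels": list(self.stage_channels),
            "stage_strides": list(self.stage_strides),
            "stem": list(self.stem) if self.stem else None,
            "backbone_out": self.backbone_out,
            "head_widths": list(self.head_widths),
            "dropout_rate": self.dropout_rate, "pretrained": False,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("stage_channels", "stage_strides", "head_widths"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("stem") is not None:
            d["stem"] = tuple(d["stem"])
        return cls(**d)


@dataclass
class FocalLossParams:
    gamma: float = 2.0
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class AttentionOutput:
    """Per-image pooled attention vectors and module-2 spatial gate map."""

    att1_vector: np.ndarray
    att2_vector: np.ndarray
    att2_map: np.ndarray


@dataclass
class ForwardResult:
    logits: np.ndarray
    probabilities: np.ndarray
    attention: list[AttentionOutput]


class AttentionGate(Module):
    """Interpolation attention: 1x1 projection of the deep map -> sigmoid ->
    corner-aligned bilinear upsample to the shallow grid -> elementwise gate
    of the shallow features -> global average pool."""

    def __init__(self, c_deep: int, rng: np.random.Generator, name: str) -> None:
        super().__init__()
        self.proj = Conv2d(c_deep, 1, 1, stride=1, pad=0, rng=rng, name=f"{name}.proj")
        self.sig = Sigmoid()
        self._cache = None

    def forward(self, shallow: np.ndarray, deep: np.ndarray):
        hs, ws = shallow.shape[2], shallow.shape[3]
        if deep.shape[2] > hs or deep.shape[3] > ws:
            raise ValueError("deep grid must not exceed the shallow grid")
        gate_small = self.sig.forward(self.proj.forward(deep))
        r, c = bilinear_matrices(gate_small.shape[2], gate_small.shape[3], hs, ws)
        gate = np.einsum("ij,ncjk,lk->ncil", r, gate_small, c, optimize=True)
        gated = shallow * gate
        vec = gated.mean(axis=(2, 3))
        self._cache = (shallow, gate, r, c)
        return vec, gate, gate_small

    def backward(self, dvec: np.ndarray):
        shallow, gate, r, c = self._cache
        self._cache = None
        n, ch, hs, ws = shallow.shape
        dgated = np.broadcast_to(dvec[:, :, None, None], shallow.shape) / (hs * ws)
        dshallow = dgated * gate
        dgate = (dgated * shallow).sum(axis=1, keepdims=True)
        dgate_small = np.einsum("ji,ncjk,kl->ncil", r, dgate, c, optimize=True)
        ddeep = self.proj.backward(self.sig.backward(dgate_small))
        return dshallow, ddeep


def _stage(c_in: int, c_out: int, k: int, stride: int,
           rng: np.random.Generator, name: str) -> Sequential:
    return Sequential(
        Conv2d(c_in, c_out, k, stride=stride, rng=rng, name=name),
        BatchNorm2d(c_out, name=f"{name}.bn"),
        ReLU(),
    )


class AttentionNet(Module):
    """The full classifier. Use :func:`build_model` to construct one."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        super().__init__()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        c1, c2, c3, c4 = config.stage_channels
        s1, s2, s3, s4 = config.stage_strides
        c_prev = 3
        self.stem = None
        if config.stem is not None:
            sc, sk, ss = config.stem
            self.stem = _stage(3, sc, sk, ss, rng, "stem")
            c_prev = sc
        self.stage1 = _stage(c_prev, c1, 3, s1, rng, "stage1")
        self.stage2 = _stage(c1, c2, 3, s2, rng, "stage2")
        self.stage3 = _stage(c2, c3, 3, s3, rng, "stage3")
        self.stage4 = _stage(c3, c4, 3, s4, rng, "stage4")
        self.att1 = AttentionGate(c2, rng, "att1")
        self.att2 = AttentionGate(c4, rng, "att2")
        self.gap = GlobalAvgPool()
        self.fc = Linear(c4, config.backbone_out, rng=rng, name="backbone_fc")
        widths = [config.concat_width, *config.head_widths]
        head: list[Module] = []
        self._dropouts: list[Dropout] = []
        for i in range(len(widths) - 1):
            head.append(Linear(widths[i], widths[i + 1], rng=rng, name=f"head{i}"))
            if i < len(widths) - 2:
                head.append(ReLU())
                drop = Dropout(config.dropout_rate)
                self._dropouts.append(drop)
                head.append(drop)
        self.head = Sequential(*head)
        self.set_dropout_seed(self.seed + 1)
        self._split = (config.backbone_out, c1, c3)

    def set_dropout_seed(self, seed: int) -> None:
        rng = np.random.default_rng(int(seed))
        for d in self._dropouts:
            d.rng = rng

    def forward_batch(self, x: np.ndarray) -> ForwardResult:
        """Run a (N, 3, H, W) standardized batch through the network."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        h = self.stem.forward(x) if self.stem is not None else x
        a1 = self.stage1.forward(h)
        a2 = self.stage2.forward(a1)
        a3 = self.stage3.forward(a2)
        a4 = self.stage4.forward(a3)
        v1, _, _ = self.att1.forward(a1, a2)
        v2, _, gmap2 = self.att2.forward(a3, a4)
        f = self.fc.forward(self.gap.forward(a4))
        concat = np.concatenate([f, v1, v2], axis=1)
        logits = self.head.forward(concat)
        probs = softmax(logits)
        attention = [
            AttentionOutput(v1[i].copy(), v2[i].copy(), gmap2[i, 0].copy())
            for i in range(x.shape[0])
        ]
        return ForwardResult(logits, probs, attention)

    def backward_batch(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for the last forward_batch call."""
        dcat = self.head.backward(dlogits)
        o, c1, c3 = self._split
        df, dv1, dv2 = dcat[:, :o], dcat[:, o:o + c1], dcat[:, o + c1:]
        da4 = self.gap.backward(self.fc.backward(df))
        ds3_att, ds4_att = self.att2.backward(dv2)
        da3 = self.stage4.backward(da4 + ds4_att) + ds3_att
        ds1_att, ds2_att = self.att1.backward(dv1)
        da2 = self.stage3.backward(da3) + ds2_att
        da1 = self.stage2.backward(da2) + ds1_att
        dh = self.stage1.backward(da1)
        if self.stem is not None:
            self.stem.backward(dh)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(config: ModelConfig, seed: int = 0) -> AttentionNet:
    """Construct an :class:`AttentionNet` with deterministic initialization."""
    return AttentionNet(config, seed=seed)


def standardize_tile(image: np.ndarray) -> np.ndarray:
    """Per-channel standardization of an (H, W, 3) image to mean 0, std 1;
    returns a float32 (3, H, W) array."""
    img = np.asarray(image, dtype=DTYPE)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got {img.shape}")
    x = img.transpose(2, 0, 1)
    mean = x.mean(axis=(1, 2), keepdims=True)
    std = x.std(axis=(1, 2), keepdims=True)
    return (x - mean) / np.maximum(std, 1e-6)


def forward(model: AttentionNet, images: np.ndarray) -> ForwardResult:
    """Evaluation-mode forward pass over raw (N, H, W, 3) RGB images.

    Images are standardized per channel; the batch must match the model's
    configured input size.
    """
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValueError(f"expected (N, H, W, 3) images, got {images.shape}")
    s = model.config.input_size
    if images.shape[1] != s or images.shape[2] != s:
        raise ValueError(
            f"images must be {s}x{s} for this model, got {images.shape[1:3]}")
    x = np.stack([standardize_tile(im) for im in images])
    model.eval()
    return model.forward_batch(x)


EPS_PROB = 1e-7


def focal_loss(probabilities: np.ndarray, targets: np.ndarray,
               params: FocalLossParams | None = None) -> float:
    """Mean focal loss -alpha * (1 - p_t)^gamma * ln(p_t) over the batch."""
    params = params or FocalLossParams()
    p = np.asarray(probabilities, dtype=float)
    t = np.asarray(targets)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("probabilities must be (N, 2)")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("targets must be binary")
    p_t = np.clip(p[np.arange(len(t)), t.astype(int)], EPS_PROB, 1.0)
    return float(np.mean(-params.alpha * (1.0 - p_t) ** params.gamma * np.log(p_t)))


def focal_loss_grad(probabilities: np.ndarray, targets: np.ndarray,
                    params: FocalLossParams | None = None) -> np.ndarray:
    """Gradient of the mean focal loss with respect to the logits."""
    params = params or FocalLossParams()
    p = np.asarray(probabilities, dtype=float)
    t = np.asarray(targets).astype(int)
    n = len(t)
    p_t = np.clip(p[np.arange(n), t], EPS_PROB, 1.0 - EPS_PROB)
    q = 1.0 - p_t
    # d/dp_t of -alpha * q^gamma * ln(p_t), divided by N for the mean
    if params.gamma == 0:
        dldpt = -params.alpha / p_t / n
    else:
        dldpt = params.alpha * (params.gamma * q ** (params.gamma - 1) * np.log(p_t)
                                - q ** params.gamma / p_t) / n
    onehot = np.zeros_like(p)
    onehot[np.arange(n), t] = 1.0
    return (dldpt * p_t)[:, None] * (onehot - p)


def attention_heatmap(model: AttentionNet, image: np.ndarray) -> np.ndarray:
    """Attention-module-2 gate map for one image, upsampled to image
    resolution and min-max normalized to [0, 1] (constant maps -> zeros)."""
    res = forward(model, np.asarray(image)[None])
    gate = res.attention[0].att2_map
    h, w = image.shape[0], image.shape[1]
    up = upsample_bilinear(gate, h, w)
    lo, hi = float(up.min()), float(up.max())
    if hi - lo < 1e-12:
        return np.zeros((h, w), dtype=DTYPE)
    return ((up - lo) / (hi - lo)).astype(DTYPE)


def attention_saliency(model: AttentionNet, image: np.ndarray) -> np.ndarray:
    """Score-weighted attention map for one image.

    The raw module-2 gate is sign-ambiguous: a model may gate informative
    regions either up or down and let the head absorb the sign, so the
    gate alone does not say which regions *support* the positive (long
    survival) class. The overlay therefore weights the gate by the
    sensitivity of the logit margin to it: M = g * d(logit1 - logit0)/dg,
    evaluated at the gate's spatial grid, bilinearly upsampled to image
    resolution and min-max normalized to [0, 1] (constant maps -> zeros).
    """
    img = np.asarray(image)
    x = standardize_tile(img)[None].astype(DTYPE)
    model.eval()
    h = model.stem.forward(x) if model.stem is not None else x
    a1 = model.stage1.forward(h)
    a2 = model.stage2.forward(a1)
    a3 = model.stage3.forward(a2)
    a4 = model.stage4.forward(a3)
    v1, _, _ = model.att1.forward(a1, a2)
    v2, gate, _ = model.att2.forward(a3, a4)
    f = model.fc.forward(model.gap.forward(a4))
    model.head.forward(np.concatenate([f, v1, v2], axis=1))
    dcat = model.head.backward(np.array([[-1.0, 1.0]], dtype=DTYPE))
    model.zero_grad()
    o, c1, _ = model._split
    dv2 = dcat[:, o + c1:]
    _, _, hs, ws = a3.shape
    dgated = np.broadcast_to(dv2[:, :, None, None], a3.shape) / (hs * ws)
    dgate = (dgated * a3).sum(axis=1)
    sal = (gate[:, 0] * dgate)[0]
    up = upsample_bilinear(sal, img.shape[0], img.shape[1])
    lo, hi = float(up.min()), float(up.max())
    if hi - lo < 1e-12:
        return np.zeros(img.shape[:2], dtype=DTYPE)
    return ((up - lo) / (hi - lo)).astype(DTYPE)


def heatmap_overlay(image: np.ndarray, heatmap: np.ndarray,
                    alpha: float = 0.45) -> np.ndarray:
    """Blend a [0,1] heatmap over an RGB image with a blue-to-red colormap;
    returns a uint8 RGB array (a red-blue density map)."""
    from matplotlib import cm

    rgb = np.asarray(image, dtype=float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    colored = cm.get_cmap("coolwarm")(np.clip(heatmap, 0, 1))[..., :3]
    blend = (1 - alpha) * rgb + alpha * colored
    return (np.clip(blend, 0, 1) * 255).astype(np.uint8)


def save_checkpoint(model: AttentionNet, path) -> None:
    """Serialize parameters, batch-norm statistics, config and seed."""
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"param_{i:03d}"] = p.value
    for i, m in enumerate(model.modules()):
        if isinstance(m, BatchNorm2d):
            arrays[f"bn_{i:03d}_mean"] = m.running_mean
            arrays[f"bn_{i:03d}_var"] = m.running_var
    meta = json.dumps({"config": model.config.to_dict(), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> AttentionNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = AttentionNet(ModelConfig.from_dict(meta["config"]), seed=meta["seed"])
        for i, p in enumerate(model.parameters()):
            p.value = data[f"param_{i:03d}"].astype(DTYPE)
            p.grad = np.zeros_like(p.value)
        for i, m in enumerate(model.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = data[f"bn_{i:03d}_mean"].astype(DTYPE)
                m.running_var = data[f"bn_{i:03d}_var"].astype(DTYPE)
    return model
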