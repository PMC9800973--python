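"""The pest detector: YOLOv5s-style topology with CLA attention and GSPPF.

Architecture (strides 8/16/32, three anchored detection scales):

* backbone — a 6×6 stride-2 convolution stem (the successor of the Focus
  slicing block), alternating stride-2 convs and CSP1_X cross-stage-partial
  blocks; with ``use_cla`` each backbone CSP1_X is followed by a CLA block
  (CLA-CSP1_X), recalibrating its output;
* the deepest map passes through SPPF, or GSPPF when ``use_gsppf``;
* neck — FPN top-down fusion followed by a PAN bottom-up path, built from
  shortcut-free CSP2_X blocks;
* head — one 1×1 conv per scale emitting 3 anchors × (4 box + 1 objectness
  + num_classes) channels per cell.

Width/depth multipliers scale the nominal channel plan [64, 128, 256, 512,
1024] and repeat counts [3, 6, 9, 3]; the published small variant uses
0.50 / 0.33.  All activations are SiLU except inside CLA (Leaky ReLU).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np

from .attention import CoordLocalAttention
from .nn import ConvBnSiLU, Conv2d, Module, ModuleList, Tensor, concat, profile_record, upsample2x
from .pooling import GSPPF, SPPF

# default anchor priors (input-image pixels), three per stride 8 / 16 / 32
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)
STRIDES = (8, 16, 32)


@dataclass
class AnchorSet:
    """Nine (w, h) priors in input pixels, grouped three per stride."""

    anchors: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_ANCHORS, dtype=np.float64))
    strides: tuple = STRIDES

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=np.float64)
        if self.anchors.shape != (3, 3, 2):
            raise ValueError(f"expected anchors of shape (3,3,2), got {self.anchors.shape}")
        if (self.anchors <= 0).any():
            raise ValueError("anchor dimensions must be positive")
        if list(self.strides) != sorted(self.strides):
            raise ValueError("anchor groups must be sorted by stride ascending")


@dataclass
class ModelConfig:
    num_classes: int = 24
    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    input_size: int = 640
    use_cla: bool = True
    use_gsppf: bool = True
    cla_reduction: int = 32
    cla_negative_slope: float = 0.1
    cla_bounded_local: bool = False
    anchors: tuple = DEFAULT_ANCHORS
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise ValueError(f"input_size must be divisible by 32, got {self.input_size}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    def anchor_set(self) -> AnchorSet:
        return AnchorSet(np.array(self.anchors, dtype=np.float64))


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(math.ceil(x / divisor) * divisor))


class Bottleneck(Module):
    def __init__(self, c: int, shortcut: bool = True, rng=None):
        super().__init__()
        self.cv1 = ConvBnSiLU(c, c, 1, rng=rng)
        self.cv2 = ConvBnSiLU(c, c, 3, rng=rng)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class CSP(Module):
    """Cross-stage-partial block (CSP1_X with shortcuts; CSP2_X without)."""

    def __init__(self, cin: int, cout: int, n: int = 1, shortcut: bool = True, rng=None):
        super().__init__()
        c_ = cout // 2
        self.cv1 = ConvBnSiLU(cin, c_, 1, rng=rng)
        self.cv2 = ConvBnSiLU(cin, c_, 1, rng=rng)
        self.m = ModuleList([Bottleneck(c_, shortcut, rng=rng) for _ in range(n)])
        self.cv3 = ConvBnSiLU(2 * c_, cout, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(concat([y, self.cv2(x)], axis=1))


class Detector(Module):
    """Full detection network; ``forward`` yields three raw prediction grids."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        gw, gd = cfg.width_multiple, cfg.depth_multiple
        ch = [make_divisible(c * gw) for c in (64, 128, 256, 512, 1024)]
        n = [max(round(r * gd), 1) for r in (3, 6, 9, 3)]
        self.channels, self.repeats = ch, n
        c1, c2, c3, c4, c5 = ch

        def cla(c):
            r = min(cfg.cla_reduction, c)
            return CoordLocalAttention(c, r, cfg.cla_negative_slope,
                                       bounded_local=cfg.cla_bounded_local, rng=rng)

        # backbone
        self.stem = ConvBnSiLU(3, c1, 6, 2, rng=rng)
        self.stem.conv.padding = 2
        self.down1 = ConvBnSiLU(c1, c2, 3, 2, rng=rng)
        self.csp1 = CSP(c2, c2, n[0], rng=rng)
        self.down2 = ConvBnSiLU(c2, c3, 3, 2, rng=rng)
        self.csp2 = CSP(c3, c3, n[1], rng=rng)
        self.down3 = ConvBnSiLU(c3, c4, 3, 2, rng=rng)
        self.csp3 = CSP(c4, c4, n[2], rng=rng)
        self.down4 = ConvBnSiLU(c4, c5, 3, 2, rng=rng)
        self.csp4 = CSP(c5, c5, n[3], rng=rng)
        if cfg.use_cla:
            self.cla1, self.cla2 = cla(c2), cla(c3)
            self.cla3, self.cla4 = cla(c4), cla(c5)
        if cfg.use_gsppf:
            self.spp = GSPPF(c5, c5, rng=rng)
        else:
            self.spp = SPPF(c5, c5, rng=rng)

        # neck: FPN (top-down) + PAN (bottom-up)
        self.lat5 = ConvBnSiLU(c5, c4, 1, rng=rng)
        self.fpn4 = CSP(2 * c4, c4, n[3], shortcut=False, rng=rng)
        self.lat4 = ConvBnSiLU(c4, c3, 1, rng=rng)
        self.fpn3 = CSP(2 * c3, c3, n[3], shortcut=False, rng=rng)
        self.pan3 = ConvBnSiLU(c3, c3, 3, 2, rng=rng)
        self.pan_csp4 = CSP(2 * c3, c4, n[3], shortcut=False, rng=rng)
        self.pan4 = ConvBnSiLU(c4, c4, 3, 2, rng=rng)
        self.pan_csp5 = CSP(2 * c4, c5, n[3], shortcut=False, rng=rng)

        # head: one 1x1 conv per scale, 3 anchors x (5 + nc) channels
        no = 3 * (5 + cfg.num_classes)
        self.heads = ModuleList([Conv2d(c, no, 1, rng=rng) for c in (c3, c4, c5)])
        self._init_head_biases()

    def _init_head_biases(self):
        """Prior-aware bias init: rare objectness, near-uniform classes."""
        nc = self.cfg.num_classes
        for head, s in zip(self.heads, STRIDES):
            b = head.bias.data.reshape(3, 5 + nc)
            b[:, 4] += math.log(8 / (self.cfg.input_size / s) ** 2)
            b[:, 5:] += math.log(0.6 / (nc - 0.99)) if nc > 1 else 0.0
            head.bias.data[...] = b.reshape(-1)

    def forward(self, x, capture: dict | None = None):
        """x: (N, 3, H, W) with H, W divisible by 32.

        Returns three tensors of shape (N, 3, S, S, 5 + nc) at strides
        8, 16, 32 — raw logits, no activation applied.
        """
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        cfg = self.cfg
        y = self.stem(t)
        y = self.csp1(self.down1(y))
        if cfg.use_cla:
            y = self.cla1(y)
        y = self.csp2(self.down2(y))
        if cfg.use_cla:
            y = self.cla2(y)
        p3 = y
        y = self.csp3(self.down3(y))
        if cfg.use_cla:
            y = self.cla3(y)
        p4 = y
        y = self.csp4(self.down4(y))
        if cfg.use_cla:
            y = self.cla4(y)
        p5 = self.spp(y)

        lat5 = self.lat5(p5)
        f4 = self.fpn4(concat([upsample2x(lat5), p4], axis=1))
        lat4 = self.lat4(f4)
        f3 = self.fpn3(concat([upsample2x(lat4), p3], axis=1))
        o3 = f3
        o4 = self.pan_csp4(concat([self.pan3(f3), lat4], axis=1))
        o5 = self.pan_csp5(concat([self.pan4(o4), lat5], axis=1))
        if capture is not None:
            for name, v in [("P3", o3), ("P4", o4), ("P5", o5)]:
                capture[name] = v.data.shape

        outs = []
        nc = cfg.num_classes
        for head, feat in zip(self.heads, (o3, o4, o5)):
            raw = head(feat)
            nb, _, s1, s2 = raw.shape
            raw = raw.reshape(nb, 3, 5 + nc, s1, s2).transpose((0, 1, 3, 4, 2))
            outs.append(raw)
        return outs


def build_model(cfg: ModelConfig) -> Detector:
    return Detector(cfg)


class Detection(NamedTuple):
    """One detection: half-open pixel box, class index, confidence."""

    box: tuple            # (x1, y1, x2, y2) absolute pixels
    class_id: int
    score: float


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def decode_predictions(raw, anchors: AnchorSet, conf_thr: float = 0.25,
                       input_size: int | None = None) -> list[Detection]:
    """Decode raw grids for ONE image into detections above ``conf_thr``.

    Per cell and anchor: center = (2σ(t_xy) − 0.5 + cell)·stride,
    size = (2σ(t_wh))²·anchor, score = σ(obj)·max_c σ(cls_c).  Boxes are
    clipped to the image square.
    """
    if isinstance(raw, (Tensor,)):
        raw = raw.data
    if isinstance(raw, np.ndarray):
        raw = [raw]
    raw = [r.data if isinstance(r, Tensor) else np.asarray(r) for r in raw]
    dets: list[Detection] = []
    for level, r in enumerate(raw):
        if r.ndim == 5:
            if r.shape[0] != 1:
                raise ValueError("decode_predictions expects a single image")
            r = r[0]
        na, s1, s2 = r.shape[:3]
        stride = anchors.strides[level]
        size = input_size if input_size is not None else s1 * stride
        if s1 * stride != size and s2 * stride != size:
            raise ValueError(
                f"grid {s1}x{s2} at stride {stride} does not match input size {size}")
        anc = anchors.anchors[level]
        if na != anc.shape[0]:
            raise ValueError(f"anchor/stride group mismatch at level {level}")
        sig = _sigmoid(r.astype(np.float64))
        gy, gx = np.meshgrid(np.arange(s1), np.arange(s2), indexing="ij")
        cx = (2 * sig[..., 0] - 0.5 + gx) * stride
        cy = (2 * sig[..., 1] - 0.5 + gy) * stride
        bw = (2 * sig[..., 2]) ** 2 * anc[:, None, None, 0]
        bh = (2 * sig[..., 3]) ** 2 * anc[:, None, None, 1]
        cls_scores = sig[..., 5:]
        best = cls_scores.argmax(axis=-1)
        score = sig[..., 4] * np.take_along_axis(cls_scores, best[..., None], -1)[..., 0]
        keep = score >= conf_thr
        for a, i, j in zip(*np.nonzero(keep)):
            x1 = np.clip(cx[a, i, j] - bw[a, i, j] / 2, 0, size)
            y1 = np.clip(cy[a, i, j] - bh[a, i, j] / 2, 0, size)
            x2 = np.clip(cx[a, i, j] + bw[a, i, j] / 2, 0, size)
            y2 = np.clip(cy[a, i, j] + bh[a, i, j] / 2, 0, size)
            if x2 > x1 and y2 > y1:
                dets.append(Detection((float(x1), float(y1), float(x2), float(y2)),
                                      int(best[a, i, j]), float(score[a, i, j])))
    return dets


# -- profiling (architecture numbers) --------------------------------------

_PROFILE_BASE = 64  # smallest input all strides divide; MACs scale as (size/base)^2


@dataclass
class ModelProfile:
    parameter_count: int
    gflops: float


def count_parameters(model: Module) -> int:
    """Exact count of learnable scalars (conv weights/biases, BN affine)."""
    return model.num_parameters()


def count_flops(model: Detector, input_size: int | None = None) -> float:
    """Forward-pass cost in GFLOPs: 2 x multiply-accumulates (+ bias adds).

    The net is fully convolutional, so per-conv MACs at any input size are
    the MACs measured at a small reference size scaled by the pixel ratio;
    the measurement runs a real forward pass, so layer bookkeeping is taken
    from the executed graph, not from a hand-maintained table.
    """
    input_size = input_size or model.cfg.input_size
    if input_size % 32 != 0:
        raise ValueError("input_size must be divisible by 32")
    was_training = model.training
    model.eval()
    with profile_record() as prof_a:
        model(np.zeros((1, 3, _PROFILE_BASE, _PROFILE_BASE), dtype=np.float32))
    with profile_record() as prof_b:
        model(np.zeros((1, 3, 2 * _PROFILE_BASE, 2 * _PROFILE_BASE), dtype=np.float32))
    if was_training:
        model.train()
    # per-conv scaling exponent: output pixels grow as (size/base)^e with
    # e = 2 for spatial maps, 1 for the pooled (H+W)-profile convs in CLA,
    # measured by doubling the reference input
    ratio = input_size / _PROFILE_BASE
    flops = 0.0
    for ra, rb in zip(prof_a.records, prof_b.records):
        e = math.log2(rb["out_pixels"] / ra["out_pixels"])
        f = 2.0 * ra["macs_per_pixel"] * ra["out_pixels"] + ra["bias_elems"]
        flops += f * ratio ** e
    return flops / 1e9


def profile_model(model: Detector, input_size: int | None = None) -> ModelProfile:
    return ModelProfile(count_parameters(model), count_flops(model, input_size))


def summary(model: Detector) -> str:
    """Plain-text architecture summary: block name, parameters, output shape."""
    capture: dict = {}
    model_was_training = model.training
    model.eval()
    model(np.zeros((1, 3, _PROFILE_BASE, _PROFILE_BASE), dtype=np.float32), capture=capture)
    if model_was_training:
        model.train()
    k = model.cfg.input_size // _PROFILE_BASE
    buf = io.StringIO()
    total = 0
    buf.write(f"{'block':<12}{'params':>12}\n")
    for name, mod in model._modules.items():
        p = mod.num_parameters()
        total += p
        buf.write(f"{name:<12}{p:>12,}\n")
    buf.write(f"{'total':<12}{total:>12,}\n")
    for name, shp in capture.items():
        n, c, h, w = shp
        buf.write(f"{name}: ({c}, {h * k}, {w * k})\n")
    buf.write(f"GFLOPs@{model.cfg.input_size}: {count_flops(model):.2f}\n")
    return buf.getvalue()


# -- checkpoint I/O ---------------------------------------------------------

def save_checkpoint(model: Detector, path, extra: dict | None = None):
    """Single-file checkpoint: JSON config + named weight/buffer arrays."""
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for key, val in model.state_dict().items():
        arrays["w:" + key] = val
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[Detector, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        cfg_d = meta["config"]
        cfg_d["anchors"] = tuple(tuple(tuple(a) for a in lvl) for lvl in cfg_d["anchors"])
        cfg = ModelConfig(**cfg_d)
        model = Detector(cfg)
        model.load_state_dict({k[2:]: z[k] for k in z.files if k.startswith("w:")})
    return model, meta["extra"]
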