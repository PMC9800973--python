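"""Target assignment, losses, online augmentations and the training loop.

Loss semantics follow the anchored-YOLO lineage this detector extends:

* **box** — mean (1 − GIoU) between decoded predictions and their assigned
  ground-truth boxes; GIoU keeps a usable gradient even when the prediction
  and the target do not intersect;
* **objectness** — binary cross-entropy against an IoU-valued target: an
  assigned cell's target confidence is Pr(object)·IoU, i.e. the (clipped)
  GIoU the decoded box actually achieves, and 0 elsewhere;
* **class** — binary cross-entropy of the per-class logits at assigned
  cells (one-vs-all).

Assignment is ratio-based and cross-grid: a label matches every anchor
whose w/h ratios are within ``anchor_ratio_thr`` (default 4), in its own
cell and the two adjacent cells nearest its center, which triples the
positive samples for small objects.

The five online augmentations (HSV jitter with gains 0.03/0.7/0.5,
horizontal flip at p=0.5, ±0.1 translation, 0.5–1.5 scaling, 4-image
mosaic) match the published training recipe, as do the optimiser settings
(SGD, lr 0.01, momentum 0.937, weight decay 5e-4).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import AffineTransform, warp

from .data import (GroundTruthLabel, PAD_VALUE, letterbox, list_dataset,
                   load_image, read_labels)
from .model import (AnchorSet, DEFAULT_ANCHORS, Detector, ModelConfig, STRIDES,
                    save_checkpoint)
from .nn import SGD, Tensor, bce_with_logits
from .nn import concat as nn_concat

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr0: float = 0.01
    weight_decay: float = 5e-4
    momentum: float = 0.937
    batch_size: int = 16
    epochs: int = 300
    input_size: int = 640
    hsv_gains: tuple = (0.03, 0.7, 0.5)
    flip_p: float = 0.5
    translate: float = 0.1
    scale: tuple = (0.5, 1.5)
    mosaic: bool = True
    augment: bool = True
    box_weight: float = 0.05
    obj_weight: float = 1.0
    cls_weight: float = 0.5
    obj_balance: tuple = (4.0, 1.0, 0.4)   # per-stride objectness weights
    anchor_ratio_thr: float = 4.0
    nominal_batch: int = 64                # loss scale: gradients emulate the
                                           # lineage's accumulate-to-64 rule
    min_area_frac: float = 0.1             # drop boxes reduced below this
    lr_final_frac: float = 0.1             # cosine decay floor
    fit_anchors: bool = True
    eval_interval: int = 1                 # epochs between val evaluations
    conf_thr: float = 0.001
    seed: int = 0

    def __post_init__(self):
        for name in ("lr0", "weight_decay", "momentum", "batch_size", "input_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.flip_p <= 1:
            raise ValueError("flip_p must be a probability")


# -- target assignment -----------------------------------------------------

@dataclass
class ScaleAssignment:
    """Index maps + targets for one detection scale (arrays over matches)."""

    img: np.ndarray          # image index in batch
    anchor: np.ndarray       # anchor index 0..2
    gj: np.ndarray           # cell row
    gi: np.ndarray           # cell col
    txy: np.ndarray          # target center offset from cell origin, grid units
    twh: np.ndarray          # target size, grid (stride) units
    anchor_wh: np.ndarray    # matched anchor size, grid units
    cls: np.ndarray          # class ids


def assign_targets(batch_labels: list[list[GroundTruthLabel]], anchors: AnchorSet,
                   input_size: int, ratio_thr: float = 4.0
                   ) -> tuple[list[ScaleAssignment], int]:
    """Match labels to (scale, anchor, cell) triples.

    Returns one :class:`ScaleAssignment` per stride and the count of labels
    that matched no anchor at any scale (extreme aspect/size outliers).
    """
    per_scale = []
    matched_any = np.zeros(sum(len(ls) for ls in batch_labels), dtype=bool)
    flat_base = np.cumsum([0] + [len(ls) for ls in batch_labels])
    for level, stride in enumerate(anchors.strides):
        g = input_size // stride
        anc = anchors.anchors[level] / stride        # grid units
        rows = {k: [] for k in ("img", "anchor", "gj", "gi", "txy", "twh",
                                "anchor_wh", "cls")}
        for bi, labels in enumerate(batch_labels):
            for li, lb in enumerate(labels):
                gx, gy = lb.cx * g, lb.cy * g
                gw, gh = lb.w * input_size / stride, lb.h * input_size / stride
                if gw <= 0 or gh <= 0:
                    continue
                for ai, (aw, ah) in enumerate(anc):
                    r = max(gw / aw, aw / gw, gh / ah, ah / gh)
                    if r >= ratio_thr:
                        continue
                    matched_any[flat_base[bi] + li] = True
                    cells = [(int(gx), int(gy))]
                    fx, fy = gx - int(gx), gy - int(gy)
                    if fx < 0.5 and gx > 1:
                        cells.append((int(gx) - 1, int(gy)))
                    elif fx >= 0.5 and gx < g - 1:
                        cells.append((int(gx) + 1, int(gy)))
                    if fy < 0.5 and gy > 1:
                        cells.append((int(gx), int(gy) - 1))
                    elif fy >= 0.5 and gy < g - 1:
                        cells.append((int(gx), int(gy) + 1))
                    for ci, cj in cells:
                        ci = min(max(ci, 0), g - 1)
                        cj = min(max(cj, 0), g - 1)
                        rows["img"].append(bi)
                        rows["anchor"].append(ai)
                        rows["gj"].append(cj)
                        rows["gi"].append(ci)
                        rows["txy"].append((gx - ci, gy - cj))
                        rows["twh"].append((gw, gh))
                        rows["anchor_wh"].append((aw, ah))
                        rows["cls"].append(lb.class_id)
        per_scale.append(ScaleAssignment(
            img=np.array(rows["img"], dtype=np.intp),
            anchor=np.array(rows["anchor"], dtype=np.intp),
            gj=np.array(rows["gj"], dtype=np.intp),
            gi=np.array(rows["gi"], dtype=np.intp),
            txy=np.array(rows["txy"], dtype=np.float32).reshape(-1, 2),
            twh=np.array(rows["twh"], dtype=np.float32).reshape(-1, 2),
            anchor_wh=np.array(rows["anchor_wh"], dtype=np.float32).reshape(-1, 2),
            cls=np.array(rows["cls"], dtype=np.intp),
        ))
    return per_scale, int((~matched_any).sum())


# -- loss ------------------------------------------------------------------

def _giou_xywh(pred: Tensor, tgt: np.ndarray) -> Tensor:
    """Vectorised GIoU between predicted and target (cx, cy, w, h) boxes."""
    px1 = pred[:, 0] - pred[:, 2] * 0.5
    py1 = pred[:, 1] - pred[:, 3] * 0.5
    px2 = pred[:, 0] + pred[:, 2] * 0.5
    py2 = pred[:, 1] + pred[:, 3] * 0.5
    tx1, ty1 = tgt[:, 0] - tgt[:, 2] / 2, tgt[:, 1] - tgt[:, 3] / 2
    tx2, ty2 = tgt[:, 0] + tgt[:, 2] / 2, tgt[:, 1] + tgt[:, 3] / 2
    iw = (px2.minimum(tx2) - px1.maximum(tx1)).clamp_min(0.0)
    ih = (py2.minimum(ty2) - py1.maximum(ty1)).clamp_min(0.0)
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter + 1e-9
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    enclose = cw * ch + 1e-9
    return inter / union - (enclose - union) / enclose


def compute_loss(raw_outs: list[Tensor], assignments: list[ScaleAssignment],
                 cfg: TrainConfig, anchors: AnchorSet) -> dict:
    """Weighted detection loss; returns dict with 'total' Tensor and floats."""
    nc = raw_outs[0].shape[-1] - 5
    box_terms, cls_terms = [], []
    obj_total = None
    for level, (raw, asg) in enumerate(zip(raw_outs, assignments)):
        tobj = np.zeros(raw.shape[:-1], dtype=np.float32)
        n_match = len(asg.img)
        if n_match:
            idx = (asg.img, asg.anchor, asg.gj, asg.gi)
            ps = raw[idx]                                   # (M, 5+nc)
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2.0 * asg.anchor_wh
            pbox = nn_concat([pxy, pwh], axis=1)
            tbox = np.concatenate([asg.txy, asg.twh], axis=1)
            giou = _giou_xywh(pbox, tbox)
            box_terms.append((1.0 - giou).mean())
            np.maximum.at(tobj, idx, np.clip(giou.data, 0, 1).astype(np.float32))
            if nc > 1:
                tcls = np.zeros((n_match, nc), dtype=np.float32)
                tcls[np.arange(n_match), asg.cls] = 1.0
                cls_terms.append(bce_with_logits(ps[:, 5:], tcls).mean())
        obj_term = bce_with_logits(raw[..., 4], tobj).mean() * cfg.obj_balance[level]
        obj_total = obj_term if obj_total is None else obj_total + obj_term
        if not np.isfinite(obj_term.data):
            raise RuntimeError(f"non-finite objectness loss at stride {STRIDES[level]}")

    zero = Tensor(np.float32(0.0))
    box_loss = sum(box_terms[1:], box_terms[0]) * (1.0 / len(box_terms)) \
        if box_terms else zero
    cls_loss = sum(cls_terms[1:], cls_terms[0]) * (1.0 / len(cls_terms)) \
        if cls_terms else zero
    total = (box_loss * cfg.box_weight + obj_total * cfg.obj_weight
             + cls_loss * cfg.cls_weight) * float(cfg.nominal_batch)
    for name, t in (("box", box_loss), ("cls", cls_loss), ("total", total)):
        if not np.isfinite(t.data):
            raise RuntimeError(f"non-finite {name} loss")
    return {"box": float(box_loss.data), "obj": float(obj_total.data),
            "cls": float(cls_loss.data), "total": total}


# -- augmentations ---------------------------------------------------------

def augment_hsv(img: np.ndarray, gains=(0.03, 0.7, 0.5), rng=None) -> np.ndarray:
    """Multiplicative HSV jitter; hue wraps, S/V clip; 8-bit in and out."""
    rng = rng if rng is not None else np.random.default_rng(0)
    factors = np.array([rng.uniform(1 - g, 1 + g) for g in gains])
    if np.allclose(factors, 1.0):
        return img.copy()
    hsv = rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] * factors[0]) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * factors[1], 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * factors[2], 0, 1)
    return np.clip(hsv2rgb(hsv) * 255.0, 0, 255).astype(np.uint8)


def augment_geometric(img: np.ndarray, labels: list[GroundTruthLabel],
                      flip_p: float = 0.5, translate: float = 0.1,
                      scale=(0.5, 1.5), rng=None, min_area_frac: float = 0.1,
                      force_flip: bool | None = None):
    """Random flip / center scale / translation with exact label remapping.

    Labels are remapped by transforming box corners, re-boxing and clipping;
    boxes whose visible area falls below ``min_area_frac`` of the original
    are dropped.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    h, w = img.shape[:2]
    flip = rng.uniform() < flip_p if force_flip is None else force_flip
    s = rng.uniform(*scale)
    tx = rng.uniform(-translate, translate) * w
    ty = rng.uniform(-translate, translate) * h

    out = img[:, ::-1].copy() if flip else img
    if flip:
        labels = [GroundTruthLabel(lb.class_id, 1.0 - lb.cx, lb.cy, lb.w, lb.h)
                  for lb in labels]
    if s == 1.0 and tx == 0.0 and ty == 0.0:
        return out, list(labels)
    # scale about the image center, then translate
    tform = (AffineTransform(translation=(-w / 2, -h / 2))
             + AffineTransform(scale=(s, s))
             + AffineTransform(translation=(w / 2 + tx, h / 2 + ty)))
    warped = warp(out, tform.inverse, order=1, cval=PAD_VALUE / 255.0,
                  preserve_range=True)
    warped = np.clip(warped, 0, 255).astype(img.dtype)
    new_labels = []
    for lb in labels:
        x1, y1, x2, y2 = lb.to_xyxy(w, h)
        corners = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]])
        tc = tform(corners)
        nx1, ny1 = tc.min(axis=0)
        nx2, ny2 = tc.max(axis=0)
        cx1, cy1 = max(nx1, 0.0), max(ny1, 0.0)
        cx2, cy2 = min(nx2, float(w)), min(ny2, float(h))
        if cx2 <= cx1 or cy2 <= cy1:
            continue
        if (cx2 - cx1) * (cy2 - cy1) < min_area_frac * (x2 - x1) * (y2 - y1):
            continue
        new_labels.append(GroundTruthLabel(
            lb.class_id, (cx1 + cx2) / 2 / w, (cy1 + cy2) / 2 / h,
            (cx2 - cx1) / w, (cy2 - cy1) / h))
    return warped, new_labels


def mosaic(samples: list[tuple[np.ndarray, list[GroundTruthLabel]]],
           output_size: int = 640, rng=None):
    """Stitch four samples 2×2 around a random center, remapping labels."""
    if len(samples) != 4:
        raise ValueError(f"mosaic needs exactly 4 samples, got {len(samples)}")
    rng = rng if rng is not None else np.random.default_rng(0)
    s = output_size
    canvas = np.full((s, s, 3), PAD_VALUE, dtype=np.uint8)
    xc = int(rng.uniform(0.3, 0.7) * s)
    yc = int(rng.uniform(0.3, 0.7) * s)
    out_labels: list[GroundTruthLabel] = []
    regions = [(0, 0, xc, yc), (xc, 0, s, yc), (0, yc, xc, s), (xc, yc, s, s)]
    for (img, labels), (rx1, ry1, rx2, ry2) in zip(samples, regions):
        rw, rh = rx2 - rx1, ry2 - ry1
        if rw < 2 or rh < 2:
            continue
        h, w = img.shape[:2]
        # random crop of the tile-sized window (pad with gray if too small)
        ox = int(rng.integers(0, max(w - rw, 0) + 1))
        oy = int(rng.integers(0, max(h - rh, 0) + 1))
        cw, ch = min(rw, w), min(rh, h)
        canvas[ry1:ry1 + ch, rx1:rx1 + cw] = img[oy:oy + ch, ox:ox + cw]
        for lb in labels:
            x1, y1, x2, y2 = lb.to_xyxy(w, h)
            nx1, ny1 = x1 - ox + rx1, y1 - oy + ry1
            nx2, ny2 = x2 - ox + rx1, y2 - oy + ry1
            cx1, cy1 = max(nx1, rx1), max(ny1, ry1)
            cx2, cy2 = min(nx2, rx1 + cw), min(ny2, ry1 + ch)
            if cx2 - cx1 < 2 or cy2 - cy1 < 2:
                continue
            if (cx2 - cx1) * (cy2 - cy1) < 0.1 * (x2 - x1) * (y2 - y1):
                continue
            out_labels.append(GroundTruthLabel(
                lb.class_id, (cx1 + cx2) / 2 / s, (cy1 + cy2) / 2 / s,
                (cx2 - cx1) / s, (cy2 - cy1) / s))
    return canvas, out_labels


# -- anchor fitting --------------------------------------------------------

def fit_anchors(labels: list[GroundTruthLabel], input_size: int, k: int = 9,
                iterations: int = 50, seed: int = 0) -> AnchorSet:
    """k-means over label (w, h) in pixels under the 1 − IoU(wh) distance.

    Centroids are sorted by area and split 3/3/3 across strides 8/16/32;
    with fewer than k labels the preset anchors are returned with a warning.
    """
    wh = np.array([(lb.w * input_size, lb.h * input_size) for lb in labels],
                  dtype=np.float64)
    wh = wh[(wh > 0).all(axis=1)]
    if len(wh) < k:
        log.warning("fewer than %d labels; using preset anchors", k)
        return AnchorSet()
    rng = np.random.default_rng(seed)
    cent = wh[rng.choice(len(wh), k, replace=False)]

    def iou_wh(a, c):
        iw = np.minimum(a[:, None, 0], c[None, :, 0])
        ih = np.minimum(a[:, None, 1], c[None, :, 1])
        inter = iw * ih
        union = (a[:, 0] * a[:, 1])[:, None] + (c[:, 0] * c[:, 1])[None, :] - inter
        return inter / union

    for _ in range(iterations):
        d = 1.0 - iou_wh(wh, cent)
        assign = d.argmin(axis=1)
        new = cent.copy()
        for j in range(k):
            pts = wh[assign == j]
            if len(pts):
                new[j] = pts.mean(axis=0)
        if np.allclose(new, cent):
            break
        cent = new
    order = np.argsort(cent[:, 0] * cent[:, 1])
    cent = cent[order]
    return AnchorSet(cent.reshape(3, 3, 2))


# -- dataset + training loop -----------------------------------------------

class DetectionDataset:
    """In-memory dataset over the images/labels layout (fixture scale)."""

    def __init__(self, root, split: str, input_size: int):
        self.pairs = list_dataset(root, split)
        self.input_size = input_size
        self.items = []
        for img_path, lbl_path in self.pairs:
            try:
                labels = read_labels(lbl_path)
            except ValueError as err:
                raise RuntimeError(f"unreadable label file {lbl_path}: {err}") from err
            self.items.append((load_image(img_path), labels, img_path.stem))

    def __len__(self):
        return len(self.items)

    def sample(self, i: int, cfg: TrainConfig, rng) -> tuple[np.ndarray, list]:
        img, labels, _ = self.items[i]
        if cfg.augment and cfg.mosaic and len(self.items) >= 4:
            idxs = [i] + list(rng.choice(len(self.items), 3))
            tiles = []
            for j in idxs:
                im, lbs, _ = self.items[j]
                im, lbs = letterbox(im, self.input_size, lbs)
                tiles.append((im, lbs))
            img, labels = mosaic(tiles, self.input_size, rng)
        else:
            img, labels = letterbox(img, self.input_size, labels)
        if cfg.augment:
            img = augment_hsv(img, cfg.hsv_gains, rng)
            img, labels = augment_geometric(img, labels, cfg.flip_p, cfg.translate,
                                            cfg.scale, rng, cfg.min_area_frac)
        return img, labels

    def plain(self, i: int) -> tuple[np.ndarray, list, str]:
        img, labels, stem = self.items[i]
        img, labels = letterbox(img, self.input_size, labels)
        return img, labels, stem


def _to_input(imgs: list[np.ndarray]) -> np.ndarray:
    batch = np.stack(imgs).astype(np.float32) / 255.0
    return batch.transpose(0, 3, 1, 2)


def cosine_lr(epoch: int, epochs: int, lr0: float, final_frac: float) -> float:
    if epochs <= 1:
        return lr0
    t = epoch / (epochs - 1)
    return lr0 * (final_frac + (1 - final_frac) * 0.5 * (1 + math.cos(math.pi * t)))


def train(dataset_dir, model: Detector | ModelConfig, cfg: TrainConfig,
          out_dir=None, val_split: str | None = "val"):
    """Train a detector on a dataset directory.

    Writes ``metrics.csv`` (epoch, box, obj, cls, mAP50, mAP5095) and
    ``best.npz`` / ``last.npz`` checkpoints when ``out_dir`` is given.
    Returns ``(model, history)``.
    """
    from .evaluation import evaluate_model  # local import; avoids a cycle

    if isinstance(model, ModelConfig):
        model = Detector(model)
    mcfg = model.cfg
    ds = DetectionDataset(dataset_dir, "train", cfg.input_size)
    rng = np.random.default_rng(cfg.seed)
    anchors = mcfg.anchor_set()
    if cfg.fit_anchors:
        all_labels = [lb for _, lbs, _ in ds.items for lb in lbs]
        anchors = fit_anchors(all_labels, cfg.input_size, seed=cfg.seed)
        mcfg.anchors = tuple(tuple(tuple(float(v) for v in a) for a in lvl)
                             for lvl in anchors.anchors)
    opt = SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    history = []
    best_map = -1.0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    val_ds = None
    if val_split is not None:
        try:
            val_ds = DetectionDataset(dataset_dir, val_split, cfg.input_size)
        except FileNotFoundError:
            val_ds = None

    for epoch in range(cfg.epochs):
        model.train()
        opt.lr = cosine_lr(epoch, cfg.epochs, cfg.lr0, cfg.lr_final_frac)
        order = rng.permutation(len(ds))
        sums = {"box": 0.0, "obj": 0.0, "cls": 0.0, "total": 0.0}
        nb = 0
        for start in range(0, len(ds), cfg.batch_size):
            idxs = order[start:start + cfg.batch_size]
            imgs, blabels = [], []
            for i in idxs:
                img, labels = ds.sample(int(i), cfg, rng)
                imgs.append(img)
                blabels.append(labels)
            x = Tensor(_to_input(imgs))
            outs = model(x)
            assignments, _ = assign_targets(blabels, anchors, cfg.input_size,
                                            cfg.anchor_ratio_thr)
            losses = compute_loss(outs, assignments, cfg, anchors)
            opt.zero_grad()
            losses["total"].backward()
            opt.step()
            for key in sums:
                sums[key] += losses[key] if key != "total" else float(losses["total"].data)
            nb += 1
        row = {"epoch": epoch, **{k: v / max(nb, 1) for k, v in sums.items()},
               "lr": opt.lr, "mAP50": float("nan"), "mAP5095": float("nan")}
        if val_ds is not None and (epoch % cfg.eval_interval == 0
                                   or epoch == cfg.epochs - 1):
            rep = evaluate_model(model, val_ds, anchors, conf_thr=cfg.conf_thr)
            row["mAP50"], row["mAP5095"] = rep.map50, rep.map5095
            if rep.map50 > best_map and out_dir is not None:
                best_map = rep.map50
                save_checkpoint(model, out_dir / "best.npz",
                                {"epoch": epoch, "mAP50": rep.map50})
        history.append(row)
        log.info("epoch %d: box %.4f obj %.4f cls %.4f total %.4f mAP50 %s",
                 epoch, row["box"], row["obj"], row["cls"], row["total"], row["mAP50"])

    if out_dir is not None:
        save_checkpoint(model, out_dir / "last.npz", {"epoch": cfg.epochs - 1})
        if best_map < 0:
            save_checkpoint(model, out_dir / "best.npz", {"epoch": cfg.epochs - 1})
        with open(out_dir / "metrics.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "box", "obj", "cls",
                                                    "total", "lr", "mAP50", "mAP5095"])
            writer.writeheader()
            writer.writerows(history)
    return model, history
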