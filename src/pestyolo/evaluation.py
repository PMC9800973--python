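"""Detection metrics (precision/recall/AP/mAP) and the noise-robustness
harness.

AP for one class is the area under the precision–recall curve traced in
descending score order, integrated over the monotone (all-point
interpolated) precision envelope; mAP@0.5 averages per-class AP at IoU 0.5
and mAP@[0.5:0.95] additionally averages over the ten IoU thresholds
0.50–0.95 in steps of 0.05.  Matching is greedy in score order: a detection
is a true positive iff it overlaps an unmatched same-class ground truth at
or above the threshold; each ground truth matches at most once.

Classes with no ground truth in the evaluation set are excluded from the
means (and logged) rather than scored zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .model import AnchorSet, Detection, Detector, decode_predictions
from .postprocess import iou, soft_nms, nms

log = logging.getLogger(__name__)

IOU_THRESHOLDS = np.round(np.arange(0.50, 1.00, 0.05), 2)  # 0.50 ... 0.95


def match_detections(dets: list[Detection], gts: list[tuple], iou_thr: float
                     ) -> tuple[np.ndarray, int]:
    """Flag each detection TP/FP against ground truths ``(box, class_id)``.

    ``dets`` must already be sorted by score descending.  Returns a boolean
    TP array aligned with ``dets`` and the FN count.
    """
    scores = [d.score for d in dets]
    if any(a < b for a, b in zip(scores, scores[1:])):
        raise ValueError("detections must be sorted by score descending")
    used = [False] * len(gts)
    tp = np.zeros(len(dets), dtype=bool)
    for di, d in enumerate(dets):
        best, best_iou = -1, iou_thr
        for gi, (gbox, gcls) in enumerate(gts):
            if used[gi] or gcls != d.class_id:
                continue
            ov = iou(d.box, gbox)
            if ov >= best_iou:
                best, best_iou = gi, ov
        if best >= 0:
            used[best] = True
            tp[di] = True
    return tp, used.count(False)


@dataclass
class PRCurve:
    """Precision–recall trace in descending score order for one class."""

    recall: np.ndarray
    precision: np.ndarray
    n_gt: int

    def __post_init__(self):
        if np.any(np.diff(self.recall) < -1e-12):
            raise ValueError("recall must be non-decreasing along the trace")


def pr_curve(tp_flags: np.ndarray, n_gt: int) -> PRCurve:
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(~np.asarray(tp_flags, dtype=bool))
    recall = tp / n_gt if n_gt else np.zeros_like(tp, dtype=float)
    precision = tp / np.maximum(tp + fp, 1)
    return PRCurve(recall, precision, n_gt)


def average_precision(curve: PRCurve, interpolation: str = "all") -> float:
    """Area under the monotone precision envelope over recall in [0, 1].

    ``interpolation='101'`` uses the 101-point COCO grid instead of the
    exact all-point integral (provided for cross-checking; the two agree to
    sampling resolution).
    """
    if curve.n_gt == 0:
        raise ValueError("AP undefined for a class with zero ground truths")
    if len(curve.recall) == 0:
        return 0.0
    r = np.concatenate([[0.0], curve.recall, [curve.recall[-1]]])
    p = np.concatenate([[1.0], curve.precision, [0.0]])
    # monotone envelope: running max of precision from the right
    p = np.maximum.accumulate(p[::-1])[::-1]
    if interpolation == "101":
        grid = np.linspace(0, 1, 101)
        pi = np.array([p[np.searchsorted(r, g, side="left")] if g <= r[-1] else 0.0
                       for g in grid])
        return float(pi.mean())
    idx = np.nonzero(np.diff(r))[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


@dataclass
class EvalReport:
    """Per-class AP at each IoU threshold plus the rolled-up means."""

    ap: dict = field(default_factory=dict)       # {class: {thr: AP}}
    ap5095: dict = field(default_factory=dict)   # {class: mean over thr}
    map50: float = 0.0
    map5095: float = 0.0
    n_classes_evaluated: int = 0
    skipped_classes: tuple = ()

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"map50": self.map50, "map5095": self.map5095,
                       "ap": {str(k): {str(t): v for t, v in d.items()}
                              for k, d in self.ap.items()},
                       "ap5095": {str(k): v for k, v in self.ap5095.items()}},
                      fh, indent=1)

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("class," + ",".join(f"AP{int(t * 100)}" for t in IOU_THRESHOLDS)
                     + ",AP50:95\n")
            for cls, d in sorted(self.ap.items()):
                fh.write(f"{cls}," + ",".join(f"{d[t]:.4f}" for t in IOU_THRESHOLDS)
                         + f",{self.ap5095[cls]:.4f}\n")
            fh.write(f"mean,{self.map50:.4f}" + "," * (len(IOU_THRESHOLDS) - 1)
                     + f",{self.map5095:.4f}\n")


def evaluate(dets_per_image: dict[str, list[Detection]],
             gts_per_image: dict[str, list[tuple]],
             num_classes: int, interpolation: str = "all") -> EvalReport:
    """Full evaluation: per-class AP over the ten IoU thresholds + means.

    ``gts_per_image`` maps image id to a list of ``(box, class_id)`` pairs.
    """
    report = EvalReport()
    present = sorted({cls for gts in gts_per_image.values() for _, cls in gts})
    skipped = [c for c in range(num_classes) if c not in present]
    if skipped:
        log.info("classes with no ground truth excluded from means: %s", skipped)
    for cls in present:
        per_thr = {}
        for thr in IOU_THRESHOLDS:
            flags, scores, n_gt = [], [], 0
            for image_id, gts in gts_per_image.items():
                cls_gts = [g for g in gts if g[1] == cls]
                n_gt += len(cls_gts)
                cls_dets = sorted([d for d in dets_per_image.get(image_id, [])
                                   if d.class_id == cls], key=lambda d: -d.score)
                tp, _ = match_detections(cls_dets, cls_gts, thr)
                flags.extend(tp.tolist())
                scores.extend(d.score for d in cls_dets)
            order = np.argsort(-np.asarray(scores)) if scores else []
            flags = np.asarray(flags, dtype=bool)[order] if len(flags) else \
                np.zeros(0, dtype=bool)
            per_thr[thr] = average_precision(pr_curve(flags, n_gt), interpolation)
        report.ap[cls] = per_thr
        report.ap5095[cls] = float(np.mean(list(per_thr.values())))
    if present:
        report.map50 = float(np.mean([report.ap[c][0.5] for c in present]))
        report.map5095 = float(np.mean([report.ap5095[c] for c in present]))
    report.n_classes_evaluated = len(present)
    report.skipped_classes = tuple(skipped)
    return report


# -- model-level helpers ---------------------------------------------------

def detect_image(model: Detector, img_chw: np.ndarray, anchors: AnchorSet,
                 conf_thr: float = 0.25, use_soft_nms: bool = True,
                 nms_thr: float = 0.45, soft_alpha: float = 0.5,
                 final_thr: float = 1e-3, max_det: int = 300) -> list[Detection]:
    """Forward one normalised (3, S, S) image and post-process."""
    outs = model(img_chw[None])
    dets = decode_predictions([o.data for o in outs], anchors, conf_thr,
                              input_size=img_chw.shape[-1])
    if use_soft_nms:
        dets = soft_nms(dets, alpha=soft_alpha, final_thr=max(final_thr, conf_thr))
    else:
        dets = nms(dets, iou_thr=nms_thr)
    return dets[:max_det]


def evaluate_model(model: Detector, dataset, anchors: AnchorSet,
                   conf_thr: float = 0.001, use_soft_nms: bool = True,
                   noise=None, interpolation: str = "all") -> EvalReport:
    """Evaluate a detector over a :class:`DetectionDataset`.

    ``noise`` is an optional callable applied to each uint8 image before
    inference (the robustness harness hooks in here).
    """
    was_training = model.training
    model.eval()
    dets_per_image, gts_per_image = {}, {}
    size = dataset.input_size
    for i in range(len(dataset)):
        img, labels, stem = dataset.plain(i)
        if noise is not None:
            img = noise(img)
        x = img.astype(np.float32).transpose(2, 0, 1) / 255.0
        dets_per_image[stem] = detect_image(model, x, anchors, conf_thr,
                                            use_soft_nms)
        gts_per_image[stem] = [(lb.to_xyxy(size, size), lb.class_id)
                               for lb in labels]
    if was_training:
        model.train()
    nc = model.cfg.num_classes
    return evaluate(dets_per_image, gts_per_image, nc, interpolation)


# -- noise models (robustness protocol) ------------------------------------

def add_salt_pepper(img: np.ndarray, level: float, seed: int = 0) -> np.ndarray:
    """Set a fraction ``level`` of pixels (without replacement) to pure
    black or white with equal probability."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must lie in [0, 1]")
    out = img.copy()
    if level == 0:
        return out
    h, w = img.shape[:2]
    n = round(level * h * w)
    rng = np.random.default_rng(seed)
    flat = rng.choice(h * w, size=n, replace=False)
    vals = rng.integers(0, 2, size=n) * 255
    out.reshape(h * w, -1)[flat] = vals[:, None]
    return out


def add_gaussian(img: np.ndarray, mean: float = 0.1, std: float = 0.05,
                 seed: int = 0) -> np.ndarray:
    """Additive i.i.d. Gaussian noise on the [0, 1] scale, clipped, 8-bit out."""
    if std < 0:
        raise ValueError("std must be non-negative")
    rng = np.random.default_rng(seed)
    x = img.astype(np.float64) / 255.0
    x = x + rng.normal(mean, std, img.shape)
    return (np.clip(x, 0, 1) * 255).round().astype(np.uint8)


def robustness_sweep(model: Detector, dataset, anchors: AnchorSet,
                     levels=None, kind: str = "salt_pepper",
                     gaussian_mean: float = 0.1, gaussian_std: float = 0.05,
                     conf_thr: float = 0.001, seed: int = 0) -> list[dict]:
    """mAP as a function of injected noise level (level 0 = plain eval).

    The default grid is the published protocol: salt-&-pepper fractions
    0.005 … 0.05 in steps of 0.005 (plus the clean baseline).
    """
    if levels is None:
        levels = [0.0] + [round(0.005 * i, 3) for i in range(1, 11)]
    rows = []
    for li, level in enumerate(levels):
        if level == 0:
            noise = None
        elif kind == "salt_pepper":
            noise = lambda im, lv=level, s=seed + li: add_salt_pepper(im, lv, s)
        elif kind == "gaussian":
            noise = lambda im, lv=level, s=seed + li: add_gaussian(
                im, gaussian_mean * lv / max(levels), gaussian_std, s)
        else:
            raise ValueError(f"unknown noise kind {kind!r}")
        rep = evaluate_model(model, dataset, anchors, conf_thr, noise=noise)
        rows.append({"level": level, "mAP50": rep.map50, "mAP5095": rep.map5095})
    return rows


def write_sweep_csv(path, rows: list[dict]):
    with open(path, "w") as fh:
        fh.write("level,mAP50,mAP5095\n")
        for r in rows:
            fh.write(f"{r['level']},{r['mAP50']:.6f},{r['mAP5095']:.6f}\n")
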