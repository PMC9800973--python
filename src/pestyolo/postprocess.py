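"""Box geometry and duplicate suppression.

Dense light-trap scenes make the detector emit several boxes per insect.
Classical NMS greedily keeps the top-scoring box of each cluster and deletes
same-class neighbours above an IoU threshold; with genuinely overlapping
insects that deletes true detections.  Gaussian Soft-NMS instead *decays*
neighbour scores,

    S_i <- S_i * exp(-IoU(B_max, b_i) / alpha^2),        alpha = 0.5,

so a heavily-overlapped second insect survives with a reduced score rather
than vanishing.  Suppression is per class in both algorithms.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .model import Detection

log = logging.getLogger(__name__)


def iou(a, b) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes in [0, 1]."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = max(ax2 - ax1, 0.0) * max(ay2 - ay1, 0.0)
    area_b = max(bx2 - bx1, 0.0) * max(by2 - by1, 0.0)
    if area_a <= 0 or area_b <= 0:
        log.warning("degenerate zero-area box in IoU; overlap defined as 0")
        return 0.0
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def giou(a, b) -> float:
    """Generalized IoU in [-1, 1]: IoU minus the normalised empty share of
    the smallest enclosing box; informative even for disjoint boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = max(ax2 - ax1, 0.0) * max(ay2 - ay1, 0.0)
    area_b = max(bx2 - bx1, 0.0) * max(by2 - by1, 0.0)
    iw = max(min(ax2, bx2) - max(ax1, bx1), 0.0)
    ih = max(min(ay2, by2) - max(ay1, by1), 0.0)
    inter = iw * ih
    union = area_a + area_b - inter
    cw = max(ax2, bx2) - min(ax1, bx1)
    ch = max(ay2, by2) - min(ay1, by1)
    enclose = cw * ch
    if enclose <= 0 or union <= 0:
        log.warning("degenerate box in GIoU")
        return 0.0
    return inter / union - (enclose - union) / enclose


def _pairwise_iou(boxes: np.ndarray) -> np.ndarray:
    x1, y1, x2, y2 = boxes.T
    area = (x2 - x1).clip(0) * (y2 - y1).clip(0)
    iw = (np.minimum(x2[:, None], x2) - np.maximum(x1[:, None], x1)).clip(0)
    ih = (np.minimum(y2[:, None], y2) - np.maximum(y1[:, None], y1)).clip(0)
    inter = iw * ih
    union = area[:, None] + area - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def nms(dets: list[Detection], iou_thr: float = 0.45) -> list[Detection]:
    """Greedy per-class hard suppression; kept boxes sorted by score."""
    if not 0.0 < iou_thr < 1.0:
        raise ValueError("iou_thr must lie in (0, 1)")
    kept: list[Detection] = []
    for cls in sorted({d.class_id for d in dets}):
        group = sorted([d for d in dets if d.class_id == cls],
                       key=lambda d: -d.score)
        boxes = np.array([d.box for d in group], dtype=np.float64)
        alive = np.ones(len(group), dtype=bool)
        M = _pairwise_iou(boxes)
        for i in range(len(group)):
            if not alive[i]:
                continue
            kept.append(group[i])
            alive[M[i] > iou_thr] = False
            alive[i] = False
    return sorted(kept, key=lambda d: -d.score)


def soft_nms(dets: list[Detection], alpha: float = 0.5,
             final_thr: float = 1e-3) -> list[Detection]:
    """Gaussian Soft-NMS: greedy iterative per-class rescoring.

    Repeatedly commits the highest currently-scored unprocessed box and
    multiplies every remaining same-class score by exp(-IoU/alpha^2); boxes
    whose final score falls below ``final_thr`` are dropped.  Output sorted
    by final score descending.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    out: list[Detection] = []
    inv_a2 = 1.0 / (alpha * alpha)
    for cls in sorted({d.class_id for d in dets}):
        group = [d for d in dets if d.class_id == cls]
        boxes = np.array([d.box for d in group], dtype=np.float64)
        scores = np.array([d.score for d in group], dtype=np.float64)
        M = _pairwise_iou(boxes)
        remaining = list(range(len(group)))
        while remaining:
            top = max(remaining, key=lambda i: scores[i])
            if scores[top] >= final_thr:
                out.append(Detection(group[top].box, cls, float(scores[top])))
            remaining.remove(top)
            for i in remaining:
                scores[i] *= math.exp(-M[top, i] * inv_a2)
    return sorted(out, key=lambda d: -d.score)


# -- delimited-text round-tripping ------------------------------------------

def write_detections(path, dets_per_image: dict[str, list[Detection]]):
    """Tab-separated detections: image_id, class, score, x1, y1, x2, y2."""
    with open(path, "w") as fh:
        for image_id, dets in dets_per_image.items():
            for d in dets:
                x1, y1, x2, y2 = d.box
                fh.write(f"{image_id}\t{d.class_id}\t{d.score:.6f}\t"
                         f"{x1:.2f}\t{y1:.2f}\t{x2:.2f}\t{y2:.2f}\n")


def read_detections(path) -> dict[str, list[Detection]]:
    out: dict[str, list[Detection]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            image_id, cls, score = parts[0], int(parts[1]), float(parts[2])
            box = tuple(float(v) for v in parts[3:7])
            out.setdefault(image_id, []).append(Detection(box, cls, score))
    return out
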