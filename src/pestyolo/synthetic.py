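"""Seeded generator of synthetic light-trap scenes with exact annotations.

Real light-trap photographs show many small dark insects on a bright,
uniformly lit trap surface, with non-target debris and specular light spots,
frequent overlap/adhesion between insects, a long-tailed class balance and
relative object scales concentrated well below 0.05 of the image with rare
much larger individuals.  The generator reproduces these pathologies
procedurally — no image assets — so every stage of the detector (assignment,
loss, suppression, evaluation) is exercisable offline:

* insects are dark rotated ellipses with per-class shape/shade/leg
  signatures (classification is learnable but not trivial);
* clutter blobs and white reflection discs are rendered but never labeled,
  exercising false-positive suppression;
* a ``density`` knob makes insects cluster, creating overlapping labeled
  pairs (the occlusion/adhesion pathology);
* labels are the exact bounding boxes of the rendered insect pixels.

Everything is reproducible from the scene seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np

from .data import GroundTruthLabel, write_labels


@dataclass
class SceneSpec:
    """Parameters of one synthetic light-trap scene."""

    image_size: int = 640
    n_insects: int = 30
    size_range: tuple = (0.005, 0.05)     # relative scale of typical insects
    outlier_scale: float = 0.4            # rare large individuals, up to ~0.95
    outlier_prob: float = 0.02
    n_classes: int = 24
    class_proportions: tuple | None = None  # None = long-tailed default
    density: float = 0.3                  # probability an insect is placed
                                          # adjacent to an existing one
    n_clutter: int = 6
    n_reflections: int = 3
    background: int = 205                 # bright trap-surface base tone
    texture_noise: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_insects < 0:
            raise ValueError("n_insects must be >= 0")
        if not (0 < self.size_range[0] <= self.size_range[1] < 1):
            raise ValueError("size_range must lie within (0, 1)")
        if not 1 <= self.n_classes <= 24:
            raise ValueError("n_classes must be in [1, 24]")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if len(p) != self.n_classes or abs(p.sum() - 1) > 1e-6:
                raise ValueError("class_proportions must have n_classes entries summing to 1")

    def proportions(self) -> np.ndarray:
        if self.class_proportions is not None:
            return np.asarray(self.class_proportions, dtype=float)
        # long-tailed default mirroring field data: geometric decay
        p = 0.6 ** np.arange(self.n_classes)
        return p / p.sum()


class SceneResult(NamedTuple):
    image: np.ndarray                 # (H, W, 3) uint8
    labels: list[GroundTruthLabel]
    stats: dict                       # mean_rel_scale, overlap pairs, shortfall


def _class_signature(class_id: int) -> dict:
    """Deterministic appearance parameters for a class."""
    return {
        "aspect": 1.3 + 0.22 * (class_id % 5),          # body elongation
        "shade": 25 + 14 * (class_id % 4),              # body darkness (0=black)
        "legs": (class_id % 3) * 3,                     # 0, 3 or 6 legs
        "head": class_id % 2 == 0,                      # darker head blob
    }


def _render_ellipse(img, cx, cy, a, b, theta, shade, soft=1.0):
    """Darken an elliptical region; returns the pixel-extent bbox or None."""
    size = img.shape[0]
    r = int(np.ceil(max(a, b))) + 2
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, size)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, size)
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    d2 = u * u + v * v
    mask = d2 <= 1.0
    if not mask.any():
        return None
    alpha = np.clip((1.0 - d2) * (2.0 * soft), 0, 1)[..., None]
    region = img[y0:y1, x0:x1].astype(np.float64)
    img[y0:y1, x0:x1] = (region * (1 - alpha) + shade * alpha).astype(np.uint8)
    ys, xs = np.nonzero(mask)
    return (x0 + xs.min(), y0 + ys.min(), x0 + xs.max() + 1, y0 + ys.max() + 1)


def _render_insect(img, cx, cy, body_len, class_id, rng) -> tuple | None:
    """Draw one insect; returns its exact pixel bbox (x1, y1, x2, y2)."""
    sig = _class_signature(class_id)
    a = body_len / 2
    b = a / sig["aspect"]
    theta = rng.uniform(0, np.pi)
    shade = sig["shade"] + rng.normal(0, 4)
    bbox = _render_ellipse(img, cx, cy, a, b, theta, shade)
    if bbox is None:
        return None
    boxes = [bbox]
    ct, st = np.cos(theta), np.sin(theta)
    if sig["head"] and a > 2:
        hb = _render_ellipse(img, cx + 0.8 * a * ct, cy + 0.8 * a * st,
                             max(b * 0.6, 1.0), max(b * 0.6, 1.0), 0.0,
                             max(shade - 12, 5))
        if hb:
            boxes.append(hb)
    for k in range(sig["legs"]):
        # legs: thin ellipses fanned out perpendicular to the body
        frac = -0.5 + k % 3 * 0.5
        side = 1 if k < 3 else -1
        lx = cx + frac * a * ct - side * 1.1 * b * st
        ly = cy + frac * a * st + side * 1.1 * b * ct
        ang = theta + side * rng.uniform(0.9, 1.6)
        lb = _render_ellipse(img, lx, ly, max(b * 0.8, 1.2), 0.6, ang,
                             shade + 25, soft=2.0)
        if lb:
            boxes.append(lb)
    xs1, ys1, xs2, ys2 = zip(*boxes)
    return (min(xs1), min(ys1), max(xs2), max(ys2))


def _boxes_overlap(a, b) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def generate_scene(spec: SceneSpec) -> SceneResult:
    """Render one scene; labels are exact boxes of rendered insects only."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = np.clip(rng.normal(spec.background, spec.texture_noise, (size, size, 3)),
                  0, 255).astype(np.uint8)
    # smooth illumination gradient, as from off-center trap lighting
    gy, gx = np.mgrid[0:size, 0:size] / size
    grad = (10 * (gx - 0.5) * rng.uniform(-1, 1)
            + 10 * (gy - 0.5) * rng.uniform(-1, 1))
    img = np.clip(img.astype(np.float64) + grad[..., None], 0, 255).astype(np.uint8)

    # unlabeled clutter: mid-gray soft blobs (debris, moth dust)
    for _ in range(spec.n_clutter):
        r = rng.uniform(2, max(0.04 * size, 3))
        _render_ellipse(img, rng.uniform(0, size), rng.uniform(0, size),
                        r, r * rng.uniform(0.5, 1), rng.uniform(0, np.pi),
                        rng.uniform(120, 170), soft=0.5)
    # unlabeled specular reflections: bright white discs
    for _ in range(spec.n_reflections):
        r = rng.uniform(1.5, max(0.02 * size, 2.5))
        _render_ellipse(img, rng.uniform(0, size), rng.uniform(0, size),
                        r, r, 0.0, 252, soft=1.5)

    proportions = spec.proportions()
    labels: list[GroundTruthLabel] = []
    placed_centers: list[tuple] = []
    boxes: list[tuple] = []
    shortfall = 0
    for _ in range(spec.n_insects):
        if rng.uniform() < spec.outlier_prob:
            rel = rng.uniform(spec.size_range[1], spec.outlier_scale)
        else:
            lo, hi = np.log(spec.size_range[0]), np.log(spec.size_range[1])
            rel = float(np.exp(rng.uniform(lo, hi)))
        body = max(rel * size, 2.5)
        cls = int(rng.choice(spec.n_classes, p=proportions))
        placed = False
        for _attempt in range(30):
            if placed_centers and rng.uniform() < spec.density:
                bx, by = placed_centers[rng.integers(len(placed_centers))]
                cx = bx + rng.normal(0, body * 0.7)
                cy = by + rng.normal(0, body * 0.7)
            else:
                cx, cy = rng.uniform(body, size - body, 2) if size > 2 * body \
                    else (size / 2, size / 2)
            if not (0 <= cx < size and 0 <= cy < size):
                continue
            bbox = _render_insect(img, cx, cy, body, cls, rng)
            if bbox is None:
                continue
            x1, y1, x2, y2 = bbox
            x1, y1 = max(x1, 0), max(y1, 0)
            x2, y2 = min(x2, size), min(y2, size)
            if x2 - x1 < 2 or y2 - y1 < 2:
                continue
            labels.append(GroundTruthLabel(
                cls, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
                (x2 - x1) / size, (y2 - y1) / size))
            placed_centers.append((cx, cy))
            boxes.append((x1, y1, x2, y2))
            placed = True
            break
        if not placed:
            shortfall += 1

    n_overlap = sum(_boxes_overlap(boxes[i], boxes[j])
                    for i in range(len(boxes)) for j in range(i + 1, len(boxes)))
    stats = {
        "mean_rel_scale": float(np.mean([max(lb.w, lb.h) for lb in labels]))
        if labels else 0.0,
        "overlapping_pairs": int(n_overlap),
        "shortfall": shortfall,
    }
    return SceneResult(img, labels, stats)


def generate_dataset(out_dir, n_images: int, spec: SceneSpec | None = None,
                     splits: dict | None = None, seed: int = 0) -> Path:
    """Write a full dataset directory (images + labels + manifest.json)."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    spec = spec or SceneSpec()
    splits = splits or {"train": 0.8, "val": 0.2}
    if abs(sum(splits.values()) - 1) > 1e-6:
        raise ValueError("split fractions must sum to 1")
    out = Path(out_dir)
    counts, acc = {}, 0.0
    names = list(splits)
    for i, name in enumerate(names):
        if i == len(names) - 1:
            counts[name] = n_images - sum(counts.values())
        else:
            counts[name] = int(round(splits[name] * n_images))
    manifest = {"n_images": n_images, "seed": seed, "splits": counts,
                "class_names": [f"pest_{c:02d}" for c in range(spec.n_classes)],
                "images": []}
    idx = 0
    for split, cnt in counts.items():
        (out / "images" / split).mkdir(parents=True, exist_ok=True)
        (out / "labels" / split).mkdir(parents=True, exist_ok=True)
        for _ in range(cnt):
            sp = SceneSpec(**{**spec.__dict__, "seed": seed * 100_000 + idx})
            scene = generate_scene(sp)
            stem = f"scene_{idx:05d}"
            iio.imwrite(out / "images" / split / f"{stem}.png", scene.image)
            write_labels(out / "labels" / split / f"{stem}.txt", scene.labels)
            manifest["images"].append({"stem": stem, "split": split,
                                       "seed": sp.seed, **scene.stats})
            idx += 1
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
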