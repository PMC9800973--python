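"""Dataset plumbing: YOLO-format labels, directory layout, letterboxing.

Layout: ``<root>/images/<split>/*.png|jpg`` paired with
``<root>/labels/<split>/*.txt``; each label line is
``class cx cy w h`` with normalized center/size coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _resize

IMG_EXTS = (".png", ".jpg", ".jpeg")
PAD_VALUE = 114  # neutral gray used for letterbox padding


@dataclass(frozen=True)
class GroundTruthLabel:
    """One annotated object: 0-based class, normalized center-size box."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def to_xyxy(self, width: float, height: float) -> tuple:
        """Absolute half-open pixel corners for an image of given size."""
        return ((self.cx - self.w / 2) * width, (self.cy - self.h / 2) * height,
                (self.cx + self.w / 2) * width, (self.cy + self.h / 2) * height)

    def validate(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"non-positive box size: {self}")
        for v in (self.cx, self.cy):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"center outside [0,1]: {self}")


def write_labels(path, labels: list[GroundTruthLabel]):
    with open(path, "w") as fh:
        for lb in labels:
            fh.write(f"{lb.class_id} {lb.cx:.6f} {lb.cy:.6f} {lb.w:.6f} {lb.h:.6f}\n")


def read_labels(path) -> list[GroundTruthLabel]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5:
                raise ValueError(f"malformed label line in {path!s}: {line!r}")
            out.append(GroundTruthLabel(int(parts[0]), *(float(v) for v in parts[1:])))
    return out


def list_dataset(root, split: str) -> list[tuple[Path, Path]]:
    """Paired (image, label) paths for a split; fails fast when empty or
    a label file is missing."""
    root = Path(root)
    img_dir = root / "images" / split
    lbl_dir = root / "labels" / split
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no image directory {img_dir}")
    pairs = []
    for img in sorted(img_dir.iterdir()):
        if img.suffix.lower() not in IMG_EXTS:
            continue
        lbl = lbl_dir / (img.stem + ".txt")
        if not lbl.is_file():
            raise FileNotFoundError(f"missing label file {lbl} for image {img}")
        pairs.append((img, lbl))
    if not pairs:
        raise FileNotFoundError(f"no images found under {img_dir}")
    return pairs


def load_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3]


def letterbox(img: np.ndarray, size: int,
              labels: list[GroundTruthLabel] | None = None):
    """Aspect-preserving resize onto a ``size``×``size`` gray canvas.

    Returns ``(canvas, labels)`` with labels remapped to the canvas frame
    (unchanged if None).
    """
    h, w = img.shape[:2]
    scale = size / max(h, w)
    nh, nw = round(h * scale), round(w * scale)
    if (nh, nw) != (h, w):
        resized = _resize(img, (nh, nw), order=1, preserve_range=True,
                          anti_aliasing=scale < 1).astype(img.dtype)
    else:
        resized = img
    canvas = np.full((size, size, 3), PAD_VALUE, dtype=img.dtype)
    top, left = (size - nh) // 2, (size - nw) // 2
    canvas[top:top + nh, left:left + nw] = resized
    if labels is None:
        return canvas, None
    out = [GroundTruthLabel(lb.class_id,
                            (lb.cx * nw + left) / size, (lb.cy * nh + top) / size,
                            lb.w * nw / size, lb.h * nh / size)
           for lb in labels]
    return canvas, out
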