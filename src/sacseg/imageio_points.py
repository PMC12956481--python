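"""Readers/writers for images, point annotations and coded label maps,
plus geometric augmentation applied consistently to all three.

Conventions (used everywhere in the package):

* coordinates are 0-based ``(row, col)`` pairs;
* coded label maps are single-channel uint8 with 0 = negative/background,
  1 = positive/foreground, 255 = unlabeled (so a binary label saved as PNG
  is still human-viewable);
* images are H×W×3 uint8 RGB, stored as PNG or TIFF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv
from skimage.filters import gaussian
from skimage.transform import AffineTransform, warp

logger = logging.getLogger(__name__)

UNLABELED = 255


class PointValidationError(ValueError):
    pass


@dataclass(frozen=True)
class PointSet:
    """Nucleus centroid coordinates for one image, 0-based (row, col)."""

    coords: tuple
    image_shape: tuple

    def __post_init__(self):
        coords = tuple((int(r), int(c)) for r, c in self.coords)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "image_shape",
                           (int(self.image_shape[0]), int(self.image_shape[1])))
        H, W = self.image_shape
        seen = set()
        for i, (r, c) in enumerate(coords):
            if not (0 <= r < H and 0 <= c < W):
                raise PointValidationError(
                    f"point {i} = ({r}, {c}) outside image of shape {H}x{W}")
            if (r, c) in seen:
                raise PointValidationError(f"duplicate point {i} = ({r}, {c})")
            seen.add((r, c))

    def __len__(self):
        return len(self.coords)

    def as_array(self):
        return np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)


@dataclass
class CodedLabelMap:
    """H×W small-integer label map restricted to a declared coding."""

    values: np.ndarray
    coding: frozenset = field(default_factory=lambda: frozenset({0, 1, UNLABELED}))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("label map must be 2-D")
        self.coding = frozenset(int(v) for v in self.coding)
        self.validate()

    def validate(self):
        present = set(np.unique(self.values).tolist())
        extra = present - self.coding
        if extra:
            raise ValueError(f"label map contains uncoded values {sorted(extra)}")

    @property
    def shape(self):
        return self.values.shape

    def fill_value(self):
        """Value for pixels entering the frame under a geometric transform."""
        return UNLABELED if UNLABELED in self.coding else 0


# ---------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3].astype(np.uint8)


def write_image(image: np.ndarray, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile
        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image).save(path)


def read_label_map(path, coding=frozenset({0, 1, UNLABELED})) -> CodedLabelMap:
    arr = np.asarray(Image.open(path)).astype(np.uint8)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return CodedLabelMap(arr, coding)


def write_label_map(label: CodedLabelMap, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(label.values.astype(np.uint8), mode="L").save(path)


def read_points(path, image_shape) -> PointSet:
    """Read a `row,col` CSV of 0-based pixel coordinates."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["row", "col"]:
        raise PointValidationError(
            f"{path}: expected header 'row,col', got {list(df.columns)}")
    coords = []
    H, W = image_shape
    for i, (r, c) in enumerate(zip(df["row"], df["col"])):
        r, c = int(r), int(c)
        if not (0 <= r < H and 0 <= c < W):
            raise PointValidationError(
                f"{path} row {i}: point ({r}, {c}) outside image {H}x{W}")
        coords.append((r, c))
    return PointSet(tuple(coords), (H, W))


def write_points(points: PointSet, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(points.as_array(), columns=["row", "col"])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

DEFAULT_AUGMENT = {
    "hflip": True,
    "vflip": True,
    "affine": {"rotation_deg": 30.0, "scale": (0.8, 1.2), "shear_deg": 10.0},
    "blur_sigma": (0.0, 1.0),
    "hue_jitter": 0.02,
    "sat_jitter": 0.1,
}

IDENTITY_AUGMENT = {
    "hflip": False,
    "vflip": False,
    "affine": None,
    "blur_sigma": None,
    "hue_jitter": 0.0,
    "sat_jitter": 0.0,
}


def _sample_affine(rng, ops, shape):
    cfg = ops.get("affine")
    if cfg is None:
        return None
    rot = np.deg2rad(rng.uniform(-cfg["rotation_deg"], cfg["rotation_deg"]))
    scale = rng.uniform(*cfg["scale"])
    shear = np.deg2rad(rng.uniform(-cfg["shear_deg"], cfg["shear_deg"]))
    H, W = shape
    # rotate/scale/shear about the image centre, in (x, y) = (col, row) space
    centre = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    t = (AffineTransform(translation=-centre)
         + AffineTransform(rotation=rot, scale=(scale, scale), shear=shear)
         + AffineTransform(translation=centre))
    return t


def augment(image, label_maps, points, ops=None, seed=0):
    """Apply one random augmentation draw consistently to every input.

    Geometric transforms (affine, flips) move the image, every label map
    (nearest-neighbour) and the points identically; photometric transforms
    (Gaussian blur, hue/saturation jitter) touch the image only.  Points
    carried outside the frame are dropped and the drop count logged.

    Returns ``(image, label_maps, points, n_dropped)``.
    """
    ops = DEFAULT_AUGMENT if ops is None else ops
    H, W = image.shape[:2]
    for lm in label_maps:
        if lm.shape != (H, W):
            raise ValueError("image and label maps must share H and W")
    if points.image_shape != (H, W):
        raise ValueError("points declared for a different image shape")
    rng = np.random.default_rng(seed)

    img = image.astype(np.float32) / 255.0
    maps = [lm.values.copy() for lm in label_maps]
    pts = points.as_array().astype(np.float64)

    tform = _sample_affine(rng, ops, (H, W))
    if tform is not None:
        img = warp(img, tform.inverse, order=1, mode="constant", cval=1.0,
                   preserve_range=True)
        maps = [
            warp(m, tform.inverse, order=0, mode="constant",
                 cval=lm.fill_value(), preserve_range=True).astype(m.dtype)
            for m, lm in zip(maps, label_maps)
        ]
        if len(pts):
            xy = np.stack([pts[:, 1], pts[:, 0]], axis=1)
            xy = tform(xy)
            pts = np.stack([xy[:, 1], xy[:, 0]], axis=1)

    def _coin(flag):
        # True → Bernoulli(0.5); "always" → deterministic flip
        if flag == "always":
            return True
        return bool(flag) and rng.random() < 0.5

    if _coin(ops.get("hflip")):
        img = img[:, ::-1]
        maps = [m[:, ::-1] for m in maps]
        if len(pts):
            pts[:, 1] = (W - 1) - pts[:, 1]
    if _coin(ops.get("vflip")):
        img = img[::-1]
        maps = [m[::-1] for m in maps]
        if len(pts):
            pts[:, 0] = (H - 1) - pts[:, 0]

    # photometric: image only
    sig_rng = ops.get("blur_sigma")
    if sig_rng:
        sigma = rng.uniform(*sig_rng)
        if sigma > 1e-3:
            img = gaussian(img, sigma=sigma, channel_axis=-1)
    hj, sj = ops.get("hue_jitter", 0.0), ops.get("sat_jitter", 0.0)
    if hj or sj:
        hsv = rgb2hsv(np.clip(img, 0, 1))
        hsv[..., 0] = np.mod(hsv[..., 0] + rng.uniform(-hj, hj), 1.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-sj, sj)), 0, 1)
        img = hsv2rgb(hsv)

    out_img = np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8)
    out_maps = [CodedLabelMap(np.ascontiguousarray(m), lm.coding)
                for m, lm in zip(maps, label_maps)]

    rounded = np.round(pts).astype(np.int64)
    kept, seen = [], set()
    for r, c in rounded:
        if 0 <= r < H and 0 <= c < W and (r, c) not in seen:
            kept.append((r, c))
            seen.add((r, c))
    n_dropped = len(rounded) - len(kept)
    if n_dropped:
        logger.info("augment: dropped %d point(s) transformed outside the frame",
                    n_dropped)
    out_points = PointSet(tuple(kept), (H, W))
    return out_img, out_maps, out_points, n_dropped
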