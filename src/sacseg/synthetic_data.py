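"""Procedural H&E-like scenes with exact ground truth.

Each scene is a lighter pink textured background with darker purple
rotated-ellipse nuclei, per-nucleus colour jitter and additive pixel
noise — enough texture that SLIC superpixel boundaries are informative
but imperfect, which is the regime the weakly supervised pipeline is
designed for.  Every scene carries its instance masks and one centroid
point per nucleus, so pseudo-labels and predictions can be scored
against a known truth without any external dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import ellipse

from .imageio_points import PointSet, write_image, write_points

BACKGROUND_RGB = np.array([230.0, 200.0, 220.0])
NUCLEUS_RGB = np.array([110.0, 70.0, 140.0])
INSTANCE_JITTER_SIGMA = 15.0
PIXEL_NOISE_SIGMA = 8.0
# semi-axis range in pixels at a 96-px frame; scales linearly with frame size
AXIS_RANGE_AT_96 = (4.0, 12.0)
MAX_PAIRWISE_IOU = 0.30


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without violating the overlap rule."""


@dataclass
class SyntheticScene:
    image: np.ndarray            # H×W×3 uint8
    instance_masks: list         # list of H×W bool
    gt_mask: np.ndarray          # H×W bool, union of instances
    points: PointSet
    seed: int


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    return inter / np.logical_or(a, b).sum()


def _centroid_in_mask(mask: np.ndarray) -> tuple:
    rr, cc = np.nonzero(mask)
    r, c = int(round(rr.mean())), int(round(cc.mean()))
    if mask[r, c]:
        return (r, c)
    # clipped/rounded centroid can fall just off the region: snap to the
    # nearest foreground pixel
    d2 = (rr - r) ** 2 + (cc - c) ** 2
    k = int(np.argmin(d2))
    return (int(rr[k]), int(cc[k]))


def generate_scene(height: int, width: int, n_nuclei: int, seed: int,
                   overlap_allowed: bool = True,
                   max_attempts_per_nucleus: int = 200) -> SyntheticScene:
    """Render one scene; bit-deterministic for a fixed seed.

    With ``overlap_allowed`` (default) instances may overlap up to a
    pairwise IoU of 0.30, mimicking touching nuclei; without it instances
    are disjoint and placement failure raises :class:`PlacementError`.
    """
    if height < 32 or width < 32:
        raise ValueError("frame must be at least 32x32")
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)
    scale = min(height, width) / 96.0
    ax_lo, ax_hi = (AXIS_RANGE_AT_96[0] * scale, AXIS_RANGE_AT_96[1] * scale)
    ax_lo, ax_hi = max(ax_lo, 1.5), max(ax_hi, 2.5)

    masks: list[np.ndarray] = []
    for _ in range(n_nuclei):
        placed = False
        for _attempt in range(max_attempts_per_nucleus):
            minor = rng.uniform(ax_lo, 0.6 * ax_hi)
            major = rng.uniform(minor, ax_hi)
            theta = rng.uniform(0, np.pi)
            r0 = rng.uniform(0, height - 1)
            c0 = rng.uniform(0, width - 1)
            rr, cc = ellipse(r0, c0, major, minor, shape=(height, width),
                             rotation=theta)
            if rr.size < 4:
                continue
            cand = np.zeros((height, width), dtype=bool)
            cand[rr, cc] = True
            if overlap_allowed:
                ok = all(_mask_iou(cand, m) <= MAX_PAIRWISE_IOU for m in masks)
            else:
                ok = not any(np.logical_and(cand, m).any() for m in masks)
            if ok:
                masks.append(cand)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {len(masks)} after "
                f"{max_attempts_per_nucleus} attempts in a {height}x{width} frame")

    # render: background, then nuclei (later instances paint over earlier)
    img = np.empty((height, width, 3), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    for m in masks:
        colour = NUCLEUS_RGB + rng.normal(0, INSTANCE_JITTER_SIGMA, size=3)
        img[m] = colour
    img += rng.normal(0, PIXEL_NOISE_SIGMA, size=img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)

    # centroids recomputed from the rendered (possibly clipped) masks
    coords, used = [], set()
    for m in masks:
        r, c = _centroid_in_mask(m)
        if (r, c) in used:  # overlapping instances can share a centroid pixel
            rr_, cc_ = np.nonzero(m)
            for k in np.argsort((rr_ - r) ** 2 + (cc_ - c) ** 2):
                cand_pt = (int(rr_[k]), int(cc_[k]))
                if cand_pt not in used:
                    r, c = cand_pt
                    break
            else:  # pragma: no cover - would need a fully shadowed instance
                raise PlacementError("no free centroid pixel for instance")
        coords.append((r, c))
        used.add((r, c))

    gt = np.zeros((height, width), dtype=bool)
    for m in masks:
        gt |= m
    return SyntheticScene(image=image, instance_masks=masks, gt_mask=gt,
                          points=PointSet(tuple(coords), (height, width)),
                          seed=seed)


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-image seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def generate_dataset(n_images: int, height: int, width: int,
                     n_nuclei_range, seed: int,
                     overlap_allowed: bool = True) -> list:
    """Generate ``n_images`` scenes with per-image seeds derived from ``seed``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    lo, hi = int(n_nuclei_range[0]), int(n_nuclei_range[1])
    scenes = []
    for i in range(n_images):
        s = child_seed(seed, i)
        count_rng = np.random.default_rng(child_seed(seed, 10_000 + i))
        n = int(count_rng.integers(lo, hi + 1))
        scenes.append(generate_scene(height, width, n, s,
                                     overlap_allowed=overlap_allowed))
    return scenes


def write_dataset(scenes, out_dir) -> list:
    """Write scenes in the on-disk layout:

    ``images/<id>.png``, ``masks/<id>.png`` (0/255),
    ``points/<id>.csv`` (header ``row,col``), ``meta.json``.
    """
    out = Path(out_dir)
    ids = []
    meta = {"images": {}}
    for i, sc in enumerate(scenes):
        sid = f"img_{i:03d}"
        ids.append(sid)
        write_image(sc.image, out / "images" / f"{sid}.png")
        write_image((sc.gt_mask.astype(np.uint8) * 255), out / "masks" / f"{sid}.png")
        write_points(sc.points, out / "points" / f"{sid}.csv")
        meta["images"][sid] = {
            "seed": sc.seed,
            "height": int(sc.image.shape[0]),
            "width": int(sc.image.shape[1]),
            "n_nuclei": len(sc.instance_masks),
        }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return ids
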