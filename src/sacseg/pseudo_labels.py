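"""Pseudo-labels from point annotations.

Two complementary label families drive training:

* **Voronoi labels** — the frame is partitioned into nearest-point cells;
  small discs around the points become positives, the inter-cell ridges
  become negatives, everything else stays unlabeled.  They encode global
  topology (one nucleus per cell) but say nothing about true boundaries.
* **Superpixel labels** — SLIC oversegments the RGB image and every
  superpixel containing at least one point is marked foreground.  They
  follow local colour boundaries but inherit SLIC's over/under-
  segmentation noise.

Also here: the point-perturbation model for annotation-noise experiments
and Reinhard LAB colour normalisation for stain variation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import lab2rgb, rgb2lab
from skimage.segmentation import slic
from scipy import ndimage

from .imageio_points import UNLABELED, CodedLabelMap, PointSet

logger = logging.getLogger(__name__)

DEFAULT_R_PT = 2
DEFAULT_RIDGE_WIDTH = 1
DEFAULT_COMPACTNESS = 10.0
SLIC_PIXELS_PER_SEGMENT = 150


@dataclass
class VoronoiLabel:
    label: CodedLabelMap          # 1 positive, 0 negative, 255 unlabeled
    cell_index: np.ndarray        # H×W int, nearest point index


@dataclass
class SuperpixelLabel:
    label: CodedLabelMap          # binary, no unlabeled code
    sp_index: np.ndarray          # H×W int, SLIC membership


def voronoi_partition(points: PointSet, shape) -> np.ndarray:
    """Nearest-point cell index per pixel (Euclidean, ties to lowest index)."""
    if len(points) == 0:
        raise ValueError("voronoi_partition needs at least one point")
    H, W = int(shape[0]), int(shape[1])
    pts = points.as_array()                            # int64: exact distances,
    rows = np.arange(H, dtype=np.int64)[:, None]       # ties resolve by index
    cols = np.arange(W, dtype=np.int64)[None, :]
    # the (h, W, n) distance stack is fine at the tile sizes this package
    # targets; chunk over rows to bound memory on larger frames
    out = np.empty((H, W), dtype=np.int64)
    chunk = max(1, int(4_000_000 / max(1, len(points) * W)))
    for r0 in range(0, H, chunk):
        r1 = min(H, r0 + chunk)
        dr = rows[r0:r1, :, None] - pts[:, 0]          # (h, 1, n)
        dc = cols[:, :, None] - pts[:, 1]              # (1, W, n)
        d2 = dr * dr + dc * dc                         # (h, W, n)
        out[r0:r1] = np.argmin(d2, axis=2)             # argmin = lowest index on ties
    return out


def min_point_distance(points: PointSet, shape) -> np.ndarray:
    """Euclidean distance from each pixel to its nearest point."""
    H, W = int(shape[0]), int(shape[1])
    seeds = np.ones((H, W), dtype=bool)
    arr = points.as_array()
    seeds[arr[:, 0], arr[:, 1]] = False
    return ndimage.distance_transform_edt(seeds)


def make_voronoi_label(points: PointSet, shape, r_pt: int = DEFAULT_R_PT,
                       ridge_width: int = DEFAULT_RIDGE_WIDTH) -> VoronoiLabel:
    """Tri-state Voronoi label: point discs positive, cell ridges negative."""
    if r_pt < 0:
        raise ValueError("r_pt must be >= 0")
    if ridge_width < 0:
        raise ValueError("ridge_width must be >= 0")
    cell = voronoi_partition(points, shape)
    H, W = cell.shape
    positives = min_point_distance(points, shape) <= r_pt
    if ridge_width == 0:
        ridges = np.zeros((H, W), dtype=bool)
    else:
        size = 2 * ridge_width + 1
        ridges = (ndimage.maximum_filter(cell, size=size)
                  != ndimage.minimum_filter(cell, size=size))
    values = np.full((H, W), UNLABELED, dtype=np.uint8)
    values[ridges & ~positives] = 0
    values[positives] = 1
    return VoronoiLabel(label=CodedLabelMap(values), cell_index=cell)


def make_superpixel_label(image: np.ndarray, points: PointSet,
                          n_segments: int | None = None,
                          compactness: float = DEFAULT_COMPACTNESS) -> SuperpixelLabel:
    """Binary label marking SLIC superpixels that contain a point."""
    H, W = image.shape[:2]
    if points.image_shape != (H, W):
        raise ValueError("image and points must share H and W")
    if n_segments is None:
        n_segments = max(2, (H * W) // SLIC_PIXELS_PER_SEGMENT)
    sp = slic(image, n_segments=n_segments, compactness=compactness,
              start_label=0, channel_axis=-1)
    if len(points) == 0:
        warnings.warn("make_superpixel_label: no points; all-background label")
        values = np.zeros((H, W), dtype=np.uint8)
        return SuperpixelLabel(label=CodedLabelMap(values, frozenset({0, 1})),
                               sp_index=sp)
    arr = points.as_array()
    fg_ids = np.unique(sp[arr[:, 0], arr[:, 1]])
    values = np.isin(sp, fg_ids).astype(np.uint8)
    return SuperpixelLabel(label=CodedLabelMap(values, frozenset({0, 1})),
                           sp_index=sp)


def _best_integer_displacement(r: float, theta: float) -> tuple:
    """Integer displacement with norm closest to ``r`` among the four
    roundings of (r sinθ, r cosθ); ties broken by distance to the real
    vector.  Guarantees the realised shift stays within half a pixel of
    the requested radius in norm."""
    dy, dx = r * np.sin(theta), r * np.cos(theta)
    best, best_key = (0, 0), None
    for fy in (np.floor(dy), np.ceil(dy)):
        for fx in (np.floor(dx), np.ceil(dx)):
            iy, ix = int(fy), int(fx)
            norm = np.hypot(iy, ix)
            key = (abs(norm - r), (iy - dy) ** 2 + (ix - dx) ** 2)
            if best_key is None or key < best_key:
                best, best_key = (iy, ix), key
    return best


def perturb_points(points: PointSet, r: int, seed: int = 0,
                   mode: str = "fixed") -> PointSet:
    """Displace every point by radius ``r`` in an independent random direction.

    ``mode='fixed'`` (default) shifts by exactly ``r`` pixels (after snapping
    to the grid); ``mode='range'`` draws the radius uniformly in ``[3, 5]``
    per point, for the alternative reading of a 3–5 px annotation shift.
    ``r = 0`` is the identity.  Shifts are clipped to the frame, and a
    colliding destination is re-drawn so points remain distinct.
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    if r == 0 and mode == "fixed":
        return points
    rng = np.random.default_rng(seed)
    H, W = points.image_shape
    out, used = [], set()
    for (row, col) in points.coords:
        placed = False
        for _ in range(200):
            radius = rng.uniform(3.0, 5.0) if mode == "range" else float(r)
            theta = rng.uniform(0, 2 * np.pi)
            dy, dx = _best_integer_displacement(radius, theta)
            nr = int(np.clip(row + dy, 0, H - 1))
            nc = int(np.clip(col + dx, 0, W - 1))
            if (nr, nc) not in used:
                out.append((nr, nc))
                used.add((nr, nc))
                placed = True
                break
        if not placed:  # crowded corner: fall back to the original location
            for cand in [(row, col)] + [(row + a, col + b)
                                        for a in range(-r, r + 1)
                                        for b in range(-r, r + 1)]:
                nr = int(np.clip(cand[0], 0, H - 1))
                nc = int(np.clip(cand[1], 0, W - 1))
                if (nr, nc) not in used:
                    out.append((nr, nc))
                    used.add((nr, nc))
                    break
    return PointSet(tuple(out), (H, W))


def color_normalize(image: np.ndarray, reference_image: np.ndarray) -> np.ndarray:
    """Reinhard normalisation: match per-channel LAB mean/std to a reference."""
    img = np.asarray(image)
    ref = np.asarray(reference_image)
    lab = rgb2lab(img.astype(np.float64) / 255.0)
    lab_ref = rgb2lab(ref.astype(np.float64) / 255.0)
    std = lab.reshape(-1, 3).std(axis=0)
    if np.any(std < 1e-6):
        warnings.warn("color_normalize: constant-valued channel; "
                      "returning image unchanged")
        return img.copy()
    mean = lab.reshape(-1, 3).mean(axis=0)
    ref_mean = lab_ref.reshape(-1, 3).mean(axis=0)
    ref_std = lab_ref.reshape(-1, 3).std(axis=0)
    out_lab = (lab - mean) / std * ref_std + ref_mean
    out = lab2rgb(out_lab)
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)
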