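"""Pixel-level label-noise estimation and correction (confident learning).

Given per-pixel class probabilities from a trained model and the noisy
superpixel labels, the procedure is:

1. per-class confidence thresholds ``t_j`` — the mean predicted
   probability of class j over the pixels currently labeled j;
2. a counting matrix ``C[i][j]`` of pixels labeled i but confidently
   predicted j (probability above ``t_j`` and j the argmax class);
3. the calibrated joint distribution ``Q`` — each row of C rescaled to
   the labeled-class frequency, then normalised to sum to one;
4. correction — for every off-diagonal cell (i, j), the
   ``round(n·Q[i][j])`` pixels labeled i with the largest margin
   ``p̂(j) − p̂(i)`` are flipped to j.

Binary case here: class 0 is background, class 1 foreground, with
``p̂(1) = f(I)`` and ``p̂(0) = 1 − f(I)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .imageio_points import CodedLabelMap

logger = logging.getLogger(__name__)

N_CLASSES = 2


@dataclass
class PixelDataset:
    """Flattened per-pixel probabilities and given labels."""

    probs: np.ndarray                 # (n, m) rows sum to 1
    labels: np.ndarray                # (n,) values in {0, 1}
    pixel_index: np.ndarray | None = None  # optional map back to (image,row,col)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.probs.ndim != 2:
            raise ValueError("probs must be (n, m)")
        if self.probs.shape[0] != self.labels.shape[0]:
            raise ValueError("probs and labels length mismatch")
        if not np.all(np.isin(self.labels, [0, 1])):
            raise ValueError("labels must be in {0, 1}")
        rs = self.probs.sum(axis=1)
        if self.probs.size and not np.allclose(rs, 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    def __len__(self):
        return self.labels.shape[0]

    @classmethod
    def from_probability_map(cls, prob_map: np.ndarray, label_map) -> "PixelDataset":
        """Build from a foreground-probability map and a binary label map."""
        p1 = np.asarray(prob_map, dtype=np.float64).ravel()
        labels = np.asarray(getattr(label_map, "values", label_map)).ravel()
        probs = np.stack([1.0 - p1, p1], axis=1)
        return cls(probs=probs, labels=labels)


@dataclass
class NoiseModel:
    t: np.ndarray                     # (m,) class thresholds
    C: np.ndarray                     # (m, m) counting matrix, int
    Q: np.ndarray                     # (m, m) joint distribution


@dataclass
class RefinedLabel:
    label: CodedLabelMap              # binary refined label y_re
    flip_mask: np.ndarray             # H×W bool, corrected pixels


def class_thresholds(data: PixelDataset) -> np.ndarray:
    """t_j = mean predicted probability of class j over pixels labeled j."""
    m = data.probs.shape[1]
    t = np.empty(m, dtype=np.float64)
    for j in range(m):
        mask = data.labels == j
        if not mask.any():
            raise ValueError(f"class_thresholds: no pixels labeled {j}")
        t[j] = data.probs[mask, j].mean()
    return t


def counting_matrix(data: PixelDataset, t: np.ndarray) -> np.ndarray:
    """C[i][j] = #{z : label(z)=i, argmax_k p̂(k;z)=j, p̂(j;z) > t_j}.

    The strict inequality is relaxed to ``>=`` when ``t_j = 1`` so that
    perfectly confident one-hot predictions are still counted.
    """
    t = np.asarray(t, dtype=np.float64)
    m = data.probs.shape[1]
    pred = data.probs.argmax(axis=1)
    pmax = data.probs[np.arange(len(data)), pred]
    tj = t[pred]
    confident = np.where(tj >= 1.0, pmax >= tj, pmax > tj)
    C = np.zeros((m, m), dtype=np.int64)
    np.add.at(C, (data.labels[confident], pred[confident]), 1)
    return C


def joint_distribution(C: np.ndarray, data: PixelDataset) -> np.ndarray:
    """Row-calibrated, globally normalised joint distribution Q."""
    C = np.asarray(C, dtype=np.float64)
    m = C.shape[0]
    row_sums = C.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = int(np.argmin(row_sums))
        raise ValueError(
            f"joint_distribution: row {bad} of the counting matrix is empty; "
            "train longer or lower the confidence thresholds")
    label_counts = np.array([(data.labels == i).sum() for i in range(m)],
                            dtype=np.float64)
    scaled = C / row_sums[:, None] * label_counts[:, None]
    return scaled / scaled.sum()


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def correct_labels(data: PixelDataset, Q: np.ndarray, t: np.ndarray | None = None):
    """Flip the highest-margin off-diagonal pixels; returns
    ``(refined_labels, flip_mask)`` as flat arrays over the dataset.

    For each off-diagonal cell (i, j) the ``round(n·Q[i][j])`` corrections
    are extracted from that cell of the counting matrix — pixels labeled i
    but confidently predicted j — ranked by the margin ``p̂(j) − p̂(i)``.
    When thresholds are given the candidate set is exactly the counted
    one; without them every pixel labeled i is a candidate.  If the budget
    exceeds the candidates, all candidates flip and a warning is logged.
    """
    Q = np.asarray(Q, dtype=np.float64)
    n = len(data)
    labels = data.labels.copy()
    flip = np.zeros(n, dtype=bool)
    m = Q.shape[0]
    pred = data.probs.argmax(axis=1)
    if t is not None:
        t = np.asarray(t, dtype=np.float64)
        pj = data.probs[np.arange(n), pred]
        tj = t[pred]
        confident = np.where(tj >= 1.0, pj >= tj, pj > tj)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            k = _round_half_away(n * Q[i, j])
            if k <= 0:
                continue
            cand = (data.labels == i)
            if t is not None:
                cand = cand & (pred == j) & confident
            cand = np.nonzero(cand)[0]
            if k > cand.size:
                logger.warning(
                    "correct_labels: requested %d flips %d->%d but only %d "
                    "candidate pixels; flipping all", k, i, j, cand.size)
                k = cand.size
            margin = data.probs[cand, j] - data.probs[cand, i]
            # stable sort on negated margin: ties resolve to lowest pixel index
            order = np.argsort(-margin, kind="stable")[:k]
            chosen = cand[order]
            labels[chosen] = j
            flip[chosen] = True
    return labels, flip


def refine_pixels(data: PixelDataset) -> tuple:
    """thresholds → counting matrix → Q → correction, on one dataset."""
    t = class_thresholds(data)
    C = counting_matrix(data, t)
    Q = joint_distribution(C, data)
    labels, flip = correct_labels(data, Q, t=t)
    return labels, flip, NoiseModel(t=t, C=C, Q=Q)


def refine_dataset(model_probs: dict, superpixel_labels: dict,
                   scope: str = "per_image"):
    """Confident-learning refinement over a set of images.

    Parameters
    ----------
    model_probs : dict of image id → H×W foreground-probability map
        Probabilities from the trained stage-1 model in eval mode.
    superpixel_labels : dict of image id → binary label array (or
        CodedLabelMap)
    scope : "per_image" (thresholds, C, Q and flip budgets within each
        image) or "pooled" (one noise model over all pixels).

    Returns ``(refined, summary)`` where refined maps image id →
    :class:`RefinedLabel` and summary carries t, C, Q and flip counts.
    """
    if scope not in ("per_image", "pooled"):
        raise ValueError("scope must be 'per_image' or 'pooled'")
    ids = sorted(model_probs)
    if sorted(superpixel_labels) != ids:
        raise ValueError("model_probs and superpixel_labels ids differ")
    refined: dict[str, RefinedLabel] = {}
    summary: dict = {"scope": scope, "per_image": {}}
    flips_01 = flips_10 = 0

    def _to_refined(labels_flat, flip_flat, shape):
        lab = labels_flat.reshape(shape).astype(np.uint8)
        return RefinedLabel(label=CodedLabelMap(lab, frozenset({0, 1})),
                            flip_mask=flip_flat.reshape(shape))

    if scope == "per_image":
        for sid in ids:
            shape = np.asarray(model_probs[sid]).shape
            data = PixelDataset.from_probability_map(
                model_probs[sid], superpixel_labels[sid])
            labels, flip, nm = refine_pixels(data)
            refined[sid] = _to_refined(labels, flip, shape)
            n01 = int(((data.labels == 0) & flip).sum())
            n10 = int(((data.labels == 1) & flip).sum())
            flips_01 += n01
            flips_10 += n10
            summary["per_image"][sid] = {
                "t": nm.t.tolist(), "C": nm.C.tolist(), "Q": nm.Q.tolist(),
                "flips_bg_to_fg": n01, "flips_fg_to_bg": n10,
                "flip_fraction": float(flip.mean()),
            }
    else:
        shapes = {sid: np.asarray(model_probs[sid]).shape for sid in ids}
        datasets = [PixelDataset.from_probability_map(
            model_probs[sid], superpixel_labels[sid]) for sid in ids]
        pooled = PixelDataset(
            probs=np.concatenate([d.probs for d in datasets]),
            labels=np.concatenate([d.labels for d in datasets]))
        labels, flip, nm = refine_pixels(pooled)
        off = 0
        for sid, d in zip(ids, datasets):
            n = len(d)
            refined[sid] = _to_refined(labels[off:off + n], flip[off:off + n],
                                       shapes[sid])
            off += n
        flips_01 = int(((pooled.labels == 0) & flip).sum())
        flips_10 = int(((pooled.labels == 1) & flip).sum())
        summary["pooled"] = {"t": nm.t.tolist(), "C": nm.C.tolist(),
                             "Q": nm.Q.tolist()}
    summary["flips_bg_to_fg"] = int(flips_01)
    summary["flips_fg_to_bg"] = int(flips_10)
    total_px = sum(int(np.prod(np.asarray(model_probs[s]).shape)) for s in ids)
    summary["flip_fraction"] = (flips_01 + flips_10) / max(1, total_px)
    return refined, summary
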