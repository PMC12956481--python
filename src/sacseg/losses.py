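"""Training objectives for the three branches.

* ``seg_loss`` — binary cross-entropy between the attention-masked
  SegNet prediction ``f(I) ⊙ f_att`` and the superpixel label.
* ``att_loss`` — partial L1 loss of the attention map against the
  tri-state Voronoi label: positives and negatives both pull the map
  toward 1 (the map marks *confident* regions, nucleus core or clear
  background alike); unlabeled pixels contribute nothing.  The
  ``neg_target`` flag provides the alternative reading where negatives
  pull toward 0.
* ``cons_loss`` — mean per-channel L1 between SegNet's output and the
  N-channel ConsNet output.
* ``total_loss`` — β·L_seg + γ·L_att + δ·L_cons.

Gradient flow: by default ``f_att`` is detached inside ``seg_loss`` and
``f(I)`` inside ``cons_loss``, so AttNet learns only from its own loss
and the constraint loss trains ConsNet's output branch — this blocks the
degenerate solution where the attention map collapses to zero to zero
out the segmentation loss.  ``detach=False`` restores fully joint
gradients for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imageio_points import UNLABELED
from .nn import functional as F
from .nn.autodiff import Tensor, as_tensor

BCE_EPS = 1e-7


@dataclass
class LossWeights:
    """alpha balances Voronoi positives/negatives; beta, gamma, delta
    weight the three losses in the total."""

    alpha: float = 0.4
    beta: float = 0.8
    gamma: float = 1.0
    delta: float = 0.4

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.delta) < 0:
            raise ValueError("loss weights must be >= 0")


def _label_array(y) -> np.ndarray:
    values = getattr(y, "values", None)
    if values is None:
        values = getattr(getattr(y, "label", None), "values", y)
    return np.asarray(values)


def seg_loss(pred, f_att, y_s, detach=True) -> Tensor:
    """Mean BCE between ``pred ⊙ f_att`` and the binary superpixel label."""
    pred = as_tensor(pred)
    f_att = as_tensor(f_att)
    ys = _label_array(y_s)
    if np.any(ys == UNLABELED):
        raise ValueError("seg_loss: superpixel label must be binary "
                         "(unlabeled code 255 found)")
    if detach:
        f_att = f_att.detach()
    y = ys.reshape(f_att.shape).astype(pred.data.dtype)
    q = F.clamp(F.mul(pred, f_att), BCE_EPS, 1.0 - BCE_EPS)
    ll = F.add(F.mul(Tensor(y), F.log(q)),
               F.mul(Tensor(1.0 - y), F.log(F.sub(Tensor(np.array(1.0, dtype=pred.data.dtype)), q))))
    return F.neg(F.mean_all(ll))


def att_loss(f_att, y_v, alpha: float = 0.4, neg_target: float = 1.0) -> Tensor:
    """Partial per-pixel L1 loss on the labeled Voronoi pixels.

    ``Σ_{p∈y_v+} |1 − f_att(p)| / |y_v+| + α · Σ_{p∈y_v−} |t − f_att(p)| / |y_v−|``
    with ``t = neg_target`` (1 as printed; 0 for the alternative reading).
    """
    f_att = as_tensor(f_att)
    yv = _label_array(y_v)
    pos = (yv == 1)
    negm = (yv == 0)
    if not pos.any():
        raise ValueError("att_loss: Voronoi label has no positive pixels")
    if not negm.any():
        raise ValueError("att_loss: Voronoi label has no negative pixels")
    dt = f_att.data.dtype
    pos_m = Tensor(pos.reshape(f_att.shape).astype(dt))
    neg_m = Tensor(negm.reshape(f_att.shape).astype(dt))
    one = Tensor(np.array(1.0, dtype=dt))
    tgt = Tensor(np.array(neg_target, dtype=dt))
    pos_term = F.sum_all(F.mul(F.absolute(F.sub(one, f_att)), pos_m))
    neg_term = F.sum_all(F.mul(F.absolute(F.sub(tgt, f_att)), neg_m))
    return F.add(F.mul(pos_term, Tensor(np.array(1.0 / pos.sum(), dtype=dt))),
                 F.mul(neg_term, Tensor(np.array(alpha / negm.sum(), dtype=dt))))


def cons_loss(f_I, h, detach=True) -> Tensor:
    """(1/N) Σ_n mean |f(I) − h_n| over the N ConsNet channels."""
    f_I = as_tensor(f_I)
    h = as_tensor(h)
    if h.ndim < 1 or h.shape[1] == 0:
        raise ValueError("cons_loss: ConsNet output has zero channels")
    if detach:
        f_I = f_I.detach()
    return F.mean_all(F.absolute(F.sub(h, f_I)))


def total_loss(L_seg, L_att, L_cons, w: LossWeights):
    """β·L_seg + γ·L_att + δ·L_cons; floats in → float out."""
    parts = (L_seg, L_att, L_cons)
    for p in parts:
        val = p.item() if isinstance(p, Tensor) else float(p)
        if not np.isfinite(val):
            raise ValueError("total_loss: non-finite component")
    if not any(isinstance(p, Tensor) for p in parts):
        return w.beta * float(L_seg) + w.gamma * float(L_att) + w.delta * float(L_cons)
    terms = [F.mul(as_tensor(p), Tensor(np.array(c, dtype=np.float64)))
             for p, c in zip(parts, (w.beta, w.gamma, w.delta))]
    return F.add(F.add(terms[0], terms[1]), terms[2])
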