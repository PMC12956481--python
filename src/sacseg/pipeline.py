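"""Two-stage orchestration: joint training on pseudo-labels, confident-
learning refinement, retraining, and evaluation.

Stage 1 trains SegNet, AttNet and ConsNet jointly on Voronoi + superpixel
pseudo-labels with Adam (plateau-halved learning rate).  Stage 2 predicts
the training images with the stage-1 model, corrects the superpixel
labels pixel-wise with confident learning, and retrains the whole
three-branch network from scratch on the refined labels (which also feed
AttNet's fourth input channel).

All artifacts of a full run land in one run directory: the dataset,
pseudo-labels, both checkpoints, the confident-learning summary, metrics
for both stages and a label-quality report.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import confident_learning as cl
from . import pseudo_labels as pl
from . import synthetic_data as synth
from .imageio_points import (DEFAULT_AUGMENT, UNLABELED, CodedLabelMap,
                             PointSet, augment, read_image, read_label_map,
                             read_points, write_image, write_label_map)
from .losses import LossWeights, att_loss, cons_loss, seg_loss, total_loss
from .nn import Adam
from .nn.autodiff import Tensor
from .sacnet import NetConfig, PlainUNet, SACNet, image_to_input

logger = logging.getLogger(__name__)

# instrumentation hook: called as hook(image_id, attnet_label_values) on
# every training forward; used by tests to verify which label feeds AttNet
ATTNET_INPUT_HOOK = None


@dataclass
class TrainConfig:
    lr: float = 0.001
    weight_decay: float = 0.0005
    epochs: int = 60
    batch_size: int = 1
    plateau_patience_epochs: int = 4
    lr_halving_factor: float = 0.5
    loss_weights: LossWeights = field(default_factory=LossWeights)
    net: NetConfig = field(default_factory=NetConfig)
    augmentation: dict | None = field(default_factory=lambda: dict(DEFAULT_AUGMENT))
    seed: int = 0
    val_fraction: float = 0.2
    detach: bool = True
    att_neg_target: float = 1.0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class RunRecord:
    stage: int
    epochs: list = field(default_factory=list)   # per-epoch loss dicts
    lr_trace: list = field(default_factory=list)
    checkpoint_path: str | None = None
    best_epoch: int | None = None

    def to_json(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class Sample:
    sid: str
    image: np.ndarray
    points: PointSet
    voronoi: CodedLabelMap
    superpixel: CodedLabelMap
    gt_mask: np.ndarray | None = None


# ---------------------------------------------------------------------
# dataset + pseudo-label I/O
# ---------------------------------------------------------------------

def dataset_ids(dataset_dir) -> list:
    img_dir = Path(dataset_dir) / "images"
    return sorted(p.stem for p in img_dir.glob("*.png"))


def make_pseudo_labels(dataset_dir, out_dir, r_pt=pl.DEFAULT_R_PT,
                       ridge_width=pl.DEFAULT_RIDGE_WIDTH, n_segments=None,
                       compactness=pl.DEFAULT_COMPACTNESS, shift_r=0,
                       shift_mode="fixed", shift_seed=0,
                       color_norm_ref=None) -> list:
    """Generate and write Voronoi + superpixel labels for every image."""
    dataset_dir, out_dir = Path(dataset_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_img = read_image(color_norm_ref) if color_norm_ref else None
    ids = dataset_ids(dataset_dir)
    if not ids:
        raise FileNotFoundError(f"no images under {dataset_dir}/images")
    for k, sid in enumerate(ids):
        image = read_image(dataset_dir / "images" / f"{sid}.png")
        if ref_img is not None:
            image = pl.color_normalize(image, ref_img)
            write_image(image, out_dir / f"{sid}_normalized.png")
        pts_path = dataset_dir / "points" / f"{sid}.csv"
        if not pts_path.exists():
            raise FileNotFoundError(f"missing point annotations for {sid}")
        points = read_points(pts_path, image.shape[:2])
        if shift_r > 0 or shift_mode == "range":
            points = pl.perturb_points(points, shift_r,
                                       seed=synth.child_seed(shift_seed, k),
                                       mode=shift_mode)
        vor = pl.make_voronoi_label(points, image.shape[:2], r_pt=r_pt,
                                    ridge_width=ridge_width)
        sup = pl.make_superpixel_label(image, points, n_segments=n_segments,
                                       compactness=compactness)
        write_label_map(vor.label, out_dir / f"{sid}_voronoi.png")
        write_label_map(sup.label, out_dir / f"{sid}_superpixel.png")
        _write_spindex(sup.sp_index, out_dir / f"{sid}_spindex.png")
    return ids


def _write_spindex(sp_index, path):
    from PIL import Image
    arr = np.asarray(sp_index)
    if arr.max() > 65535:
        raise ValueError("superpixel index exceeds 16-bit PNG range")
    Image.fromarray(arr.astype(np.uint16)).save(path)


def load_samples(dataset_dir, labels_dir, superpixel_override_dir=None) -> list:
    """Assemble training samples; a missing label is an error naming the id."""
    dataset_dir, labels_dir = Path(dataset_dir), Path(labels_dir)
    samples = []
    for sid in dataset_ids(dataset_dir):
        image = read_image(dataset_dir / "images" / f"{sid}.png")
        vor_p = labels_dir / f"{sid}_voronoi.png"
        if superpixel_override_dir is not None:
            sup_p = Path(superpixel_override_dir) / f"{sid}_refined.png"
        else:
            sup_p = labels_dir / f"{sid}_superpixel.png"
        if not vor_p.exists():
            raise FileNotFoundError(f"missing Voronoi label for image '{sid}'")
        if not sup_p.exists():
            raise FileNotFoundError(f"missing superpixel label for image '{sid}'")
        norm_p = labels_dir / f"{sid}_normalized.png"
        if norm_p.exists():
            image = read_image(norm_p)
        points = read_points(dataset_dir / "points" / f"{sid}.csv",
                             image.shape[:2])
        gt_p = dataset_dir / "masks" / f"{sid}.png"
        gt = None
        if gt_p.exists():
            gt = np.asarray(read_label_map(gt_p, frozenset({0, 255})).values) > 127
        samples.append(Sample(
            sid=sid, image=image, points=points,
            voronoi=read_label_map(vor_p),
            superpixel=read_label_map(sup_p, frozenset({0, 1})),
            gt_mask=gt))
    return samples


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

class PlateauScheduler:
    """Halve the learning rate when the monitored loss fails to improve
    for ``patience`` consecutive epochs."""

    def __init__(self, optimizer, patience: int, factor: float = 0.5):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.best = np.inf
        self.stale = 0

    def step(self, value: float) -> bool:
        """Report one epoch's monitored value; returns True if the lr dropped."""
        if value < self.best:
            self.best = value
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.opt.lr *= self.factor
            self.stale = 0
            return True
        return False


def _split(ids, val_fraction, seed):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_val = min(len(ids) - 1, max(1, int(round(val_fraction * len(ids)))))
    val = {ids[i] for i in order[:n_val]}
    return [i for i in ids if i not in val], [i for i in ids if i in val]


def _augmented(sample: Sample, cfg: TrainConfig, epoch: int, idx: int):
    if cfg.augmentation is None:
        return sample.image, sample.voronoi, sample.superpixel
    seed = synth.child_seed(cfg.seed, 1_000_000 + epoch * 10_000 + idx)
    img, (vor, sup), _pts, _ = augment(
        sample.image, [sample.voronoi, sample.superpixel], sample.points,
        ops=cfg.augmentation, seed=seed)
    v = vor.values
    # a draw can rotate every labeled Voronoi pixel out of frame; training
    # needs at least one positive and one negative, so fall back
    if not ((v == 1).any() and (v == 0).any()):
        return sample.image, sample.voronoi, sample.superpixel
    return img, vor, sup


def _forward_losses(model: SACNet, image, vor, sup, cfg: TrainConfig, sid=""):
    x = Tensor(image_to_input(image))
    f_cons, h = model.consnet(x)
    f = model.segnet(x, f_cons=f_cons)
    if ATTNET_INPUT_HOOK is not None:
        ATTNET_INPUT_HOOK(sid, np.array(sup.values))
    f_att = model.attnet(x, sup.values)
    w = cfg.loss_weights
    ls = seg_loss(f, f_att, sup, detach=cfg.detach)
    la = att_loss(f_att, vor, alpha=w.alpha, neg_target=cfg.att_neg_target)
    lc = cons_loss(f, h, detach=cfg.detach)
    lt = total_loss(ls, la, lc, w)
    return lt, ls, la, lc


def train_sacnet(samples, config: TrainConfig, out_dir, stage: int = 1):
    """Optimise the joint loss; returns ``(model, RunRecord)``.

    The best-validation-loss parameters are retained and written to
    ``checkpoint_stage<stage>.npz``; the learning rate is halved whenever
    the validation total loss fails to improve for
    ``plateau_patience_epochs`` consecutive epochs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = [s.sid for s in samples]
    by_id = {s.sid: s for s in samples}
    train_ids, val_ids = _split(ids, config.val_fraction, config.seed)
    net_cfg = copy.deepcopy(config.net)
    net_cfg.seed = synth.child_seed(config.seed, 555 + stage)
    model = SACNet(net_cfg)
    opt = Adam(model.parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    record = RunRecord(stage=stage)
    sched = PlateauScheduler(opt, config.plateau_patience_epochs,
                             config.lr_halving_factor)
    best_val = np.inf
    best_state = None
    best_epoch = None
    log_rows = []

    for epoch in range(config.epochs):
        model.train()
        order = np.random.default_rng(
            synth.child_seed(config.seed, 77 + epoch)).permutation(len(train_ids))
        sums = np.zeros(4)
        opt.zero_grad()
        pending = 0
        for step, oi in enumerate(order):
            s = by_id[train_ids[oi]]
            img, vor, sup = _augmented(s, config, epoch, int(oi))
            lt, ls, la, lc = _forward_losses(model, img, vor, sup, config, s.sid)
            lt.backward()
            pending += 1
            if pending >= config.batch_size or step == len(order) - 1:
                if pending > 1:
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad = p.grad / pending
                opt.step()
                opt.zero_grad()
                pending = 0
            sums += [lt.item(), ls.item(), la.item(), lc.item()]
            log_rows.append({"stage": stage, "epoch": epoch, "image": s.sid,
                             "split": "train", "total": lt.item(),
                             "seg": ls.item(), "att": la.item(),
                             "cons": lc.item()})
        n_tr = len(train_ids)
        model.eval()
        val_tot = 0.0
        for vid in val_ids:
            s = by_id[vid]
            lt, ls, la, lc = _forward_losses(model, s.image, s.voronoi,
                                             s.superpixel, config, s.sid)
            val_tot += lt.item()
            log_rows.append({"stage": stage, "epoch": epoch, "image": s.sid,
                             "split": "val", "total": lt.item(),
                             "seg": ls.item(), "att": la.item(),
                             "cons": lc.item()})
        val_tot /= max(1, len(val_ids))
        record.epochs.append({
            "epoch": epoch,
            "train_total": sums[0] / n_tr, "train_seg": sums[1] / n_tr,
            "train_att": sums[2] / n_tr, "train_cons": sums[3] / n_tr,
            "val_total": val_tot, "lr": opt.lr,
        })
        record.lr_trace.append(opt.lr)
        if val_tot < best_val:
            best_val = val_tot
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            best_epoch = epoch
        if sched.step(val_tot):
            logger.info("stage %d epoch %d: lr halved to %.2e",
                        stage, epoch, opt.lr)
        logger.info("stage %d epoch %d: train %.4f val %.4f lr %.2e",
                    stage, epoch, sums[0] / n_tr, val_tot, opt.lr)

    if best_state is not None:
        model.load_state_dict(best_state)
    ckpt = out_dir / f"checkpoint_stage{stage}.npz"
    model.save(ckpt)
    record.checkpoint_path = str(ckpt)
    record.best_epoch = best_epoch
    record.to_json(out_dir / f"run_record_stage{stage}.json")
    pd.DataFrame(log_rows).to_csv(out_dir / f"loss_log_stage{stage}.csv",
                                  index=False)
    return model, record


def train_stage1(dataset_dir, labels_dir, config: TrainConfig, out_dir):
    samples = load_samples(dataset_dir, labels_dir)
    return train_sacnet(samples, config, out_dir, stage=1)


def train_stage2(dataset_dir, labels_dir, refined_dir, config: TrainConfig,
                 out_dir):
    """Stage-1 recipe with the refined superpixel labels replacing y_s
    everywhere, including AttNet's fourth input channel."""
    samples = load_samples(dataset_dir, labels_dir,
                           superpixel_override_dir=refined_dir)
    return train_sacnet(samples, config, out_dir, stage=2)


# ---------------------------------------------------------------------
# confident-learning refinement step
# ---------------------------------------------------------------------

def refine_labels(model: SACNet, dataset_dir, labels_dir, out_dir,
                  scope="per_image", rounds=1):
    """Predict every image with the trained model and correct its
    superpixel label with confident learning; writes ``<id>_refined.png``,
    ``<id>_flips.png`` and ``cl_summary.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = load_samples(dataset_dir, labels_dir)
    current = {s.sid: np.array(s.superpixel.values) for s in samples}
    summary = None
    for _ in range(max(1, rounds)):
        probs = {s.sid: model.predict_prob(s.image) for s in samples}
        refined, summary = cl.refine_dataset(probs, current, scope=scope)
        current = {sid: np.array(r.label.values) for sid, r in refined.items()}
    for sid, r in refined.items():
        write_label_map(r.label, out_dir / f"{sid}_refined.png")
        write_label_map(CodedLabelMap(r.flip_mask.astype(np.uint8),
                                      frozenset({0, 1})),
                        out_dir / f"{sid}_flips.png")
    (out_dir / "cl_summary.json").write_text(json.dumps(summary, indent=2))
    return refined, summary


# ---------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------

def iou_dice(pred: np.ndarray, gt: np.ndarray) -> tuple:
    """Pixel IoU and Dice of two binary masks (both-empty counts as 1)."""
    pred = np.asarray(pred, bool)
    gt = np.asarray(gt, bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: prediction {pred.shape} vs "
                         f"ground truth {gt.shape}")
    inter = np.logical_and(pred, gt).sum()
    union = np.logical_or(pred, gt).sum()
    if union == 0:
        return 1.0, 1.0
    iou = inter / union
    dice = 2.0 * inter / (pred.sum() + gt.sum())
    return float(iou), float(dice)


def evaluate(model, dataset_dir, threshold=0.5, out_prefix=None) -> dict:
    """Per-image and mean IoU/Dice of the thresholded probability map
    against the ground-truth masks; written as JSON and CSV if requested."""
    dataset_dir = Path(dataset_dir)
    metrics = {}
    ious, dices = [], []
    for sid in dataset_ids(dataset_dir):
        image = read_image(dataset_dir / "images" / f"{sid}.png")
        gt_path = dataset_dir / "masks" / f"{sid}.png"
        if not gt_path.exists():
            raise FileNotFoundError(f"missing ground-truth mask for '{sid}'")
        gt = np.asarray(read_label_map(gt_path, frozenset({0, 255})).values) > 127
        prob = model.predict_prob(image)
        iou, dice = iou_dice(prob >= threshold, gt)
        metrics[sid] = {"iou": iou, "dice": dice}
        ious.append(iou)
        dices.append(dice)
    metrics["mean"] = {"iou": float(np.mean(ious)), "dice": float(np.mean(dices))}
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(f"{out_prefix}.json").write_text(json.dumps(metrics, indent=2))
        pd.DataFrame([{"image": k, **v} for k, v in metrics.items()]).to_csv(
            f"{out_prefix}.csv", index=False)
    return metrics


# ---------------------------------------------------------------------
# full two-stage run
# ---------------------------------------------------------------------

def default_config(seed=0) -> dict:
    """Full-scale defaults (60-epoch training, full-width networks)."""
    return {
        "seed": seed,
        "data": {"n_images": 16, "height": 96, "width": 96,
                 "n_nuclei_range": [6, 14], "overlap_allowed": True},
        "pseudo_labels": {"r_pt": 2, "ridge_width": 1, "n_segments": None,
                          "compactness": 10.0, "shift_r": 0,
                          "shift_mode": "fixed", "color_norm_ref": None},
        "train": {"lr": 0.001, "weight_decay": 0.0005, "epochs": 60,
                  "batch_size": 1, "plateau_patience_epochs": 4,
                  "lr_halving_factor": 0.5, "val_fraction": 0.2,
                  "augmentation": "default",
                  "loss_weights": {"alpha": 0.4, "beta": 0.8, "gamma": 1.0,
                                   "delta": 0.4},
                  "detach": True, "att_neg_target": 1.0},
        "net": {"segnet_encoder": "resnet50", "attnet_encoder": "resnet18",
                "width_multiplier": 1.0, "use_deformable": False,
                "dilation_last_block": 2, "consnet_channels": 3},
        "stage2": {"epochs": None, "cl_scope": "per_image", "cl_rounds": 1},
        "evaluate": {"threshold": 0.5},
        "baseline": {"enabled": False, "epochs": 10, "base_width": 8},
    }


def desk_scale_config(seed=0) -> dict:
    """Desk-scale profile: 16 synthetic 96x96 images, tiny networks,
    5 epochs per stage — a full two-stage run on one CPU in minutes."""
    cfg = default_config(seed)
    cfg["train"].update({"epochs": 5})
    cfg["net"].update({"segnet_encoder": "tiny", "attnet_encoder": "tiny",
                       "width_multiplier": 0.25})
    cfg["stage2"]["epochs"] = 5
    return cfg


def _train_config_from(cfg: dict, stage: int) -> TrainConfig:
    t = cfg["train"]
    aug = t.get("augmentation", "default")
    if aug in (None, "none", "off"):
        aug_ops = None
    elif aug == "default":
        aug_ops = dict(DEFAULT_AUGMENT)
    else:
        aug_ops = dict(aug)
    epochs = t["epochs"]
    if stage == 2 and cfg.get("stage2", {}).get("epochs"):
        epochs = cfg["stage2"]["epochs"]
    return TrainConfig(
        lr=t["lr"], weight_decay=t["weight_decay"], epochs=epochs,
        batch_size=t.get("batch_size", 1),
        plateau_patience_epochs=t["plateau_patience_epochs"],
        lr_halving_factor=t.get("lr_halving_factor", 0.5),
        loss_weights=LossWeights(**t["loss_weights"]),
        net=NetConfig(**cfg["net"]), augmentation=aug_ops,
        seed=synth.child_seed(cfg["seed"], 40 + stage),
        val_fraction=t["val_fraction"], detach=t.get("detach", True),
        att_neg_target=t.get("att_neg_target", 1.0))


def pixel_accuracy(label, gt_mask) -> float:
    lab = np.asarray(getattr(label, "values", label)) > 0
    return float((lab == np.asarray(gt_mask, bool)).mean())


def run_full(config: dict, out_dir, dataset_dir=None) -> dict:
    """Generate/load data → pseudo-labels → stage 1 → CL refinement →
    stage 2 → evaluation.  Returns a result summary; every intermediate
    is written under ``out_dir``."""
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config))

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    if dataset_dir is None:
        d = config["data"]
        scenes = _stage("generate-data", lambda: synth.generate_dataset(
            d["n_images"], d["height"], d["width"],
            tuple(d["n_nuclei_range"]), seed=synth.child_seed(config["seed"], 1),
            overlap_allowed=d.get("overlap_allowed", True)))
        dataset_dir = out_dir / "data"
        _stage("write-data", lambda: synth.write_dataset(scenes, dataset_dir))
    dataset_dir = Path(dataset_dir)

    labels_dir = out_dir / "pseudo_labels"
    p = config["pseudo_labels"]
    _stage("pseudo-labels", lambda: make_pseudo_labels(
        dataset_dir, labels_dir, r_pt=p["r_pt"], ridge_width=p["ridge_width"],
        n_segments=p["n_segments"], compactness=p["compactness"],
        shift_r=p["shift_r"], shift_mode=p.get("shift_mode", "fixed"),
        shift_seed=synth.child_seed(config["seed"], 2),
        color_norm_ref=p.get("color_norm_ref")))

    cfg1 = _train_config_from(config, stage=1)
    model1, rec1 = _stage("train-stage1", lambda: train_stage1(
        dataset_dir, labels_dir, cfg1, out_dir))

    refined_dir = out_dir / "refined_labels"
    s2 = config.get("stage2", {})
    _stage("refine-labels", lambda: refine_labels(
        model1, dataset_dir, labels_dir, refined_dir,
        scope=s2.get("cl_scope", "per_image"),
        rounds=s2.get("cl_rounds", 1)))

    cfg2 = _train_config_from(config, stage=2)
    model2, rec2 = _stage("train-stage2", lambda: train_stage2(
        dataset_dir, labels_dir, refined_dir, cfg2, out_dir))

    thr = config["evaluate"]["threshold"]
    metrics1 = _stage("evaluate-stage1", lambda: evaluate(
        model1, dataset_dir, threshold=thr,
        out_prefix=out_dir / "metrics_stage1"))
    metrics2 = _stage("evaluate-stage2", lambda: evaluate(
        model2, dataset_dir, threshold=thr,
        out_prefix=out_dir / "metrics_stage2"))

    # label-quality report: refined vs original superpixel accuracy w.r.t.
    # the synthetic ground truth
    quality = {}
    n_better = 0
    samples = load_samples(dataset_dir, labels_dir)
    for s in samples:
        if s.gt_mask is None:
            continue
        ref = read_label_map(refined_dir / f"{s.sid}_refined.png",
                             frozenset({0, 1}))
        acc_s = pixel_accuracy(s.superpixel, s.gt_mask)
        acc_re = pixel_accuracy(ref, s.gt_mask)
        quality[s.sid] = {"acc_superpixel": acc_s, "acc_refined": acc_re,
                          "improved": acc_re >= acc_s}
        n_better += acc_re >= acc_s
    if quality:
        quality["fraction_improved_or_equal"] = n_better / len(
            [k for k in quality if k != "fraction_improved_or_equal"])
    (out_dir / "label_quality.json").write_text(json.dumps(quality, indent=2))

    result = {
        "runtime_s": time.time() - t0,
        "stage1": {"metrics": metrics1["mean"],
                   "first_epoch_train_total": rec1.epochs[0]["train_total"],
                   "last_epoch_train_total": rec1.epochs[-1]["train_total"]},
        "stage2": {"metrics": metrics2["mean"]},
        "label_quality_fraction_improved": quality.get(
            "fraction_improved_or_equal"),
    }

    b = config.get("baseline", {})
    if b.get("enabled"):
        bl_metrics = _stage("baseline", lambda: train_supervised_baseline(
            dataset_dir, epochs=b.get("epochs", 10),
            base_width=b.get("base_width", 8),
            seed=synth.child_seed(config["seed"], 9), threshold=thr,
            out_prefix=out_dir / "metrics_baseline"))
        result["baseline"] = {"metrics": bl_metrics["mean"]}

    (out_dir / "result.json").write_text(json.dumps(result, indent=2))
    return result


# ---------------------------------------------------------------------
# fully supervised baseline
# ---------------------------------------------------------------------

def train_supervised_baseline(dataset_dir, epochs=10, base_width=8, seed=0,
                              lr=0.001, threshold=0.5, out_prefix=None):
    """Plain U-Net trained on the ground-truth masks with BCE; the upper
    reference every weakly supervised run is compared against."""
    dataset_dir = Path(dataset_dir)
    ids = dataset_ids(dataset_dir)
    images, gts = [], []
    for sid in ids:
        images.append(read_image(dataset_dir / "images" / f"{sid}.png"))
        gt = read_label_map(dataset_dir / "masks" / f"{sid}.png",
                            frozenset({0, 255})).values > 127
        gts.append(gt.astype(np.float32))
    model = PlainUNet(base_width=base_width, seed=seed)
    opt = Adam(model.parameters(), lr=lr)
    eps = 1e-7
    from .nn import functional as F
    for epoch in range(epochs):
        order = np.random.default_rng(
            synth.child_seed(seed, epoch)).permutation(len(ids))
        for oi in order:
            model.train()
            x = Tensor(image_to_input(images[oi]))
            prob = model(x)
            y = Tensor(gts[oi][None, None])
            q = F.clamp(prob, eps, 1 - eps)
            ll = F.add(F.mul(y, F.log(q)),
                       F.mul(F.sub(Tensor(np.float32(1.0)), y),
                             F.log(F.sub(Tensor(np.float32(1.0)), q))))
            loss = F.neg(F.mean_all(ll))
            opt.zero_grad()
            loss.backward()
            opt.step()
    metrics = {}
    ious, dices = [], []
    for sid, img, gt in zip(ids, images, gts):
        iou, dice = iou_dice(model.predict_prob(img) >= threshold, gt > 0.5)
        metrics[sid] = {"iou": iou, "dice": dice}
        ious.append(iou)
        dices.append(dice)
    metrics["mean"] = {"iou": float(np.mean(ious)), "dice": float(np.mean(dices))}
    if out_prefix is not None:
        Path(f"{out_prefix}.json").write_text(json.dumps(metrics, indent=2))
    return metrics
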