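"""The three-branch architecture: SegNet, AttNet and ConsNet.

* **SegNet** — residual encoder (four stages feed the decoder; the last
  stage is dilated, rate 2, so the output stride is 1/16) with an
  efficient additive decoder.  The three decoder outputs pass through
  CBAM attention blocks, are summed element-wise and bilinearly
  upsampled into a single foreground-probability map.  Optionally every
  encoder convolution is deformable (offset-predicting convolution +
  bilinear sampling).
* **AttNet** — the same decoder/aggregation design on a smaller encoder;
  its input is the RGB image concatenated with the binary superpixel
  label (4 channels) and its output is a per-pixel confidence mask.
* **ConsNet** — a shallow network on the raw image.  A side branch
  produces ``f_cons``, merged into SegNet's first encoder stage by
  element-wise addition; the main branch returns an N-channel
  full-resolution map ``h`` supervised by SegNet's output.

Everything is size-scalable through :class:`NetConfig` so training runs
at desk scale on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autodiff import Tensor
from .imageio_points import UNLABELED

# encoder families: block type, blocks per stage, stage widths, stem width
# and stem stride.  "resnet50"/"resnet18" follow the classic layouts
# (output stride 1/16 with the dilated last stage).  "tiny" is the
# desk-scale profile: every stride is halved so that the feature-to-nucleus
# size ratio on ~96 px synthetic tiles matches what the full-width encoders
# see on ~1000 px histology tiles.
ENCODER_FAMILIES = {
    "resnet50": {"block": "bottleneck", "layers": [3, 4, 6, 3],
                 "widths": [256, 512, 1024, 2048], "stem": 64,
                 "stem_stride": 2},
    "resnet18": {"block": "basic", "layers": [2, 2, 2, 2],
                 "widths": [64, 128, 256, 512], "stem": 64,
                 "stem_stride": 2},
    "tiny": {"block": "basic", "layers": [1, 1, 1, 1],
             "widths": [64, 128, 128, 128], "stem": 48,
             "stem_stride": 1},
}


@dataclass
class NetConfig:
    """Size/behaviour knobs shared by the three networks."""

    segnet_encoder: str = "resnet50"
    attnet_encoder: str = "resnet18"
    width_multiplier: float = 1.0
    use_deformable: bool = False
    dilation_last_block: int = 2
    consnet_channels: int = 3           # N output channels of ConsNet
    consnet_width: int = 32
    cbam_reduction: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be > 0")
        if self.dilation_last_block < 1:
            raise ValueError("dilation_last_block must be >= 1")

    def scaled(self, w: int) -> int:
        return max(4, int(round(w * self.width_multiplier)))

    @classmethod
    def tiny(cls, **kw) -> "NetConfig":
        kw.setdefault("segnet_encoder", "tiny")
        kw.setdefault("attnet_encoder", "tiny")
        kw.setdefault("width_multiplier", 0.25)
        kw.setdefault("use_deformable", False)
        return cls(**kw)


def _conv3(in_ch, out_ch, rng, stride=1, dilation=1, deformable=False):
    pad = dilation
    if deformable:
        return nn.DeformConv2d(in_ch, out_ch, 3, rng, stride=stride,
                               padding=pad, dilation=dilation, bias=False)
    return nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=pad,
                     dilation=dilation, bias=False)


class BasicBlock(nn.Module):
    def __init__(self, in_ch, out_ch, rng, stride=1, dilation=1,
                 deformable=False):
        super().__init__()
        self.conv1 = _conv3(in_ch, out_ch, rng, stride=stride,
                            dilation=dilation, deformable=deformable)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = _conv3(out_ch, out_ch, rng, dilation=dilation,
                            deformable=deformable)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch))

    def forward(self, x):
        idt = self.proj(x) if self.proj is not None else x
        out = F.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return F.relu(F.add(out, idt))


class Bottleneck(nn.Module):
    def __init__(self, in_ch, out_ch, rng, stride=1, dilation=1,
                 deformable=False):
        super().__init__()
        mid = max(4, out_ch // 4)
        self.conv1 = nn.Conv2d(in_ch, mid, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = _conv3(mid, mid, rng, stride=stride, dilation=dilation,
                            deformable=deformable)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, out_ch, 1, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch))

    def forward(self, x):
        idt = self.proj(x) if self.proj is not None else x
        out = F.relu(self.bn1(self.conv1(x)))
        out = F.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        return F.relu(F.add(out, idt))


class ResidualEncoder(nn.Module):
    """Stem (stride 2) + four residual stages at strides 4/8/16/16; the
    last stage trades its stride for dilation."""

    def __init__(self, in_ch, family, config: NetConfig, rng):
        super().__init__()
        fam = ENCODER_FAMILIES[family]
        Block = BasicBlock if fam["block"] == "basic" else Bottleneck
        widths = [config.scaled(w) for w in fam["widths"]]
        stem_w = config.scaled(fam["stem"])
        deform = config.use_deformable
        self.stem_stride = fam["stem_stride"]
        self.stem = nn.ConvBNReLU(in_ch, stem_w, 3, rng,
                                  stride=self.stem_stride)
        self.stage_widths = widths
        self.encoder1_stride = self.stem_stride * 2
        ch = stem_w
        stages = []
        stage_cfg = [(2, 1), (2, 1), (2, 1), (1, config.dilation_last_block)]
        for si, (n_blocks, (stride, dil)) in enumerate(zip(fam["layers"], stage_cfg)):
            blocks = []
            for bi in range(n_blocks):
                blocks.append(Block(ch, widths[si], rng,
                                    stride=stride if bi == 0 else 1,
                                    dilation=dil, deformable=deform))
                ch = widths[si]
            stages.append(nn.Sequential(*blocks))
        self.stage1, self.stage2, self.stage3, self.stage4 = stages

    def forward(self, x, f_cons=None):
        """Returns the four stage outputs; ``f_cons`` (if given) is added
        element-wise to the first stage's feature map."""
        x = self.stem(x)
        e1 = self.stage1(x)
        if f_cons is not None:
            if f_cons.shape != e1.shape:
                raise ValueError(
                    f"f_cons shape {tuple(f_cons.shape)} does not match "
                    f"encoder-1 output {tuple(e1.shape)}")
            e1 = F.add(e1, f_cons)
        e2 = self.stage2(e1)
        e3 = self.stage3(e2)
        e4 = self.stage4(e3)
        return e1, e2, e3, e4


class CBAM(nn.Module):
    """Convolutional block attention: channel attention (shared MLP over
    global max/avg pools, summed, sigmoid) then spatial attention (channel
    max/avg maps through a 7x7 convolution, sigmoid), both multiplicative."""

    def __init__(self, ch, rng, reduction=8):
        super().__init__()
        hidden = max(1, ch // reduction)
        self.mlp1 = nn.Conv2d(ch, hidden, 1, rng, bias=True)
        self.mlp2 = nn.Conv2d(hidden, ch, 1, rng, bias=True)
        self.spatial = nn.Conv2d(2, 1, 7, rng, padding=3, bias=True)

    def forward(self, x):
        avg = self.mlp2(F.relu(self.mlp1(F.global_avg_pool(x))))
        mx = self.mlp2(F.relu(self.mlp1(F.global_max_pool(x))))
        ca = F.sigmoid(F.add(avg, mx))
        x = F.mul(x, ca)
        smap = F.concat([reduce_channel_max(x), F.reduce_mean(x, axis=1)], axis=1)
        sa = F.sigmoid(self.spatial(smap))
        return F.mul(x, sa)


def reduce_channel_max(x):
    return F.reduce_max(x, axis=1, keepdims=True)


class DecoderBlock(nn.Module):
    """1x1 transform of the upper features, upsample if one level coarser,
    element-wise add with the encoder skip, then a 1x1 / 3x3 / 1x1 stack."""

    def __init__(self, upper_ch, skip_ch, rng):
        super().__init__()
        self.transform = nn.Conv2d(upper_ch, skip_ch, 1, rng, bias=True)
        self.stack = nn.Sequential(
            nn.ConvBNReLU(skip_ch, skip_ch, 1, rng),
            nn.ConvBNReLU(skip_ch, skip_ch, 3, rng),
            nn.ConvBNReLU(skip_ch, skip_ch, 1, rng),
        )

    def forward(self, upper, skip):
        up = self.transform(upper)
        uh, uw = up.shape[2], up.shape[3]
        sh, sw = skip.shape[2], skip.shape[3]
        if (uh, uw) != (sh, sw):
            if sh < uh or sw < uw or sh > 2 * uh or sw > 2 * uw:
                raise ValueError(
                    f"decoder_block: upper {uh}x{uw} and skip {sh}x{sw} are "
                    "not the same or adjacent pyramid levels")
            up = F.upsample_bilinear(up, (sh, sw))
        merged = F.add(up, skip)
        return self.stack(merged)


class _AggregatingSegmenter(nn.Module):
    """Shared SegNet/AttNet body: residual encoder, three decoder blocks,
    per-block CBAM, element-wise aggregation, bilinear upsample, sigmoid."""

    def __init__(self, in_ch, family, config: NetConfig, rng):
        super().__init__()
        self.encoder = ResidualEncoder(in_ch, family, config, rng)
        w1, w2, w3, w4 = self.encoder.stage_widths
        self.dec3 = DecoderBlock(w4, w3, rng)   # stride 16 -> 16
        self.dec2 = DecoderBlock(w3, w2, rng)   # stride 16 -> 8
        self.dec1 = DecoderBlock(w2, w1, rng)   # stride 8 -> 4
        self.cbam3 = CBAM(w3, rng, config.cbam_reduction)
        self.cbam2 = CBAM(w2, rng, config.cbam_reduction)
        self.cbam1 = CBAM(w1, rng, config.cbam_reduction)
        agg = w1
        self.proj3 = nn.Conv2d(w3, agg, 1, rng, bias=True)
        self.proj2 = nn.Conv2d(w2, agg, 1, rng, bias=True)
        self.proj1 = nn.Conv2d(w1, agg, 1, rng, bias=True)
        self.head = nn.Conv2d(agg, 1, 1, rng, bias=True)

    def forward(self, x, f_cons=None):
        H, W = x.shape[2], x.shape[3]
        x, (ph, pw) = pad_to_stride(x, 16)
        e1, e2, e3, e4 = self.encoder(x, f_cons=f_cons)
        d3 = self.dec3(e4, e3)
        d2 = self.dec2(d3, e2)
        d1 = self.dec1(d2, e1)
        fine = (d1.shape[2], d1.shape[3])
        a3 = F.upsample_bilinear(self.proj3(self.cbam3(d3)), fine)
        a2 = F.upsample_bilinear(self.proj2(self.cbam2(d2)), fine)
        a1 = self.proj1(self.cbam1(d1))
        agg = F.add(F.add(a3, a2), a1)
        logits = F.upsample_bilinear(self.head(agg), (H + ph, W + pw))
        prob = F.sigmoid(logits)
        if ph or pw:
            prob = crop2d(prob, H, W)
        return prob


def pad_to_stride(x, stride):
    H, W = x.shape[2], x.shape[3]
    ph = (-H) % stride
    pw = (-W) % stride
    if ph or pw:
        x = F.pad2d(x, ph, pw, value=0.0)
    return x, (ph, pw)


def crop2d(x, H, W):
    t = F.as_tensor(x)
    data = t.data[:, :, :H, :W]

    def backward(g):
        gg = np.zeros(t.shape, dtype=g.dtype)
        gg[:, :, :H, :W] = g
        F._accum(t, gg)

    return F._make(data.copy(), (t,), backward)


class SegNet(_AggregatingSegmenter):
    """Foreground-probability network on the RGB image, with the optional
    ``f_cons`` merge into its first encoder stage."""

    def __init__(self, config: NetConfig, rng):
        super().__init__(3, config.segnet_encoder, config, rng)

    @property
    def encoder1_channels(self):
        return self.encoder.stage_widths[0]

    @property
    def encoder1_stride(self):
        return self.encoder.encoder1_stride


class AttNet(_AggregatingSegmenter):
    """Confidence-mask network on the 4-channel (RGB + superpixel label)
    input, trained against the tri-state Voronoi label."""

    def __init__(self, config: NetConfig, rng):
        super().__init__(4, config.attnet_encoder, config, rng)

    def forward(self, image, superpixel_label):
        lab = superpixel_label.data if isinstance(superpixel_label, Tensor) \
            else np.asarray(superpixel_label)
        if np.any(lab == UNLABELED):
            raise ValueError("AttNet expects a binary superpixel label "
                             "(unlabeled code 255 found)")
        lab_t = Tensor(lab.astype(image.data.dtype).reshape(
            image.shape[0], 1, image.shape[2], image.shape[3]))
        x = F.concat([image, lab_t], axis=1)
        return super().forward(x)


class ConsNet(nn.Module):
    """Shallow constraint network.

    conv1 (full resolution) and conv2 (stride 2) learn local detail; an
    average pool takes the side branch to stride 4 where conv3 matches
    encoder-1's channel count, producing ``f_cons``.  The main branch
    upsamples conv2's features back to full resolution, then conv4 and a
    linear conv5 give the N-channel output ``h``.
    """

    def __init__(self, config: NetConfig, enc1_channels: int, rng,
                 enc1_stride: int = 4):
        super().__init__()
        w = max(4, int(round(config.consnet_width * config.width_multiplier)))
        self.n_channels = config.consnet_channels
        if self.n_channels < 1:
            raise ValueError("consnet_channels must be >= 1")
        if enc1_stride not in (2, 4):
            raise ValueError("enc1_stride must be 2 or 4")
        self.enc1_stride = enc1_stride
        self.conv1 = nn.ConvBNReLU(3, w, 3, rng)
        self.conv2 = nn.ConvBNReLU(w, w, 3, rng, stride=2)
        self.conv3 = nn.ConvBNReLU(w, enc1_channels, 3, rng)
        self.conv4 = nn.ConvBNReLU(w, w, 3, rng)
        self.conv5 = nn.Conv2d(w, self.n_channels, 3, rng, padding=1, bias=True)

    def forward(self, x):
        H, W = x.shape[2], x.shape[3]
        xp, (ph, pw) = pad_to_stride(x, 16)
        c1 = self.conv1(xp)
        c2 = self.conv2(c1)                       # stride 2
        side = c2 if self.enc1_stride == 2 else F.avg_pool2d(c2, 2, 2)
        f_cons = self.conv3(side)
        up = F.upsample_bilinear(c2, (xp.shape[2], xp.shape[3]))
        h = self.conv5(self.conv4(up))
        if ph or pw:
            h = crop2d(h, H, W)
        return f_cons, h


class SACNet(nn.Module):
    """SegNet + AttNet + ConsNet under one config, with checkpointing."""

    def __init__(self, config: NetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.segnet = SegNet(config, rng)
        self.attnet = AttNet(config, rng)
        self.consnet = ConsNet(config, self.segnet.encoder1_channels, rng,
                               enc1_stride=self.segnet.encoder1_stride)

    def forward(self, image, superpixel_label):
        """Full joint pass: returns (f, f_att, f_cons, h)."""
        f_cons, h = self.consnet(image)
        f = self.segnet(image, f_cons=f_cons)
        f_att = self.attnet(image, superpixel_label)
        return f, f_att, f_cons, h

    def predict_prob(self, image) -> np.ndarray:
        """Eval-mode foreground probability map for one H×W×3 uint8 image."""
        was_training = self.training
        self.eval()
        x = Tensor(image_to_input(image))
        f_cons, _ = self.consnet(x)
        prob = self.segnet(x, f_cons=f_cons).data[0, 0]
        self.train(was_training)
        return prob

    def save(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, __config__=json.dumps(asdict(self.config)),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "SACNet":
        with np.load(path, allow_pickle=False) as z:
            cfg = NetConfig(**json.loads(str(z["__config__"])))
            model = cls(cfg)
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model


def image_to_input(image: np.ndarray) -> np.ndarray:
    """uint8 H×W×3 → standardised float32 (1, 3, H, W)."""
    x = image.astype(np.float32) / 255.0
    x = (x - 0.5) / 0.25
    return np.ascontiguousarray(x.transpose(2, 0, 1)[None])


# ---------------------------------------------------------------------
# plain U-Net baseline (fully supervised reference configuration)
# ---------------------------------------------------------------------

class PlainUNet(nn.Module):
    """Small symmetric encoder-decoder with skip concatenation, used as the
    fully supervised baseline trained on ground-truth masks."""

    def __init__(self, base_width=8, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed)
        w = base_width
        self.enc1 = nn.Sequential(nn.ConvBNReLU(3, w, 3, rng),
                                  nn.ConvBNReLU(w, w, 3, rng))
        self.down1 = nn.ConvBNReLU(w, 2 * w, 3, rng, stride=2)
        self.enc2 = nn.ConvBNReLU(2 * w, 2 * w, 3, rng)
        self.down2 = nn.ConvBNReLU(2 * w, 4 * w, 3, rng, stride=2)
        self.mid = nn.ConvBNReLU(4 * w, 4 * w, 3, rng)
        self.up2 = nn.Conv2d(4 * w, 2 * w, 1, rng, bias=True)
        self.dec2 = nn.ConvBNReLU(4 * w, 2 * w, 3, rng)
        self.up1 = nn.Conv2d(2 * w, w, 1, rng, bias=True)
        self.dec1 = nn.ConvBNReLU(2 * w, w, 3, rng)
        self.head = nn.Conv2d(w, 1, 1, rng, bias=True)

    def forward(self, x):
        H, W = x.shape[2], x.shape[3]
        x, (ph, pw) = pad_to_stride(x, 4)
        e1 = self.enc1(x)
        e2 = self.enc2(self.down1(e1))
        m = self.mid(self.down2(e2))
        u2 = F.upsample_bilinear(self.up2(m), (e2.shape[2], e2.shape[3]))
        d2 = self.dec2(F.concat([u2, e2], axis=1))
        u1 = F.upsample_bilinear(self.up1(d2), (e1.shape[2], e1.shape[3]))
        d1 = self.dec1(F.concat([u1, e1], axis=1))
        prob = F.sigmoid(self.head(d1))
        if ph or pw:
            prob = crop2d(prob, H, W)
        return prob

    def predict_prob(self, image) -> np.ndarray:
        was_training = self.training
        self.eval()
        prob = self(Tensor(image_to_input(image))).data[0, 0]
        self.train(was_training)
        return prob
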