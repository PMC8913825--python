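"""The three encoder–decoder segmentation networks.

* **UNet** — nine blocks (four encoders, bridge, four decoders with the
  1x1 sigmoid head folded into the last), 21 convolutional layers: each
  block is a double 3x3 conv; the two deepest decoders pair their
  upsampling with a dedicated channel-halving convolution (nearest-neighbor
  upsample + conv by default, or a 2x2 transposed conv), the two
  shallowest upsample by plain nearest-neighbor interpolation.
* **ResUNet** — seven sublevels of pre-activation residual units
  (BN→ReLU→conv, twice, plus a parameter-free identity shortcut), 15
  convolutional layers including the 1x1 head.
* **ResUNet++** — stem, three squeeze-and-excitation-gated residual
  encoders, an ASPP bridge, three additive-attention-gated residual
  decoders with nearest-neighbor upsampling, a second ASPP and the 1x1
  sigmoid head: 41 convolutional layers.

``conv_layer_census`` counts every convolution-type layer exactly once and
is the architecture contract the builders must honor (21 / 15 / 41 for the
default configs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import tensor as F
from .nn.tensor import Tensor

__all__ = ["ModelConfig", "SegmentationModel", "build_model",
           "conv_layer_census", "block_census", "save_model", "load_model"]

_ARCH_DEPTH = {"unet": 4, "resunet": 3, "resunetpp": 3}


@dataclass(frozen=True)
class ModelConfig:
    """Declarative description of a segmentation network.

    ``input_size`` must be divisible by ``2**n`` for the architecture's
    ``n`` pooling stages so every downsample/upsample round-trips cleanly.
    ``base_width`` is the channel width of the first stage (doubling with
    depth); 16 is a desk-scale default, 64 matches full-scale practice.
    """

    arch: str = "unet"           # unet | resunet | resunetpp
    input_size: int = 256
    base_width: int = 16
    seed: int = 0
    upsample_mode: str = "nearest_neighbor"  # nearest_neighbor | transposed_conv
    aspp_rates: tuple[int, ...] = (1, 6, 12, 18)
    se_ratio: int = 8

    def validate(self) -> None:
        if self.arch not in _ARCH_DEPTH:
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.upsample_mode not in ("nearest_neighbor", "transposed_conv"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        n = _ARCH_DEPTH[self.arch]
        if self.input_size % (2 ** n) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^{n} "
                f"for {self.arch}")
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")


# ---------------------------------------------------------------------------
# building blocks

class DoubleConv(nn.Module):
    """conv3x3 + BN + ReLU, twice (plain UNet block)."""

    def __init__(self, cin, cout, rng):
        self.c1 = nn.Conv2d(cin, cout, 3, rng)
        self.b1 = nn.BatchNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, 3, rng)
        self.b2 = nn.BatchNorm2d(cout)

    def forward(self, x):
        x = F.relu(self.b1(self.c1(x)))
        return F.relu(self.b2(self.c2(x)))


class ResidualUnit(nn.Module):
    """Pre-activation residual unit: BN→ReLU→conv3x3, twice.

    The shortcut is parameter-free (channel zero-pad / truncation) unless
    ``project=True``, in which case a 1x1 conv projects it.
    """

    def __init__(self, cin, cout, rng, project: bool = False):
        self.cin, self.cout = cin, cout
        self.b1 = nn.BatchNorm2d(cin)
        self.c1 = nn.Conv2d(cin, cout, 3, rng)
        self.b2 = nn.BatchNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, 3, rng)
        self.shortcut = nn.Conv2d(cin, cout, 1, rng) if project else None

    def forward(self, x):
        y = self.c1(F.relu(self.b1(x)))
        y = self.c2(F.relu(self.b2(y)))
        skip = self.shortcut(x) if self.shortcut is not None \
            else F.channel_resize(x, self.cout)
        return y + skip


class SqueezeExcite(nn.Module):
    """Channel gating from globally pooled features (dense layers only)."""

    def __init__(self, ch, rng, ratio: int = 8):
        hidden = max(ch // ratio, 1)
        self.fc1 = nn.Dense(ch, hidden, rng)
        self.fc2 = nn.Dense(hidden, ch, rng)

    def forward(self, x):
        s = F.global_avg_pool(x)                      # (N, C)
        s = F.sigmoid(self.fc2(F.relu(self.fc1(s))))  # (N, C)
        n, c = s.shape
        return x * s.reshape(n, c, 1, 1)


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: parallel dilated 3x3 convs fused 1x1."""

    def __init__(self, cin, cout, rng, rates=(1, 6, 12, 18)):
        self.branches = [nn.Conv2d(cin, cout, 3, rng, dilation=r) for r in rates]
        self.fuse = nn.Conv2d(cout * len(rates), cout, 1, rng)

    def forward(self, x):
        ys = [b(x) for b in self.branches]
        return self.fuse(F.concat(ys, axis=1))


class AttentionGate(nn.Module):
    """Additive attention: skip * sigmoid(psi(relu(Wg·g + Wx·skip)))."""

    def __init__(self, ch_g, ch_x, rng):
        inter = max(ch_x // 2, 1)
        self.wg = nn.Conv2d(ch_g, inter, 1, rng)
        self.wx = nn.Conv2d(ch_x, inter, 1, rng)
        self.psi = nn.Conv2d(inter, 1, 1, rng)

    def forward(self, g, x):
        a = F.sigmoid(self.psi(F.relu(self.wg(g) + self.wx(x))))
        return x * a


# ---------------------------------------------------------------------------
# architectures

class UpConv(nn.Module):
    """Spatial doubling with channel reduction: nearest-neighbor upsample
    followed by a 3x3 conv (default) or a 2x2 transposed conv."""

    def __init__(self, cin, cout, rng, mode: str = "nearest_neighbor"):
        self.mode = mode
        if mode == "transposed_conv":
            self.conv = nn.ConvTranspose2d(cin, cout, rng)
        else:
            self.conv = nn.Conv2d(cin, cout, 3, rng)

    def forward(self, x):
        if self.mode == "transposed_conv":
            return self.conv(x)
        return self.conv(F.upsample_nearest_2x(x))


class UNet(nn.Module):
    def __init__(self, w: int, rng, upsample_mode: str = "nearest_neighbor"):
        self.enc1 = DoubleConv(3, w, rng)
        self.enc2 = DoubleConv(w, 2 * w, rng)
        self.enc3 = DoubleConv(2 * w, 4 * w, rng)
        self.enc4 = DoubleConv(4 * w, 8 * w, rng)
        self.bridge = DoubleConv(8 * w, 16 * w, rng)
        self.up4 = UpConv(16 * w, 8 * w, rng, upsample_mode)
        self.dec4 = DoubleConv(16 * w, 8 * w, rng)
        self.up3 = UpConv(8 * w, 4 * w, rng, upsample_mode)
        self.dec3 = DoubleConv(8 * w, 4 * w, rng)
        self.dec2 = DoubleConv(4 * w + 2 * w, 2 * w, rng)
        self.dec1 = DoubleConv(2 * w + w, w, rng)
        self.head = nn.Conv2d(w, 1, 1, rng)

    def forward(self, x):
        e1 = self.enc1(x)
        e2 = self.enc2(F.maxpool2d_2x2(e1))
        e3 = self.enc3(F.maxpool2d_2x2(e2))
        e4 = self.enc4(F.maxpool2d_2x2(e3))
        b = self.bridge(F.maxpool2d_2x2(e4))
        d4 = self.dec4(F.concat([self.up4(b), e4], axis=1))
        d3 = self.dec3(F.concat([self.up3(d4), e3], axis=1))
        d2 = self.dec2(F.concat([F.upsample_nearest_2x(d3), e2], axis=1))
        d1 = self.dec1(F.concat([F.upsample_nearest_2x(d2), e1], axis=1))
        return F.sigmoid(self.head(d1))


class ResUNet(nn.Module):
    def __init__(self, w: int, rng):
        self.enc1 = ResidualUnit(3, w, rng)
        self.enc2 = ResidualUnit(w, 2 * w, rng)
        self.enc3 = ResidualUnit(2 * w, 4 * w, rng)
        self.bridge = ResidualUnit(4 * w, 8 * w, rng)
        self.dec3 = ResidualUnit(8 * w + 4 * w, 4 * w, rng)
        self.dec2 = ResidualUnit(4 * w + 2 * w, 2 * w, rng)
        self.dec1 = ResidualUnit(2 * w + w, w, rng)
        self.head = nn.Conv2d(w, 1, 1, rng)

    def forward(self, x):
        e1 = self.enc1(x)
        e2 = self.enc2(F.maxpool2d_2x2(e1))
        e3 = self.enc3(F.maxpool2d_2x2(e2))
        b = self.bridge(F.maxpool2d_2x2(e3))
        d3 = self.dec3(F.concat([F.upsample_nearest_2x(b), e3], axis=1))
        d2 = self.dec2(F.concat([F.upsample_nearest_2x(d3), e2], axis=1))
        d1 = self.dec1(F.concat([F.upsample_nearest_2x(d2), e1], axis=1))
        return F.sigmoid(self.head(d1))


class Stem(nn.Module):
    """Entry block of ResUNet++: two 3x3 convs with a projected shortcut."""

    def __init__(self, cin, cout, rng):
        self.c1 = nn.Conv2d(cin, cout, 3, rng)
        self.b1 = nn.BatchNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, 3, rng)
        self.shortcut = nn.Conv2d(cin, cout, 1, rng)

    def forward(self, x):
        y = self.c2(F.relu(self.b1(self.c1(x))))
        return y + self.shortcut(x)


class ResUNetPP(nn.Module):
    def __init__(self, w: int, rng, rates=(1, 6, 12, 18), se_ratio: int = 8):
        self.stem = Stem(3, w, rng)
        self.se0 = SqueezeExcite(w, rng, se_ratio)
        self.enc1 = ResidualUnit(w, 2 * w, rng, project=True)
        self.se1 = SqueezeExcite(2 * w, rng, se_ratio)
        self.enc2 = ResidualUnit(2 * w, 4 * w, rng, project=True)
        self.se2 = SqueezeExcite(4 * w, rng, se_ratio)
        self.enc3 = ResidualUnit(4 * w, 8 * w, rng, project=True)
        self.aspp_bridge = ASPP(8 * w, 16 * w, rng, rates)
        self.att3 = AttentionGate(16 * w, 4 * w, rng)
        self.dec3 = ResidualUnit(16 * w + 4 * w, 8 * w, rng, project=True)
        self.att2 = AttentionGate(8 * w, 2 * w, rng)
        self.dec2 = ResidualUnit(8 * w + 2 * w, 4 * w, rng, project=True)
        self.att1 = AttentionGate(4 * w, w, rng)
        self.dec1 = ResidualUnit(4 * w + w, 2 * w, rng, project=True)
        self.aspp_out = ASPP(2 * w, w, rng, rates)
        self.head = nn.Conv2d(w, 1, 1, rng)

    def forward(self, x):
        x0 = self.se0(self.stem(x))
        x1 = self.se1(self.enc1(F.maxpool2d_2x2(x0)))
        x2 = self.se2(self.enc2(F.maxpool2d_2x2(x1)))
        x3 = self.enc3(F.maxpool2d_2x2(x2))
        b = self.aspp_bridge(x3)
        u3 = F.upsample_nearest_2x(b)
        d3 = self.dec3(F.concat([u3, self.att3(u3, x2)], axis=1))
        u2 = F.upsample_nearest_2x(d3)
        d2 = self.dec2(F.concat([u2, self.att2(u2, x1)], axis=1))
        u1 = F.upsample_nearest_2x(d2)
        d1 = self.dec1(F.concat([u1, self.att1(u1, x0)], axis=1))
        return F.sigmoid(self.head(self.aspp_out(d1)))


_BLOCKS = {
    "unet": ["encoder1", "encoder2", "encoder3", "encoder4", "bridge",
             "decoder4", "decoder3", "decoder2", "decoder1+head"],
    "resunet": ["encoder1", "encoder2", "encoder3", "bridge",
                "decoder3", "decoder2", "decoder1+head"],
    "resunetpp": ["stem", "encoder1", "encoder2", "encoder3", "aspp_bridge",
                  "decoder3", "decoder2", "decoder1", "aspp_out+head"],
}
_ENCODERS = {"unet": 4, "resunet": 3, "resunetpp": 3}


@dataclass
class SegmentationModel:
    """A built network plus its auditable architecture summary."""

    net: nn.Module
    config: ModelConfig
    summary: dict = field(default_factory=dict)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)

    def forward_array(self, batch: np.ndarray) -> np.ndarray:
        """(N, 3, H, W) float batch in [0,1] -> (N, H, W) probabilities."""
        return self.net(Tensor(batch)).data[:, 0]

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Single RGB image (HxWx3, uint8 or [0,1] float) -> H x W ProbMap."""
        x = np.asarray(image, dtype=np.float32)
        if x.max() > 1.5:
            x = x / 255.0
        batch = x.transpose(2, 0, 1)[None]
        self.net.eval()
        return self.forward_array(batch)[0]


def build_model(config: ModelConfig) -> SegmentationModel:
    """Instantiate the configured architecture with seeded initialization."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    w = config.base_width
    if config.arch == "unet":
        net = UNet(w, rng, upsample_mode=config.upsample_mode)
    elif config.arch == "resunet":
        net = ResUNet(w, rng)
    else:
        net = ResUNetPP(w, rng, rates=config.aspp_rates, se_ratio=config.se_ratio)
    model = SegmentationModel(net=net, config=config)
    model.summary = {
        "arch": config.arch,
        "blocks": list(_BLOCKS[config.arch]),
        "encoders": _ENCODERS[config.arch],
        "conv_layers": conv_layer_census(model),
        "parameters": int(sum(p.data.size for p in net.parameters())),
        "base_width": w,
        "input_size": config.input_size,
    }
    return model


def conv_layer_census(model: SegmentationModel | nn.Module) -> int:
    """Count every convolution-type layer (3x3, 1x1, dilated, transposed)
    exactly once.  Dense layers (SE gating) are not convolutions."""
    net = model.net if isinstance(model, SegmentationModel) else model
    return sum(1 for m in net.modules()
               if isinstance(m, (nn.Conv2d, nn.ConvTranspose2d)))


def block_census(model: SegmentationModel) -> int:
    """Number of named blocks/sublevels in the architecture summary."""
    return len(model.summary["blocks"])


# ---------------------------------------------------------------------------
# checkpoints

def save_model(model: SegmentationModel, path: Path) -> None:
    """npz checkpoint plus a JSON architecture summary side-file."""
    path = Path(path)
    arrays = model.net.state_arrays()
    np.savez(path, *arrays,
             _config=json.dumps({
                 "arch": model.config.arch,
                 "input_size": model.config.input_size,
                 "base_width": model.config.base_width,
                 "seed": model.config.seed,
                 "upsample_mode": model.config.upsample_mode,
                 "aspp_rates": list(model.config.aspp_rates),
                 "se_ratio": model.config.se_ratio,
             }))
    path.with_suffix(".summary.json").write_text(
        json.dumps(model.summary, indent=2))


def load_model(path: Path) -> SegmentationModel:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"),
                 allow_pickle=False) as z:
        cfg = json.loads(str(z["_config"]))
        config = ModelConfig(arch=cfg["arch"], input_size=cfg["input_size"],
                             base_width=cfg["base_width"], seed=cfg["seed"],
                             upsample_mode=cfg.get("upsample_mode",
                                                   "nearest_neighbor"),
                             aspp_rates=tuple(cfg["aspp_rates"]),
                             se_ratio=cfg["se_ratio"])
        model = build_model(config)
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    model.net.load_state_arrays(arrays)
    return model
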