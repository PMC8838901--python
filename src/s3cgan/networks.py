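"""The three parametric function families of the stain-transfer model.

* :class:`UNetGenerator` — encoder/decoder with skip connections at every
  resolution level and a tanh output, so generated patches stay inside
  the canonical signed range [-1, 1].
* :class:`PatchCritic` — a Markovian (patch) critic: a stack of strided
  convolutions mapping an image to an N x N map of unbounded scores,
  each covering only a local receptive field. No batch-coupled
  normalization, as the gradient penalty is computed per sample.
* :class:`ColorClassifier` — a lightweight binary network that scores
  whether a patch carries the style-A or style-B stain appearance. It is
  pretrained and then frozen: during adversarial training it acts purely
  as a fixed "color consultant".

All constructors take a seed; identical seeds give bit-identical initial
parameters. The helper functions ``build_*`` are thin wrappers matching
the config-dict style used by the training layer.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

LEAK = 0.2


class UNetGenerator(nn.Module):
    """Image-to-image U-Net, NCHW in/out, output in [-1, 1].

    ``depth`` down/up levels; channel width doubles per level starting at
    ``base_width`` (capped at 8x). Input height and width must be
    divisible by ``2**depth``.
    """

    def __init__(self, depth: int = 4, base_width: int = 64, seed: int = 0,
                 in_channels: int = 3, identifier: str = "G"):
        super().__init__()
        if depth < 2:
            raise ValueError("generator depth must be >= 2")
        self.depth = depth
        self.base_width = base_width
        self.identifier = identifier
        rng = np.random.default_rng(seed)
        widths = [min(base_width * 2 ** i, base_width * 8) for i in range(depth + 1)]

        self.enc_convs: list[nn.Conv2d] = []
        self.down_convs: list[nn.Conv2d] = []
        ch = in_channels
        for i in range(depth):
            conv = nn.Conv2d(ch, widths[i], 3, stride=1, pad=1, rng=rng)
            down = nn.Conv2d(widths[i], widths[i + 1], 4, stride=2, pad=1, rng=rng)
            setattr(self, f"enc{i}", conv)
            setattr(self, f"down{i}", down)
            self.enc_convs.append(conv)
            self.down_convs.append(down)
            ch = widths[i + 1]
        self.bottleneck = nn.Conv2d(ch, ch, 3, stride=1, pad=1, rng=rng)
        self.up_convs: list[nn.Conv2d] = []
        self.dec_convs: list[nn.Conv2d] = []
        for i in reversed(range(depth)):
            up = nn.Conv2d(ch, widths[i], 3, stride=1, pad=1, rng=rng)
            dec = nn.Conv2d(widths[i] * 2, widths[i], 3, stride=1, pad=1, rng=rng)
            setattr(self, f"up{i}", up)
            setattr(self, f"dec{i}", dec)
            self.up_convs.append(up)
            self.dec_convs.append(dec)
            ch = widths[i]
        self.head = nn.Conv2d(ch, in_channels, 3, stride=1, pad=1, rng=rng)
        # skip_enabled is a test hook: disabling a level replaces the skip
        # tensor with zeros, keeping every parameter shape unchanged.
        self.skip_enabled = [True] * depth

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[2], x.shape[3]
        div = 2 ** self.depth
        if H % div or W % div:
            raise ValueError(
                f"input {H}x{W} not divisible by 2^depth = {div}; "
                f"pad or crop the patch to a multiple of {div}")
        skips = []
        h = x
        for i in range(self.depth):
            s = ad.leaky_relu(self.enc_convs[i](h), LEAK)
            skips.append(s)
            h = ad.leaky_relu(self.down_convs[i](s), LEAK)
        h = ad.leaky_relu(self.bottleneck(h), LEAK)
        for j, i in enumerate(reversed(range(self.depth))):
            h = ad.leaky_relu(self.up_convs[j](ad.upsample_nearest2(h)), LEAK)
            skip = skips[i]
            if not self.skip_enabled[i]:
                skip = Tensor(np.zeros_like(skip.data))
            h = ad.leaky_relu(self.dec_convs[j](ad.concat([h, skip], axis=1)), LEAK)
        return ad.tanh(self.head(h))


class PatchCritic(nn.Module):
    """Markovian critic: H x W x 3 -> N x N unbounded score map."""

    def __init__(self, n_layers: int = 4, base_width: int = 64, seed: int = 0,
                 in_channels: int = 3, identifier: str = "D"):
        super().__init__()
        if n_layers < 1:
            raise ValueError("critic needs at least one layer")
        self.n_layers = n_layers
        self.base_width = base_width
        self.identifier = identifier
        rng = np.random.default_rng(seed)
        self.convs: list[nn.Conv2d] = []
        ch = in_channels
        for i in range(n_layers):
            width = min(base_width * 2 ** i, base_width * 8)
            conv = nn.Conv2d(ch, width, 4, stride=2, pad=1, rng=rng)
            setattr(self, f"conv{i}", conv)
            self.convs.append(conv)
            ch = width
        self.head = nn.Conv2d(ch, 1, 4, stride=1, pad=1, rng=rng)
        self.receptive_field = self._receptive_field()
        self.stride = 2 ** n_layers

    def _receptive_field(self) -> int:
        # walk the stack backwards: rf <- rf * s + (k - s)
        rf = 1
        for _ in range(1):  # head conv, k=4 s=1
            rf = rf * 1 + (4 - 1)
        for _ in range(self.n_layers):
            rf = rf * 2 + (4 - 2)
        return rf

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = ad.leaky_relu(conv(h), LEAK)
        out = self.head(h)  # no squashing: Wasserstein scores are unbounded
        return ad.reshape(out, (out.shape[0], out.shape[2], out.shape[3]))


class ColorClassifier(nn.Module):
    """Binary stain-style classifier; class 0 = domain A, class 1 = domain B."""

    def __init__(self, base_width: int = 8, seed: int = 0, in_channels: int = 3):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.conv0 = nn.Conv2d(in_channels, base_width, 3, stride=1, pad=1, rng=rng)
        self.conv1 = nn.Conv2d(base_width, base_width * 2, 3, stride=1, pad=1, rng=rng)
        self.conv2 = nn.Conv2d(base_width * 2, base_width * 2, 3, stride=1, pad=1, rng=rng)
        self.fc = nn.Linear(base_width * 2, 2, rng=rng)
        self.frozen = False

    def logits(self, x: Tensor) -> Tensor:
        h = ad.avg_pool2(ad.leaky_relu(self.conv0(x), LEAK))
        h = ad.avg_pool2(ad.leaky_relu(self.conv1(h), LEAK))
        h = ad.leaky_relu(self.conv2(h), LEAK)
        h = ad.mean(h, axis=(2, 3))  # global average pool -> (N, C)
        return self.fc(h)

    def forward(self, x: Tensor) -> Tensor:
        return ad.softmax(self.logits(x), axis=1)

    def freeze(self) -> "ColorClassifier":
        for p in self.parameters():
            p.requires_grad = False
        self.frozen = True
        return self

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        with ad.no_grad():
            return self(Tensor(batch)).data


def build_unet_generator(cfg: dict) -> UNetGenerator:
    return UNetGenerator(depth=cfg.get("depth", 4), base_width=cfg.get("base_width", 64),
                         seed=cfg.get("seed", 0), identifier=cfg.get("identifier", "G"))


def build_patch_critic(cfg: dict) -> PatchCritic:
    return PatchCritic(n_layers=cfg.get("n_layers", 4), base_width=cfg.get("base_width", 64),
                       seed=cfg.get("seed", 0), identifier=cfg.get("identifier", "D"))


def build_color_classifier(cfg: dict) -> ColorClassifier:
    return ColorClassifier(base_width=cfg.get("base_width", 8), seed=cfg.get("seed", 0))


def describe(model: nn.Module) -> str:
    lines = [f"{type(model).__name__}: {model.parameter_count()} parameters"]
    if isinstance(model, PatchCritic):
        lines.append(f"receptive field: {model.receptive_field} px, output stride: {model.stride}")
    if isinstance(model, UNetGenerator):
        lines.append(f"depth {model.depth}, base width {model.base_width}; "
                     f"input sides must be divisible by {2 ** model.depth}")
    for name, p in model.named_parameters():
        lines.append(f"  {name}: {p.data.shape}")
    return "\n".join(lines)
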