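"""Network architectures.

Two U-Net variants share one implementation:

* the dual-branch counting / segmentation network — a shared
  encoder-decoder trunk with additive attention gates on the skip
  connections and two 1x1 projection heads: a sigmoid head producing
  crown probabilities and a linear head regressing the Gaussian density
  map (most weights are shared; only the heads are task-specific);
* the canopy-height network — the same trunk with the final decoding
  block removed, so the single linear head predicts at half the input
  resolution, matching height references that are 2x coarser than the
  imagery.

A multi-resolution input variant accepts extra coarse bands (e.g. a
height map at half resolution) which are injected after the first
down-sampling step, where the spatial grids match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autodiff import Tensor, as_tensor

__all__ = ["ModelConfig", "UNet", "build_count_seg_model", "build_height_model",
           "save_checkpoint", "load_checkpoint"]

HEADS = ("count_seg", "seg", "count", "height")


@dataclass(frozen=True)
class ModelConfig:
    in_bands: int = 4
    base_channels: int = 8
    depth: int = 3
    attention: bool = True
    batch_norm: bool = True
    multires_band_count: int = 0
    heads: str = "count_seg"
    density_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.in_bands < 1:
            raise ValueError("in_bands must be >= 1")
        if self.multires_band_count < 0:
            raise ValueError("multires_band_count must be >= 0")
        if self.heads not in HEADS:
            raise ValueError(f"heads must be one of {HEADS}")
        if self.density_scale <= 0:
            raise ValueError("density_scale must be positive")


class ConvBlock(nn.Module):
    """(conv 3x3 -> [BN] -> ReLU) twice."""

    def __init__(self, cin: int, cout: int, rng, batch_norm: bool):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.bn1 = nn.BatchNorm2d(cout) if batch_norm else None
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.bn2 = nn.BatchNorm2d(cout) if batch_norm else None

    def forward(self, x):
        x = self.conv1(x)
        if self.bn1 is not None:
            x = self.bn1(x)
        x = x.relu()
        x = self.conv2(x)
        if self.bn2 is not None:
            x = self.bn2(x)
        return x.relu()


class AttentionGate(nn.Module):
    """Additive attention gate modulating a skip connection.

    att = sigmoid(psi(relu(Wg g + Wx x))); returns x * att. The gating
    signal g is the upsampled decoder feature at the same spatial size.
    """

    def __init__(self, ch_x: int, ch_g: int, ch_int: int, rng):
        super().__init__()
        self.wx = nn.Conv2d(ch_x, ch_int, 1, rng, bias=False)
        self.wg = nn.Conv2d(ch_g, ch_int, 1, rng, bias=True)
        self.psi = nn.Conv2d(ch_int, 1, 1, rng, bias=True)

    def forward(self, x, g):
        att = self.psi((self.wx(x) + self.wg(g)).relu()).sigmoid()
        return x * att


class UNet(nn.Module):
    """Shared U-Net trunk with configurable heads (see module docstring)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        bn = cfg.batch_norm
        base, depth = cfg.base_channels, cfg.depth

        enc_out = [base * 2 ** i for i in range(depth)]
        self.encoders = []
        cin = cfg.in_bands
        for i, cout in enumerate(enc_out):
            if i == 1:
                cin += cfg.multires_band_count
            self.encoders.append(ConvBlock(cin, cout, rng, bn))
            cin = cout
        self.bottleneck = ConvBlock(enc_out[-1], base * 2 ** depth, rng, bn)

        # decoder levels from deep to shallow; the height variant stops
        # one level early (its output is at half the input resolution)
        n_dec = depth if cfg.heads != "height" else depth - 1
        self.up_convs = []
        self.gates = []
        self.decoders = []
        cprev = base * 2 ** depth
        for i in range(n_dec):
            skip_ch = enc_out[depth - 1 - i]
            self.up_convs.append(nn.Conv2d(cprev, skip_ch, 3, rng))
            if cfg.attention:
                self.gates.append(AttentionGate(skip_ch, skip_ch, max(skip_ch // 2, 1), rng))
            self.decoders.append(ConvBlock(2 * skip_ch, skip_ch, rng, bn))
            cprev = skip_ch

        def head():
            # zero-init: the density/height heads start at 0 and the seg head
            # at probability 0.5, so no branch dominates the shared trunk at
            # the start of training
            conv = nn.Conv2d(cprev, 1, 1, rng)
            conv.weight.data[...] = 0.0
            return conv

        self.seg_head = head() if cfg.heads in ("count_seg", "seg") else None
        self.count_head = head() if cfg.heads in ("count_seg", "count") else None
        self.height_head = head() if cfg.heads == "height" else None

    # -- forward ---------------------------------------------------------
    def _check_shapes(self, x, coarse):
        _, c, h, w = x.shape
        if c != self.cfg.in_bands:
            raise ValueError(f"expected {self.cfg.in_bands} input bands, got {c}")
        div = 2 ** self.cfg.depth
        if h % div or w % div:
            raise ValueError(f"spatial size {h}x{w} not divisible by 2^depth={div}")
        if self.cfg.multires_band_count:
            if coarse is None:
                raise ValueError("model expects a coarse-band input")
            _, cc, hc, wc = coarse.shape
            if cc != self.cfg.multires_band_count or (hc, wc) != (h // 2, w // 2):
                raise ValueError(
                    f"coarse input must be ({self.cfg.multires_band_count}, {h // 2}, {w // 2}), "
                    f"got ({cc}, {hc}, {wc})"
                )
        elif coarse is not None:
            raise ValueError("model was built without multi-resolution inputs")

    def forward(self, x, coarse=None):
        x = as_tensor(x)
        coarse = as_tensor(coarse) if coarse is not None else None
        self._check_shapes(x.data, coarse.data if coarse is not None else None)

        skips = []
        for i, enc in enumerate(self.encoders):
            if i > 0:
                x = F.maxpool2x2(x)
            if i == 1 and coarse is not None:
                x = F.concat_channels([x, coarse])
            x = enc(x)
            skips.append(x)
        x = F.maxpool2x2(x)
        x = self.bottleneck(x)

        for i, (up, dec) in enumerate(zip(self.up_convs, self.decoders)):
            x = up(F.upsample2x(x))
            skip = skips[len(skips) - 1 - i]
            if self.cfg.attention:
                skip = self.gates[i](skip, x)
            x = dec(F.concat_channels([skip, x]))

        out = {}
        if self.seg_head is not None:
            out["seg"] = self.seg_head(x).sigmoid()
        if self.count_head is not None:
            out["density"] = self.count_head(x)
        if self.height_head is not None:
            out["height"] = self.height_head(x)
        return out

    # -- numpy conveniences ------------------------------------------------
    def predict(self, x: np.ndarray, coarse: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Eval-mode forward pass on (C,H,W) or (N,C,H,W) numpy input."""
        single = x.ndim == 3
        if single:
            x = x[None]
            coarse = coarse[None] if coarse is not None else None
        was_training = self.training
        self.eval()
        with nn.no_grad():
            out = self.forward(Tensor(x), Tensor(coarse) if coarse is not None else None)
        if was_training:
            self.train()
        arrays = {k: v.data[:, 0] for k, v in out.items()}
        if "density" in arrays and self.cfg.density_scale != 1.0:
            # the counting branch is trained against scaled density targets;
            # predictions are mapped back to physical (trees/pixel) units
            arrays = dict(arrays)
            arrays["density"] = arrays["density"] / self.cfg.density_scale
        if single:
            arrays = {k: v[0] for k, v in arrays.items()}
        return arrays


def build_count_seg_model(cfg: ModelConfig) -> UNet:
    """Dual-branch (or single-branch) counting/segmentation network."""
    if cfg.heads == "height":
        raise ValueError("use build_height_model for the height head")
    return UNet(cfg)


def build_height_model(cfg: ModelConfig) -> UNet:
    """Height-regression network predicting at half the input resolution."""
    if cfg.heads != "height":
        cfg = ModelConfig(**{**asdict(cfg), "heads": "height"})
    return UNet(cfg)


def save_checkpoint(path, model: UNet) -> None:
    """Write weights plus the architecture config to an .npz file."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    ).copy()
    np.savez(path, **state)


def load_checkpoint(path) -> UNet:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = UNet(cfg)
    model.load_state_dict(state)
    return model
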