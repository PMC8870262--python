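"""U-Net and ResTLU-Net segmentation networks for 2D MRI slices.

The encoder has five blocks of two convolution+norm+ReLU stages each, with
2x2 max pooling between blocks, taking the channel count from 3 up to the
bottleneck width while the spatial grid shrinks by a factor of 16. The
decoder has four blocks of transposed-convolution + ReLU, each concatenated
with the same-resolution encoder feature map, and a final 1x1 convolution
maps to a two-class (background/brain) score map.

The ResTLU variant replaces the leading convolution of every encoder block
with a pre-activation residual unit: the unit computes

    x_{i+1} = f_i(x_i) + shortcut(x_i),
    f_i(x)  = W_i . relu(B(W'_i . relu(B(x))))

where B is batch normalization and the shortcut is the identity when input
and output channel counts match, otherwise a 1x1 projection convolution.
Passing the input forward unchanged alongside its transform preserves
low-dimensional spatial information that plain stacked convolutions lose,
which is what makes the variant generalize better across acquisition sites.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .exceptions import SpecError
from .nn import DTYPE

PROB_EPS = 1e-7  # clamp for log terms of the cross-entropy


@dataclass
class ArchSpec:
    """Architecture descriptor.

    encoder_channels lists the output width of each of the five encoder
    blocks; the decoder halves widths back down symmetrically. The grid must
    be divisible by 16 so four pooling stages land on an integer bottleneck.
    """

    variant: str = "restlu"
    in_channels: int = 3
    class_channels: int = 2
    encoder_channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    grid: tuple[int, int] = (256, 256)
    norm: str = "batch"
    activation: str = "relu"

    def __post_init__(self):
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        self.grid = tuple(int(g) for g in self.grid)
        if self.variant not in ("unet", "restlu"):
            raise SpecError(f"unknown variant {self.variant!r}")
        if len(self.encoder_channels) != 5:
            raise SpecError("encoder_channels must list exactly 5 block widths")
        if any(b <= a for a, b in zip(self.encoder_channels,
                                      self.encoder_channels[1:])):
            raise SpecError("encoder_channels must be strictly increasing")
        if any(g % 16 != 0 or g <= 0 for g in self.grid):
            raise SpecError(f"grid {self.grid} must be positive and divisible by 16")
        if self.in_channels != 3 or self.class_channels != 2:
            raise SpecError("network expects 3 input channels and 2 classes")

    @property
    def bottleneck_grid(self) -> tuple[int, int]:
        return (self.grid[0] // 16, self.grid[1] // 16)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        return cls(**d)


class ConvBNReLU(nn.Layer):
    """conv -> batch norm -> ReLU."""

    def __init__(self, cin, cout, rng, name):
        self.name = name
        self.conv = nn.Conv2d(cin, cout, 3, rng=rng, name=f"{name}.conv")
        self.bn = nn.BatchNorm2d(cout, name=f"{name}.bn")
        self.relu = nn.ReLU()
        self._layers = [self.conv, self.bn]

    def forward(self, x, train=False):
        return self.relu.forward(
            self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, d):
        return self.conv.backward(self.bn.backward(self.relu.backward(d)))


class ResidualUnit(nn.Layer):
    """Pre-activation residual unit: f(x) + shortcut(x).

    f = BN -> ReLU -> conv(cin->cout) -> BN -> ReLU -> conv(cout->cout);
    the shortcut is the identity when cin == cout, else a 1x1 projection.
    """

    def __init__(self, cin, cout, rng, name):
        self.name = name
        self.cin, self.cout = cin, cout
        self.bn1 = nn.BatchNorm2d(cin, name=f"{name}.bn1")
        self.relu1 = nn.ReLU()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng=rng, name=f"{name}.conv1")
        self.bn2 = nn.BatchNorm2d(cout, name=f"{name}.bn2")
        self.relu2 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, rng=rng, name=f"{name}.conv2")
        self.proj = (None if cin == cout else
                     nn.Conv2d(cin, cout, 1, rng=rng, name=f"{name}.proj"))
        self._layers = [self.bn1, self.conv1, self.bn2, self.conv2]
        if self.proj is not None:
            self._layers.append(self.proj)
        self._x = None

    def transform(self, x, train=False):
        """The residual branch f(x) alone (without the shortcut)."""
        h = self.relu1.forward(self.bn1.forward(x, train), train)
        h = self.conv1.forward(h, train)
        h = self.relu2.forward(self.bn2.forward(h, train), train)
        return self.conv2.forward(h, train)

    def shortcut(self, x, train=False):
        return x if self.proj is None else self.proj.forward(x, train)

    def forward(self, x, train=False):
        if x.shape[1] != self.cin:
            raise SpecError(f"{self.name}: expected {self.cin} channels, "
                            f"got {x.shape[1]}")
        return self.transform(x, train) + self.shortcut(x, train)

    def backward(self, d):
        df = self.conv2.backward(d)
        df = self.bn1.backward(self.relu1.backward(
            self.conv1.backward(self.bn2.backward(self.relu2.backward(df)))))
        ds = d if self.proj is None else self.proj.backward(d)
        return df + ds


def residual_unit(x: np.ndarray, unit: ResidualUnit,
                  train: bool = False) -> np.ndarray:
    """Apply one residual unit to a feature tensor."""
    return unit.forward(x, train)


class _EncoderBlock:
    def __init__(self, variant, cin, cout, rng, name):
        self.stages = []
        if variant == "restlu":
            # leading convolution replaced by a residual unit, then the
            # block's two plain conv stages (three transforms in all)
            self.stages.append(ResidualUnit(cin, cout, rng, f"{name}.ru"))
            self.stages.append(ConvBNReLU(cout, cout, rng, f"{name}.c1"))
            self.stages.append(ConvBNReLU(cout, cout, rng, f"{name}.c2"))
        else:
            self.stages.append(ConvBNReLU(cin, cout, rng, f"{name}.c1"))
            self.stages.append(ConvBNReLU(cout, cout, rng, f"{name}.c2"))

    def forward(self, x, train=False):
        for s in self.stages:
            x = s.forward(x, train)
        return x

    def backward(self, d):
        for s in reversed(self.stages):
            d = s.backward(d)
        return d


class Model:
    """The assembled computation graph with explicit skip bookkeeping."""

    def __init__(self, spec: ArchSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        ch = spec.encoder_channels
        self.encoders = []
        cin = spec.in_channels
        for i, cout in enumerate(ch):
            self.encoders.append(
                _EncoderBlock(spec.variant, cin, cout, rng, f"enc{i + 1}"))
            cin = cout
        self.pools = [nn.MaxPool2(f"pool{i + 1}") for i in range(4)]
        # decoder: tconv -> ReLU -> concat skip; widths halve per level
        self.tconvs, self.urelus = [], []
        prev = ch[4]
        for i in range(4):
            cout = ch[3 - i]
            self.tconvs.append(
                nn.ConvTranspose2d(prev, cout, rng=rng, name=f"dec{i + 1}.tconv"))
            self.urelus.append(nn.ReLU())
            prev = 2 * cout  # after concatenation with the skip feature map
        self.head = nn.Conv2d(prev, spec.class_channels, 1, rng=rng, name="head")
        self._layers = []
        for e in self.encoders:
            for s in e.stages:
                self._layers.extend(s._layers)
        self._layers.extend(self.tconvs)
        self._layers.append(self.head)
        self.bottleneck: np.ndarray | None = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for l in self._layers:
            out.update(l.parameters())
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for l in self._layers:
            out.update(l.gradients())
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for l in self._layers:
            out.update(l.buffers())
        return out

    def zero_grad(self):
        for l in self._layers:
            l.zero_grad()

    def load_arrays(self, arrays: dict[str, np.ndarray]):
        for k, p in {**self.parameters(), **self.buffers()}.items():
            p[...] = arrays[k]

    # -- computation --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        H, W = self.spec.grid
        if x.shape[1:] != (3, H, W):
            raise SpecError(
                f"input {x.shape} does not match grid {(3, H, W)}")
        x = np.ascontiguousarray(x, dtype=DTYPE)
        skips = []
        for i in range(4):
            x = self.encoders[i].forward(x, train)
            skips.append(x)
            x = self.pools[i].forward(x, train)
        x = self.encoders[4].forward(x, train)
        self.bottleneck = x
        self._concat_splits = []
        for i in range(4):
            x = self.tconvs[i].forward(x, train)
            x = self.urelus[i].forward(x, train)
            skip = skips[3 - i]
            self._concat_splits.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
        return self.head.forward(x, train)

    def backward(self, dscores: np.ndarray) -> None:
        d = self.head.backward(dscores)
        dskips = []
        for i in range(3, -1, -1):
            split = self._concat_splits[i]
            dup, dskip = d[:, :split], d[:, split:]
            dskips.append(dskip)
            d = self.tconvs[i].backward(self.urelus[i].backward(dup))
        dskips.reverse()  # dskips[j] pairs with encoder block 4-j
        d = self.encoders[4].backward(d)
        for i in range(3, -1, -1):
            d = self.pools[i].backward(d)
            d = d + dskips[3 - i]
            d = self.encoders[i].backward(d)


@dataclass
class ModelState:
    """A model plus the bookkeeping needed to reproduce and resume it."""

    spec: ArchSpec
    model: Model
    rng_seed: int
    epoch: int = 0
    optimizer_state: dict | None = None

    def clone(self) -> "ModelState":
        return copy.deepcopy(self)


def build_network(spec: ArchSpec, seed: int) -> ModelState:
    """Construct a freshly initialized network; deterministic in seed."""
    model = Model(spec, seed)
    return ModelState(spec=spec, model=model, rng_seed=int(seed))


def forward(state: ModelState, batch: np.ndarray,
            train: bool = False) -> np.ndarray:
    """Run the network on a (batch, 3, H, W) tensor -> (batch, 2, H, W) scores."""
    arr = batch.tensor if hasattr(batch, "tensor") else batch
    return state.model.forward(arr, train=train)


def softmax_fg(scores: np.ndarray) -> np.ndarray:
    """Foreground probability from a (batch, 2, H, W) score map."""
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e[:, 1] / (e[:, 0] + e[:, 1])


def bce_loss(fg_probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy, probabilities clamped to [eps, 1-eps]."""
    if fg_probs.shape != labels.shape:
        raise SpecError(f"shape mismatch {fg_probs.shape} vs {labels.shape}")
    p = np.clip(np.asarray(fg_probs, dtype=np.float64), PROB_EPS, 1 - PROB_EPS)
    y = np.asarray(labels, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def bce_loss_grad(fg_probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Analytic gradient of bce_loss with respect to the probabilities."""
    p = np.clip(np.asarray(fg_probs, dtype=np.float64), PROB_EPS, 1 - PROB_EPS)
    y = np.asarray(labels, dtype=np.float64)
    inside = (fg_probs > PROB_EPS) & (fg_probs < 1 - PROB_EPS)
    return (inside * (p - y) / (p * (1 - p))) / p.size


def softmax_bce_score_grad(scores: np.ndarray,
                           labels: np.ndarray) -> np.ndarray:
    """Gradient of the softmax+BCE loss with respect to the raw scores.

    With p the softmax foreground probability, dL/dz_fg = (p - y)/N and
    dL/dz_bg = -(p - y)/N.
    """
    p = softmax_fg(scores)
    n = p.size
    g = ((p - labels) / n).astype(DTYPE)
    return np.stack([-g, g], axis=1)


def decode_mask(scores: np.ndarray) -> np.ndarray:
    """Per-pixel two-class softmax -> binary mask; exact ties go to background."""
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite network scores")
    return (softmax_fg(scores) > 0.5).astype(np.uint8)


# -- checkpoint I/O ---------------------------------------------------------

def save_checkpoint(state: ModelState, path) -> str:
    """Serialize spec, weights, normalization statistics, optimizer state,
    epoch counter and seed; reload is bit-exact."""
    arrays = {}
    for k, v in {**state.model.parameters(), **state.model.buffers()}.items():
        arrays["arr:" + k] = v
    opt = state.optimizer_state or {}
    for k, v in opt.get("m", {}).items():
        arrays["opt.m:" + k] = v
    for k, v in opt.get("v", {}).items():
        arrays["opt.v:" + k] = v
    meta = {"spec": state.spec.to_dict(), "rng_seed": state.rng_seed,
            "epoch": state.epoch, "opt_t": opt.get("t")}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)
    return str(path)


def load_checkpoint(path) -> ModelState:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        spec = ArchSpec.from_dict(meta["spec"])
        state = build_network(spec, meta["rng_seed"])
        state.epoch = int(meta["epoch"])
        state.model.load_arrays(
            {k[4:]: z[k] for k in z.files if k.startswith("arr:")})
        if meta["opt_t"] is not None:
            state.optimizer_state = {
                "t": meta["opt_t"],
                "m": {k[6:]: z[k] for k in z.files if k.startswith("opt.m:")},
                "v": {k[6:]: z[k] for k in z.files if k.startswith("opt.v:")},
            }
    return state
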