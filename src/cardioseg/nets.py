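"""LS-Net and SS-Net: slice-wise U-Net encoder–decoder architectures.

Both stages share one topology: a contracting path of four encoding
modules (two 3×3 conv + BN + ReLU, then 2×2 max-pool halving the
feature map), a bottleneck, and a symmetric expanding path (×2
upsampling, skip concatenation with the matching encoder level, two
3×3 conv + BN + ReLU).  The output module applies two further 3×3
convolutions, dropout, and a 1×1 convolution with per-pixel softmax.
Batch normalization sits on every convolution except that final 1×1.

* **LS-Net** (coarse stage) takes the single normalized CT slice and
  predicts the coarse-group classes plus background.
* **SS-Net** (fine stage) is topologically identical but its input
  concatenates the slice with one binary prior channel per coarse
  structure (one-hot, background omitted), embedding the position,
  shape and scale of the large substructures; it predicts the
  fine-group classes plus background.

Upsampling is nearest-neighbour followed by a 3×3 convolution by
default; a learned 2×2 transposed convolution is available by flag.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    ChannelSoftmax,
    Conv2d,
    ConvTranspose2x2,
    Dropout,
    MaxPool2d,
    ReLU,
    Sequential,
    UpsampleNearest2,
)

__all__ = ["NetSpec", "UNet2D", "build_lsnet", "build_ssnet", "save_network", "load_network"]


@dataclass(frozen=True)
class NetSpec:
    """Architecture hyperparameters of one network stage."""

    in_channels: int = 1
    out_classes: int = 2
    base_width: int = 64
    depth: int = 4
    dropout_rate: float = 0.5
    batch_norm: bool = True
    transposed_up: bool = False

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.out_classes < 2:
            raise ValueError("out_classes must be >= 2 (background + >=1 class)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _conv_block(cin: int, cout: int, bn: bool, rng) -> Sequential:
    layers: list = [Conv2d(cin, cout, 3, rng)]
    if bn:
        layers.append(BatchNorm2d(cout))
    layers.append(ReLU())
    layers.append(Conv2d(cout, cout, 3, rng))
    if bn:
        layers.append(BatchNorm2d(cout))
    layers.append(ReLU())
    return Sequential(*layers)


class UNet2D:
    """U-Net over (N, C, H, W) slices; H and W must be divisible by 2**depth."""

    def __init__(self, spec: NetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w, d = spec.base_width, spec.depth

        self.enc: list[Sequential] = []
        cin = spec.in_channels
        for level in range(d):
            cout = w * (2**level)
            self.enc.append(_conv_block(cin, cout, spec.batch_norm, rng))
            cin = cout
        self.pool = MaxPool2d()
        self.bottleneck = _conv_block(cin, w * (2**d), spec.batch_norm, rng)

        self.up: list = []
        self.dec: list[Sequential] = []
        for level in reversed(range(d)):
            c_deep = w * (2 ** (level + 1))
            c_here = w * (2**level)
            if spec.transposed_up:
                self.up.append(ConvTranspose2x2(c_deep, c_here, rng))
            else:
                self.up.append(Sequential(UpsampleNearest2(), Conv2d(c_deep, c_here, 3, rng)))
            self.dec.append(_conv_block(c_here * 2, c_here, spec.batch_norm, rng))

        out_layers: list = [Conv2d(w, w, 3, rng)]
        if spec.batch_norm:
            out_layers.append(BatchNorm2d(w))
        out_layers.append(ReLU())
        out_layers.append(Conv2d(w, w, 3, rng))
        if spec.batch_norm:
            out_layers.append(BatchNorm2d(w))
        out_layers.append(ReLU())
        out_layers.append(Dropout(spec.dropout_rate, np.random.default_rng(seed + 1)))
        out_layers.append(Conv2d(w, spec.out_classes, 1, rng))
        self.head = Sequential(*out_layers)
        self.softmax = ChannelSoftmax()

        self._skip_channels = [w * (2**level) for level in range(d)]
        self._cache_ups: list = []

    # -- parameter plumbing ------------------------------------------------
    def _modules(self):
        mods = list(self.enc) + [self.bottleneck] + list(self.up) + list(self.dec) + [self.head]
        return mods

    def params(self):
        out = []
        for m in self._modules():
            out.extend(m.params())
        return out

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def _bn_layers(self):
        out = []
        stack = [m for m in self._modules()]
        while stack:
            m = stack.pop(0)
            if isinstance(m, Sequential):
                stack = m.layers + stack
            elif isinstance(m, BatchNorm2d):
                out.append(m)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value.copy() for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn_{i}_mean"] = bn.running_mean.copy()
            state[f"bn_{i}_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"bn_{i}_mean"]
            bn.running_var[...] = state[f"bn_{i}_var"]

    # -- forward / backward ------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected input (N, {self.spec.in_channels}, H, W), got {x.shape}"
            )
        div = 2**self.spec.depth
        _, _, h, w = x.shape
        if h % div or w % div:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by 2^depth={div}; "
                "pad or crop the slices first"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probability maps (N, out_classes, H, W); channels sum to 1.

        Accepts (N, C, H, W); internally the engine runs channels-last.
        """
        x = np.asarray(x, dtype=np.float32)
        self._check_input(x)
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
        skips = []
        for block in self.enc:
            x = block.forward(x, train)
            skips.append(x)
            x = self.pool.forward(x, train)
            if train:
                self._cache_ups.append((self.pool._x, self.pool._y))
        x = self.bottleneck.forward(x, train)
        for i, level in enumerate(reversed(range(self.spec.depth))):
            x = self.up[i].forward(x, train)
            x = np.concatenate([skips[level], x], axis=-1)
            x = self.dec[i].forward(x, train)
        logits = self.head.forward(x, train)
        probs = self.softmax.forward(logits, train)
        return np.ascontiguousarray(probs.transpose(0, 3, 1, 2))

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate gradients w.r.t. the (N, C, H, W) output probabilities."""
        dy = np.ascontiguousarray(dprobs.astype(np.float32).transpose(0, 2, 3, 1))
        dy = self.softmax.backward(dy)
        dy = self.head.backward(dy)
        dskips: dict[int, np.ndarray] = {}
        # dec[i]/up[i] were applied at level depth-1-i; walk them back
        for i in reversed(range(self.spec.depth)):
            level = self.spec.depth - 1 - i
            dy = self.dec[i].backward(dy)
            c_skip = self._skip_channels[level]
            dskips[level] = dy[..., :c_skip]
            dy = self.up[i].backward(np.ascontiguousarray(dy[..., c_skip:]))
        dy = self.bottleneck.backward(dy)
        for level in reversed(range(self.spec.depth)):
            self.pool._x, self.pool._y = self._cache_ups[level]
            dy = self.pool.backward(dy)
            dy = dy + dskips[level]
            dy = self.enc[level].backward(dy)
        self._cache_ups = []

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params(), lr=lr)


def build_lsnet(spec: NetSpec, seed: int = 0) -> UNet2D:
    """Coarse-stage network: single-channel normalized CT slice in."""
    if spec.in_channels != 1:
        raise ValueError(
            f"LS-Net takes the CT slice alone (in_channels=1), got {spec.in_channels}"
        )
    return UNet2D(spec, seed=seed)


def build_ssnet(spec: NetSpec, n_prior_channels: int, seed: int = 0) -> UNet2D:
    """Fine-stage network: CT slice plus one prior channel per CG class."""
    if n_prior_channels < 1:
        raise ValueError("SS-Net needs at least one prior channel")
    if spec.in_channels != 1 + n_prior_channels:
        raise ValueError(
            f"SS-Net in_channels must be 1 + n_prior_channels = "
            f"{1 + n_prior_channels}, got {spec.in_channels}"
        )
    return UNet2D(spec, seed=seed)


def save_network(net: UNet2D, path_prefix: str | os.PathLike) -> None:
    """Save weights (.npz) plus a self-describing spec sidecar (.json)."""
    prefix = os.fspath(path_prefix)
    np.savez(prefix + ".npz", **net.state_dict())
    with open(prefix + ".json", "w") as fh:
        json.dump(asdict(net.spec), fh, indent=1)


def load_network(path_prefix: str | os.PathLike) -> UNet2D:
    prefix = os.fspath(path_prefix)
    with open(prefix + ".json") as fh:
        spec = NetSpec(**json.load(fh))
    net = UNet2D(spec)
    with np.load(prefix + ".npz") as data:
        net.load_state_dict(dict(data))
    return net
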