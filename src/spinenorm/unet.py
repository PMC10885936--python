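"""2D U-Net for spinal-canal delineation on two-channel ADC / S0 slices.

Symmetric encoder/decoder with skip connections at each of four levels.
Encoder blocks are two 3x3 convolutions, each followed by batch
normalisation and ReLU; levels are joined by 2x2 max pooling and dropout.
The decoder upsamples with stride-2 transposed convolutions (kernel 3),
concatenates the matching encoder features, and applies dropout plus two
further convolutions.  A 1x1 convolution with sigmoid yields per-pixel
canal probabilities.  The architecture is size-parametric: any input whose
spatial size is divisible by 2^4 works, so a reduced-filter variant runs on
64 x 64 phantom slices at CPU speed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["UNetConfig", "UNet", "build_unet", "save_checkpoint", "load_checkpoint"]

DEPTH = 4


@dataclass
class UNetConfig:
    encoder_filters: tuple[int, ...] = (32, 64, 128, 256)
    bottleneck_filters: int = 512
    dropout_rate: float = 0.2
    in_channels: int = 2

    def __post_init__(self) -> None:
        self.encoder_filters = tuple(int(f) for f in self.encoder_filters)
        if len(self.encoder_filters) != DEPTH:
            raise ValueError(f"encoder depth must be {DEPTH}")
        if not all(a < b for a, b in zip(self.encoder_filters, self.encoder_filters[1:])):
            raise ValueError("encoder filters must be strictly increasing")
        if not self.encoder_filters[-1] < self.bottleneck_filters:
            raise ValueError("bottleneck must be deeper than the last encoder level")


def _conv_block(cin: int, cout: int, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, rng=rng), nn.BatchNorm2d(cout), nn.ReLU(),
        nn.Conv2d(cout, cout, rng=rng), nn.BatchNorm2d(cout), nn.ReLU(),
    )


class UNet:
    """Explicit forward/backward U-Net built on :mod:`spinenorm.nn`."""

    def __init__(self, cfg: UNetConfig, seed: int = 0) -> None:
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        rng = self.rng
        f = cfg.encoder_filters
        self.enc = []
        cin = cfg.in_channels
        for fl in f:
            self.enc.append(_conv_block(cin, fl, rng))
            cin = fl
        self.pools = [nn.MaxPool2d() for _ in f]
        self.drop_enc = [nn.Dropout(cfg.dropout_rate, rng) for _ in f]
        self.bottleneck = _conv_block(f[-1], cfg.bottleneck_filters, rng)
        self.up = []
        self.drop_dec = []
        self.dec = []
        prev = cfg.bottleneck_filters
        for fl in reversed(f):
            self.up.append(nn.ConvTranspose2d(prev, fl, rng=rng))
            self.drop_dec.append(nn.Dropout(cfg.dropout_rate, rng))
            self.dec.append(_conv_block(2 * fl, fl, rng))
            prev = fl
        self.out_conv = nn.Conv2d(f[0], 1, k=1, pad=0, rng=rng)
        self.trained = False

    # ------------------------------------------------------------------

    def _layers(self) -> list[nn.Layer]:
        return [*self.enc, *self.pools, *self.drop_enc, self.bottleneck,
                *self.up, *self.drop_dec, *self.dec, self.out_conv]

    def n_parameters(self) -> int:
        return sum(v.size for l in self._layers()
                   for sub in nn.iter_layers(l) for v in sub.params.values())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map ``(N, in_channels, H, W)`` to ``(N, 1, H, W)`` probabilities."""
        if x.shape[2] % 2 ** DEPTH or x.shape[3] % 2 ** DEPTH:
            raise ValueError(f"input spatial size must be divisible by {2 ** DEPTH}")
        skips = []
        h = x
        for enc, pool, drop in zip(self.enc, self.pools, self.drop_enc):
            h = enc.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
            h = drop.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for i, (up, drop, dec) in enumerate(zip(self.up, self.drop_dec, self.dec)):
            skip = skips[-(i + 1)]
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=1)
            h = drop.forward(h, train)
            h = dec.forward(h, train)
        self._logits = self.out_conv.forward(h, train)
        self._prob = nn.sigmoid(self._logits)
        return self._prob

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        dlogits = dprob.astype(self._prob.dtype) * self._prob * (1.0 - self._prob)
        d = self.out_conv.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * DEPTH
        for i in range(DEPTH - 1, -1, -1):
            dec, drop, up = self.dec[i], self.drop_dec[i], self.up[i]
            d = dec.backward(d)
            d = drop.backward(d)
            fl = self.cfg.encoder_filters[DEPTH - 1 - i]
            dskips[DEPTH - 1 - i] = d[:, :fl]
            d = up.backward(d[:, fl:])
        d = self.bottleneck.backward(d)
        for i in range(DEPTH - 1, -1, -1):
            d = self.drop_enc[i].backward(d)
            d = self.pools[i].backward(d)
            d = self.enc[i].backward(d + dskips[i])

    # ------------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for li, layer in enumerate(l for root in self._layers()
                                   for l in nn.iter_layers(root)):
            for k, v in layer.params.items():
                state[f"{li}.{k}"] = v
            if isinstance(layer, nn.BatchNorm2d):
                state[f"{li}.running_mean"] = layer.running_mean
                state[f"{li}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(l for root in self._layers()
                                   for l in nn.iter_layers(root)):
            for k in layer.params:
                layer.params[k][...] = state[f"{li}.{k}"]
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean[...] = state[f"{li}.running_mean"]
                layer.running_var[...] = state[f"{li}.running_var"]


def build_unet(cfg: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Construct a (deterministically initialised) U-Net from a config."""
    return UNet(cfg or UNetConfig(), seed=seed)


def save_checkpoint(model: UNet, path: str | Path, meta: dict | None = None) -> None:
    """Save weights as ``.npz`` with a JSON sidecar recording the configs."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {"encoder_filters": list(model.cfg.encoder_filters),
               "bottleneck_filters": model.cfg.bottleneck_filters,
               "dropout_rate": model.cfg.dropout_rate,
               "in_channels": model.cfg.in_channels,
               "trained": model.trained}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> UNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = UNetConfig(encoder_filters=tuple(sidecar["encoder_filters"]),
                     bottleneck_filters=sidecar["bottleneck_filters"],
                     dropout_rate=sidecar["dropout_rate"],
                     in_channels=sidecar["in_channels"])
    model = UNet(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict(dict(data))
    model.trained = bool(sidecar.get("trained", True))
    return model
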