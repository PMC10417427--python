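"""CSR-UNet: an encoder-decoder segmentation network built from CSR blocks.

The encoder applies ``depth`` CSR stages with 2x max-pool downsampling and
channel doubling from ``base_channels``; the decoder mirrors it with
transposed-convolution upsampling, skip concatenations and CSR stages; a
final 1x1(x1) convolution maps to the output classes. Inputs whose spatial
extents are not divisible by the cumulative pooling factors are zero-padded
internally and the logits cropped back, so the output spatial shape always
equals the input spatial shape.

The 3D variant consumes ``(B, C, x, y, z)`` volumes; the 2.5D variant
consumes ``(B, k, x, y)`` multi-slice slabs (slices as channels) and
predicts the centre slice.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import Concat, Conv, CSRBlock, MaxPool, TransposedConv

__all__ = ["CSRUNet", "save_checkpoint", "load_checkpoint"]


class CSRUNet:
    def __init__(self, config, seed: int = 0):
        # config is a csrseg.model.ModelConfig (kept duck-typed here)
        self.config = config
        ndim = 2 if config.dims == "2.5d" else 3
        self.ndim = ndim
        rng = np.random.default_rng(seed)
        depth = config.depth
        ch = [config.base_channels * 2 ** i for i in range(depth + 1)]

        zp = config.resolved_z_pool()
        self.pool_factors = []
        for i in range(depth):
            if ndim == 2:
                self.pool_factors.append((2, 2))
            else:
                self.pool_factors.append((2, 2, 2 if zp[i] else 1))

        self.enc = []
        in_c = config.in_channels
        for i in range(depth):
            self.enc.append(CSRBlock(in_c, ch[i], ndim, rng,
                                     config.se_reduction, name=f"enc{i}"))
            in_c = ch[i]
        self.pools = [MaxPool(f) for f in self.pool_factors]
        self.bottleneck = CSRBlock(ch[depth - 1], ch[depth], ndim, rng,
                                   config.se_reduction, name="bottleneck")
        self.ups = []
        self.dec = []
        self.cats = []
        for i in reversed(range(depth)):
            self.ups.append(TransposedConv(ch[i + 1], ch[i], self.pool_factors[i],
                                           rng, name=f"up{i}"))
            self.cats.append(Concat())
            self.dec.append(CSRBlock(2 * ch[i], ch[i], ndim, rng,
                                     config.se_reduction, name=f"dec{i}"))
        self.final = Conv(ch[0], config.out_channels, 1, ndim, rng, bias=True,
                          name="final")

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        yield from self.enc
        yield self.bottleneck
        yield from self.ups
        yield from self.dec
        yield self.final

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for layer in self._layers():
            for attr in ("bn1", "bn2"):
                bn = getattr(layer, attr, None)
                if bn is not None:
                    state[f"{bn.gamma.name}.running_mean"] = bn.running_mean.copy()
                    state[f"{bn.gamma.name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for p in self.params():
            p.value[...] = state[p.name]
        for layer in self._layers():
            for attr in ("bn1", "bn2"):
                bn = getattr(layer, attr, None)
                if bn is not None:
                    bn.running_mean[...] = state[f"{bn.gamma.name}.running_mean"]
                    bn.running_var[...] = state[f"{bn.gamma.name}.running_var"]

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    # -- forward / backward ------------------------------------------------
    def _pad_multiples(self):
        mult = [1] * self.ndim
        for f in self.pool_factors:
            for i in range(self.ndim):
                mult[i] *= f[i]
        return mult

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != self.ndim + 2:
            raise ValueError(f"expected {self.ndim + 2}D input (B, C, spatial), "
                             f"got shape {x.shape}")
        S = x.shape[2:]
        mult = self._pad_multiples()
        pad = [(-s) % m for s, m in zip(S, mult)]
        self._pad = pad
        self._orig_S = S
        if any(pad):
            x = np.pad(x, ((0, 0), (0, 0)) + tuple((0, p) for p in pad))

        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for up, cat, dec, skip in zip(self.ups, self.cats, self.dec,
                                      reversed(skips)):
            h = up.forward(h, train)
            h = cat.forward2(skip, h)
            h = dec.forward(h, train)
        logits = self.final.forward(h, train)
        if any(pad):
            crop = (slice(None), slice(None)) + tuple(slice(0, s) for s in S)
            logits = logits[crop]
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        pad = self._pad
        if any(pad):
            dlogits = np.pad(dlogits, ((0, 0), (0, 0)) + tuple((0, p) for p in pad))
        dh = self.final.backward(dlogits)
        dskips = [None] * len(self.dec)
        for j in reversed(range(len(self.dec))):
            dh = self.dec[j].backward(dh)
            dskip, dh = self.cats[j].backward(dh)
            dskips[j] = dskip
            dh = self.ups[j].backward(dh)
        dh = self.bottleneck.backward(dh)
        for i in reversed(range(len(self.enc))):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[len(self.dec) - 1 - i]
            dh = self.enc[i].backward(dh)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode softmax class probabilities."""
        logits = self.forward(x, train=False)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


def save_checkpoint(net: CSRUNet, path) -> Path:
    """Write config + weights to an .npz checkpoint."""
    from ..model import config_to_dict  # local import to avoid a cycle
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = net.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(config_to_dict(net.config)).encode(), dtype=np.uint8)
    np.savez_compressed(path, **state)
    return path


def load_checkpoint(path) -> CSRUNet:
    from ..model import config_from_dict
    with np.load(Path(path)) as data:
        cfg = config_from_dict(json.loads(bytes(data["__config__"]).decode()))
        state = {k: data[k] for k in data.files if k != "__config__"}
    net = CSRUNet(cfg, seed=0)
    net.load_state_dict(state)
    return net
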