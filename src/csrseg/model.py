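"""CSR-UNet model configuration and construction.

A CSR-UNet is a U-Net whose convolution stages are CSR blocks: dual
3x3 convolutions with batch normalisation, squeeze-and-excitation channel
attention, and a residual shortcut. Two variants exist:

* ``dims="3d"`` — 3D convolutions over ``(x, y, z)`` volumes (1 input
  channel); used for whole-volume coarse tumour segmentation.
* ``dims="2.5d"`` — 2D convolutions over 5-slice slabs stacked as channels,
  predicting the centre slice; used for the liver stage and for fine
  segmentation of small detected-lesion crops, where slice spacing is far
  coarser than in-plane resolution.

Because slices are typically 5 mm thick against sub-millimetre in-plane
resolution, 3D networks can disable z pooling at early stages
(``z_pool`` / ``min_z``) to avoid collapsing an already-short slice axis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .nn.layers import CSRBlock, SEBlock
from .nn.unet import CSRUNet, load_checkpoint, save_checkpoint

__all__ = ["ModelConfig", "build_csr_unet", "SEBlock", "CSRBlock", "CSRUNet",
           "save_checkpoint", "load_checkpoint", "plan_z_pooling",
           "config_to_dict", "config_from_dict"]


def plan_z_pooling(z_extent: int, depth: int) -> tuple[bool, ...]:
    """Decide per-stage z pooling for an anisotropic volume.

    Pool z at a stage only while the (padded) remaining z extent is at least
    4 voxels, so the slice axis never collapses below 2 before the
    bottleneck.
    """
    out = []
    rem = int(z_extent)
    for _ in range(depth):
        if rem >= 4:
            out.append(True)
            rem = (rem + 1) // 2
        else:
            out.append(False)
    return tuple(out)


@dataclass(frozen=True)
class ModelConfig:
    dims: str = "3d"            # "3d" or "2.5d"
    in_channels: int = 1        # 5 for 2.5D slabs
    out_channels: int = 2       # background / lesion
    base_channels: int = 16
    depth: int = 4              # number of downsamplings
    se_reduction: int = 4
    z_pool: tuple[bool, ...] | None = None  # per-stage z pooling (3D only)
    min_z: int | None = None    # typical z extent; drives z_pool when unset

    def __post_init__(self):
        if self.dims not in ("3d", "2.5d"):
            raise ValueError(f"dims must be '3d' or '2.5d', got {self.dims!r}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < self.se_reduction:
            raise ValueError("base_channels must be >= se_reduction")
        if min(self.in_channels, self.out_channels, self.base_channels,
               self.se_reduction) < 1:
            raise ValueError("channel counts must be positive")
        if self.z_pool is not None and len(self.z_pool) != self.depth:
            raise ValueError("z_pool must have one flag per stage")

    def resolved_z_pool(self) -> tuple[bool, ...]:
        if self.dims == "2.5d":
            return (False,) * self.depth
        if self.z_pool is not None:
            return tuple(bool(b) for b in self.z_pool)
        if self.min_z is None:
            return (True,) * self.depth
        return plan_z_pooling(self.min_z, self.depth)


def build_csr_unet(config: ModelConfig, seed: int = 0) -> CSRUNet:
    """Build a CSR-UNet with deterministic weight initialisation."""
    return CSRUNet(config, seed=seed)


def config_to_dict(config: ModelConfig) -> dict:
    d = asdict(config)
    if d["z_pool"] is not None:
        d["z_pool"] = list(d["z_pool"])
    return d


def config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    if d.get("z_pool") is not None:
        d["z_pool"] = tuple(bool(b) for b in d["z_pool"])
    return ModelConfig(**d)
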