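"""Preprocessing, patch planning, sliding-window assembly and augmentation.

The preprocessing recipe mirrors standard practice for patch-based 3D
segmentation: in-plane resampling to a fixed matrix size (bilinear for
images, nearest-neighbour for labels), percentile clipping (0.5-99.5 by
default) followed by min-max normalisation to [0, 1], partition of the
volume into overlapping patches for training and sliding-window inference,
and online augmentation (axis flips with probability 0.5 per axis, in-plane
rotations up to +-20 degrees, global intensity scaling in (0.9, 1.1)).

All voxel indices are 0-based; patches and boxes are half-open
``[start, start + size)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import LabelVolume, VolumeGrid, check_aligned

__all__ = ["PatchSpec", "AugmentParams", "resample_inplane", "clip_normalize",
           "plan_patches", "extract_patch", "assemble", "augment",
           "make_2p5d_slabs", "sample_patch_start"]

log = logging.getLogger(__name__)


@dataclass
class PatchSpec:
    """One axis-aligned patch: half-open window [start, start+size)."""

    start: tuple[int, int, int]
    size: tuple[int, int, int]
    weight_map: np.ndarray | None = None  # filled lazily by assemble()

    def slices(self) -> tuple[slice, ...]:
        return tuple(slice(s, s + z) for s, z in zip(self.start, self.size))


@dataclass
class AugmentParams:
    flip_prob_per_axis: float = 0.5
    max_rotation_deg: float = 20.0
    intensity_scale_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.flip_prob_per_axis <= 1:
            raise ValueError("flip probability must be in [0, 1]")
        lo, hi = self.intensity_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("intensity scale range must be positive and ordered")


def resample_inplane(volume, target_xy, mode: str = "linear"):
    """Resample the in-plane (x, y) dimensions to ``target_xy``.

    Images use linear interpolation, label volumes must use nearest
    neighbour; spacing is rescaled by the shape ratio so the physical extent
    is preserved.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    is_label = isinstance(volume, LabelVolume)
    if is_label and mode != "nearest":
        raise ValueError("label volumes must be resampled with nearest mode")
    tx, ty = (int(t) for t in target_xy)
    if tx <= 0 or ty <= 0:
        raise ValueError("target_xy must be positive")
    nx, ny, nz = volume.shape
    new_spacing = (volume.spacing[0] * nx / tx, volume.spacing[1] * ny / ty,
                   volume.spacing[2])
    if (tx, ty) == (nx, ny):
        out = volume.values.copy()
    else:
        zoom = (tx / nx, ty / ny, 1.0)
        order = 0 if mode == "nearest" else 1
        out = ndimage.zoom(volume.values, zoom, order=order, mode="nearest",
                           grid_mode=True)
        out = out[:tx, :ty, :]  # guard against rounding overshoot
    if is_label:
        return LabelVolume(out.astype(volume.values.dtype), new_spacing)
    return VolumeGrid(out.astype(np.float32), new_spacing)


def clip_normalize(volume: VolumeGrid, lo_pct: float = 0.5, hi_pct: float = 99.5,
                   mask: LabelVolume | None = None) -> VolumeGrid:
    """Percentile clipping followed by affine normalisation to [0, 1].

    Values at/below the ``lo_pct`` percentile map to 0, at/above ``hi_pct``
    to 1. With a mask, percentiles are computed over the masked voxels only
    (the usual choice when contrast matters only inside the organ). A
    degenerate intensity range yields an all-zero volume with a logged
    warning rather than an exception, so empty ROIs do not abort a pipeline.
    """
    if lo_pct >= hi_pct:
        raise ValueError("need lo_pct < hi_pct")
    vals = volume.values
    sample = vals[mask.binary()] if mask is not None else vals
    if sample.size == 0:
        log.warning("clip_normalize: empty mask; returning zeros")
        return VolumeGrid(np.zeros_like(vals, dtype=np.float32), volume.spacing)
    lo, hi = np.percentile(sample, [lo_pct, hi_pct])
    if hi <= lo:
        log.warning("clip_normalize: degenerate intensity range (lo == hi); "
                    "returning zeros")
        return VolumeGrid(np.zeros_like(vals, dtype=np.float32), volume.spacing)
    out = (np.clip(vals, lo, hi) - lo) / (hi - lo)
    return VolumeGrid(out.astype(np.float32), volume.spacing)


def plan_patches(shape, patch, overlap_frac: float = 0.5) -> list[PatchSpec]:
    """Plan a sliding-window grid of patches covering the whole volume.

    Per axis the stride is ``floor(patch * (1 - overlap_frac))`` and the last
    start is snapped so the final patch ends exactly at the volume edge; a
    patch larger than the volume is snapped down to the volume (with a
    warning). The union of patches covers every voxel.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    shape = tuple(int(s) for s in shape)
    patch = tuple(int(p) for p in patch)
    if any(p <= 0 for p in patch):
        raise ValueError("patch size must be positive")
    if any(p > s for p, s in zip(patch, shape)):
        log.warning("patch %s exceeds volume %s; snapping down", patch, shape)
        patch = tuple(min(p, s) for p, s in zip(patch, shape))

    axis_starts = []
    for s, p in zip(shape, patch):
        stride = max(1, int(np.floor(p * (1 - overlap_frac))))
        starts = list(range(0, s - p + 1, stride))
        if starts[-1] != s - p:
            starts.append(s - p)
        axis_starts.append(starts)
    specs = []
    for sx in axis_starts[0]:
        for sy in axis_starts[1]:
            for sz in axis_starts[2]:
                specs.append(PatchSpec(start=(sx, sy, sz), size=patch))
    return specs


def extract_patch(values: np.ndarray, spec: PatchSpec) -> np.ndarray:
    return values[spec.slices()]


def _weight_map(size, weighting: str) -> np.ndarray:
    if weighting == "uniform":
        return np.ones(size, dtype=np.float32)
    if weighting == "gaussian":
        # peak-normalised separable Gaussian, sigma = patch/8 per axis
        axes = []
        for n in size:
            x = np.arange(n) - (n - 1) / 2
            sigma = max(n / 8.0, 1e-3)
            axes.append(np.exp(-0.5 * (x / sigma) ** 2))
        w = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        return np.maximum(w, 1e-6).astype(np.float32)
    raise ValueError(f"unknown weighting {weighting!r}")


def assemble(patch_outputs, shape, weighting: str = "gaussian") -> np.ndarray:
    """Weighted-average fusion of overlapping patch outputs into one volume.

    ``patch_outputs`` is a list of (PatchSpec, array); arrays are either the
    patch shape or channels-first ``(C, *patch_shape)``. A PatchSpec's own
    ``weight_map`` takes precedence over the ``weighting`` scheme.
    """
    shape = tuple(int(s) for s in shape)
    first = np.asarray(patch_outputs[0][1])
    channels = first.ndim == 4
    out_shape = (first.shape[0],) + shape if channels else shape
    acc = np.zeros(out_shape, dtype=np.float64)
    wacc = np.zeros(shape, dtype=np.float64)
    for spec, arr in patch_outputs:
        arr = np.asarray(arr)
        expected = (first.shape[0],) + tuple(spec.size) if channels else tuple(spec.size)
        if arr.shape != expected:
            raise ValueError(f"patch output shape {arr.shape} does not match "
                             f"spec size {expected}")
        w = spec.weight_map if spec.weight_map is not None else _weight_map(spec.size, weighting)
        sl = spec.slices()
        if channels:
            acc[(slice(None),) + sl] += arr * w
        else:
            acc[sl] += arr * w
        wacc[sl] += w
    if np.any(wacc == 0):
        raise ValueError("patch plan does not cover the whole volume")
    return (acc / wacc).astype(np.float32)


def augment(image: VolumeGrid, label: LabelVolume, params: AugmentParams,
            rng: np.random.Generator | None = None):
    """Identical spatial transform on image and label, intensity on image only.

    Flips are drawn per axis with ``flip_prob_per_axis``; rotation is
    in-plane (about the slice axis, where resolution is finest) with an angle
    uniform in [-max_rotation_deg, +max_rotation_deg]; the image is finally
    scaled by a factor uniform in ``intensity_scale_range``. Deterministic
    for a fixed seed/rng.
    """
    check_aligned(image, label)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    img = image.values
    lab = label.values
    for ax in range(3):
        if rng.uniform() < params.flip_prob_per_axis:
            img = np.flip(img, axis=ax)
            lab = np.flip(lab, axis=ax)
    if params.max_rotation_deg > 0:
        angle = float(rng.uniform(-params.max_rotation_deg, params.max_rotation_deg))
        if angle != 0.0:
            img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False,
                                 order=1, mode="nearest")
            lab = ndimage.rotate(lab, angle, axes=(0, 1), reshape=False,
                                 order=0, mode="nearest")
    lo, hi = params.intensity_scale_range
    scale = float(rng.uniform(lo, hi))
    img = np.ascontiguousarray(img, dtype=np.float32) * scale
    lab = np.ascontiguousarray(lab)
    return VolumeGrid(img, image.spacing), LabelVolume(lab, label.spacing)


def make_2p5d_slabs(volume: VolumeGrid | np.ndarray, k: int = 5):
    """Decompose a volume into per-slice k-channel 2D slabs.

    For each slice c the slab stacks slices ``c - k//2 .. c + k//2`` (edge
    slices replicated at the boundaries) as channels; a 2.5D network consumes
    the slab and predicts the centre slice. Returns a list of
    ``(slab (k, nx, ny), center_index)``.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    vals = volume.values if isinstance(volume, VolumeGrid) else np.asarray(volume)
    nz = vals.shape[2]
    half = k // 2
    slabs = []
    for c in range(nz):
        idx = np.clip(np.arange(c - half, c + half + 1), 0, nz - 1)
        slab = np.stack([vals[:, :, i] for i in idx], axis=0)
        slabs.append((slab, c))
    return slabs


def sample_patch_start(label_values: np.ndarray, shape, patch, p_fg: float,
                       rng: np.random.Generator) -> tuple[int, int, int]:
    """Foreground-biased training patch sampling.

    With probability ``p_fg`` the patch is centred on a random foreground
    voxel (clamped into bounds); otherwise the start is uniform. This is the
    weighting scheme that puts training emphasis on the lesion-bearing
    positions the network needs to focus on.
    """
    shape = np.asarray(shape)
    patch = np.asarray(patch)
    fg = np.argwhere(label_values > 0)
    if len(fg) > 0 and rng.uniform() < p_fg:
        c = fg[int(rng.integers(0, len(fg)))]
        start = np.clip(c - patch // 2, 0, shape - patch)
    else:
        start = np.array([int(rng.integers(0, s - p + 1)) for s, p in zip(shape, patch)])
    return tuple(int(v) for v in start)
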