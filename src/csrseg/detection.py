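"""Candidate-lesion detection and fixed-size ROI cropping.

Small lesions (long diameter below a 30 mm size gate) are detected and
cropped to a uniform 64x64x5 window for fine segmentation. Three detector
sources are supported:

* ``proposal`` — connected components of a thresholded coarse probability
  map inside the liver; the built-in default. The threshold is deliberately
  low (0.1) so faint small lesions the coarse argmax would miss still
  produce a candidate box.
* ``oracle``  — boxes derived from a ground-truth lesion label map; used
  for training the fine stage and as a test oracle.
* ``external`` — boxes read from a JSON file produced by any external
  detector, re-snapped to the uniform crop size about their centres.

The size gate is strict (< 30 mm): lesions at or above the gate are left to
the coarse stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import LabelVolume, VolumeGrid
from .metrics import STRUCT_26, long_diameter

__all__ = ["DetectionBox", "Placement", "propose_boxes", "oracle_boxes",
           "crop_roi", "paste_back", "read_external_boxes", "write_boxes",
           "DEFAULT_CROP_SIZE"]

DEFAULT_CROP_SIZE = (64, 64, 5)


@dataclass(frozen=True)
class DetectionBox:
    """Axis-aligned ROI in global voxel coordinates, half-open [start, start+size)."""

    start: tuple[int, int, int]
    size: tuple[int, int, int] = DEFAULT_CROP_SIZE
    score: float = 1.0
    source: str = "proposal"

    def __post_init__(self):
        if len(self.start) != 3 or len(self.size) != 3:
            raise ValueError("start and size must be 3-vectors")
        if any(int(s) <= 0 for s in self.size):
            raise ValueError("box size must be positive")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")
        object.__setattr__(self, "start", tuple(int(v) for v in self.start))
        object.__setattr__(self, "size", tuple(int(v) for v in self.size))

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple(s + (z - 1) / 2 for s, z in zip(self.start, self.size))

    def to_dict(self) -> dict:
        return {"start": list(self.start), "size": list(self.size),
                "score": float(self.score), "source": self.source}


def _box_at_center(center_vox, crop_size, score, source) -> DetectionBox:
    start = tuple(int(np.rint(c)) - s // 2 for c, s in zip(center_vox, crop_size))
    return DetectionBox(start=start, size=tuple(crop_size), score=score, source=source)


def _merge_duplicates(boxes: list[DetectionBox]) -> list[DetectionBox]:
    """Merge boxes whose centres are within half a crop per axis, keeping the
    higher score."""
    kept: list[DetectionBox] = []
    for box in sorted(boxes, key=lambda b: -b.score):
        dup = any(all(abs(c1 - c2) < s / 2 for c1, c2, s in
                      zip(box.center, k.center, box.size)) for k in kept)
        if not dup:
            kept.append(box)
    return kept


def propose_boxes(prob_map: VolumeGrid, liver_mask: LabelVolume,
                  threshold: float = 0.1, size_gate_mm: float = 30.0,
                  crop_size=DEFAULT_CROP_SIZE) -> list[DetectionBox]:
    """Detect sub-gate candidates on a coarse foreground probability map.

    Connected components (26-connectivity) of ``prob >= threshold`` inside
    the liver whose long diameter is strictly below the gate become boxes
    centred on the component centroid; the score is the mean probability
    over the component. Boxes are returned sorted by descending score.
    """
    prob = prob_map.values
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    cand = (prob >= threshold) & liver_mask.binary()
    comp, n = ndimage.label(cand, structure=STRUCT_26)
    boxes = []
    for i in range(1, n + 1):
        idx = np.argwhere(comp == i)
        d = long_diameter(idx, prob_map.spacing)
        if d >= size_gate_mm:
            continue
        score = float(prob[tuple(idx.T)].mean())
        boxes.append(_box_at_center(idx.mean(axis=0), crop_size, score, "proposal"))
    boxes = _merge_duplicates(boxes)
    return sorted(boxes, key=lambda b: -b.score)


def oracle_boxes(lesion_label: LabelVolume, size_gate_mm: float = 30.0,
                 crop_size=DEFAULT_CROP_SIZE) -> list[DetectionBox]:
    """Ground-truth boxes for every labelled lesion below the size gate.

    One box per lesion label, centred on the component centroid (rounded to
    the nearest voxel), score 1. Lesions at or above the gate are excluded
    (strict <).
    """
    arr = lesion_label.values
    boxes = []
    for i in np.unique(arr):
        if i == 0:
            continue
        idx = np.argwhere(arr == i)
        if long_diameter(idx, lesion_label.spacing) >= size_gate_mm:
            continue
        boxes.append(_box_at_center(idx.mean(axis=0), crop_size, 1.0, "oracle"))
    return boxes


@dataclass(frozen=True)
class Placement:
    """Record of where a crop's in-bounds window sits, for exact paste-back."""

    box: DetectionBox
    global_slices: tuple[slice, slice, slice]
    local_slices: tuple[slice, slice, slice]


def crop_roi(volume, box: DetectionBox):
    """Extract a fixed-size crop; out-of-bounds margins are zero-padded.

    Returns ``(crop, placement)`` where the placement allows exact
    paste-back of the in-bounds sub-window.
    """
    vals = volume.values if hasattr(volume, "values") else np.asarray(volume)
    shape = vals.shape
    g_lo = [max(s, 0) for s in box.start]
    g_hi = [min(s + z, n) for s, z, n in zip(box.start, box.size, shape)]
    if any(lo >= hi for lo, hi in zip(g_lo, g_hi)):
        raise ValueError(f"box {box.start} size {box.size} lies fully outside "
                         f"volume of shape {shape}")
    l_lo = [lo - s for lo, s in zip(g_lo, box.start)]
    l_hi = [hi - s for hi, s in zip(g_hi, box.start)]
    crop = np.zeros(box.size, dtype=vals.dtype)
    gsl = tuple(slice(a, b) for a, b in zip(g_lo, g_hi))
    lsl = tuple(slice(a, b) for a, b in zip(l_lo, l_hi))
    crop[lsl] = vals[gsl]
    return crop, Placement(box=box, global_slices=gsl, local_slices=lsl)


def paste_back(target: np.ndarray, crop: np.ndarray, placement: Placement) -> None:
    """Write a crop's in-bounds sub-window back into a global array."""
    target[placement.global_slices] = crop[placement.local_slices]


def write_boxes(boxes: list[DetectionBox], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"boxes": [b.to_dict() for b in boxes]}, indent=2))
    return path


def read_external_boxes(path, crop_size=DEFAULT_CROP_SIZE,
                        min_score: float = 0.0) -> list[DetectionBox]:
    """Read detector boxes from JSON and re-snap them to the uniform crop size.

    Each record needs ``start`` (3 ints), ``size`` (3 positive ints) and
    ``score``; a malformed record raises an error naming its index. Boxes are
    re-centred: the output box has the configured crop size about the input
    box's centre. Records below ``min_score`` are dropped.
    """
    data = json.loads(Path(path).read_text())
    records = data["boxes"] if isinstance(data, dict) else data
    boxes = []
    for i, rec in enumerate(records):
        try:
            start = [int(v) for v in rec["start"]]
            size = [int(v) for v in rec["size"]]
            score = float(rec["score"])
            if len(start) != 3 or len(size) != 3 or any(s <= 0 for s in size):
                raise ValueError("bad geometry")
            if not 0.0 <= score <= 1.0:
                raise ValueError("score out of range")
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed box record at index {i}: {exc}") from exc
        if score < min_score:
            continue
        if tuple(size) == tuple(crop_size):
            new_start = tuple(start)
        else:  # re-snap about the box centre, all-integer arithmetic
            new_start = tuple(s + z // 2 - c // 2
                              for s, z, c in zip(start, size, crop_size))
        boxes.append(DetectionBox(start=new_start, size=tuple(crop_size),
                                  score=score, source="external"))
    return boxes
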