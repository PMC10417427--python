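"""Synthetic liver-lesion phantoms.

Generates 3D grayscale volumes that mimic the statistical structure of a
delayed-phase abdominal MRI lesion dataset: a large ellipsoidal organ on a
dark background, containing ellipsoidal lesions whose in-plane long diameters
span the clinical bins (5-10, 10-30, >30 mm), with controlled lesion/organ
contrast, additive Gaussian noise, and anisotropic voxel spacing (slices much
thicker than the in-plane resolution). Every case carries exact ground truth
(organ mask, per-lesion label map, lesion table), so the full detection and
segmentation pipeline is testable without any external data.

Lesions are axis-aligned ellipsoids with the long axis in-plane and their
centres snapped to voxel centres; at 5 mm slice thickness the long diameter
of a small lesion is an in-plane measurement, so this guarantees that the
specified diameter is recoverable from the voxelised component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import LabelVolume, VolumeGrid, read_labels, read_volume
from .metrics import STRUCT_26

__all__ = ["LesionSpec", "PhantomConfig", "PhantomCase", "PlacementError",
           "generate_case", "generate_cohort", "write_case", "read_case",
           "write_cohort", "read_cohort"]


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed disjointly inside the organ."""


@dataclass(frozen=True)
class LesionSpec:
    diameter_mm: float
    contrast: float          # intensity offset relative to the organ, in [-1, 1]
    class_tag: str = "malignant"

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.contrast == 0 or not -1 <= self.contrast <= 1:
            raise ValueError("contrast must be nonzero and in [-1, 1]")
        if self.class_tag not in ("benign", "malignant"):
            raise ValueError(f"unknown class_tag {self.class_tag!r}")


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic case.

    Defaults emulate a delayed-phase liver MRI crop: near-isotropic in-plane
    resolution with 5 mm slices, an organ filling most of the field of view,
    and moderate additive noise.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 20)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 5.0)
    organ_semiaxes_mm: tuple[float, float, float] = (46.0, 42.0, 45.0)
    organ_intensity: float = 0.5
    background_intensity: float = 0.1
    lesion_specs: tuple[LesionSpec, ...] = ()
    noise_sigma: float = 0.03
    seed: int = 0
    # cohort sampling: exact lesion count per size bin per case, plus a
    # uniform random number of extra lesions in random bins
    lesions_per_bin: dict = field(default_factory=lambda: {"5-10": 1, "10-30": 1, ">30": 1})
    extra_lesions_range: tuple[int, int] = (0, 2)
    contrast_magnitude_range: tuple[float, float] = (0.2, 0.35)

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive reals")
        if any(a <= 0 for a in self.organ_semiaxes_mm):
            raise ValueError("organ semiaxes must be positive")
        for v in (self.organ_intensity, self.background_intensity):
            if not 0 < v < 1:
                raise ValueError("intensities must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)
        if np.any(2 * np.asarray(self.organ_semiaxes_mm) > extent):
            raise ValueError("grid does not physically contain the organ")
        dmax = 2 * min(self.organ_semiaxes_mm)
        for spec in self.lesion_specs:
            if spec.diameter_mm >= dmax:
                raise ValueError(
                    f"lesion diameter {spec.diameter_mm} mm does not fit in organ "
                    f"(needs < {dmax} mm)")


@dataclass
class PhantomCase:
    image: VolumeGrid
    liver_label: LabelVolume
    lesion_label: LabelVolume
    lesion_table: pd.DataFrame  # lesion_id, diameter_mm, class_tag, cx, cy, cz
    seed: int = 0


def _ellipsoid_mask(shape, spacing, center_vox, semiaxes_mm) -> np.ndarray:
    """Boolean mask of voxel centres inside an axis-aligned ellipsoid."""
    coords = [(np.arange(n) - c) * s for n, c, s in zip(shape, center_vox, spacing)]
    terms = [((x / a) ** 2)[sl] for x, a, sl in zip(
        coords, semiaxes_mm,
        [(slice(None), None, None), (None, slice(None), None), (None, None, slice(None))])]
    return terms[0] + terms[1] + terms[2] <= 1.0


def _lesion_semiaxes(diameter_mm: float, rng: np.random.Generator):
    """Semiaxes (mm) with the long axis in-plane and exact max extent."""
    long_axis = int(rng.integers(0, 2))  # x or y
    # tiny epsilon so voxel centres exactly at +-d/2 are included
    a_long = diameter_mm / 2 + 1e-9
    a_short = a_long * rng.uniform(0.75, 1.0)
    # z extent capped: at 5 mm slices large lesions are flatter through-plane
    a_z = min(a_long, 12.5)
    semi = [a_short, a_short, a_z]
    semi[long_axis] = a_long
    return tuple(semi)


def generate_case(config: PhantomConfig) -> PhantomCase:
    """Generate one phantom case; identical config + seed gives identical arrays.

    The image is piecewise constant (background / organ / organ + lesion
    contrast) plus Gaussian noise of sd ``noise_sigma``, clamped to [0, 1].
    Lesions are placed by rejection sampling inside the organ, fully
    contained, pairwise non-touching (>= 1 background voxel apart under
    26-connectivity); failure after 200 retries raises :class:`PlacementError`
    naming the offending lesion.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.grid_shape)
    spacing = config.spacing_mm
    center = tuple((n - 1) / 2 for n in shape)

    organ = _ellipsoid_mask(shape, spacing, center, config.organ_semiaxes_mm)
    image = np.full(shape, config.background_intensity, dtype=np.float32)
    image[organ] = config.organ_intensity

    lesion_label = np.zeros(shape, dtype=np.int16)
    occupied_dilated = np.zeros(shape, dtype=bool)  # existing lesions grown by 1 voxel
    records = []
    # place largest first (ids keep the spec order) to ease disjoint packing
    order = sorted(range(len(config.lesion_specs)),
                   key=lambda j: -config.lesion_specs[j].diameter_mm)
    for j in order:
        i, spec = j + 1, config.lesion_specs[j]
        semi = _lesion_semiaxes(spec.diameter_mm, rng)
        # candidate centres: organ eroded by the lesion semiaxes, so the
        # lesion fits inside the organ by construction (verified below)
        eroded_semi = tuple(max(a - s, 1e-6) for a, s in
                            zip(config.organ_semiaxes_mm, semi))
        feasible = np.argwhere(_ellipsoid_mask(shape, spacing, center, eroded_semi)
                               & organ)
        if len(feasible) == 0:
            raise PlacementError(
                f"lesion {i} (diameter {spec.diameter_mm} mm) cannot fit "
                f"inside the organ")
        placed = False
        for _ in range(200):
            c = tuple(int(v) for v in feasible[int(rng.integers(0, len(feasible)))])
            mask = _ellipsoid_mask(shape, spacing, c, semi)
            if not mask.any():
                continue
            if np.any(mask & ~organ):      # must sit fully inside the organ
                continue
            if np.any(mask & occupied_dilated):  # keep >= 1 voxel gap
                continue
            lesion_label[mask] = i
            image[mask] = config.organ_intensity + spec.contrast
            occupied_dilated |= ndimage.binary_dilation(mask, structure=STRUCT_26)
            records.append({"lesion_id": i, "diameter_mm": spec.diameter_mm,
                            "class_tag": spec.class_tag,
                            "cx": c[0], "cy": c[1], "cz": c[2]})
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place lesion {i} (diameter {spec.diameter_mm} mm, "
                f"class {spec.class_tag}) after 200 retries")

    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, shape).astype(np.float32)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    table = pd.DataFrame(records, columns=["lesion_id", "diameter_mm", "class_tag",
                                           "cx", "cy", "cz"])
    if len(table):
        table = table.sort_values("lesion_id").reset_index(drop=True)
    return PhantomCase(
        image=VolumeGrid(image, spacing),
        liver_label=LabelVolume(organ.astype(np.int16), spacing),
        lesion_label=LabelVolume(lesion_label, spacing),
        lesion_table=table,
        seed=config.seed,
    )


_BIN_DIAMETER_RANGES = {"5-10": (6.0, 9.5), "10-30": (11.0, 28.0), ">30": (31.0, 38.0)}


def _sample_specs(config: PhantomConfig, rng: np.random.Generator) -> tuple[LesionSpec, ...]:
    bins = []
    for b, count in config.lesions_per_bin.items():
        bins.extend([b] * int(count))
    lo, hi = config.extra_lesions_range
    for _ in range(int(rng.integers(lo, hi + 1))):
        bins.append(list(config.lesions_per_bin)[int(rng.integers(0, len(config.lesions_per_bin)))])
    specs = []
    clo, chi = config.contrast_magnitude_range
    for b in bins:
        dlo, dhi = _BIN_DIAMETER_RANGES[b]
        d = float(rng.uniform(dlo, dhi))
        contrast = float(rng.uniform(clo, chi))
        tag = "malignant" if rng.uniform() < 0.55 else "benign"
        specs.append(LesionSpec(d, contrast, tag))
    return tuple(specs)


def generate_cohort(config: PhantomConfig, n_cases: int, seed: int) -> list[PhantomCase]:
    """Generate independent cases with per-case seeds derived from ``seed``.

    When ``config.lesion_specs`` is empty, each case's lesions are sampled
    from ``config.lesions_per_bin`` (exact count per bin) plus
    ``extra_lesions_range`` extras in random bins, with diameters uniform
    within each bin and contrasts from ``contrast_magnitude_range``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    master = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        case_seed = int(master.integers(0, 2**31 - 1))
        case_rng = np.random.default_rng(case_seed)
        specs = config.lesion_specs or _sample_specs(config, case_rng)
        cfg = replace(config, lesion_specs=specs, seed=case_seed)
        cases.append(generate_case(cfg))
    return cases


def write_case(case: PhantomCase, directory) -> dict[str, Path]:
    """Write one case as NIfTI volumes plus a ``lesions.csv`` sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": case.image.save(d / "image.nii.gz"),
        "liver_label": case.liver_label.save(d / "liver_label.nii.gz"),
        "lesion_label": case.lesion_label.save(d / "lesion_label.nii.gz"),
    }
    csv = d / "lesions.csv"
    case.lesion_table.to_csv(csv, index=False)
    paths["lesions"] = csv
    return paths


def read_case(directory) -> PhantomCase:
    d = Path(directory)
    return PhantomCase(
        image=read_volume(d / "image.nii.gz"),
        liver_label=read_labels(d / "liver_label.nii.gz"),
        lesion_label=read_labels(d / "lesion_label.nii.gz"),
        lesion_table=pd.read_csv(d / "lesions.csv"),
    )


def write_cohort(cases: list[PhantomCase], directory) -> Path:
    """Write all cases plus a manifest JSON listing case dirs and seeds."""
    d = Path(directory)
    entries = []
    for i, case in enumerate(cases):
        sub = d / f"case_{i:03d}"
        write_case(case, sub)
        entries.append({"dir": sub.name, "seed": int(case.seed)})
    manifest = d / "manifest.json"
    manifest.write_text(json.dumps({"cases": entries}, indent=2))
    return manifest


def read_cohort(directory) -> list[PhantomCase]:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cases = []
    for entry in manifest["cases"]:
        case = read_case(d / entry["dir"])
        case.seed = int(entry["seed"])
        cases.append(case)
    return cases
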