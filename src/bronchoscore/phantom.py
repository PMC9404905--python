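"""Synthetic lung-CT phantom generator.

Generates 2D slices that structurally mimic axial lung LDCT for testing the
detection-and-scoring chain end to end: two dark elliptical lung fields on a
soft-tissue background, partitioned into lobes by a fixed template; bright
vessel disks; and bronchiectasis lesions drawn as a bright annular airway
wall around a darker lumen with an adjacent vessel disk. Each lesion's
severity class is determined by its lumen-diameter-to-vessel-diameter ratio
through :func:`bronchoscore.score.grade_from_ratio` (1–2x mild, 2–3x
moderate, >3x severe), so the generator's annotations carry exact
ground-truth grades and per-lobe findings.

The phantoms are geometric stand-ins, not anatomically realistic CT: no
fissure anatomy, airway trees, or HU calibration.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import coco
from .ctslice import CTSlice, LobeMask, write_png
from .score import LOBE_SCHEMES, LobeFindings, grade_from_ratio

__all__ = [
    "PhantomSpec",
    "LesionAnnotation",
    "PhantomSample",
    "generate_phantom",
    "write_dataset",
    "load_dataset",
    "lobe_template",
]

# 8-bit intensity model: dark air-filled lung on soft tissue, bright vessels.
BODY_LEVEL = 150.0
LUNG_LEVEL = 40.0
VESSEL_LEVEL = 200.0
LUMEN_LEVEL = 25.0
WALL_THICKNESS_PX = 2.0
VESSEL_OFFSET_LUMEN_DIAMETERS = 1.5  # center-to-center gap, in lumen diameters

#: Severity-class mix used when ratios are not given, matching a screening
#: cohort with mild:moderate:severe roughly 588:566:838.
CLASS_WEIGHTS = np.array([588.0, 566.0, 838.0]) / 1992.0
CLASS_RATIO_RANGES = {1: (1.2, 2.0), 2: (2.05, 3.0), 3: (3.05, 4.0)}

_MAX_PLACEMENT_TRIES = 200


class LesionPlacementError(RuntimeError):
    """Raised when a lesion cannot be placed inside its target lobe."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic slice.

    severity_ratios: per-lesion lumen/vessel diameter ratios (> 1 each);
    None samples ratios from the default class mix. lesion_lobes optionally
    pins each lesion to a lobe id of the layout.
    """

    image_size: int = 256
    lobe_layout: str = "lobes4"
    n_lesions: int = 2
    severity_ratios: list[float] | None = None
    lesion_lobes: list[int] | None = None
    vessel_radius_px: float | None = None  # default scales with image size
    n_distractor_vessels: int = 4
    noise_sigma: float = 2.0
    background_drift: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.lobe_layout not in LOBE_SCHEMES:
            raise ValueError(f"unknown lobe layout {self.lobe_layout!r}")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.vessel_radius_px is None:
            # 4 px at the default 256 grid, proportionally less on small grids
            self.vessel_radius_px = self.image_size / 64.0
        if self.vessel_radius_px <= 0:
            raise ValueError("vessel_radius_px must be positive")
        if self.noise_sigma < 0 or self.background_drift < 0:
            raise ValueError("noise_sigma and background_drift must be >= 0")
        if self.severity_ratios is not None:
            if len(self.severity_ratios) != self.n_lesions:
                raise ValueError("severity_ratios length must equal n_lesions")
            if any(r <= 1.0 for r in self.severity_ratios):
                raise ValueError("severity ratios must exceed 1 (a lesion is dilated)")
        if self.lesion_lobes is not None:
            if len(self.lesion_lobes) != self.n_lesions:
                raise ValueError("lesion_lobes length must equal n_lesions")
            table = LOBE_SCHEMES[self.lobe_layout]
            for lobe in self.lesion_lobes:
                if lobe not in table:
                    raise ValueError(f"lobe id {lobe} not in layout {self.lobe_layout!r}")


@dataclass
class LesionAnnotation:
    """Ground truth for one drawn lesion."""

    bbox: tuple[int, int, int, int]  # x, y, w, h
    mask: np.ndarray  # full-size boolean instance mask (wall + lumen)
    severity_class: int
    lobe_id: int
    ratio: float
    lumen_diameter_px: float
    vessel_diameter_px: float


@dataclass
class PhantomSample:
    """One generated slice with full ground truth."""

    image: CTSlice
    lobe_mask: LobeMask
    annotations: list[LesionAnnotation]
    truth_findings: LobeFindings
    spec: PhantomSpec


def lobe_template(image_size: int, layout: str) -> np.ndarray:
    """Deterministic lobe label image for the given layout.

    Two elliptical lung fields; each lung is split into horizontal bands:
    two per lung for the 4-lobe layout, three per lung (upper / lingula or
    middle / lower) for the six-region layout.
    """
    if layout not in LOBE_SCHEMES:
        raise ValueError(f"unknown lobe layout {layout!r}")
    s = image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy, ay = 0.52 * s, 0.40 * s
    lungs = {}
    for side, cx in (("left", 0.29 * s), ("right", 0.71 * s)):
        ax = 0.185 * s
        lungs[side] = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    labels = np.zeros((s, s), dtype=np.int32)
    if layout == "lobes4":
        split = yy < 0.52 * s
        labels[lungs["left"] & split] = 1
        labels[lungs["left"] & ~split] = 2
        labels[lungs["right"] & split] = 3
        labels[lungs["right"] & ~split] = 4
    else:  # lobes6
        upper = yy < 0.42 * s
        middle = (yy >= 0.42 * s) & (yy < 0.60 * s)
        lower = yy >= 0.60 * s
        labels[lungs["left"] & upper] = 1
        labels[lungs["left"] & middle] = 2  # lingula
        labels[lungs["left"] & lower] = 3
        labels[lungs["right"] & upper] = 4
        labels[lungs["right"] & middle] = 5
        labels[lungs["right"] & lower] = 6
    return labels


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _sample_ratios(spec: PhantomSpec, rng: np.random.Generator) -> list[float]:
    if spec.severity_ratios is not None:
        return list(spec.severity_ratios)
    ratios = []
    for _ in range(spec.n_lesions):
        cls = int(rng.choice([1, 2, 3], p=CLASS_WEIGHTS))
        lo, hi = CLASS_RATIO_RANGES[cls]
        ratios.append(float(rng.uniform(lo, hi)))
    return ratios


def _place_lesion(
    rng: np.random.Generator,
    lobe_mask: np.ndarray,
    lung_mask: np.ndarray,
    occupied: np.ndarray,
    lobe_id: int,
    lumen_radius: float,
    vessel_radius: float,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Rejection-sample a lesion center (inside its lobe) and vessel center."""
    ys, xs = np.nonzero(lobe_mask == lobe_id)
    if ys.size == 0:
        raise LesionPlacementError(f"lobe {lobe_id} is empty in this template")
    outer = lumen_radius + WALL_THICKNESS_PX
    offset = VESSEL_OFFSET_LUMEN_DIAMETERS * 2.0 * lumen_radius
    for _ in range(_MAX_PLACEMENT_TRIES):
        k = int(rng.integers(ys.size))
        cy, cx = float(ys[k]), float(xs[k])
        footprint = _disk(lobe_mask.shape, (cy, cx), outer + 1.0)
        # whole airway cross-section must sit inside its lobe, off other lesions
        if not np.all(lobe_mask[footprint] == lobe_id) or np.any(occupied[footprint]):
            continue
        # several vessel angles per candidate center
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for j in range(8):
            angle = phase + j * np.pi / 4.0
            vy = cy + offset * np.sin(angle)
            vx = cx + offset * np.cos(angle)
            vfoot = _disk(lobe_mask.shape, (vy, vx), vessel_radius + 1.0)
            if np.any(vfoot) and np.all(lung_mask[vfoot]) and not np.any(occupied[vfoot]):
                return (cy, cx), (vy, vx)
    raise LesionPlacementError(
        f"could not place a lesion of lumen radius {lumen_radius:.1f}px "
        f"inside lobe {lobe_id} after {_MAX_PLACEMENT_TRIES} tries"
    )


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one synthetic slice with ground-truth annotations.

    Deterministic for a fixed spec (all randomness from ``spec.seed``). With
    ``noise_sigma == 0`` and ``background_drift == 0`` the image is a pure
    function of the drawn geometry.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    lobe_mask = lobe_template(s, spec.lobe_layout)
    lung_mask = lobe_mask > 0

    image = np.full((s, s), BODY_LEVEL, dtype=np.float64)
    image[lung_mask] = LUNG_LEVEL

    occupied = np.zeros((s, s), dtype=bool)

    # distractor vessels: plain bright disks with no dilated airway
    for _ in range(spec.n_distractor_vessels):
        ys, xs = np.nonzero(lung_mask)
        for _try in range(_MAX_PLACEMENT_TRIES):
            k = int(rng.integers(ys.size))
            cy, cx = float(ys[k]), float(xs[k])
            foot = _disk((s, s), (cy, cx), spec.vessel_radius_px + 1.0)
            if np.all(lung_mask[foot]) and not np.any(occupied[foot]):
                image[_disk((s, s), (cy, cx), spec.vessel_radius_px)] = VESSEL_LEVEL
                occupied |= foot
                break

    ratios = _sample_ratios(spec, rng)
    lobe_ids = list(LOBE_SCHEMES[spec.lobe_layout])
    annotations: list[LesionAnnotation] = []
    for i, ratio in enumerate(ratios):
        lobe_id = (
            spec.lesion_lobes[i]
            if spec.lesion_lobes is not None
            else int(rng.choice(lobe_ids))
        )
        vessel_diameter = 2.0 * spec.vessel_radius_px
        lumen_diameter = ratio * vessel_diameter
        lumen_radius = lumen_diameter / 2.0
        (cy, cx), (vy, vx) = _place_lesion(
            rng, lobe_mask, lung_mask, occupied, lobe_id, lumen_radius, spec.vessel_radius_px
        )
        wall = _disk((s, s), (cy, cx), lumen_radius + WALL_THICKNESS_PX)
        lumen = _disk((s, s), (cy, cx), lumen_radius)
        vessel = _disk((s, s), (vy, vx), spec.vessel_radius_px)
        image[wall] = VESSEL_LEVEL
        image[lumen] = LUMEN_LEVEL
        image[vessel] = VESSEL_LEVEL
        occupied |= wall | vessel
        instance = wall  # airway cross-section: wall ring plus lumen interior
        annotations.append(
            LesionAnnotation(
                bbox=coco.bbox_from_mask(instance),
                mask=instance,
                severity_class=grade_from_ratio(lumen_diameter, vessel_diameter),
                lobe_id=lobe_id,
                ratio=float(ratio),
                lumen_diameter_px=float(lumen_diameter),
                vessel_diameter_px=float(vessel_diameter),
            )
        )

    if spec.background_drift > 0:
        coarse = rng.normal(0.0, 1.0, size=(4, 4))
        drift = ndimage.zoom(coarse, s / 4.0, order=3)[:s, :s]
        drift = drift - drift.mean()
        peak = np.abs(drift).max()
        if peak > 0:
            image = image + spec.background_drift * drift / peak
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(s, s))
    image = np.clip(image, 0.0, 255.0)

    grades: dict[int, int] = {}
    for ann in annotations:
        grades[ann.lobe_id] = max(grades.get(ann.lobe_id, 0), ann.severity_class)
    truth = LobeFindings(grades=grades, scheme=spec.lobe_layout)

    return PhantomSample(
        image=CTSlice(pixels=image, provenance="synthetic"),
        lobe_mask=LobeMask(labels=lobe_mask, lobe_table=LOBE_SCHEMES[spec.lobe_layout]),
        annotations=annotations,
        truth_findings=truth,
        spec=spec,
    )


def write_dataset(samples: list[PhantomSample], out_dir: str | os.PathLike) -> str:
    """Write a phantom dataset: PNG images and masks, COCO JSON, manifest.

    Returns the manifest path. Lobe masks are 8-bit PNGs whose pixel values
    are the lobe ids (0 = background); the manifest records the id table.
    """
    if not samples:
        raise ValueError("write_dataset needs at least one sample")
    out_dir = os.fspath(out_dir)
    os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "masks"), exist_ok=True)

    images_rec, anns_rec = [], []
    manifest: dict = {"samples": [], "annotations": "annotations.json"}
    ann_id = 1
    for idx, sample in enumerate(samples):
        img_name = f"images/img_{idx:04d}.png"
        mask_name = f"masks/mask_{idx:04d}.png"
        write_png(os.path.join(out_dir, img_name), sample.image)
        write_png(os.path.join(out_dir, mask_name), sample.lobe_mask.labels.astype(np.float64))
        h, w = sample.image.shape
        images_rec.append(
            {"id": idx + 1, "file_name": img_name, "width": w, "height": h,
             "seed": sample.spec.seed}
        )
        for ann in sample.annotations:
            anns_rec.append(
                {
                    "id": ann_id,
                    "image_id": idx + 1,
                    "category_id": ann.severity_class,
                    "bbox": list(ann.bbox),
                    "area": int(ann.mask.sum()),
                    "segmentation": coco.rle_encode(ann.mask),
                    "iscrowd": 0,
                    "lobe_id": ann.lobe_id,
                    "ratio": ann.ratio,
                }
            )
            ann_id += 1
        manifest["samples"].append(
            {
                "image": img_name,
                "mask": mask_name,
                "seed": sample.spec.seed,
                "truth_grades": {str(k): v for k, v in sample.truth_findings.grades.items()},
            }
        )
    manifest["layout"] = samples[0].spec.lobe_layout
    manifest["lobe_table"] = {
        str(k): v for k, v in LOBE_SCHEMES[samples[0].spec.lobe_layout].items()
    }
    coco.write_coco(os.path.join(out_dir, "annotations.json"), images_rec, anns_rec)
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def load_dataset(manifest_path: str | os.PathLike) -> list[dict]:
    """Load a written dataset back: image/mask arrays plus COCO annotations.

    Returns one dict per sample with keys image (CTSlice), lobe_mask,
    annotations (COCO records with decoded masks), layout.
    """
    manifest_path = os.fspath(manifest_path)
    root = os.path.dirname(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    doc = coco.read_coco(os.path.join(root, manifest["annotations"]))
    by_image: dict[int, list[dict]] = {}
    for ann in doc["annotations"]:
        by_image.setdefault(ann["image_id"], []).append(ann)

    from .ctslice import read_slice

    out = []
    for idx, rec in enumerate(manifest["samples"]):
        image = read_slice(os.path.join(root, rec["image"]))
        import imageio.v3 as iio

        mask_arr = np.asarray(iio.imread(os.path.join(root, rec["mask"])), dtype=np.int32)
        mask = LobeMask(
            labels=mask_arr,
            lobe_table={int(k): v for k, v in manifest["lobe_table"].items()},
        )
        anns = []
        for ann in by_image.get(idx + 1, []):
            ann = dict(ann)
            ann["mask"] = coco.rle_decode(ann["segmentation"])
            anns.append(ann)
        out.append(
            {"image": image, "lobe_mask": mask, "annotations": anns,
             "layout": manifest["layout"], "seed": rec["seed"]}
        )
    return out
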