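"""Seeded synthetic labelled orthomosaics.

Real reference data for savanna tree-species segmentation are manually
delineated polygons over UAV orthomosaics: a dominant bare-ground/herb
background, strongly imbalanced woody-species classes arranged in patchy
canopies, and class-specific fine-grained (leaf-scale) texture as the main
discriminative signal.  This module generates rasters with that statistical
structure so the whole downstream pipeline (tiling, training, inference,
evaluation, landscape metrics) is testable without any field data.

Patches are elliptical blobs placed by rejection sampling until each class's
pixel budget is met; a pixel keeps the first label painted on it, so masks
are single-label.  Texture is per-class band-passed noise added to the class
base colour.  All randomness flows from one explicit seed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ClassSpec", "SceneSpec", "LabeledScene",
    "generate_scene", "perturb_scene", "empirical_class_proportions",
    "save_scene", "load_scene", "savanna_spec", "three_class_spec",
]


@dataclass(frozen=True)
class ClassSpec:
    """One segmentation class: its share of the scene and its appearance."""

    class_id: int
    name: str
    target_proportion: float
    base_color: tuple = (100, 120, 60)
    texture_scale: float = 3.0       # characteristic granule size, px
    patch_area_mean: float = 2000.0  # mean canopy patch area, px
    elongation: float = 0.3          # 0 = circular patches, 1 = maximally elongated
    is_background: bool = False


@dataclass(frozen=True)
class SceneSpec:
    height_px: int
    width_px: int
    classes: tuple
    gsd_cm: float = 1.2              # ground sampling distance, cm per pixel
    perturbation_strength: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "classes", tuple(self.classes))
        validate_scene_spec(self)


def validate_scene_spec(spec: SceneSpec):
    if spec.height_px < 64 or spec.width_px < 64:
        raise ValueError("scene dimensions must be at least 64 px")
    if spec.gsd_cm <= 0:
        raise ValueError("gsd_cm must be positive")
    ids = [c.class_id for c in spec.classes]
    if len(set(ids)) != len(ids):
        raise ValueError("class_ids must be unique")
    total = sum(c.target_proportion for c in spec.classes)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"target proportions must sum to 1 (got {total:.8f})")
    n_bg = sum(c.is_background for c in spec.classes)
    if n_bg != 1:
        raise ValueError(f"exactly one background class required (got {n_bg})")
    if not 0.0 <= spec.perturbation_strength <= 1.0:
        raise ValueError("perturbation_strength must be in [0, 1]")
    area = spec.height_px * spec.width_px
    for c in spec.classes:
        if not c.is_background and c.target_proportion > 0 and c.patch_area_mean > area:
            raise ValueError(
                f"class {c.class_id}: patch_area_mean {c.patch_area_mean} exceeds "
                f"scene area {area}")


@dataclass
class LabeledScene:
    """RGB raster + integer class mask + class table: the unit of pipeline I/O."""

    image: np.ndarray                 # (H, W, 3) uint8
    mask: np.ndarray                  # (H, W) int
    class_table: list                 # [(class_id, name), ...]
    gsd_cm: float = 1.2
    scene_id: str = ""
    pixel_counts: dict = field(default_factory=dict)  # generator bookkeeping

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions differ")
        known = {cid for cid, _ in self.class_table}
        present = set(np.unique(self.mask).tolist())
        if not present <= known:
            raise ValueError(f"mask contains ids not in class table: {sorted(present - known)}")

    @property
    def shape(self):
        return self.mask.shape


def _ellipse_pixels(center_r, center_c, major, minor, theta, h, w):
    """Pixel coordinates inside a rotated ellipse, clipped to the raster."""
    half = int(np.ceil(major)) + 1
    r0, r1 = max(0, int(center_r) - half), min(h, int(center_r) + half + 1)
    c0, c1 = max(0, int(center_c) - half), min(w, int(center_c) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - center_r, cc - center_c
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    inside = (u / major) ** 2 + (v / minor) ** 2 <= 1.0
    return rr[inside], cc[inside]


def generate_scene(spec: SceneSpec, seed: int) -> LabeledScene:
    """Deterministic synthetic scene for a given (spec, seed).

    Background fills every pixel no other class claims.  Non-background
    classes are painted as elliptical patches until their pixel budget
    (target_proportion x scene area) is met; the final patch of a class is
    truncated at the budget so empirical shares track targets tightly.
    """
    validate_scene_spec(spec)
    rng = np.random.default_rng(seed)
    h, w = spec.height_px, spec.width_px
    background = next(c for c in spec.classes if c.is_background)
    mask = np.full((h, w), background.class_id, dtype=np.int32)
    unclaimed = np.ones((h, w), dtype=bool)
    counts = {}

    for cls in spec.classes:
        if cls.is_background:
            continue
        budget = int(round(cls.target_proportion * h * w))
        painted = 0
        attempts, max_attempts = 0, 200 + 50 * max(1, budget // max(1, int(cls.patch_area_mean)))
        while painted < budget and attempts < max_attempts:
            attempts += 1
            area = rng.gamma(4.0, cls.patch_area_mean / 4.0)
            ratio = max(1e-2, 1.0 - 0.9 * cls.elongation)   # minor/major axis ratio
            major = np.sqrt(area / (np.pi * ratio))
            minor = major * ratio
            cr, cc_ = rng.uniform(0, h), rng.uniform(0, w)
            theta = rng.uniform(0, np.pi)
            rr, cc = _ellipse_pixels(cr, cc_, major, minor, theta, h, w)
            if rr.size == 0:
                continue
            free = unclaimed[rr, cc]
            rr, cc = rr[free], cc[free]
            if rr.size == 0:
                continue
            remaining = budget - painted
            if rr.size > remaining:
                rr, cc = rr[:remaining], cc[:remaining]
            mask[rr, cc] = cls.class_id
            unclaimed[rr, cc] = False
            painted += rr.size
        counts[cls.class_id] = painted
    counts[background.class_id] = int(unclaimed.sum())

    image = _render(mask, spec.classes, rng)
    return LabeledScene(
        image=image, mask=mask,
        class_table=[(c.class_id, c.name) for c in spec.classes],
        gsd_cm=spec.gsd_cm, pixel_counts=counts)


def _bandpass_noise(shape, scale, rng):
    """Zero-mean unit-variance noise band-passed at the given granule size."""
    noise = rng.normal(0.0, 1.0, shape)
    fine = gaussian_filter(noise, sigma=max(scale / 2.0, 0.5))
    coarse = gaussian_filter(noise, sigma=max(scale * 2.0, 1.0))
    band = fine - coarse
    sd = band.std()
    return band / sd if sd > 0 else band


def _render(mask, classes, rng):
    h, w = mask.shape
    image = np.zeros((h, w, 3), dtype=np.float64)
    for cls in classes:
        sel = mask == cls.class_id
        if not sel.any():
            continue
        tex = _bandpass_noise((h, w), cls.texture_scale, rng)
        chroma = rng.normal(0.0, 0.3, 3)  # slight per-channel texture decorrelation
        for ch in range(3):
            layer = cls.base_color[ch] + 28.0 * tex * (1.0 + chroma[ch])
            image[..., ch][sel] = layer[sel]
    return np.clip(np.round(image), 0, 255).astype(np.uint8)


def perturb_scene(scene: LabeledScene, strength: float, seed: int) -> LabeledScene:
    """Class-conditional appearance drift emulating a phenology shift.

    The mask is untouched.  Each class's pixels are shifted along a seeded
    class-specific colour direction (towards mid-grey, so clipping stays
    negligible) by an amount linear in ``strength``, plus extra seeded noise;
    strength 0 is the identity.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    if strength == 0.0:
        return replace(scene, image=scene.image.copy(), mask=scene.mask.copy())
    rng = np.random.default_rng(seed)
    image = scene.image.astype(np.float64)
    for class_id, _ in scene.class_table:
        sel = scene.mask == class_id
        crng = np.random.default_rng([seed, class_id])
        if not sel.any():
            continue
        mean_color = image[sel].mean(axis=0)
        direction = 128.0 - mean_color
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([1.0, 0, 0])
        magnitude = crng.uniform(50.0, 90.0)
        image[sel] += strength * magnitude * direction
    image += rng.normal(0.0, 10.0 * strength, image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return replace(scene, image=image, mask=scene.mask.copy())


def empirical_class_proportions(mask: np.ndarray, class_table) -> np.ndarray:
    """Pixel shares per class, ordered by the class table; sums to 1."""
    ids = [cid for cid, _ in class_table]
    counts = np.bincount(np.asarray(mask).ravel())
    known = set(ids)
    for value in np.nonzero(counts)[0]:
        if int(value) not in known:
            raise ValueError(f"mask contains unknown class id {int(value)}")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty mask")
    out = np.array([counts[i] if i < len(counts) else 0 for i in ids], dtype=np.float64)
    return out / total


# ---------------------------------------------------------------------------
# persistence: image PNG + mask PNG + class-table CSV sidecar

def save_scene(scene: LabeledScene, directory, stem: str):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{stem}_image.png", scene.image)
    if scene.mask.max(initial=0) > 255 or scene.mask.min(initial=0) < 0:
        raise ValueError("mask ids must fit 8-bit PNG storage")
    iio.imwrite(directory / f"{stem}_mask.png", scene.mask.astype(np.uint8))
    with open(directory / f"{stem}_classes.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class_id", "name"])
        for cid, name in scene.class_table:
            writer.writerow([cid, name])
        fh.write(f"# gsd_cm={scene.gsd_cm}\n")


def load_scene(directory, stem: str) -> LabeledScene:
    directory = Path(directory)
    image = np.asarray(iio.imread(directory / f"{stem}_image.png"))
    mask = np.asarray(iio.imread(directory / f"{stem}_mask.png")).astype(np.int32)
    class_table, gsd_cm = [], 1.2
    with open(directory / f"{stem}_classes.csv", newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0] == "class_id":
                continue
            if row[0].startswith("# gsd_cm="):
                gsd_cm = float(row[0].split("=", 1)[1])
                continue
            class_table.append((int(row[0]), row[1]))
    return LabeledScene(image=image, mask=mask, class_table=class_table,
                        gsd_cm=gsd_cm, scene_id=stem)


# ---------------------------------------------------------------------------
# ready-made class compositions

def three_class_spec(height_px=256, width_px=256) -> SceneSpec:
    """Small well-separated composition used by the desk-scale experiment."""
    classes = (
        ClassSpec(0, "bare_ground", 0.60, base_color=(168, 142, 108),
                  texture_scale=2.0, is_background=True),
        ClassSpec(1, "species_a", 0.25, base_color=(58, 110, 48),
                  texture_scale=3.0, patch_area_mean=1200.0, elongation=0.2),
        ClassSpec(2, "species_b", 0.15, base_color=(120, 60, 40),
                  texture_scale=6.0, patch_area_mean=800.0, elongation=0.5),
    )
    return SceneSpec(height_px, width_px, classes)


def savanna_spec(height_px=1024, width_px=1024, n_species=16, seed=0) -> SceneSpec:
    """A 17-class composition with the study system's structure: one dominant
    bare-ground/herb background plus strongly imbalanced woody classes whose
    shares decay geometrically."""
    rng = np.random.default_rng(seed)
    bg_share = 0.55
    raw = 0.72 ** np.arange(n_species)
    shares = (1.0 - bg_share) * raw / raw.sum()
    classes = [ClassSpec(0, "bare_ground_herbs", float(bg_share),
                         base_color=(170, 146, 110), texture_scale=2.0,
                         is_background=True)]
    for i in range(n_species):
        color = (int(rng.integers(30, 90)), int(rng.integers(80, 150)),
                 int(rng.integers(30, 80)))
        classes.append(ClassSpec(
            i + 1, f"species_{i + 1:02d}", float(shares[i]),
            base_color=color,
            texture_scale=float(rng.uniform(1.5, 7.0)),
            patch_area_mean=float(rng.uniform(600.0, 4000.0)),
            elongation=float(rng.uniform(0.1, 0.7))))
    # absorb rounding so proportions sum to exactly 1
    total = sum(c.target_proportion for c in classes)
    classes[0] = replace(classes[0], target_proportion=classes[0].target_proportion + (1.0 - total))
    return SceneSpec(height_px, width_px, tuple(classes))
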