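"""Non-overlapping square tiling and whole-scene train/validation/test splits.

Tiles lie on a grid anchored at the top-left origin; partial rows/columns at
the right and bottom edges are discarded, so the tile count is
floor(H/T) * floor(W/T).  Splits operate at whole-scene granularity only:
spatial separation of training areas from validation and test plots protects
evaluation from spatial autocorrelation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .scenes import LabeledScene

__all__ = ["Tile", "SplitAssignment", "tile_scene", "reassemble",
           "spatial_split", "save_tiles", "load_tiles"]

ROLES = ("train", "validation", "test")


@dataclass
class Tile:
    image: np.ndarray      # (T, T, 3)
    mask: np.ndarray       # (T, T)
    origin_row: int
    origin_col: int
    tile_size: int
    scene_id: str = ""

    def __post_init__(self):
        t = self.tile_size
        if self.image.shape[:2] != (t, t) or self.mask.shape != (t, t):
            raise ValueError("tile rasters must be square of side tile_size")


@dataclass
class SplitAssignment:
    """scene_id -> role mapping with disjoint roles."""

    roles: dict = field(default_factory=dict)

    def scenes(self, role: str):
        return sorted(s for s, r in self.roles.items() if r == role)


def tile_scene(scene: LabeledScene, tile_size: int) -> list:
    """Row-major list of non-overlapping tiles; edge remainders are dropped."""
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    h, w = scene.mask.shape
    n_rows, n_cols = h // tile_size, w // tile_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            f"scene {scene.scene_id or '<unnamed>'} ({h}x{w}) smaller than one "
            f"{tile_size}-px tile; no tiles produced")
        return []
    tiles = []
    for i in range(n_rows):
        for j in range(n_cols):
            r, c = i * tile_size, j * tile_size
            tiles.append(Tile(
                image=scene.image[r:r + tile_size, c:c + tile_size].copy(),
                mask=scene.mask[r:r + tile_size, c:c + tile_size].copy(),
                origin_row=r, origin_col=c, tile_size=tile_size,
                scene_id=scene.scene_id))
    return tiles


def reassemble(tiles, shape=None):
    """Place tiles back at their origins; returns (image, mask) covering the
    cropped extent (or ``shape`` if given)."""
    if not tiles:
        raise ValueError("no tiles to reassemble")
    t = tiles[0].tile_size
    if shape is None:
        h = max(tl.origin_row for tl in tiles) + t
        w = max(tl.origin_col for tl in tiles) + t
    else:
        h, w = shape
    image = np.zeros((h, w, 3), dtype=tiles[0].image.dtype)
    mask = np.zeros((h, w), dtype=tiles[0].mask.dtype)
    for tl in tiles:
        image[tl.origin_row:tl.origin_row + t, tl.origin_col:tl.origin_col + t] = tl.image
        mask[tl.origin_row:tl.origin_row + t, tl.origin_col:tl.origin_col + t] = tl.mask
    return image, mask


def spatial_split(scene_ids, scheme: dict) -> SplitAssignment:
    """Validate a declarative role mapping ``{role: [scene ids]}``.

    Every scene must be assigned exactly one role; a scene appearing under
    two roles is an error.  Empty validation/test roles are allowed with a
    warning (useful for single-scene smoke runs).
    """
    scene_ids = list(scene_ids)
    assignment = {}
    for role, members in scheme.items():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
        for sid in members:
            if sid in assignment:
                raise ValueError(f"scene {sid!r} assigned to both "
                                 f"{assignment[sid]!r} and {role!r}")
            assignment[sid] = role
    missing = [s for s in scene_ids if s not in assignment]
    if missing:
        raise ValueError(f"scenes not covered by the scheme: {missing}")
    extra = [s for s in assignment if s not in scene_ids]
    if extra:
        raise ValueError(f"scheme references unknown scenes: {extra}")
    for role in ("validation", "test"):
        if not any(r == role for r in assignment.values()):
            warnings.warn(f"split has no {role} scenes")
    return SplitAssignment(roles=assignment)


def save_tiles(tiles, directory, role="train"):
    """Persist tiles as paired PNGs plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, tl in enumerate(tiles):
        tid = f"{tl.scene_id or 'scene'}_{tl.origin_row}_{tl.origin_col}"
        iio.imwrite(directory / f"{tid}_img.png", tl.image)
        iio.imwrite(directory / f"{tid}_msk.png", tl.mask.astype(np.uint8))
        rows.append([tid, tl.scene_id, tl.origin_row, tl.origin_col,
                     tl.tile_size, role])
    with open(directory / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tile_id", "scene_id", "origin_row", "origin_col",
                         "tile_size", "role"])
        writer.writerows(rows)
    return directory / "manifest.csv"


def load_tiles(manifest_path) -> list:
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    tiles = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            tid = row["tile_id"]
            tiles.append(Tile(
                image=np.asarray(iio.imread(directory / f"{tid}_img.png")),
                mask=np.asarray(iio.imread(directory / f"{tid}_msk.png")).astype(np.int32),
                origin_row=int(row["origin_row"]),
                origin_col=int(row["origin_col"]),
                tile_size=int(row["tile_size"]),
                scene_id=row["scene_id"]))
    return tiles
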