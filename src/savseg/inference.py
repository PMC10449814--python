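"""Offset-tiled ensemble inference with per-pixel majority voting.

A scene is predicted 16 times, each time on a tile grid shifted by 0, 25, 50
and 75% of the tile size in each axis (4 x 4 offsets).  Before tiling, the
scene is mirror-padded so every offset grid covers every pixel; each pixel
therefore receives one vote per layer, and the final label is the class with
the highest count, ties broken towards the lowest class id.  Voting on hard
labels matches "majority vote" literally; probability averaging is available
as an off-default option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .scenes import LabeledScene

__all__ = ["OffsetPredictionStack", "offset_grid", "predict_offset_stack",
           "majority_vote", "predict_scene", "DEFAULT_FRACTIONS"]

DEFAULT_FRACTIONS = (0.0, 0.25, 0.5, 0.75)


@dataclass
class OffsetPredictionStack:
    layers: list              # [(H, W) int rasters]
    offsets: list             # [(row_offset, col_offset)]
    tile_size: int


def offset_grid(tile_size: int, fractions=DEFAULT_FRACTIONS):
    """Cartesian product of floor(f*T) offsets in row and column."""
    fracs = []
    for f in fractions:
        if not 0.0 <= f < 1.0:
            raise ValueError(f"offset fraction {f} outside [0, 1)")
        if f not in fracs:
            fracs.append(f)
    if len(fracs) < len(list(fractions)):
        warnings.warn("duplicate offset fractions collapsed")
    if 0.0 not in fracs:
        raise ValueError("offset fractions must contain 0")
    steps = sorted(int(np.floor(f * tile_size)) for f in fracs)
    return [(r, c) for r in steps for c in steps]


def _mirror_pad(arr, pad_top, pad_bottom, pad_left, pad_right):
    """Symmetric (edge-mirroring) padding, applied iteratively so pads larger
    than the raster are handled."""
    spatial_pads = [pad_top, pad_bottom, pad_left, pad_right]
    while any(p > 0 for p in spatial_pads):
        h, w = arr.shape[:2]
        step = [min(spatial_pads[0], h), min(spatial_pads[1], h),
                min(spatial_pads[2], w), min(spatial_pads[3], w)]
        widths = [(step[0], step[1]), (step[2], step[3])]
        widths += [(0, 0)] * (arr.ndim - 2)
        arr = np.pad(arr, widths, mode="symmetric")
        spatial_pads = [p - s for p, s in zip(spatial_pads, step)]
    return arr


def predict_offset_stack(model, scene: LabeledScene, tile_size: int,
                         fractions=DEFAULT_FRACTIONS) -> OffsetPredictionStack:
    """One co-registered class-id layer per offset.

    ``model`` needs a ``predict(image) -> mask`` method on (T, T, 3) tiles.
    For each offset the scene is mirror-padded so a full tile grid covers
    every pixel, predicted tile by tile, and cropped back to H x W.
    """
    h, w = scene.shape
    t = tile_size
    offsets = offset_grid(t, fractions)
    layers = []
    for dr, dc in offsets:
        pad_top = (t - dr) % t
        pad_left = (t - dc) % t
        pad_bottom = (-(h + pad_top)) % t
        pad_right = (-(w + pad_left)) % t
        padded = _mirror_pad(scene.image, pad_top, pad_bottom, pad_left, pad_right)
        ph, pw = padded.shape[:2]
        layer = np.empty((ph, pw), dtype=np.int32)
        for r in range(0, ph, t):
            for c in range(0, pw, t):
                layer[r:r + t, c:c + t] = model.predict(padded[r:r + t, c:c + t])
        layers.append(layer[pad_top:pad_top + h, pad_left:pad_left + w])
    return OffsetPredictionStack(layers=layers, offsets=offsets, tile_size=t)


def majority_vote(stack: OffsetPredictionStack) -> np.ndarray:
    """Per-pixel modal class over layers; ties go to the lowest class id."""
    if not stack.layers:
        raise ValueError("empty prediction stack")
    arr = np.stack(stack.layers)
    n_classes = int(arr.max()) + 1
    h, w = arr.shape[1:]
    counts = np.zeros((n_classes, h, w), dtype=np.int32)
    rows, cols = np.ogrid[:h, :w]
    for layer in arr:
        np.add.at(counts, (layer, rows, cols), 1)
    return counts.argmax(axis=0).astype(np.int32)  # argmax takes lowest id on ties


def predict_scene(model, scene: LabeledScene, tile_size: int,
                  fractions=DEFAULT_FRACTIONS, average_probs: bool = False) -> np.ndarray:
    """Full ensemble prediction for a scene: offset stack + majority vote.

    ``average_probs=True`` averages softmax probabilities across layers
    instead of voting on hard labels (requires ``model.predict_probs``).
    """
    if average_probs:
        h, w = scene.shape
        t = tile_size
        acc = None
        for dr, dc in offset_grid(t, fractions):
            pad_top, pad_left = (t - dr) % t, (t - dc) % t
            pad_bottom = (-(h + pad_top)) % t
            pad_right = (-(w + pad_left)) % t
            padded = _mirror_pad(scene.image, pad_top, pad_bottom, pad_left, pad_right)
            ph, pw = padded.shape[:2]
            probs = None
            for r in range(0, ph, t):
                for c in range(0, pw, t):
                    p = model.predict_probs(padded[r:r + t, c:c + t])
                    if probs is None:
                        probs = np.zeros((p.shape[0], ph, pw))
                    probs[:, r:r + t, c:c + t] = p
            cropped = probs[:, pad_top:pad_top + h, pad_left:pad_left + w]
            acc = cropped if acc is None else acc + cropped
        return acc.argmax(axis=0).astype(np.int32)
    return majority_vote(predict_offset_stack(model, scene, tile_size, fractions))
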