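"""Per-class landscape metrics and F1-vs-metric regressions.

For each class the mask is decomposed into patches (maximal connected
components, queen/8-connectivity by default, matching the landscapemetrics
convention).  Reported per class: total area and mean patch area in
hectares, and mean patch compactness

    CIRCLE = 1 - a_patch / a_circle,

where a_circle is the area of the smallest circle enclosing the patch.  The
circle is computed on pixel *corner* points, so a single pixel (a unit
square) has radius sqrt(2)/2 and CIRCLE = 1 - 2/pi.  Compact round patches
approach 0, elongated ones approach 1.

Class F1-scores are regressed on each metric by ordinary least squares; with
16 vegetation classes (background excluded) the slope test has n - 2 = 14
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError

__all__ = ["Patch", "ClassLandscapeMetrics", "label_patches",
           "smallest_circumscribing_circle", "patch_compactness",
           "class_landscape_metrics", "f1_metric_regression"]

_STRUCTURES = {4: ndimage.generate_binary_structure(2, 1),
               8: ndimage.generate_binary_structure(2, 2)}


def _px_to_ha(area_px: float, gsd_cm: float) -> float:
    return area_px * (gsd_cm / 100.0) ** 2 / 10_000.0


@dataclass
class Patch:
    class_id: int
    pixels: np.ndarray      # (n, 2) array of (row, col)
    gsd_cm: float = 1.2

    @property
    def area_px(self) -> int:
        return len(self.pixels)

    @property
    def area_ha(self) -> float:
        return _px_to_ha(self.area_px, self.gsd_cm)


@dataclass
class ClassLandscapeMetrics:
    class_id: int
    name: str
    n_patches: int
    mean_patch_area_ha: float
    total_class_area_ha: float
    mean_compactness: float
    mean_circle_area_ha: float
    is_background: bool = False


def label_patches(mask, class_id: int, connectivity: int = 8,
                  gsd_cm: float = 1.2) -> list:
    """Maximal connected components of one class; absent class -> []."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    binary = np.asarray(mask) == class_id
    labelled, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    patches = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labelled == comp)
        patches.append(Patch(class_id=class_id,
                             pixels=np.column_stack([rows, cols]),
                             gsd_cm=gsd_cm))
    return patches


# ---------------------------------------------------------------------------
# minimal enclosing circle (randomised incremental / Welzl on hull points)

def _circle_two(p, q):
    center = (p + q) / 2.0
    return center, float(np.linalg.norm(p - center))

def _circle_three(p, q, r):
    ax, ay = p; bx, by = q; cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        # collinear: fall back to the widest pair
        pairs = [(p, q), (p, r), (q, r)]
        center, radius = max((_circle_two(a, b) for a, b in pairs),
                             key=lambda cr: cr[1])
        return center, radius
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(p - center))

def _inside(center, radius, p, tol=1e-9):
    return np.linalg.norm(p - center) <= radius * (1.0 + tol) + tol


def _mec(points: np.ndarray):
    """Minimal enclosing circle, expected O(n) incremental construction."""
    pts = points[np.random.default_rng(0).permutation(len(points))]
    center, radius = pts[0].astype(float), 0.0
    for i in range(1, len(pts)):
        if _inside(center, radius, pts[i]):
            continue
        center, radius = pts[i].astype(float), 0.0
        for j in range(i):
            if _inside(center, radius, pts[j]):
                continue
            center, radius = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _inside(center, radius, pts[k]):
                    continue
                center, radius = _circle_three(pts[i], pts[j], pts[k])
    return center, radius


def _corner_points(pixels: np.ndarray) -> np.ndarray:
    """Unique corner points (x=col, y=row convention irrelevant — symmetric)."""
    rows = pixels[:, 0][:, None]
    cols = pixels[:, 1][:, None]
    corners = np.concatenate([
        np.hstack([rows, cols]), np.hstack([rows + 1, cols]),
        np.hstack([rows, cols + 1]), np.hstack([rows + 1, cols + 1])])
    return np.unique(corners, axis=0).astype(np.float64)


def smallest_circumscribing_circle(patch: Patch):
    """(center, radius) of the minimal circle enclosing all pixel squares.

    Computed on pixel corner points, so a single pixel yields radius
    sqrt(2)/2.  Large patches are reduced to their convex hull first.
    """
    if patch.area_px == 0:
        raise ValueError("patch has no pixels")
    corners = _corner_points(patch.pixels)
    if len(corners) > 16:
        try:
            corners = corners[ConvexHull(corners).vertices]
        except QhullError:
            pass  # degenerate (collinear) point sets: use all corners
    center, radius = _mec(corners)
    return center, radius


def patch_compactness(patch: Patch) -> float:
    """CIRCLE metric: 1 - patch area / circumscribing-circle area, in [0, 1)."""
    _, radius = smallest_circumscribing_circle(patch)
    circle_area = np.pi * radius ** 2
    return float(1.0 - patch.area_px / circle_area)


def class_landscape_metrics(mask, class_table, gsd_cm: float = 1.2,
                            connectivity: int = 8,
                            background_id: int | None = None) -> list:
    """Landscape metrics for every class in the table.

    Absent classes are reported with ``n_patches = 0`` and NaN metrics
    (absent, not zero).
    """
    out = []
    for class_id, name in class_table:
        patches = label_patches(mask, class_id, connectivity, gsd_cm)
        if not patches:
            out.append(ClassLandscapeMetrics(
                class_id, name, 0, float("nan"), float("nan"), float("nan"),
                float("nan"), is_background=class_id == background_id))
            continue
        areas = np.array([p.area_ha for p in patches])
        comps, circ_areas = [], []
        for p in patches:
            _, radius = smallest_circumscribing_circle(p)
            circ_areas.append(_px_to_ha(np.pi * radius ** 2, gsd_cm))
            comps.append(1.0 - p.area_px / (np.pi * radius ** 2))
        out.append(ClassLandscapeMetrics(
            class_id, name, len(patches),
            mean_patch_area_ha=float(areas.mean()),
            total_class_area_ha=float(areas.sum()),
            mean_compactness=float(np.mean(comps)),
            mean_circle_area_ha=float(np.mean(circ_areas)),
            is_background=class_id == background_id))
    return out


def f1_metric_regression(metric_values, f1_values):
    """OLS of F1 ~ landscape metric -> (slope, intercept, p_value, df).

    Two-sided p for the slope; df = n - 2.  The background class should be
    excluded by the caller, giving df = 14 for 16 vegetation classes.
    """
    x = np.asarray(metric_values, dtype=np.float64)
    y = np.asarray(f1_values, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("metric and F1 vectors must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need at least 3 classes for a regression")
    if np.allclose(x.std(), 0.0):
        raise ValueError("metric has zero variance; regression undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.pvalue), x.size - 2
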