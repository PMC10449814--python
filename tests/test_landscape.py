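"""Patch labelling, minimal enclosing circles, compactness, regressions."""

import itertools

import numpy as np
import pytest
from scipy import ndimage, stats

from savseg.landscape import (Patch, class_landscape_metrics,
                              f1_metric_regression, label_patches,
                              patch_compactness, smallest_circumscribing_circle)
from savseg.scenes import generate_scene


def _patch(pixels):
    return Patch(class_id=1, pixels=np.asarray(pixels))


def _brute_force_circle(points):
    """Smallest circle through all pairs and triples (oracle, O(n^4))."""
    from savseg.landscape import _circle_three, _circle_two, _inside
    best = None
    pts = [np.asarray(p, float) for p in points]
    for a, b in itertools.combinations(pts, 2):
        c, r = _circle_two(a, b)
        if all(_inside(c, r, p) for p in pts):
            if best is None or r < best[1]:
                best = (c, r)
    if best is not None:
        return best
    for a, b, c3 in itertools.combinations(pts, 3):
        c, r = _circle_three(a, b, c3)
        if all(_inside(c, r, p) for p in pts):
            if best is None or r < best[1]:
                best = (c, r)
    return best


def test_solid_square_is_one_patch():
    mask = np.zeros((5, 5), int)
    mask[1:4, 1:4] = 1
    patches = label_patches(mask, 1)
    assert len(patches) == 1 and patches[0].area_px == 9


def test_diagonal_connectivity_convention():
    mask = np.zeros((4, 4), int)
    mask[1, 1] = mask[2, 2] = 1
    assert len(label_patches(mask, 1, connectivity=8)) == 1
    assert len(label_patches(mask, 1, connectivity=4)) == 2
    with pytest.raises(ValueError):
        label_patches(mask, 1, connectivity=6)


def test_component_count_matches_flood_fill_oracle(rng):
    mask = (rng.random((40, 40)) < 0.35).astype(int)
    patches = label_patches(mask, 1, connectivity=4)

    # independent BFS flood fill
    seen = np.zeros_like(mask, bool)
    n_components = 0
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        n_components += 1
        queue = [(r0, c0)]
        seen[r0, c0] = True
        while queue:
            r, c = queue.pop()
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < 40 and 0 <= cc < 40 and mask[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = True
                    queue.append((rr, cc))
    assert len(patches) == n_components
    assert sum(p.area_px for p in patches) == mask.sum()


def test_absent_class_gives_empty_list():
    assert label_patches(np.zeros((4, 4), int), 9) == []


def test_single_pixel_circle_is_half_diagonal():
    _, radius = smallest_circumscribing_circle(_patch([[0, 0]]))
    assert radius == pytest.approx(np.sqrt(2) / 2, abs=1e-12)


def test_pixel_row_circle_spans_rectangle_diagonal():
    patch = _patch([[0, c] for c in range(10)])  # 1x10 pixel row
    _, radius = smallest_circumscribing_circle(patch)
    assert radius == pytest.approx(np.sqrt(101) / 2, abs=1e-9)


def test_rasterised_disc_radius_recovered():
    rr, cc = np.mgrid[:50, :50]
    inside = (rr - 25) ** 2 + (cc - 25) ** 2 <= 20 ** 2
    patch = _patch(np.column_stack(np.nonzero(inside)))
    _, radius = smallest_circumscribing_circle(patch)
    assert abs(radius - 20) <= 1.0


def test_minimal_circle_matches_brute_force_oracle(rng):
    for _ in range(10):
        pts = rng.integers(0, 12, (rng.integers(2, 9), 2))
        patch = _patch(np.unique(pts, axis=0))
        _, radius = smallest_circumscribing_circle(patch)
        from savseg.landscape import _corner_points
        _, r_oracle = _brute_force_circle(_corner_points(patch.pixels))
        assert radius == pytest.approx(r_oracle, abs=1e-9)


def test_disc_compactness_near_zero():
    rr, cc = np.mgrid[:50, :50]
    inside = (rr - 25) ** 2 + (cc - 25) ** 2 <= 20 ** 2
    patch = _patch(np.column_stack(np.nonzero(inside)))
    assert patch_compactness(patch) <= 0.1


def test_line_compactness_increases_towards_one():
    values = [patch_compactness(_patch([[0, c] for c in range(n)]))
              for n in (2, 5, 10, 40, 100)]
    assert all(b > a for a, b in zip(values, values[1:]))
    assert values[-1] > 0.9


def test_square_compactness_is_one_minus_two_over_pi():
    patch = _patch([[r, c] for r in range(20) for c in range(20)])
    assert patch_compactness(patch) == pytest.approx(1 - 2 / np.pi, abs=1e-9)


def test_compactness_invariant_under_translation_and_rotation(rng):
    pixels = np.column_stack(np.nonzero(rng.random((15, 15)) < 0.4))
    if pixels.size == 0:
        pixels = np.array([[0, 0]])
    base = patch_compactness(_patch(pixels))
    shifted = patch_compactness(_patch(pixels + [7, 3]))
    rotated = patch_compactness(_patch(np.column_stack(
        [pixels[:, 1], 14 - pixels[:, 0]])))  # 90-degree rotation
    assert shifted == pytest.approx(base, abs=1e-9)
    assert rotated == pytest.approx(base, abs=1e-9)


def test_class_metrics_unit_conversion():
    mask = np.zeros((200, 200), int)
    mask[:100, :100] = 1
    metrics = class_landscape_metrics(mask, [(0, "bg"), (1, "a")], gsd_cm=10.0)
    m1 = next(m for m in metrics if m.class_id == 1)
    # 100x100 px at 10 cm -> 100 m^2 -> 0.01 ha
    assert m1.total_class_area_ha == pytest.approx(0.01, abs=1e-12)
    assert m1.n_patches == 1


def test_two_equal_patches_mean_is_half_total():
    mask = np.zeros((30, 30), int)
    mask[2:7, 2:7] = 1
    mask[20:25, 20:25] = 1
    m1 = next(m for m in class_landscape_metrics(mask, [(0, "bg"), (1, "a")])
              if m.class_id == 1)
    assert m1.mean_patch_area_ha == pytest.approx(m1.total_class_area_ha / 2)


def test_totals_match_generator_pixel_ledger(four_class_spec):
    scene = generate_scene(four_class_spec, seed=8)
    gsd = scene.gsd_cm
    for m in class_landscape_metrics(scene.mask, scene.class_table, gsd_cm=gsd):
        expected_px = scene.pixel_counts[m.class_id]
        if m.n_patches == 0:
            assert expected_px == 0
            continue
        observed_px = m.total_class_area_ha * 1e4 / (gsd / 100) ** 2
        assert abs(observed_px - expected_px) <= 1.0


def test_total_area_conservation(small_scene):
    metrics = class_landscape_metrics(small_scene.mask, small_scene.class_table,
                                      gsd_cm=small_scene.gsd_cm)
    total = sum(m.total_class_area_ha for m in metrics if m.n_patches > 0)
    h, w = small_scene.mask.shape
    scene_ha = h * w * (small_scene.gsd_cm / 100) ** 2 / 1e4
    assert total == pytest.approx(scene_ha, rel=1e-12)


def test_absent_class_reported_as_absent_not_zero():
    metrics = class_landscape_metrics(np.zeros((8, 8), int), [(0, "bg"), (4, "x")])
    m4 = next(m for m in metrics if m.class_id == 4)
    assert m4.n_patches == 0 and np.isnan(m4.total_class_area_ha)


def test_regression_exact_linear_relationship():
    metric = np.arange(1.0, 17.0)
    slope, intercept, p, df = f1_metric_regression(metric, 2.0 * metric)
    assert slope == pytest.approx(2.0, abs=1e-12)
    assert intercept == pytest.approx(0.0, abs=1e-9)
    assert p < 1e-12 and df == 14


def test_regression_constant_metric_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        f1_metric_regression(np.full(16, 3.0), np.arange(16.0))


def test_regression_recovers_injected_slope_within_ci(rng):
    metric = rng.uniform(0.0, 2.0, 16)
    f1 = 0.3 + 0.25 * metric + rng.normal(0, 0.05, 16)
    slope, intercept, p, df = f1_metric_regression(metric, f1)
    assert df == 14
    fit = stats.linregress(metric, f1)  # closed-form OLS oracle
    assert slope == pytest.approx(fit.slope, abs=1e-12)
    half_width = stats.t.ppf(0.975, df) * fit.stderr
    assert abs(slope - 0.25) <= half_width
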