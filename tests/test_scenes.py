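"""Synthetic-scene generator: composition, determinism, perturbation, I/O."""

import numpy as np
import pytest

from savseg.scenes import (ClassSpec, SceneSpec, empirical_class_proportions,
                           generate_scene, load_scene, perturb_scene,
                           save_scene, savanna_spec, three_class_spec)


def test_single_background_class_gives_constant_mask():
    spec = SceneSpec(64, 64, (ClassSpec(3, "bg", 1.0, is_background=True),))
    scene = generate_scene(spec, seed=0)
    assert (scene.mask == 3).all()


def test_generation_is_deterministic(four_class_spec):
    a = generate_scene(four_class_spec, seed=11)
    b = generate_scene(four_class_spec, seed=11)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask, b.mask)
    c = generate_scene(four_class_spec, seed=12)
    assert not np.array_equal(a.mask, c.mask)


def test_empirical_proportions_match_targets_on_large_scene():
    spec = SceneSpec(2048, 2048, (
        ClassSpec(0, "bg", 0.70, base_color=(170, 150, 110), is_background=True),
        ClassSpec(1, "a", 0.15, base_color=(60, 110, 50)),
        ClassSpec(2, "b", 0.10, base_color=(120, 60, 40)),
        ClassSpec(3, "c", 0.05, base_color=(40, 80, 90)),
    ))
    scene = generate_scene(spec, seed=3)
    # oracle: exhaustive pixel count of the returned mask
    counts = np.array([(scene.mask == k).sum() for k in range(4)])
    props = counts / counts.sum()
    assert np.abs(props - [0.70, 0.15, 0.10, 0.05]).max() <= 0.03
    np.testing.assert_allclose(
        props, empirical_class_proportions(scene.mask, scene.class_table), atol=1e-12)


def test_background_has_largest_share(small_scene):
    props = empirical_class_proportions(small_scene.mask, small_scene.class_table)
    assert props.sum() == pytest.approx(1.0, abs=1e-9)
    assert props[0] == props.max()  # background target share is largest


def test_proportions_brute_force_oracle(rng):
    mask = rng.integers(0, 3, (64, 64))
    table = [(0, "a"), (1, "b"), (2, "c")]
    tally = np.zeros(3)
    for r in range(64):
        for c in range(64):
            tally[mask[r, c]] += 1
    np.testing.assert_array_equal(
        empirical_class_proportions(mask, table), tally / tally.sum())


def test_proportions_reject_unknown_id():
    with pytest.raises(ValueError, match="7"):
        empirical_class_proportions(np.array([[0, 7]]), [(0, "a")])


def test_spec_validation_errors():
    with pytest.raises(ValueError, match="sum to 1"):
        SceneSpec(64, 64, (ClassSpec(0, "bg", 0.8, is_background=True),
                           ClassSpec(1, "a", 0.1)))
    with pytest.raises(ValueError, match="background"):
        SceneSpec(64, 64, (ClassSpec(0, "a", 0.5), ClassSpec(1, "b", 0.5)))
    with pytest.raises(ValueError, match="unique"):
        SceneSpec(64, 64, (ClassSpec(0, "bg", 0.5, is_background=True),
                           ClassSpec(0, "a", 0.5)))
    with pytest.raises(ValueError, match="patch_area_mean"):
        SceneSpec(64, 64, (ClassSpec(0, "bg", 0.5, is_background=True),
                           ClassSpec(1, "a", 0.5, patch_area_mean=1e6)))


def test_perturbation_identity_and_determinism(small_scene):
    zero = perturb_scene(small_scene, 0.0, seed=5)
    assert np.array_equal(zero.image, small_scene.image)
    a = perturb_scene(small_scene, 1.0, seed=5)
    b = perturb_scene(small_scene, 1.0, seed=5)
    assert np.array_equal(a.image, b.image)
    assert not np.array_equal(a.image, small_scene.image)


def test_perturbation_never_touches_mask(small_scene):
    for strength in (0.0, 0.3, 1.0):
        out = perturb_scene(small_scene, strength, seed=9)
        assert np.array_equal(out.mask, small_scene.mask)


def test_perturbation_color_shift_monotone_in_strength(small_scene):
    # oracle: per-class mean-RGB difference by direct pixel averaging
    def class_shift(strength):
        out = perturb_scene(small_scene, strength, seed=2)
        shifts = []
        for cid, _ in small_scene.class_table:
            sel = small_scene.mask == cid
            d = (out.image[sel].astype(float).mean(axis=0)
                 - small_scene.image[sel].astype(float).mean(axis=0))
            shifts.append(np.linalg.norm(d))
        return np.array(shifts)

    s0, s05, s1 = class_shift(0.0), class_shift(0.5), class_shift(1.0)
    assert (s0 <= s05 + 1e-9).all()
    assert (s05 <= s1 + 1e-9).all()


def test_perturbation_rejects_out_of_range(small_scene):
    with pytest.raises(ValueError):
        perturb_scene(small_scene, 1.5, seed=0)


def test_scene_io_roundtrip(tmp_path, small_scene):
    save_scene(small_scene, tmp_path, "s0")
    back = load_scene(tmp_path, "s0")
    assert np.array_equal(back.mask, small_scene.mask)  # lossless mask
    assert np.array_equal(back.image, small_scene.image)
    assert back.class_table == small_scene.class_table
    assert back.gsd_cm == small_scene.gsd_cm


def test_savanna_composition_matches_study_structure():
    spec = savanna_spec(128, 128)
    assert len(spec.classes) == 17
    shares = [c.target_proportion for c in spec.classes]
    assert abs(sum(shares) - 1.0) < 1e-9
    assert spec.classes[0].is_background and shares[0] == max(shares)
    assert spec.gsd_cm == pytest.approx(1.2)
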