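"""Offset grid enumeration, stacked prediction geometry, and majority vote."""

import numpy as np
import pytest

from savseg.inference import (majority_vote, offset_grid, OffsetPredictionStack,
                              predict_offset_stack, predict_scene)
from savseg.scenes import LabeledScene


class ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, image):
        return np.full(image.shape[:2], self.value, dtype=np.int32)


class OriginParityModel:
    """Labels every tile with the parity of its top-left pixel value."""

    def predict(self, image):
        return np.full(image.shape[:2], int(image[0, 0, 0]) % 2, dtype=np.int32)


def _scene(h, w, seed=0):
    rng = np.random.default_rng(seed)
    return LabeledScene(image=rng.integers(0, 256, (h, w, 3), dtype=np.uint8),
                        mask=np.zeros((h, w), dtype=np.int32),
                        class_table=[(0, "a"), (1, "b")])


def test_default_offset_grid_has_16_layers():
    offsets = offset_grid(512)
    assert len(offsets) == 16
    assert (0, 0) in offsets and (128, 384) in offsets and (384, 384) in offsets


def test_offset_grid_trivial_and_small_cases():
    assert offset_grid(512, (0.0,)) == [(0, 0)]
    assert set(offset_grid(100, (0.0, 0.5))) == {(0, 0), (0, 50), (50, 0), (50, 50)}


def test_offset_grid_validation():
    with pytest.warns(UserWarning, match="duplicate"):
        offsets = offset_grid(100, (0.0, 0.5, 0.5))
    assert len(offsets) == 4
    with pytest.raises(ValueError):
        offset_grid(100, (0.25, 0.5))  # zero offset missing
    with pytest.raises(ValueError):
        offset_grid(100, (0.0, 1.5))


def test_constant_model_gives_constant_layers():
    scene = _scene(40, 56)
    stack = predict_offset_stack(ConstantModel(1), scene, 16)
    assert len(stack.layers) == 16
    for layer in stack.layers:
        assert layer.shape == scene.shape
        assert (layer == 1).all()


def test_single_tile_scene_zero_offset_equals_direct_prediction():
    scene = _scene(32, 32)
    model = ConstantModel(0)
    stack = predict_offset_stack(model, scene, 32, fractions=(0.0,))
    assert np.array_equal(stack.layers[0], model.predict(scene.image))


def test_stack_geometry_matches_tile_origin_simulation():
    # oracle: re-enumerate padded tile origins and paint the expected parity
    scene = _scene(48, 48, seed=2)
    t = 16
    model = OriginParityModel()
    stack = predict_offset_stack(model, scene, t, fractions=(0.0, 0.5))
    for (dr, dc), layer in zip(stack.offsets, stack.layers):
        pad_top, pad_left = (t - dr) % t, (t - dc) % t
        padded = np.pad(scene.image, ((pad_top, (-(48 + pad_top)) % t),
                                      (pad_left, (-(48 + pad_left)) % t), (0, 0)),
                        mode="symmetric")
        expected = np.empty(padded.shape[:2], dtype=np.int32)
        for r in range(0, padded.shape[0], t):
            for c in range(0, padded.shape[1], t):
                expected[r:r + t, c:c + t] = int(padded[r, c, 0]) % 2
        assert np.array_equal(layer, expected[pad_top:pad_top + 48,
                                              pad_left:pad_left + 48])


def test_every_layer_pixel_is_a_valid_class_id():
    scene = _scene(50, 70, seed=3)
    stack = predict_offset_stack(OriginParityModel(), scene, 16)
    for layer in stack.layers:
        assert set(np.unique(layer)) <= {0, 1}


def test_majority_vote_identical_layers():
    layer = np.arange(12).reshape(3, 4) % 3
    stack = OffsetPredictionStack(layers=[layer] * 5, offsets=[(0, 0)] * 5,
                                  tile_size=4)
    assert np.array_equal(majority_vote(stack), layer)


def test_majority_vote_nine_vs_seven():
    layers = [np.full((2, 2), 2, dtype=np.int32)] * 9 + \
             [np.full((2, 2), 5, dtype=np.int32)] * 7
    stack = OffsetPredictionStack(layers=layers, offsets=[(0, 0)] * 16, tile_size=2)
    assert (majority_vote(stack) == 2).all()


def test_majority_vote_tie_breaks_to_lowest_id():
    layers = [np.full((2, 2), 3, dtype=np.int32)] * 8 + \
             [np.full((2, 2), 1, dtype=np.int32)] * 8
    stack = OffsetPredictionStack(layers=layers, offsets=[(0, 0)] * 16, tile_size=2)
    assert (majority_vote(stack) == 1).all()


def test_majority_vote_matches_histogram_oracle(rng):
    layers = [rng.integers(0, 4, (8, 9)).astype(np.int32) for _ in range(16)]
    stack = OffsetPredictionStack(layers=layers, offsets=[(0, 0)] * 16, tile_size=4)
    voted = majority_vote(stack)
    arr = np.stack(layers)
    for r in range(8):
        for c in range(9):
            counts = np.bincount(arr[:, r, c], minlength=4)
            assert voted[r, c] == counts.argmax()  # argmax = lowest id on ties


def test_vote_invariant_to_layer_order(rng):
    layers = [rng.integers(0, 3, (6, 6)).astype(np.int32) for _ in range(7)]
    a = OffsetPredictionStack(layers=layers, offsets=[(0, 0)] * 7, tile_size=3)
    b = OffsetPredictionStack(layers=layers[::-1], offsets=[(0, 0)] * 7, tile_size=3)
    assert np.array_equal(majority_vote(a), majority_vote(b))


def test_empty_stack_rejected():
    with pytest.raises(ValueError):
        majority_vote(OffsetPredictionStack(layers=[], offsets=[], tile_size=4))


def test_predict_scene_constant_model_end_to_end():
    scene = _scene(40, 40)
    assert (predict_scene(ConstantModel(1), scene, 16) == 1).all()
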