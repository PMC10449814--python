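"""On-the-fly label-consistent augmentation.

The operation set and parameter ranges follow the training protocol for the
UAV orthomosaic study system: random horizontal flip, rotation within
±0.35 rad, scaling by factors in [0.9, 1.1], brightness changes up to ±25%,
contrast changes of 50–200%, and saturation changes of 60–175%.  Geometric
operations are applied identically to image and mask (mask resampled
nearest-neighbour, image bilinear); photometric operations touch the image
only.  Brightness is multiplicative, contrast scales the deviation from the
image mean, and saturation scales the S channel in HSV space — the
conventional readings of "% change"; each is applied only when its drawn
factor differs from the identity, so degenerate ranges are bit-exact no-ops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

__all__ = ["AugmentParams", "augment_pair"]


@dataclass(frozen=True)
class AugmentParams:
    p_hflip: float = 0.5
    rot_range_rad: float = 0.35
    scale_range: tuple = (0.9, 1.1)
    brightness_delta: float = 0.25
    contrast_range: tuple = (0.5, 2.0)
    saturation_range: tuple = (0.6, 1.75)

    def __post_init__(self):
        if not 0.0 <= self.p_hflip <= 1.0:
            raise ValueError("p_hflip must be a probability")
        if self.rot_range_rad < 0 or self.brightness_delta < 0:
            raise ValueError("ranges must be non-negative")
        for lo, hi in (self.scale_range, self.contrast_range, self.saturation_range):
            if hi < lo:
                raise ValueError("interval upper bound below lower bound")


IDENTITY = AugmentParams(p_hflip=0.0, rot_range_rad=0.0, scale_range=(1.0, 1.0),
                         brightness_delta=0.0, contrast_range=(1.0, 1.0),
                         saturation_range=(1.0, 1.0))


def _rotate_scale(image, mask, angle, scale):
    """Joint rotation+scale about the raster centre, output dims unchanged."""
    h, w = mask.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    ct, st = np.cos(angle), np.sin(angle)
    # inverse map: output pixel y -> input pixel A @ y + offset
    a = np.array([[ct, -st], [st, ct]]) / scale
    offset = center - a @ center
    img_out = np.empty_like(image)
    for ch in range(image.shape[2]):
        img_out[..., ch] = ndimage.affine_transform(
            image[..., ch].astype(np.float64), a, offset=offset, order=1,
            mode="reflect", output_shape=(h, w))
    mask_out = ndimage.affine_transform(
        mask, a, offset=offset, order=0, mode="nearest", output_shape=(h, w))
    return img_out, mask_out


def augment_pair(image: np.ndarray, mask: np.ndarray, params: AugmentParams,
                 seed) -> tuple:
    """Augment a co-registered (image, mask) tile pair.

    Order: flip -> rotate -> scale -> brightness -> contrast -> saturation.
    ``seed`` may be an int or a numpy Generator; fixed (inputs, params, seed)
    give bit-identical outputs.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} "
                         "are not co-registered")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # draw every factor up front so the random stream is independent of which
    # operations turn out to be identities
    do_flip = rng.random() < params.p_hflip
    angle = rng.uniform(-params.rot_range_rad, params.rot_range_rad)
    scale = rng.uniform(*params.scale_range)
    brightness = rng.uniform(1.0 - params.brightness_delta, 1.0 + params.brightness_delta)
    contrast = rng.uniform(*params.contrast_range)
    saturation = rng.uniform(*params.saturation_range)

    img, msk = image, mask
    if do_flip:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if angle != 0.0 or scale != 1.0:
        imgf, msk = _rotate_scale(img.astype(np.float64), msk, angle, scale)
    else:
        imgf = img.astype(np.float64)
    photometric = (brightness != 1.0 or contrast != 1.0 or saturation != 1.0)
    if brightness != 1.0:
        imgf = imgf * brightness
    if contrast != 1.0:
        imgf = imgf.mean() + contrast * (imgf - imgf.mean())
    if saturation != 1.0:
        hsv = rgb2hsv(np.clip(imgf, 0, 255) / 255.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * saturation, 0.0, 1.0)
        imgf = hsv2rgb(hsv) * 255.0
    if angle == 0.0 and scale == 1.0 and not photometric:
        out_img = np.ascontiguousarray(img)  # bit-exact identity path
    else:
        out_img = np.clip(np.round(imgf), 0, 255).astype(image.dtype)
    return out_img, np.ascontiguousarray(msk)
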