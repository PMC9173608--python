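"""Perceptual tone: HSV saturation and lightness moments over the mask."""

from __future__ import annotations

import numpy as np
from skimage import color as skcolor

from reefscore.image import MaskedImage


def tone_features(img: MaskedImage) -> dict[str, float]:
    """Means and population SDs of the HSV S and V channels on organism pixels.

    The V channel serves as the lightness measure.
    """
    hsv = skcolor.rgb2hsv(img.masked_pixels()[None, :, :])[0]
    s, v = hsv[:, 1], hsv[:, 2]
    return {
        "mean_saturation": float(s.mean()),
        "sd_saturation": float(s.std()),
        "mean_lightness": float(v.mean()),
        "sd_lightness": float(v.std()),
    }
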