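"""Masked raster images: the unit every image-facing stage operates on."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image

# Background pixels at least this bright (per channel, 8-bit) are treated as
# white background when auto-masking.
WHITE_THRESHOLD = 250


@dataclasses.dataclass
class MaskedImage:
    """An RGB raster plus a boolean organism mask.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), float in [0, 1]
        Row-major, origin top-left.
    mask : ndarray, shape (H, W), bool
        True on organism pixels. Must contain at least one True pixel.
    """

    pixels: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must match pixel raster")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixels must be finite")
        if not self.mask.any():
            raise ValueError("mask must contain at least one organism pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def masked_pixels(self) -> np.ndarray:
        """Return the (N, 3) array of organism pixel colors."""
        return self.pixels[self.mask]

    # ------------------------------------------------------------------ I/O

    def save(self, image_path: str | Path, mask_path: str | Path | None = None) -> None:
        """Write the image (and optionally the 0/255 mask) as PNG."""
        arr = np.clip(np.rint(self.pixels * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(image_path)
        if mask_path is not None:
            Image.fromarray(self.mask.astype(np.uint8) * 255, mode="L").save(mask_path)

    @classmethod
    def load(cls, image_path: str | Path, mask_path: str | Path | None = None) -> "MaskedImage":
        """Read a PNG image plus mask; auto-mask white background if no mask given."""
        arr = np.asarray(Image.open(image_path).convert("RGB"))
        pixels = arr.astype(float) / 255.0
        if mask_path is not None:
            m = np.asarray(Image.open(mask_path).convert("L"))
            mask = m >= 128
        else:
            mask = ~np.all(arr >= WHITE_THRESHOLD, axis=2)
        return cls(pixels=pixels, mask=mask)
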