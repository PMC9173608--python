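"""Procedural organism images with known feature ground truth.

The body is a superellipse (default exponent 2, i.e. an ellipse) with
optional triangular fins; stripes are vertical bands alternating palette
colors inside the body. All drawing is deterministic given the spec, so
pixel-level reproducibility holds by construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import color as skcolor
from skimage import draw as skdraw

from reefscore.image import MaskedImage


class SizingError(ValueError):
    """Canvas too small to hold the body at the requested aspect ratio."""


FIN_PROFILES = ("none", "caudal_only", "full")

# Body half-length and caudal fin length as fractions of the canvas side.
_BODY_FRAC = 0.32
_CAUDAL_FRAC = 0.16


@dataclasses.dataclass
class FishSpec:
    """Parameters of one procedural organism image.

    body_aspect : major/minor axis ratio of the body superellipse, >= 1
    n_stripes : number of stripe bands of the secondary palette colors
    palette : list of RGB triples in [0, 1]; palette[0] is the base color
    saturation_scale : multiplier applied to the HSV S channel
    lightness_contrast : amplitude of a vertical HSV V gradient in [0, 1]
    fin_profile : one of 'none', 'caudal_only', 'full'
    canvas_px : square canvas side in pixels
    superellipse_exponent : body outline exponent (2 = ellipse)
    seed : drives the optional stripe-color randomization; rendering is
        fully deterministic given the spec (seed included)
    """

    body_aspect: float = 2.0
    n_stripes: int = 0
    palette: tuple = ((0.9, 0.5, 0.1),)
    saturation_scale: float = 1.0
    lightness_contrast: float = 0.0
    fin_profile: str = "caudal_only"
    canvas_px: int = 500
    superellipse_exponent: float = 2.0
    waviness: float = 0.0  # radial outline modulation amplitude in [0, 0.3]
    wave_lobes: int = 8
    stripe_waviness: float = 0.0  # stripe-edge lateral modulation in [0, 1]
    stripe_wave_periods: int = 3
    stripe_width_frac: float = 0.5  # stripe share of each stripe cell, (0, 1)
    randomize_stripe_colors: bool = False  # draw stripe colors with rng(seed)
    randomize_stripe_widths: bool = False  # per-stripe width fractions, rng(seed)
    stripe_total_frac: float | None = None  # pin the mean width fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_aspect < 1:
            raise ValueError("body_aspect must be >= 1")
        if self.n_stripes < 0:
            raise ValueError("n_stripes must be >= 0")
        if len(self.palette) == 0:
            raise ValueError("palette must be non-empty")
        if not (0 <= self.saturation_scale <= 1):
            raise ValueError("saturation_scale must lie in [0, 1]")
        if not (0 <= self.lightness_contrast <= 1):
            raise ValueError("lightness_contrast must lie in [0, 1]")
        if self.fin_profile not in FIN_PROFILES:
            raise ValueError(f"fin_profile must be one of {FIN_PROFILES}")
        if not (0 <= self.waviness <= 0.3):
            raise ValueError("waviness must lie in [0, 0.3]")
        if not (0 <= self.stripe_waviness <= 1):
            raise ValueError("stripe_waviness must lie in [0, 1]")
        if not (0 < self.stripe_width_frac < 1):
            raise ValueError("stripe_width_frac must lie in (0, 1)")
        if self.canvas_px < 16:
            raise SizingError("canvas must be at least 16 px")


def _body_geometry(spec: FishSpec) -> tuple[float, float, float, float]:
    """Return (cx, cy, a, b): body center and semi-axes in pixels."""
    n = spec.canvas_px
    a = _BODY_FRAC * n
    b = a / spec.body_aspect
    if b < 1.5:
        raise SizingError(
            f"canvas {n} px cannot hold a body at aspect {spec.body_aspect}: "
            f"minor semi-axis would be {b:.2f} px"
        )
    cx = 0.5 * n if spec.fin_profile == "none" else 0.42 * n
    cy = 0.5 * n
    return cx, cy, a, b


def _body_mask(spec: FishSpec) -> np.ndarray:
    """Superellipse body in polar form, optionally with a scalloped outline.

    The radial modulation (waviness) perturbs the boundary without
    materially changing the region's second-moment axis ratio.
    """
    cx, cy, a, b = _body_geometry(spec)
    n = spec.canvas_px
    yy, xx = np.mgrid[0:n, 0:n]
    dx, dy = xx - cx, yy - cy
    theta = np.arctan2(dy, dx)
    p = spec.superellipse_exponent
    radius = (np.abs(np.cos(theta) / a) ** p + np.abs(np.sin(theta) / b) ** p) ** (
        -1.0 / p
    )
    if spec.waviness > 0:
        radius = radius * (1.0 + spec.waviness * np.sin(spec.wave_lobes * theta))
    return np.hypot(dx, dy) <= radius


def _fin_mask(spec: FishSpec) -> np.ndarray:
    n = spec.canvas_px
    out = np.zeros((n, n), dtype=bool)
    if spec.fin_profile == "none":
        return out
    cx, cy, a, b = _body_geometry(spec)
    fin_len = _CAUDAL_FRAC * n
    # Caudal fin: triangle pointing left, attached near the body's right tip.
    tip_x = cx + 0.85 * a  # deep attach keeps fins connected under waviness
    half_h = max(0.8 * b, 3.0)
    rr, cc = skdraw.polygon(
        [cy, cy - half_h, cy + half_h],
        [tip_x, tip_x + fin_len, tip_x + fin_len],
        shape=out.shape,
    )
    out[rr, cc] = True
    if spec.fin_profile == "full":
        # Dorsal and anal fins: shallow triangles at mid-body.
        fh = max(0.5 * b, 3.0)
        for sign in (-1, 1):
            base_y = cy + sign * 0.8 * b
            rr, cc = skdraw.polygon(
                [base_y, base_y + sign * fh, base_y],
                [cx - 0.5 * a, cx, cx + 0.5 * a],
                shape=out.shape,
            )
            out[rr, cc] = True
    return out


def _stripe_bands(spec: FishSpec, body: np.ndarray):
    """Yield (stripe_index, band_mask) for each stripe inside the body.

    Band edges are vertical by default; ``stripe_waviness`` displaces them
    sinusoidally along the body height (each edge with its own phase),
    which roughens the inter-patch boundaries without disconnecting bands.
    """
    if spec.n_stripes == 0 or len(spec.palette) < 2:
        return
    cx, cy, a, b = _body_geometry(spec)
    n = spec.canvas_px
    # one cell per stripe across the body; the stripe occupies a centered
    # sub-band of each cell, so color proportions vary with the width
    # fraction at a fixed boundary count
    cell_w = 2.0 * a / (spec.n_stripes + 1)
    if spec.randomize_stripe_widths:
        width_rng = np.random.default_rng(spec.seed + 1)
        fracs = width_rng.uniform(0.15, 0.85, size=spec.n_stripes)
        if spec.stripe_total_frac is not None:
            # redistribute widths while pinning their mean, so color
            # proportions vary at a fixed overall stripe coverage
            fracs = np.clip(fracs * spec.stripe_total_frac / fracs.mean(), 0.05, 0.92)
    else:
        fracs = np.full(spec.n_stripes, spec.stripe_width_frac)
    yy, xx = np.mgrid[0:n, 0:n]
    for i in range(spec.n_stripes):
        seg_w = cell_w * fracs[i]
        center = cx - a + (i + 1) * cell_w
        lo, hi = center - seg_w / 2.0, center + seg_w / 2.0
        if spec.stripe_waviness > 0:
            phase = 2.39996 * i  # golden angle decorrelates edges
            shift = (
                spec.stripe_waviness
                * (seg_w / 2.0)
                * np.sin(
                    2.0 * np.pi * spec.stripe_wave_periods * (yy - cy) / (2.0 * b)
                    + phase
                )
            )
        else:
            shift = 0.0
        yield i, body & (xx >= lo + shift) & (xx < hi + shift)


def generate_fish_image(spec: FishSpec) -> MaskedImage:
    """Render the spec to a masked image on an exactly white background.

    The mask is the union of the body superellipse and fins. When
    ``n_stripes > 0`` and the palette has at least two colors, the body's
    horizontal extent is split into ``2 * n_stripes + 1`` equal segments
    and the odd segments are painted with the secondary palette colors
    (cycled), producing exactly ``n_stripes`` stripe bands.
    """
    n = spec.canvas_px
    body = _body_mask(spec)
    fins = _fin_mask(spec)
    mask = body | fins

    palette = np.asarray(spec.palette, dtype=float)
    pixels = np.ones((n, n, 3), dtype=float)
    pixels[mask] = palette[0]

    stripe_colors = palette[1:]
    if len(stripe_colors) > 0:
        if spec.randomize_stripe_colors:
            rng = np.random.default_rng(spec.seed)
            color_idx = rng.integers(0, len(stripe_colors), size=spec.n_stripes)
        else:
            color_idx = np.arange(spec.n_stripes) % max(len(stripe_colors), 1)
        for i, band in _stripe_bands(spec, body):
            pixels[band] = stripe_colors[color_idx[i]]

    pixels = _apply_tone(pixels, mask, spec)
    return MaskedImage(pixels=pixels, mask=mask)


def _apply_tone(pixels: np.ndarray, mask: np.ndarray, spec: FishSpec) -> np.ndarray:
    """Scale saturation and impose a vertical lightness gradient inside the mask."""
    if spec.saturation_scale == 1.0 and spec.lightness_contrast == 0.0:
        return pixels
    hsv = skcolor.rgb2hsv(pixels)
    hsv[..., 1] = np.where(mask, hsv[..., 1] * spec.saturation_scale, hsv[..., 1])
    if spec.lightness_contrast > 0:
        n = pixels.shape[0]
        rowfrac = np.linspace(0.0, 1.0, n)[:, None]  # 0 at top, 1 at bottom
        factor = 1.0 + spec.lightness_contrast * (0.5 - rowfrac)
        v = hsv[..., 2]
        hsv[..., 2] = np.where(mask, np.clip(v * factor, 0.0, 1.0), v)
    out = skcolor.hsv2rgb(hsv)
    out[~mask] = pixels[~mask]
    return out


def stripe_label_mask(spec: FishSpec) -> np.ndarray:
    """Ground-truth stripe labels: 0 = base color, 1..n = stripe band index.

    Background pixels get -1. Used by segmentation tests as the reference
    partition of the mask.
    """
    n = spec.canvas_px
    body = _body_mask(spec)
    mask = body | _fin_mask(spec)
    labels = np.full((n, n), -1, dtype=int)
    labels[mask] = 0
    for i, band in _stripe_bands(spec, body):
        labels[band] = i + 1
    return labels
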