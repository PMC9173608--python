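"""Feature registry and the 17-feature extraction entry point.

Each of the four feature classes is a swappable plug-in: replacing a
class computation (e.g. with an alternative pattern definition) is a
config change, not a code change.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from reefscore.features.color import color_features, segment_colors
from reefscore.features.pattern import MIN_PATCH_PX, pattern_features
from reefscore.features.shape import N_CONTOUR_POINTS, N_HARMONICS, shape_features
from reefscore.features.tone import tone_features
from reefscore.image import MaskedImage

#: canonical column order of the 17-feature vector
FEATURE_NAMES: tuple[str, ...] = (
    # color heterogeneity
    "k_colors",
    "color_entropy",
    "mean_centroid_distance",
    "dominant_color_share",
    # geometry of color patterns
    "patch_count",
    "pattern_repetition",
    "boundary_sharpness",
    "patch_area_sd",
    "boundary_fractal_dim",
    # perceptual tone
    "mean_saturation",
    "sd_saturation",
    "mean_lightness",
    "sd_lightness",
    # outline shape
    "elongatedness",
    "circularity",
    "convexity",
    "outline_harmonic_power",
)


@dataclasses.dataclass
class FeatureConfig:
    k_range: tuple[int, int] = (2, 10)
    n_init: int = 10
    tau_uniform: float = 2.0
    max_fit_pixels: int = 5000
    max_silhouette_pixels: int = 2000
    min_patch_px: int = MIN_PATCH_PX
    n_harmonics: int = N_HARMONICS
    n_contour_points: int = N_CONTOUR_POINTS
    seed: int = 0


def _color_class(img: MaskedImage, cfg: FeatureConfig) -> dict[str, float]:
    seg = segment_colors(
        img,
        k_range=cfg.k_range,
        seed=cfg.seed,
        n_init=cfg.n_init,
        tau_uniform=cfg.tau_uniform,
        max_fit_pixels=cfg.max_fit_pixels,
        max_silhouette_pixels=cfg.max_silhouette_pixels,
    )
    out = color_features(seg)
    out.update(pattern_features(seg, img, min_patch_px=cfg.min_patch_px))
    return out


def _tone_class(img: MaskedImage, cfg: FeatureConfig) -> dict[str, float]:
    return tone_features(img)


def _shape_class(img: MaskedImage, cfg: FeatureConfig) -> dict[str, float]:
    return shape_features(
        img.mask, n_harmonics=cfg.n_harmonics, n_points=cfg.n_contour_points
    )


#: class name -> callable(img, config) -> {feature: value}
REGISTRY: dict[str, Callable[[MaskedImage, FeatureConfig], dict[str, float]]] = {
    "color_and_pattern": _color_class,
    "tone": _tone_class,
    "shape": _shape_class,
}


def extract_features(
    img: MaskedImage, config: FeatureConfig | None = None
) -> dict[str, float]:
    """Compute the named 17-feature vector for one masked image."""
    cfg = config or FeatureConfig()
    values: dict[str, float] = {}
    for fn in REGISTRY.values():
        values.update(fn(img, cfg))
    missing = [n for n in FEATURE_NAMES if n not in values]
    if missing:
        raise RuntimeError(f"registry did not produce features: {missing}")
    return {name: values[name] for name in FEATURE_NAMES}


def extract_batch(
    images: Sequence[MaskedImage] | dict[str, MaskedImage],
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Extract features for many images; index is the image id."""
    if isinstance(images, dict):
        items = images.items()
    else:
        items = ((f"img{i}", im) for i, im in enumerate(images))
    rows = {name: extract_features(im, config) for name, im in items}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "image_id"
    return df


def batch_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def batch_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="image_id")
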