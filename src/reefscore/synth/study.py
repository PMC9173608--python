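"""Planted-score synthetic study: images whose aesthetic score is a known
function of three features.

The generator distribution is engineered for identifiability of the
planted features (mean_saturation, color_entropy, elongatedness): every
other battery feature is either held (near-)constant — so the correlation
filter drops it — or made strongly collinear with a planted feature — so
the filter absorbs it into the planted feature's group.
"""

from __future__ import annotations

import colorsys

import numpy as np
import pandas as pd

from reefscore.synth.images import FishSpec, generate_fish_image

PLANTED_FEATURES = ("mean_saturation", "color_entropy", "elongatedness")
PLANTED_SIGNS = {"mean_saturation": 1.0, "color_entropy": 1.0, "elongatedness": -1.0}


def planted_study_specs(
    n_images: int = 200, seed: int = 0, canvas_px: int = 120
) -> list[FishSpec]:
    """Specs varying only saturation, palette richness, and elongation.

    Palette colors share one random hue and HSV saturation and differ only
    in stepped value (lightness), which ties every color/pattern/tone
    nuisance feature to the palette-size driver rather than to the
    saturation driver. Stripe multiplicity varies the color proportions so
    entropy carries information beyond the raw cluster count. Independent
    outline and stripe-edge waviness inject variance into the outline- and
    boundary-geometry nuisances so none of them can proxy a planted
    feature more tightly than the planted feature itself.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for img_idx in range(n_images):
        # palette sizes 2-4: avoiding the single-color degenerate case
        # keeps the color features off a shared "is-colored" factor that
        # would lock them all together
        m = int(rng.integers(2, 5))
        hue = rng.random()
        vals = [0.85 - 0.4 * j / max(m - 1, 1) for j in range(m)]
        palette = tuple(colorsys.hsv_to_rgb(hue, 0.9, v) for v in vals)
        specs.append(
            FishSpec(
                body_aspect=float(rng.uniform(1.0, 3.2)),
                n_stripes=int(rng.integers(2, 5)) * (m - 1),
                palette=palette,
                saturation_scale=float(rng.uniform(0.25, 1.0)),
                lightness_contrast=0.0,
                fin_profile="caudal_only",
                waviness=float(rng.uniform(0.0, 0.13)),
                stripe_waviness=float(rng.uniform(0.0, 0.6)),
                stripe_wave_periods=int(rng.integers(4, 11)),
                randomize_stripe_colors=True,
                randomize_stripe_widths=True,
                seed=seed * 100_003 + img_idx,
                canvas_px=canvas_px,
            )
        )
    return specs


def planted_study_images(n_images: int = 200, seed: int = 0, canvas_px: int = 120):
    """Generate the study image set keyed by image id."""
    specs = planted_study_specs(n_images, seed, canvas_px)
    return {f"img{i:04d}": generate_fish_image(s) for i, s in enumerate(specs)}


def planted_scores(
    features: pd.DataFrame, noise_sd: float = 0.5, seed: int = 0
) -> pd.Series:
    """Planted response: z(saturation) + z(entropy) - z(elongatedness) + noise."""
    rng = np.random.default_rng(seed)
    z = lambda c: (features[c] - features[c].mean()) / features[c].std(ddof=0)
    signal = sum(PLANTED_SIGNS[f] * z(f) for f in PLANTED_FEATURES)
    return signal + rng.normal(0.0, noise_sd, size=len(features))
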