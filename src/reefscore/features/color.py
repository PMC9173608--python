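"""CIELAB K-means color segmentation and color-heterogeneity features.

Masked pixels are converted sRGB -> CIELAB (D65). K-means is run for each
candidate k with multiple restarts and a fixed seed; k is chosen by
maximum mean silhouette, with k = 1 declared when the total CIELAB
standard deviation falls below a uniformity threshold.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage import color as skcolor
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from reefscore.image import MaskedImage

#: images whose masked CIELAB pixels have a total SD below this are uniform
TAU_UNIFORM = 2.0


@dataclasses.dataclass
class ColorSegmentation:
    """Cluster labels over the mask plus CIELAB centroids.

    labels: full-raster int array, -1 outside the mask, 0..k-1 inside.
    """

    labels: np.ndarray
    k: int
    centroids: np.ndarray  # (k, 3) CIELAB
    mask: np.ndarray

    def __post_init__(self) -> None:
        inside = self.labels[self.mask]
        if inside.min() < 0 or inside.max() >= self.k:
            raise ValueError("labels inside the mask must cover 0..k-1")
        if (self.labels[~self.mask] != -1).any():
            raise ValueError("labels outside the mask must be -1")

    def proportions(self) -> np.ndarray:
        counts = np.bincount(self.labels[self.mask], minlength=self.k)
        return counts / counts.sum()


def masked_lab(img: MaskedImage) -> np.ndarray:
    """CIELAB (D65) colors of the organism pixels, shape (N, 3)."""
    rgb = img.masked_pixels()[None, :, :]
    return skcolor.rgb2lab(rgb)[0]


def segment_colors(
    img: MaskedImage,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    n_init: int = 10,
    tau_uniform: float = TAU_UNIFORM,
    max_fit_pixels: int = 5000,
    max_silhouette_pixels: int = 2000,
) -> ColorSegmentation:
    """Segment masked pixels into color clusters in CIELAB space."""
    k_lo, k_hi = k_range
    if not (1 <= k_lo <= k_hi <= 10):
        raise ValueError("k_range must lie within [1, 10]")
    lab = masked_lab(img)
    n_px = lab.shape[0]
    if n_px < k_hi:
        raise ValueError(f"mask has {n_px} pixels, fewer than k_max={k_hi}")

    labels_full = np.full(img.mask.shape, -1, dtype=int)
    total_sd = float(np.sqrt(lab.var(axis=0).sum()))
    if total_sd < tau_uniform or k_hi == 1:
        labels_full[img.mask] = 0
        return ColorSegmentation(
            labels=labels_full, k=1, centroids=lab.mean(axis=0, keepdims=True),
            mask=img.mask,
        )

    rng = np.random.default_rng(seed)
    if n_px > max_fit_pixels:
        fit_idx = rng.choice(n_px, size=max_fit_pixels, replace=False)
    else:
        fit_idx = np.arange(n_px)
    fit_lab = lab[fit_idx]

    # More clusters than distinct colors is ill-posed; cap k accordingly.
    n_distinct = len(np.unique(np.round(fit_lab, 4), axis=0))
    k_cap = min(k_hi, n_distinct)

    best = None
    for k in range(max(2, k_lo), k_cap + 1):
        if k >= len(fit_lab):
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate-point convergence noise
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(fit_lab)
        if len(np.unique(km.labels_)) < 2:
            continue
        if len(fit_lab) > max_silhouette_pixels:
            sil_idx = rng.choice(len(fit_lab), size=max_silhouette_pixels, replace=False)
        else:
            sil_idx = np.arange(len(fit_lab))
        try:
            score = silhouette_score(fit_lab[sil_idx], km.labels_[sil_idx])
        except ValueError:  # a subsample may collapse to one cluster
            continue
        if best is None or score > best[0]:
            best = (score, km)
    if best is None:  # all candidate clusterings degenerate -> uniform
        labels_full[img.mask] = 0
        return ColorSegmentation(
            labels=labels_full, k=1, centroids=lab.mean(axis=0, keepdims=True),
            mask=img.mask,
        )
    km = best[1]
    # Assign every masked pixel to its nearest centroid.
    d2 = ((lab[:, None, :] - km.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
    labels_full[img.mask] = d2.argmin(axis=1)
    return ColorSegmentation(
        labels=labels_full, k=km.n_clusters, centroids=km.cluster_centers_,
        mask=img.mask,
    )


def color_features(seg: ColorSegmentation) -> dict[str, float]:
    """Color heterogeneity: cluster count, entropy, centroid spread, dominance."""
    p = seg.proportions()
    p_nz = p[p > 0]
    entropy = float(-(p_nz * np.log(p_nz)).sum())
    if seg.k > 1:
        diff = seg.centroids[:, None, :] - seg.centroids[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        iu = np.triu_indices(seg.k, k=1)
        mean_dist = float(d[iu].mean())
    else:
        mean_dist = 0.0
    return {
        "k_colors": float(seg.k),
        "color_entropy": entropy,
        "mean_centroid_distance": mean_dist,
        "dominant_color_share": float(p.max()),
    }
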