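"""Outline shape features via elliptical Fourier decomposition.

The outer contour of the largest mask component is resampled to equal
arclength steps, lightly smoothed to suppress raster staircase noise, and
decomposed into harmonic ellipses (Kuhl-Giardina). Elongatedness is the
major/minor axis ratio of the region's second-moment ellipse (exact for
elliptical regions, unlike the arclength-parameterized first harmonic,
which systematically underestimates eccentric axis ratios). Circularity
and convexity come from the contour polygon; the harmonic power ratio
captures outline complexity beyond the best-fitting ellipse.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

N_HARMONICS = 20
N_CONTOUR_POINTS = 512
SMOOTH_WINDOW = 7


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest 8-connected component (warn if several)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    comp = measure.label(mask, connectivity=2)
    if comp.max() > 1:
        warnings.warn(
            f"mask has {comp.max()} components; keeping the largest", stacklevel=2
        )
        sizes = np.bincount(comp.ravel())[1:]
        mask = comp == (sizes.argmax() + 1)
    return mask


def _smooth_closed(xy: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average along a closed contour."""
    if window <= 1:
        return xy
    kernel = np.ones(window) / window
    out = np.empty_like(xy)
    for d in range(2):
        ext = np.concatenate([xy[-window:, d], xy[:, d], xy[:window, d]])
        out[:, d] = np.convolve(ext, kernel, mode="same")[window:-window]
    return out


def extract_contour(
    mask: np.ndarray,
    n_points: int = N_CONTOUR_POINTS,
    smooth_window: int = SMOOTH_WINDOW,
) -> np.ndarray:
    """Closed outer contour of the largest component, resampled to n_points.

    Returns an (n_points, 2) array of (x, y) coordinates; the polygon is
    implicitly closed (last point connects back to the first).
    """
    mask = largest_component(mask)
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0  # undo padding offset
    xy = contour[:, ::-1]  # (row, col) -> (x, y)
    return _smooth_closed(_resample_closed(xy, n_points), smooth_window)


def _resample_closed(xy: np.ndarray, n_points: int) -> np.ndarray:
    closed = np.vstack([xy, xy[:1]])
    seg = np.sqrt(((np.diff(closed, axis=0)) ** 2).sum(axis=1))
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero length")
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(targets, t, closed[:, 0])
    y = np.interp(targets, t, closed[:, 1])
    return np.stack([x, y], axis=1)


def elliptic_fourier_coefficients(xy: np.ndarray, n_harmonics: int = N_HARMONICS) -> np.ndarray:
    """Kuhl-Giardina elliptic Fourier coefficients, shape (H, 4) = (a, b, c, d)."""
    closed = np.vstack([xy, xy[:1]])
    dxy = np.diff(closed, axis=0)
    dt = np.sqrt((dxy**2).sum(axis=1))
    dt = np.where(dt == 0, 1e-12, dt)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T
    coeffs = np.empty((n_harmonics, 4))
    for h in range(1, n_harmonics + 1):
        const = T / (2.0 * h**2 * np.pi**2)
        d_cos = np.cos(h * phi[1:]) - np.cos(h * phi[:-1])
        d_sin = np.sin(h * phi[1:]) - np.sin(h * phi[:-1])
        coeffs[h - 1] = const * np.array(
            [
                (dxy[:, 0] / dt * d_cos).sum(),
                (dxy[:, 0] / dt * d_sin).sum(),
                (dxy[:, 1] / dt * d_cos).sum(),
                (dxy[:, 1] / dt * d_sin).sum(),
            ]
        )
    return coeffs


def _polygon_area_perimeter(xy: np.ndarray) -> tuple[float, float]:
    x, y = xy[:, 0], xy[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(float((x * y2 - x2 * y).sum()))
    perimeter = float(np.sqrt((x2 - x) ** 2 + (y2 - y) ** 2).sum())
    return area, perimeter


def shape_features(
    mask: np.ndarray,
    n_harmonics: int = N_HARMONICS,
    n_points: int = N_CONTOUR_POINTS,
) -> dict[str, float]:
    """Elongatedness, circularity, convexity, and outline harmonic power."""
    region = largest_component(mask)
    xy = extract_contour(region, n_points)
    coeffs = elliptic_fourier_coefficients(xy, n_harmonics)

    # Second-moment ellipse of the filled region: the square root of the
    # covariance eigenvalue ratio equals the axis ratio exactly for an
    # elliptical region and is translation/rotation/scale invariant.
    yy, xx = np.nonzero(region)
    evals = np.linalg.eigvalsh(np.cov(np.stack([xx, yy]).astype(float)))
    elongatedness = float(np.sqrt(evals[1] / max(evals[0], 1e-12)))

    area, perimeter = _polygon_area_perimeter(xy)
    circularity = float(4.0 * np.pi * area / max(perimeter**2, 1e-12))

    hull = ConvexHull(xy)
    convexity = float(area / max(hull.volume, 1e-12))

    power = (coeffs**2).sum(axis=1)
    harmonic_power = float(power[1:].sum() / max(power.sum(), 1e-30))

    return {
        "elongatedness": elongatedness,
        "circularity": min(circularity, 1.0 + 1e-6),
        "convexity": convexity,
        "outline_harmonic_power": harmonic_power,
    }
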