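"""Geometry of color patterns: patches, repetition, boundary structure.

Patches are 8-connected components of each color cluster inside the mask.
Patches below a minimum pixel size are merged into the neighboring patch
with the largest contact, suppressing rasterization speckle.
"""

from __future__ import annotations

import numpy as np
from skimage import color as skcolor
from skimage import measure

from reefscore.features.color import ColorSegmentation
from reefscore.image import MaskedImage

MIN_PATCH_PX = 10


def _patch_labels(seg: ColorSegmentation, min_patch_px: int) -> np.ndarray:
    """Global patch labeling: 0 outside mask, 1..P inside."""
    patch = np.zeros(seg.labels.shape, dtype=int)
    nxt = 1
    for c in range(seg.k):
        comp = measure.label(seg.labels == c, connectivity=2)
        n_comp = comp.max()
        sel = comp > 0
        patch[sel] = comp[sel] + (nxt - 1)
        nxt += n_comp
    if min_patch_px > 1:
        patch = _merge_small_patches(patch, min_patch_px)
    return patch


def _neighbor_pairs(patch: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """4-neighbor pixel pairs (as index arrays) lying in different patches."""
    pairs = []
    # vertical neighbors
    a, b = patch[:-1, :], patch[1:, :]
    sel = (a > 0) & (b > 0) & (a != b)
    rr, cc = np.nonzero(sel)
    pairs.append((np.stack([rr, cc], axis=1), np.stack([rr + 1, cc], axis=1)))
    # horizontal neighbors
    a, b = patch[:, :-1], patch[:, 1:]
    sel = (a > 0) & (b > 0) & (a != b)
    rr, cc = np.nonzero(sel)
    pairs.append((np.stack([rr, cc], axis=1), np.stack([rr, cc + 1], axis=1)))
    return pairs


def _merge_small_patches(patch: np.ndarray, min_patch_px: int) -> np.ndarray:
    patch = patch.copy()
    for _ in range(8):  # iterate: merging can create new adjacencies
        ids, counts = np.unique(patch[patch > 0], return_counts=True)
        small = ids[counts < min_patch_px]
        if small.size == 0:
            break
        contact: dict[int, dict[int, int]] = {s: {} for s in small}
        for p1, p2 in _neighbor_pairs(patch):
            for a_idx, b_idx in ((p1, p2), (p2, p1)):
                va = patch[a_idx[:, 0], a_idx[:, 1]]
                vb = patch[b_idx[:, 0], b_idx[:, 1]]
                for s, t in zip(va, vb):
                    if s in contact:
                        contact[s][t] = contact[s].get(t, 0) + 1
        merged_any = False
        for s in small:
            if contact[s]:
                target = max(contact[s].items(), key=lambda kv: kv[1])[0]
                patch[patch == s] = target
                merged_any = True
        if not merged_any:
            break
    # compact labels to 1..P
    ids = np.unique(patch[patch > 0])
    remap = np.zeros(patch.max() + 1, dtype=int)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[patch]


def pattern_features(
    seg: ColorSegmentation,
    img: MaskedImage,
    min_patch_px: int = MIN_PATCH_PX,
) -> dict[str, float]:
    """Patch counts, repetition, boundary sharpness/fractality, area spread."""
    patch = _patch_labels(seg, min_patch_px)
    ids, areas = np.unique(patch[patch > 0], return_counts=True)
    n_patches = len(ids)
    # patch areas as fractions of the organism area -> scale invariance
    area_fractions = areas / seg.mask.sum()

    # cluster of each surviving patch, for the repetition feature
    cluster_of_patch: dict[int, int] = {}
    flat_patch, flat_cluster = patch[seg.mask], seg.labels[seg.mask]
    for pid in ids:
        cl = flat_cluster[flat_patch == pid]
        cluster_of_patch[pid] = int(np.bincount(cl).argmax())
    n_clusters_present = len(set(cluster_of_patch.values()))
    repetition = n_patches / max(n_clusters_present, 1)

    lab = np.zeros(img.pixels.shape, dtype=float)
    lab[seg.mask] = skcolor.rgb2lab(img.masked_pixels()[None, :, :])[0]

    boundary_mask = np.zeros(patch.shape, dtype=bool)
    deltas = []
    for p1, p2 in _neighbor_pairs(patch):
        if len(p1) == 0:
            continue
        boundary_mask[p1[:, 0], p1[:, 1]] = True
        boundary_mask[p2[:, 0], p2[:, 1]] = True
        d = lab[p1[:, 0], p1[:, 1]] - lab[p2[:, 0], p2[:, 1]]
        deltas.append(np.sqrt((d**2).sum(axis=1)))
    sharpness = float(np.concatenate(deltas).mean()) if deltas else 0.0

    return {
        "patch_count": float(n_patches),
        "pattern_repetition": float(repetition),
        "boundary_sharpness": sharpness,
        "patch_area_sd": float(area_fractions.std()) if n_patches > 0 else 0.0,
        "boundary_fractal_dim": _box_counting_dimension(boundary_mask),
    }


BOX_COUNT_SIDE = 64


def _box_counting_dimension(points: np.ndarray) -> float:
    """Box-counting dimension of a boolean pixel set (0.0 if nearly empty).

    The set is cropped to its bounding box and warped to a fixed square
    before counting, so the estimate reflects boundary complexity rather
    than the set's position, scale, or gross anisotropy.
    """
    if points.sum() < 2:
        return 0.0
    rows = np.nonzero(points.any(axis=1))[0]
    cols = np.nonzero(points.any(axis=0))[0]
    points = points[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    if min(points.shape) < 2:
        return 0.0
    from skimage.transform import resize

    points = resize(points.astype(float), (BOX_COUNT_SIDE, BOX_COUNT_SIDE),
                    order=0, anti_aliasing=False) > 0.5
    n = BOX_COUNT_SIDE
    sizes = sorted({max(1, n // d) for d in (4, 8, 16, 32)})
    if len(sizes) < 2 or points.sum() < 2:
        return 0.0
    counts = []
    for s in sizes:
        h = (points.shape[0] + s - 1) // s
        w = (points.shape[1] + s - 1) // s
        padded = np.zeros((h * s, w * s), dtype=bool)
        padded[: points.shape[0], : points.shape[1]] = points
        boxes = padded.reshape(h, s, w, s).any(axis=(1, 3))
        counts.append(boxes.sum())
    slope, _ = np.polyfit(np.log(1.0 / np.array(sizes)), np.log(counts), 1)
    return float(slope)
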