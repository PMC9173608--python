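"""Survey-design stage: feature PCA, convex-hull stratified selection,
and the confidence-ellipse representativeness check."""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA


@dataclasses.dataclass
class PcaModel:
    """Standardized-feature PCA: loadings, scores, variance fractions."""

    loadings: np.ndarray  # (n_components, n_features)
    scores: np.ndarray  # (n_images, n_components)
    variance_fractions: np.ndarray  # full spectrum, sums to 1
    ids: list[str]
    feature_names: list[str]
    n_components: int

    def retained_variance(self) -> float:
        return float(self.variance_fractions[: self.n_components].sum())

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, index=pd.Index(self.ids, name="image_id"),
                            columns=cols)


def fit_pca(features: pd.DataFrame, n_components: int) -> PcaModel:
    """PCA of z-scored feature columns.

    Raises on constant columns (which cannot be standardized), naming them.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as columns ({p})")
    if not (1 <= n_components <= p):
        raise ValueError("n_components out of range")
    sd = X.std(axis=0)
    constant = [c for c, s in zip(features.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant column(s) cannot be scaled: {constant}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=p).fit(Z)
    return PcaModel(
        loadings=pca.components_[:n_components],
        scores=pca.transform(Z)[:, :n_components],
        variance_fractions=pca.explained_variance_ratio_,
        ids=[str(i) for i in features.index],
        feature_names=list(features.columns),
        n_components=n_components,
    )


@dataclasses.dataclass
class SurveySelection:
    vertex_ids: list[str]
    fill_ids: list[str]
    hull_degenerate: bool

    @property
    def selected_ids(self) -> list[str]:
        return self.vertex_ids + self.fill_ids


def select_survey_set(
    pca: PcaModel,
    n_vertex: int,
    n_fill: int,
    seed: int,
    k_per_vertex: int | None = None,
) -> SurveySelection:
    """Stratified selection: hull-vertex neighborhoods plus a uniform fill.

    The convex hull of the retained component scores defines the vertex
    stratum: each hull vertex contributes its ``k_per_vertex`` nearest
    images (including itself), and the stratum is sampled round-robin
    across vertices without replacement until ``n_vertex`` images are
    drawn. ``n_fill`` images are then drawn uniformly from the complement.
    Degenerate hulls fall back to per-axis extreme points (flagged).
    """
    X = pca.scores
    ids = pca.ids
    n = len(ids)
    if n_vertex < 0 or n_fill < 0 or n_vertex + n_fill > n:
        raise ValueError("requested selection exceeds available images")
    rng = np.random.default_rng(seed)

    degenerate = False
    try:
        hull = ConvexHull(X)
        vertices = list(hull.vertices)
    except QhullError:
        degenerate = True
        vertices = sorted(
            {int(i) for d in range(X.shape[1]) for i in (X[:, d].argmin(), X[:, d].argmax())}
        )

    if k_per_vertex is None:
        k_per_vertex = max(1, math.ceil(n_vertex / max(len(vertices), 1)))

    # Per-vertex candidate lists: the vertex itself first, then neighbors.
    neighborhoods = []
    for v in vertices:
        d = np.sqrt(((X - X[v]) ** 2).sum(axis=1))
        neighborhoods.append(list(np.argsort(d, kind="stable")[:k_per_vertex]))

    chosen: list[int] = []
    chosen_set: set[int] = set()
    order = rng.permutation(len(neighborhoods))
    depth = 0
    while len(chosen) < n_vertex and depth < k_per_vertex:
        for vi in order:
            if len(chosen) >= n_vertex:
                break
            cands = neighborhoods[vi]
            if depth < len(cands) and cands[depth] not in chosen_set:
                chosen.append(cands[depth])
                chosen_set.add(cands[depth])
        depth += 1
    if len(chosen) < n_vertex:
        # neighborhoods exhausted; top up from nearest-to-hull remainder
        remaining = [i for i in range(n) if i not in chosen_set]
        hull_pts = X[vertices]
        d = np.array(
            [np.sqrt(((hull_pts - X[i]) ** 2).sum(axis=1)).min() for i in remaining]
        )
        for i in np.array(remaining)[np.argsort(d, kind="stable")][: n_vertex - len(chosen)]:
            chosen.append(int(i))
            chosen_set.add(int(i))

    complement = np.array([i for i in range(n) if i not in chosen_set])
    fill = rng.choice(complement, size=n_fill, replace=False) if n_fill else np.array([], int)

    return SurveySelection(
        vertex_ids=[ids[i] for i in chosen],
        fill_ids=[ids[int(i)] for i in fill],
        hull_degenerate=degenerate,
    )


# --------------------------------------------------------------- coverage

def ellipse_overlap(
    mean1: np.ndarray,
    cov1: np.ndarray,
    mean2: np.ndarray,
    cov2: np.ndarray,
    q: float,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Jaccard overlap of two ellipses {x: (x-m)' S^-1 (x-m) <= q} by Monte Carlo."""
    rng = np.random.default_rng(seed)
    means = [np.asarray(mean1, float), np.asarray(mean2, float)]
    covs = [np.asarray(cov1, float), np.asarray(cov2, float)]
    for S in covs:
        if np.linalg.det(S) <= 0:
            raise ValueError("degenerate ellipse: singular covariance")
    # bounding box of both ellipses
    los, his = [], []
    for m, S in zip(means, covs):
        half = np.sqrt(q * np.diag(S))
        los.append(m - half)
        his.append(m + half)
    lo = np.minimum(*los)
    hi = np.maximum(*his)
    pts = rng.random((n_mc, 2)) * (hi - lo) + lo
    inside = []
    for m, S in zip(means, covs):
        d = pts - m
        md = (d @ np.linalg.inv(S) * d).sum(axis=1)
        inside.append(md <= q)
    union = (inside[0] | inside[1]).sum()
    if union == 0:
        return 0.0
    return float((inside[0] & inside[1]).sum() / union)


def coverage_check(
    selected_scores: np.ndarray | Sequence[Sequence[float]],
    all_scores: np.ndarray | Sequence[Sequence[float]],
    level: float = 0.99,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Jaccard overlap of the normal-theory confidence ellipses on PC1-PC2."""
    sel = np.asarray(selected_scores, float)[:, :2]
    full = np.asarray(all_scores, float)[:, :2]
    if sel.shape[0] < 3 or full.shape[0] < 3:
        raise ValueError("need at least 3 points per group")
    q = float(stats.chi2.ppf(level, df=2))
    return ellipse_overlap(
        sel.mean(axis=0), np.cov(sel.T), full.mean(axis=0), np.cov(full.T),
        q=q, n_mc=n_mc, seed=seed,
    )
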