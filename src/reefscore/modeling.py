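"""Feature-to-score modeling and the grouped image-regression harness.

The feature model follows the published protocol: a pairwise-correlation
filter, terms entered in decreasing order of univariate contribution,
backward elimination of non-significant terms, and scaled coefficients.

The image regressor is a compact convolutional feature extractor with
fixed random filters and a trainable linear regression head. A deep
pretrained backbone is substitutable via config when weights are locally
available, but is never required: the default trains on one CPU in
seconds and honors the same grouped cross-validation contract.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skimage.transform import resize, rotate

from reefscore.image import MaskedImage

# ------------------------------------------------------------ filtering


def correlation_filter(
    features: pd.DataFrame, response: Sequence[float], threshold: float = 0.7
) -> list[str]:
    """Keep one feature per correlated group.

    Features are grouped by the transitive closure of |Pearson r| >=
    threshold; within each group the feature with the highest absolute
    correlation with the response survives. Constant features are dropped
    with a warning.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != len(features):
        raise ValueError("response must align with feature rows")
    cols = list(features.columns)
    sd = features.std(axis=0, ddof=0)
    scale = features.abs().mean(axis=0)
    constant = [c for c in cols if sd[c] <= 1e-10 * max(1.0, scale[c])]
    if constant:
        warnings.warn(f"dropping constant feature(s): {constant}", stacklevel=2)
        cols = [c for c in cols if c not in constant]
    X = features[cols].to_numpy(dtype=float)
    R = np.corrcoef(X, rowvar=False)
    if R.ndim == 0:  # single column
        R = np.array([[1.0]])
    adj = (np.abs(R) >= threshold).astype(int)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    ry = np.array([abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(len(cols))])
    retained = []
    for comp in range(n_comp):
        members = np.nonzero(labels == comp)[0]
        retained.append(cols[members[ry[members].argmax()]])
    return [c for c in features.columns if c in retained]


# ------------------------------------------------------- feature model


@dataclasses.dataclass
class FeatureModel:
    """Backward-selected linear model on standardized features."""

    terms: list[str]
    coefficients: pd.Series  # scaled (per-SD) coefficients
    std_errors: pd.Series
    p_values: pd.Series
    r2: float
    elimination_trace: list[str]  # terms removed, in removal order

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef_scaled": self.coefficients,
                "se": self.std_errors,
                "p": self.p_values,
            }
        )


def fit_feature_model(
    features: pd.DataFrame,
    response: Sequence[float],
    alpha: float = 0.05,
) -> FeatureModel:
    """Ordered multiple regression with backward elimination.

    Features are z-scored (so coefficients are comparable), entered in
    decreasing order of univariate r-squared with the response, then the
    least-significant term with p > alpha is dropped repeatedly until all
    remaining terms are significant.
    """
    y = np.asarray(response, dtype=float)
    n, p = features.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    sd = features.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError(f"constant feature(s): {list(sd.index[sd == 0])}")
    Z = (features - features.mean(axis=0)) / sd

    uni_r2 = {
        c: np.corrcoef(Z[c], y)[0, 1] ** 2 for c in Z.columns
    }
    terms = sorted(Z.columns, key=lambda c: -uni_r2[c])

    trace: list[str] = []
    while True:
        X = sm.add_constant(Z[terms])
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValueError(f"rank-deficient design; collinear terms among {terms}")
        fit = sm.OLS(y, X).fit()
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] > alpha and len(terms) > 1:
            terms.remove(worst)
            trace.append(worst)
            continue
        if pvals[worst] > alpha:  # last term also non-significant
            terms.remove(worst)
            trace.append(worst)
            X = sm.add_constant(pd.DataFrame(index=Z.index))
            fit = sm.OLS(y, np.ones((n, 1))).fit()
            return FeatureModel(
                terms=[],
                coefficients=pd.Series(dtype=float),
                std_errors=pd.Series(dtype=float),
                p_values=pd.Series(dtype=float),
                r2=0.0,
                elimination_trace=trace,
            )
        return FeatureModel(
            terms=list(terms),
            coefficients=fit.params.drop("const"),
            std_errors=fit.bse.drop("const"),
            p_values=pvals,
            r2=float(fit.rsquared),
            elimination_trace=trace,
        )


def project_pca(features: pd.DataFrame, model: FeatureModel, n_components: int = 2):
    """PCA biplot coordinates of the model's retained features."""
    from reefscore.sampling import fit_pca

    if not model.terms:
        raise ValueError("model retained no terms")
    return fit_pca(features[model.terms], n_components=n_components)


# ------------------------------------------------------------- CV plan


@dataclasses.dataclass
class CvPlan:
    """Species-grouped fold assignment: every image of a species shares a fold."""

    image_fold: dict[str, int]
    k: int

    def fold_of(self, image_id: str) -> int:
        return self.image_fold[image_id]

    def images_in_fold(self, fold: int) -> list[str]:
        return [i for i, f in self.image_fold.items() if f == fold]


def make_cv_plan(
    image_species_map: Mapping[str, str], k: int = 5, seed: int = 0
) -> CvPlan:
    """Shuffle species and deal them round-robin into k folds."""
    species = sorted(set(image_species_map.values()))
    if len(species) < k:
        raise ValueError(f"need at least {k} species, got {len(species)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(species))
    species_fold = {species[si]: (pos % k) + 1 for pos, si in enumerate(order)}
    return CvPlan(
        image_fold={img: species_fold[sp] for img, sp in image_species_map.items()},
        k=k,
    )


# ------------------------------------------------- image regressor


class DivergenceError(RuntimeError):
    pass


@dataclasses.dataclass
class RegressorConfig:
    side: int = 224  # images resized to side x side
    n_filters: tuple[int, int] = (8, 16)
    pool: int = 4
    epochs: int = 100
    learning_rate: float = 0.1
    weight_decay: float = 1e-3
    rotation_range: tuple[float, float] = (-5.0, 5.0)
    augment: bool = True
    n_augment: int = 1  # augmented copies per training image
    seed: int = 0


def _conv2d(x: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Valid 3x3 convolution, x: (H, W, C_in), filters: (C_out, 3, 3, C_in)."""
    h, w, _ = x.shape
    patches = np.stack(
        [x[i : h - 2 + i, j : w - 2 + j, :] for i in range(3) for j in range(3)],
        axis=2,
    )  # (H-2, W-2, 9, C_in)
    flat = patches.reshape(h - 2, w - 2, -1)
    return flat @ filters.reshape(filters.shape[0], -1).T


def _avg_pool(x: np.ndarray, p: int) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h // p, w // p
    return x[: h2 * p, : w2 * p].reshape(h2, p, w2, p, c).mean(axis=(1, 3))


class ImageRegressor:
    """Random-filter convolutional backbone + trainable linear head."""

    def __init__(self, config: RegressorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.n_filters
        self.f1 = rng.standard_normal((c1, 3, 3, 3)) / np.sqrt(27)
        self.f2 = rng.standard_normal((c2, 3, 3, c1)) / np.sqrt(9 * c1)
        self.head_w: np.ndarray | None = None
        self.feat_mean: np.ndarray | None = None
        self.feat_sd: np.ndarray | None = None

    # backbone ---------------------------------------------------------

    def embed(self, img: MaskedImage) -> np.ndarray:
        """Fixed-feature embedding of one image."""
        x = resize(img.pixels, (self.config.side, self.config.side, 3),
                   anti_aliasing=True)
        h1 = np.maximum(_conv2d(x, self.f1), 0.0)
        h1p = _avg_pool(h1, self.config.pool)
        h2 = np.maximum(_conv2d(h1p, self.f2), 0.0)
        return np.concatenate(
            [x.mean(axis=(0, 1)), h1.mean(axis=(0, 1)), h2.mean(axis=(0, 1))]
        )

    def _augmented(self, img: MaskedImage, rng: np.random.Generator) -> MaskedImage:
        lo, hi = self.config.rotation_range
        if not self.config.augment or (lo == 0.0 and hi == 0.0):
            return img
        angle = rng.uniform(lo, hi)
        px = rotate(img.pixels, angle, cval=1.0, mode="constant")
        mk = rotate(img.mask.astype(float), angle, cval=0.0) > 0.5
        if not mk.any():
            return img
        return MaskedImage(pixels=px, mask=mk)

    def training_stream(
        self, images: Sequence[MaskedImage], rng: np.random.Generator
    ) -> np.ndarray:
        """Embeddings of the training images plus augmented copies."""
        feats = [self.embed(im) for im in images]
        if self.config.augment and self.config.n_augment > 0:
            for _ in range(self.config.n_augment):
                feats.extend(self.embed(self._augmented(im, rng)) for im in images)
        return np.asarray(feats)

    # head -------------------------------------------------------------

    def _fit_head(self, F: np.ndarray, y: np.ndarray) -> None:
        self.feat_mean = F.mean(axis=0)
        self.feat_sd = np.where(F.std(axis=0) > 0, F.std(axis=0), 1.0)
        Z = (F - self.feat_mean) / self.feat_sd
        Z = np.hstack([Z, np.ones((len(Z), 1))])
        y_mean, y_sd = y.mean(), y.std() if y.std() > 0 else 1.0
        yz = (y - y_mean) / y_sd
        w = np.zeros(Z.shape[1])
        n = len(yz)
        for _ in range(self.config.epochs):
            grad = Z.T @ (Z @ w - yz) / n + self.config.weight_decay * w
            w -= self.config.learning_rate * grad
            if not np.isfinite(w).all():
                raise DivergenceError(f"NaN loss; config: {self.config}")
        self.head_w = w
        self._y_scale = (y_mean, y_sd)

    def fit(
        self, images: Sequence[MaskedImage], targets: Sequence[float], seed: int = 0
    ) -> "ImageRegressor":
        y = np.asarray(targets, dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("targets must be finite")
        rng = np.random.default_rng(seed)
        F = self.training_stream(images, rng)
        reps = len(F) // len(y)
        self._fit_head(F, np.tile(y, reps))
        return self

    def save(self, path) -> None:
        """Persist filters, head, and normalization to an .npz archive."""
        if self.head_w is None:
            raise RuntimeError("regressor is not fitted")
        import json

        np.savez(
            path,
            f1=self.f1,
            f2=self.f2,
            head_w=self.head_w,
            feat_mean=self.feat_mean,
            feat_sd=self.feat_sd,
            y_scale=np.array(self._y_scale),
            config=np.frombuffer(
                json.dumps(dataclasses.asdict(self.config)).encode(), dtype=np.uint8
            ),
        )

    @classmethod
    def load(cls, path) -> "ImageRegressor":
        import json

        data = np.load(path)
        raw = json.loads(bytes(data["config"]).decode())
        raw["n_filters"] = tuple(raw["n_filters"])
        raw["rotation_range"] = tuple(raw["rotation_range"])
        reg = cls(RegressorConfig(**raw))
        reg.f1, reg.f2 = data["f1"], data["f2"]
        reg.head_w = data["head_w"]
        reg.feat_mean, reg.feat_sd = data["feat_mean"], data["feat_sd"]
        reg._y_scale = tuple(data["y_scale"])
        return reg

    def predict(self, images: Sequence[MaskedImage]) -> np.ndarray:
        if self.head_w is None:
            raise RuntimeError("regressor is not fitted")
        F = np.asarray([self.embed(im) for im in images])
        Z = (F - self.feat_mean) / self.feat_sd
        Z = np.hstack([Z, np.ones((len(Z), 1))])
        y_mean, y_sd = self._y_scale
        return Z @ self.head_w * y_sd + y_mean


def _prediction_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation between predictions and targets (0 if flat)."""
    if y_true.std() == 0 or y_pred.std() == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)


@dataclasses.dataclass
class CvResult:
    fold_r2: dict[int, float]
    model: ImageRegressor

    @property
    def mean_r2(self) -> float:
        return float(np.mean(list(self.fold_r2.values())))


def train_image_regressor(
    images: Mapping[str, MaskedImage],
    targets: Mapping[str, float],
    plan: CvPlan,
    config: RegressorConfig | None = None,
    image_species_map: Mapping[str, str] | None = None,
) -> CvResult:
    """Species-grouped cross-validated training with a final refit on all data."""
    config = config or RegressorConfig()
    ids = list(images)
    y = np.array([float(targets[i]) for i in ids])
    if not np.isfinite(y).all():
        raise ValueError("targets must be finite")

    fold_r2 = {}
    for fold in range(1, plan.k + 1):
        val_ids = [i for i in ids if plan.fold_of(i) == fold]
        train_ids = [i for i in ids if plan.fold_of(i) != fold]
        if image_species_map is not None:
            n_val_species = len({image_species_map[i] for i in val_ids})
            if n_val_species < 2:
                raise ValueError(f"fold {fold} holds fewer than 2 species")
            overlap = {image_species_map[i] for i in val_ids} & {
                image_species_map[i] for i in train_ids
            }
            assert not overlap, f"species leak across fold {fold}: {overlap}"
        reg = ImageRegressor(config)
        reg.fit([images[i] for i in train_ids], [targets[i] for i in train_ids],
                seed=config.seed + fold)
        preds = reg.predict([images[i] for i in val_ids])
        fold_r2[fold] = _prediction_r2(
            np.array([targets[i] for i in val_ids]), preds
        )

    final = ImageRegressor(config)
    final.fit([images[i] for i in ids], y, seed=config.seed)
    return CvResult(fold_r2=fold_r2, model=final)


# ------------------------------------------------------- aggregation


def species_score(
    image_scores: Mapping[str, float],
    image_species_map: Mapping[str, str],
    mode: str = "max",
) -> pd.Series:
    """Aggregate image scores per species by max (default) or mean."""
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    unmapped = sorted(set(image_scores) - set(image_species_map))
    if unmapped:
        raise ValueError(f"images missing a species mapping: {unmapped}")
    df = pd.DataFrame(
        {
            "species": [image_species_map[i] for i in image_scores],
            "score": list(image_scores.values()),
        }
    )
    agg = df.groupby("species")["score"].agg(mode)
    agg.name = f"score_{mode}"
    return agg
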