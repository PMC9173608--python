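"""Evolutionary and ecological context metrics.

Species age (pendant branch length), fair-proportion evolutionary
distinctiveness, Pagel's lambda with a randomization p-value, Gower
functional distinctiveness on mixed-type traits, phylogenetic GLS with
harmonic-mean p combination across trees, and one-way ANOVA with Tukey
contrasts.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.libqsturng import psturng

from reefscore.phylo import tip_covariance

# ----------------------------------------------------------- tree metrics


def species_age(tree: dendropy.Tree) -> pd.Series:
    """Pendant branch length of each tip.

    On an ultrametric tree the root-to-tip distance is constant, so the
    terminal branch is what separates young from old species.
    """
    ages = {}
    for leaf in tree.leaf_node_iter():
        length = leaf.edge.length or 0.0
        if length == 0.0:
            import warnings

            warnings.warn(f"zero-length pendant branch for {leaf.taxon.label}",
                          stacklevel=2)
        ages[leaf.taxon.label] = float(length)
    return pd.Series(ages, name="age")


def evolutionary_distinctiveness(tree: dendropy.Tree) -> pd.Series:
    """Fair-proportion ED: each edge's length split equally among its tips."""
    if tree.seed_node is None:
        raise ValueError("tree must be rooted")
    ed: dict[str, float] = {}
    tip_sets: dict[dendropy.Node, list[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips = [node.taxon.label]
            ed.setdefault(node.taxon.label, 0.0)
        else:
            tips = [t for ch in node.child_nodes() for t in tip_sets[ch]]
        tip_sets[node] = tips
        if node.parent_node is not None and node.edge.length:
            share = node.edge.length / len(tips)
            for t in tips:
                ed[t] += share
    return pd.Series(ed, name="ed")


# -------------------------------------------------------- Pagel's lambda


@dataclasses.dataclass
class SignalResult:
    lambda_hat: float
    log_likelihood: float
    p_value: float
    n_permutations: int


def _profile_loglik_eig(w_base: np.ndarray, q1: np.ndarray, z: np.ndarray,
                        lam: float) -> np.ndarray:
    """Profile log-likelihood at lambda for eigen-decomposed covariance.

    ``w_base`` are eigenvalues of (C - I); covariance eigenvalues are
    lam * w_base + 1. ``q1`` is Q' 1 and ``z`` is Q' y (columns = datasets).
    Returns one log-likelihood per column of z.
    """
    vals = lam * w_base + 1.0
    if (vals <= 0).any():
        return np.full(z.shape[1] if z.ndim == 2 else 1, -np.inf)
    w = 1.0 / vals
    logdet = np.log(vals).sum()
    n = len(vals)
    denom = (w * q1**2).sum()
    mu = (w[:, None] * q1[:, None] * z).sum(axis=0) / denom
    resid = z - q1[:, None] * mu
    quad = (w[:, None] * resid**2).sum(axis=0)
    sigma2 = quad / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def _loglik_generic(C: np.ndarray, y: np.ndarray, lam: float) -> float:
    V = lam * C.copy()
    np.fill_diagonal(V, np.diag(C))
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        V = V + 1e-10 * np.eye(len(y))
        L = linalg.cholesky(V, lower=True)
    n = len(y)
    one = np.ones(n)
    a = linalg.solve_triangular(L, y, lower=True)
    b = linalg.solve_triangular(L, one, lower=True)
    mu = (b @ a) / (b @ b)
    r = a - mu * b
    sigma2 = (r @ r) / n
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def _maximize_lambda(loglik, tol: float = 1e-4) -> tuple[float, float]:
    """Maximize a scalar log-likelihood over [0, 1]; ties break toward 0."""
    res = optimize.minimize_scalar(
        lambda lam: -loglik(lam), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": tol},
    )
    candidates = [(loglik(0.0), 0.0), (loglik(1.0), 1.0), (-res.fun, float(res.x))]
    best_ll = max(c[0] for c in candidates)
    # smallest lambda within numerical tie of the optimum
    lam_hat = min(lam for ll, lam in candidates if ll >= best_ll - 1e-9)
    return lam_hat, best_ll


def pagels_lambda(
    tree: dendropy.Tree,
    trait: Mapping[str, float] | Sequence[float],
    n_perm: int = 999,
    seed: int = 0,
    lambda_grid_step: float = 0.01,
) -> SignalResult:
    """ML estimate of Pagel's lambda with a tip-permutation p-value.

    The covariance under lambda keeps the diagonal of the Brownian matrix
    and scales off-diagonals by lambda; mean and sigma^2 are profiled out
    of the multivariate-normal likelihood. The p-value is the add-one
    permutation rank of the observed likelihood gain over lambda = 0,
    with randomized tie-breaking: the gain statistic sits on the boundary
    (an atom at exactly 0 under the null), and the randomized construction
    is what makes the permutation p-value exactly uniform there.
    """
    C, labels = tip_covariance(tree)
    if isinstance(trait, Mapping):
        y = np.array([float(trait[lb]) for lb in labels])
    else:
        y = np.asarray(trait, dtype=float)
        if len(y) != len(labels):
            raise ValueError("trait length must match tip count")
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 tips")

    diag = np.diag(C)
    eig_path = np.allclose(diag, diag[0], rtol=0, atol=1e-8)
    if eig_path:
        scale = diag[0]
        B = C / scale - np.eye(n)  # C_lam/scale = lam*B + I
        w_base, Q = np.linalg.eigh(B)
        q1 = Q.T @ np.ones(n)

        def loglik(lam: float, yy: np.ndarray = y) -> float:
            z = (Q.T @ yy)[:, None]
            # scale factor contributes a lambda-free constant; fold it in
            ll = _profile_loglik_eig(w_base, q1, z, lam)[0]
            return float(ll - 0.5 * n * np.log(scale))

    else:

        def loglik(lam: float, yy: np.ndarray = y) -> float:
            return _loglik_generic(C, yy, lam)

    lam_hat, ll_hat = _maximize_lambda(loglik)
    stat_obs = ll_hat - loglik(0.0)

    rng = np.random.default_rng(seed)
    if n_perm > 0:
        grid = np.arange(0.0, 1.0 + 1e-9, lambda_grid_step)
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
        if eig_path:
            Zp = Q.T @ perms
            ll_grid = np.stack(
                [_profile_loglik_eig(w_base, q1, Zp, lam) for lam in grid]
            )
            stats_perm = ll_grid.max(axis=0) - ll_grid[0]
        else:
            stats_perm = np.empty(n_perm)
            for b in range(n_perm):
                yb = perms[:, b]
                lls = [_loglik_generic(C, yb, lam) for lam in grid]
                stats_perm[b] = max(lls) - lls[0]
        tol = 1e-12
        n_greater = int((stats_perm > stat_obs + tol).sum())
        n_tied = int((np.abs(stats_perm - stat_obs) <= tol).sum())
        u = rng.random()
        p = (n_greater + u * (n_tied + 1)) / (n_perm + 1)
    else:
        p = 1.0
    return SignalResult(
        lambda_hat=float(lam_hat),
        log_likelihood=float(ll_hat),
        p_value=float(p),
        n_permutations=n_perm,
    )


# --------------------------------------------------- Gower distinctiveness


def gower_matrix(traits: pd.DataFrame, column_types: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise Gower distances with equal column weights.

    numeric: range-normalized absolute difference; categorical: 0/1
    mismatch; ordinal: rank-scaled absolute difference. Missing entries
    are handled by reweighting the observed columns of each pair.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 species")
    n = len(traits)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in traits.columns:
        ctype = column_types[col]
        vals = traits[col]
        if vals.isna().all():
            raise ValueError(f"column {col!r} is entirely missing")
        obs = ~vals.isna().to_numpy()
        pair_obs = obs[:, None] & obs[None, :]
        if ctype == "categorical":
            v = vals.to_numpy(dtype=object)
            d = (v[:, None] != v[None, :]).astype(float)
        else:
            x = vals.to_numpy(dtype=float)
            if ctype == "ordinal":
                # rank-scale: average ranks mapped to [0, 1]
                ranks = vals.rank(method="average").to_numpy(dtype=float)
                x = ranks
            rng_ = np.nanmax(x) - np.nanmin(x)
            if rng_ == 0:
                d = np.zeros((n, n))
            else:
                d = np.abs(x[:, None] - x[None, :]) / rng_
        d = np.where(pair_obs, np.nan_to_num(d), 0.0)
        num += d
        den += pair_obs.astype(float)
    if (den == 0).any():
        raise ValueError("some species pairs share no observed traits")
    D = num / den
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=traits.index, columns=traits.index)


def gower_distinctiveness(
    traits: pd.DataFrame, column_types: Mapping[str, str]
) -> pd.Series:
    """Functional distinctiveness: mean Gower distance to all other species."""
    D = gower_matrix(traits, column_types)
    n = len(D)
    di = (D.sum(axis=1)) / (n - 1)
    di.name = "di"
    return di


# ----------------------------------------------------------------- PGLS


@dataclasses.dataclass
class PglsResult:
    slope: float
    intercept: float
    se: float
    t: float
    p_value: float


def pgls_slope(
    tree: dendropy.Tree,
    x: Mapping[str, float] | Sequence[float],
    y: Mapping[str, float] | Sequence[float],
) -> PglsResult:
    """GLS regression of y on x with Brownian covariance from the tree."""
    C, labels = tip_covariance(tree)
    if isinstance(x, Mapping):
        xv = np.array([float(x[lb]) for lb in labels])
    else:
        xv = np.asarray(x, dtype=float)
    if isinstance(y, Mapping):
        yv = np.array([float(y[lb]) for lb in labels])
    else:
        yv = np.asarray(y, dtype=float)
    n = len(labels)
    if len(xv) != n or len(yv) != n:
        raise ValueError("x and y must align with the tree tips")
    try:
        L = linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance is not positive definite") from exc
    X = np.column_stack([np.ones(n), xv])
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, yv, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = float(np.sqrt(cov_beta[1, 1]))
    t = float(beta[1] / se)
    p = float(2 * stats.t.sf(abs(t), dof))
    return PglsResult(slope=float(beta[1]), intercept=float(beta[0]),
                      se=se, t=t, p_value=p)


def harmonic_mean_p(p_values: Sequence[float]) -> float:
    """Unweighted harmonic-mean combination: n / sum(1/p_i)."""
    p = np.asarray(p_values, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(len(p) / (1.0 / p).sum())


def pgls_over_trees(
    trees: Sequence[dendropy.Tree],
    x: Mapping[str, float],
    y: Mapping[str, float],
) -> tuple[pd.DataFrame, float]:
    """Per-tree PGLS plus the harmonic-mean combined p-value."""
    rows = []
    for i, tree in enumerate(trees):
        r = pgls_slope(tree, x, y)
        rows.append({"tree": i, "slope": r.slope, "se": r.se, "p": r.p_value})
    df = pd.DataFrame(rows)
    return df, harmonic_mean_p(df["p"].to_numpy())


# ------------------------------------------------------- group contrasts


@dataclasses.dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # symmetric matrix of pairwise adjusted p-values


def group_compare(values: Sequence[float], groups: Sequence[str]) -> GroupComparison:
    """One-way ANOVA plus Tukey HSD pairwise contrasts."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    names = sorted(set(g))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = [v[g == name] for name in names]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 members")
    f_stat, p = stats.f_oneway(*samples)

    # Tukey HSD via the studentized-range distribution
    k = len(names)
    dof = len(v) - k
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / dof
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(samples[i]), len(samples[j])
            se = np.sqrt(mse / 2 * (1 / ni + 1 / nj))
            q = abs(samples[i].mean() - samples[j].mean()) / se
            padj = float(np.atleast_1d(psturng(q, k, dof))[0])
            pmat.iloc[i, j] = pmat.iloc[j, i] = padj
    return GroupComparison(f_statistic=float(f_stat), p_value=float(p), tukey=pmat)
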