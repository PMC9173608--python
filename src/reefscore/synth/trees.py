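"""Simulated phylogenies with lambda-structured Brownian tip traits."""

from __future__ import annotations

import random

import dendropy
import numpy as np
from dendropy.model import birthdeath

from reefscore.phylo import scale_to_unit_depth, tip_covariance


def simulate_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips, scaled to unit depth."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    py_rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=py_rng,
    )
    # The simulator stops at the nth speciation, leaving the newest tips
    # with zero-length pendant edges (which make the tip covariance
    # singular). Run the clock forward by one more exponential waiting
    # time, which preserves ultrametricity.
    extra = py_rng.expovariate(1.0 * n_tips)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    if tree.seed_node.edge is not None:
        tree.seed_node.edge.length = None  # no stem above the root
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    return scale_to_unit_depth(tree)


def lambda_covariance(C: np.ndarray, lam: float) -> np.ndarray:
    """Keep the diagonal of C and multiply off-diagonals by lambda."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    C_lam = lam * C
    np.fill_diagonal(C_lam, np.diag(C))
    return C_lam


def simulate_trait_on_tree(
    tree: dendropy.Tree,
    lambda_true: float,
    sigma2: float,
    seed: int,
    n_replicates: int = 1,
) -> tuple[np.ndarray, list[str]]:
    """Draw tip traits ~ MVN(0, sigma2 * C_lambda) on an existing tree.

    Returns (traits, labels); traits has shape (n_replicates, n_tips).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    C, labels = tip_covariance(tree)
    cov = sigma2 * lambda_covariance(C, lambda_true)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(labels)))
    rng = np.random.default_rng(seed)
    traits = rng.standard_normal((n_replicates, len(labels))) @ L.T
    return traits, labels


def simulate_tree_with_trait(
    n_tips: int, lambda_true: float, sigma2: float, seed: int
) -> tuple[dendropy.Tree, np.ndarray, list[str]]:
    """Simulate a unit-depth pure-birth tree plus one lambda-structured trait."""
    tree = simulate_tree(n_tips, seed)
    traits, labels = simulate_trait_on_tree(tree, lambda_true, sigma2, seed)
    return tree, traits[0], labels
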