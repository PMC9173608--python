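"""Simulated pairwise judgments from latent scores.

The choice model is the same base-10/400 logistic the Elo update assumes,
so latent scores and recovered ratings share a scale and recovery tests
are well posed.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from reefscore.elo import Match


def win_probability(s_i: float, s_j: float) -> float:
    """P(item i beats item j) under the logistic choice model."""
    return 1.0 / (1.0 + 10.0 ** ((s_j - s_i) / 400.0))


def simulate_matches(
    scores: Mapping[str, float], n_matches: int, seed: int
) -> list[Match]:
    """Sample matches between uniformly drawn distinct pairs.

    Each match draws an unordered pair (i, j) uniformly without
    self-pairing; i wins with the logistic expectancy of the latent score
    difference.
    """
    if n_matches < 1:
        raise ValueError("n_matches must be >= 1")
    ids = list(scores)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 items to simulate matches")
    vals = np.array([float(scores[i]) for i in ids])
    if not np.isfinite(vals).all():
        raise ValueError("latent scores must be finite")

    rng = np.random.default_rng(seed)
    i_idx = rng.integers(0, n, size=n_matches)
    j_idx = rng.integers(0, n - 1, size=n_matches)
    j_idx[j_idx >= i_idx] += 1  # uniform over j != i

    diff = vals[j_idx] - vals[i_idx]
    with np.errstate(over="ignore"):  # extreme gaps saturate to p = 0 or 1
        p_i_wins = 1.0 / (1.0 + 10.0 ** (diff / 400.0))
    i_wins = rng.random(n_matches) < p_i_wins

    out = []
    for ii, jj, w in zip(i_idx, j_idx, i_wins):
        if w:
            out.append(Match(winner_id=ids[ii], loser_id=ids[jj]))
        else:
            out.append(Match(winner_id=ids[jj], loser_id=ids[ii]))
    return out
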