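"""Elo rating of items from pairwise matches.

Ratings are replayed from a common start value over many uniformly
randomized orderings of the match list ("mElo"): the per-item mean over
replays removes the order dependence of sequential Elo updating, and the
per-item SD quantifies what order sensitivity remains.

The k-factor and start value are assumptions, not published constants;
both are exposed on :class:`RatingConfig`.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass(frozen=True)
class Match:
    """One pairwise outcome: ``winner_id`` beat ``loser_id``."""

    winner_id: str
    loser_id: str
    judge_id: str | None = None

    def __post_init__(self) -> None:
        if self.winner_id == self.loser_id:
            raise ValueError("winner and loser must differ")


@dataclasses.dataclass
class RatingConfig:
    start_value: float = 1500.0
    k_factor: float = 100.0
    n_randomizations: int = 1000
    seed: int = 0
    # When True, each replay resamples matches with replacement instead of
    # permuting the full list.
    bootstrap: bool = False

    def __post_init__(self) -> None:
        if self.k_factor <= 0:
            raise ValueError("k_factor must be positive")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")


@dataclasses.dataclass
class RatingResult:
    """Per-item mean rating (mElo) and SD over randomized replays."""

    ratings: pd.DataFrame  # columns: item_id, melo, sd
    config: RatingConfig
    n_matches: int

    def melo(self, item_id: str) -> float:
        sub = self.ratings.loc[self.ratings["item_id"] == item_id, "melo"]
        if sub.empty:
            raise KeyError(f"unknown item: {item_id!r}")
        return float(sub.iloc[0])

    def to_csv(self, path) -> None:
        self.ratings.to_csv(path, index=False)


def expected_score(r_a: float, r_b: float) -> float:
    """Logistic win expectancy of A against B on the base-10/400 scale."""
    return 1.0 / (1.0 + 10.0 ** ((r_b - r_a) / 400.0))


def elo_update(r_winner: float, r_loser: float, k: float) -> tuple[float, float]:
    """One Elo update; the winner's gain equals the loser's loss."""
    if not (np.isfinite(r_winner) and np.isfinite(r_loser)):
        raise ValueError("ratings must be finite")
    if not (np.isfinite(k) and k > 0):
        raise ValueError("k must be finite and positive")
    gain = k * (1.0 - expected_score(r_winner, r_loser))
    return r_winner + gain, r_loser - gain


def _as_index_arrays(matches: Sequence[Match]) -> tuple[list, np.ndarray, np.ndarray]:
    items: dict[str, int] = {}
    w_idx = np.empty(len(matches), dtype=np.int64)
    l_idx = np.empty(len(matches), dtype=np.int64)
    for t, m in enumerate(matches):
        w_idx[t] = items.setdefault(m.winner_id, len(items))
        l_idx[t] = items.setdefault(m.loser_id, len(items))
    return list(items), w_idx, l_idx


def rate_items(
    matches: Sequence[Match],
    config: RatingConfig | None = None,
    chunk_size: int = 200,
) -> RatingResult:
    """Estimate mElo scores by replaying randomized orderings of the matches.

    Each replay starts every item at ``start_value`` and applies the Elo
    update match by match in a freshly shuffled order; final ratings are
    averaged over ``n_randomizations`` replays. Replays are vectorized
    across randomizations in chunks to bound memory.
    """
    if config is None:
        config = RatingConfig()
    matches = list(matches)
    if not matches:
        raise ValueError("match list is empty")
    item_ids, w_idx, l_idx = _as_index_arrays(matches)
    n_items, n_matches = len(item_ids), len(matches)
    rng = np.random.default_rng(config.seed)

    sum_r = np.zeros(n_items)
    sum_r2 = np.zeros(n_items)
    remaining = config.n_randomizations
    while remaining > 0:
        n_rep = min(chunk_size, remaining)
        remaining -= n_rep
        if config.bootstrap:
            order = rng.integers(0, n_matches, size=(n_rep, n_matches))
        else:
            order = np.argsort(rng.random((n_rep, n_matches)), axis=1)
        ratings = np.full((n_rep, n_items), config.start_value, dtype=float)
        rows = np.arange(n_rep)
        for t in range(n_matches):
            mi = order[:, t]
            wi, li = w_idx[mi], l_idx[mi]
            rw = ratings[rows, wi]
            rl = ratings[rows, li]
            gain = config.k_factor * (1.0 - 1.0 / (1.0 + 10.0 ** ((rl - rw) / 400.0)))
            ratings[rows, wi] = rw + gain
            ratings[rows, li] = rl - gain
        sum_r += ratings.sum(axis=0)
        sum_r2 += (ratings**2).sum(axis=0)

    n = config.n_randomizations
    melo = sum_r / n
    var = np.maximum(sum_r2 / n - melo**2, 0.0)
    df = pd.DataFrame({"item_id": item_ids, "melo": melo, "sd": np.sqrt(var)})
    return RatingResult(ratings=df, config=config, n_matches=n_matches)


@dataclasses.dataclass
class Calibration:
    """OLS mapping from an old score scale onto a new one."""

    slope: float
    intercept: float
    r2: float

    def apply(self, old_scores: Iterable[float]) -> np.ndarray:
        return self.slope * np.asarray(old_scores, dtype=float) + self.intercept


def calibrate_scales(
    shared_scores_old: Sequence[float], shared_scores_new: Sequence[float]
) -> Calibration:
    """Regress new-survey scores on old-survey scores over shared items."""
    old = np.asarray(shared_scores_old, dtype=float)
    new = np.asarray(shared_scores_new, dtype=float)
    if old.shape != new.shape:
        raise ValueError("shared score vectors must have equal length")
    if old.size < 3:
        raise ValueError("need at least 3 shared items")
    if np.ptp(old) == 0:
        raise ValueError("degenerate fit: old scores have zero variance")
    fit = stats.linregress(old, new)
    return Calibration(slope=float(fit.slope), intercept=float(fit.intercept),
                       r2=float(fit.rvalue**2))


# ------------------------------------------------------------------- I/O

def matches_to_csv(matches: Sequence[Match], path) -> None:
    pd.DataFrame(
        {
            "winner_id": [m.winner_id for m in matches],
            "loser_id": [m.loser_id for m in matches],
            "judge_id": [m.judge_id if m.judge_id is not None else "" for m in matches],
        }
    ).to_csv(path, index=False)


def matches_from_csv(path) -> list[Match]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        Match(
            winner_id=row.winner_id,
            loser_id=row.loser_id,
            judge_id=row.judge_id or None,
        )
        for row in df.itertuples()
    ]
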