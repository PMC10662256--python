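"""Network-vs-model residual analysis, behavioral summary statistics and Elo.

The central tool is the KL divergence between two move policies on the same
position, KL(reference || model): positions where a well-calibrated
reference (a trained network, or a generator standing in for it) assigns
probability mass that the candidate model does not are the model's residuals,
and ranking positions by KL surfaces systematic model failures.  The module
also computes the per-move behavioral summary statistics (distances to the
board center, to own/opponent pieces and their centers of mass, neighbor
counts, threat creation/parrying), sequential Elo ratings, NLL broken down
by group, and paired per-move log-likelihood comparisons between scorers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .board import (
    Board, DRAW, MoveObservation, P1_WIN, P2_WIN, GameRecord, apply_move,
    legal_moves,
)
from .features import threat_squares
from .agent import ModelParams, estimate_policy
from .network import PolicyNetwork

PolicyProvider = Callable[[Board, int], np.ndarray]


def _as_provider(source, n_sims: int = 200,
                 rng: Optional[np.random.Generator] = None,
                 alpha: float = 0.0) -> PolicyProvider:
    """Normalize networks / ModelParams / callables into a policy provider."""
    if isinstance(source, PolicyNetwork):
        return source.policy
    if isinstance(source, ModelParams):
        local = rng if rng is not None else np.random.default_rng()

        def provider(board: Board, mover: int) -> np.ndarray:
            return estimate_policy(board, mover, source, n_sims=n_sims,
                                   rng=local, alpha=alpha)
        return provider
    if callable(source):
        return source
    raise TypeError(f"cannot build a policy provider from {type(source)!r}")


def kl_divergence(p: np.ndarray, q: np.ndarray,
                  legal: Optional[np.ndarray] = None,
                  epsilon: float = 1e-4) -> float:
    """KL(p || q) over legal squares, with an epsilon mass floor on q.

    ``q`` gets ``epsilon`` added on every legal square and is renormalized
    (guarding against zeros from finite simulation); ``0 * log 0 = 0``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if legal is None:
        legal = (p > 0) | (q > 0)
    else:
        legal = np.asarray(legal, dtype=bool)
        if (p[~legal] != 0).any() or (q[~legal] != 0).any():
            raise ValueError("policy has mass outside the legal mask")
    ps = p[legal]
    qs = q[legal] + epsilon
    qs = qs / qs.sum()
    ps = ps / ps.sum()
    nz = ps > 0
    return float(np.sum(ps[nz] * np.log(ps[nz] / qs[nz])))


@dataclass
class ResidualRecord:
    board: Board
    mover: int
    kl: float
    nll_model: float
    nll_network: float
    human_move: Optional[int] = None


def rank_residuals(positions: Sequence[Union[MoveObservation, tuple]],
                   reference, model_params: ModelParams,
                   n_sims: int = 200,
                   rng: Optional[np.random.Generator] = None,
                   epsilon: float = 1e-4,
                   alpha: float = 0.5) -> list[ResidualRecord]:
    """Positions sorted by descending KL(reference || model policy).

    ``positions`` are MoveObservations or (board, mover) pairs; ``reference``
    is a PolicyNetwork, ModelParams or callable.  The model policy is the
    empirical distribution of ``n_sims`` simulated moves (pseudocount
    ``alpha``).  When observations carry the chosen move, per-position NLLs
    under both policies are recorded.
    """
    rng = rng if rng is not None else np.random.default_rng()
    base_seed = int(rng.integers(2**31))
    records = []
    for pos in positions:
        if isinstance(pos, MoveObservation):
            board, mover, chosen = pos.board, pos.mover, pos.chosen
        else:
            board, mover = pos
            chosen = None
        # per-position stream keyed by content, so the ranking is invariant
        # to the order in which positions are supplied
        s1, s2 = board.to_strings()
        pos_rng = np.random.default_rng(
            [base_seed, zlib.crc32(f"{s1}|{s2}|{mover}".encode())])
        ref = _as_provider(reference, n_sims=n_sims, rng=pos_rng, alpha=alpha)
        p = ref(board, mover)
        q = estimate_policy(board, mover, model_params, n_sims=n_sims,
                            rng=pos_rng, alpha=alpha)
        occupied = np.zeros(board.geometry.n_squares, dtype=bool)
        occupied[list(board.p1 | board.p2)] = True
        kl = kl_divergence(p, q, legal=~occupied, epsilon=epsilon)
        nll_m = float(-np.log(q[chosen] + epsilon)) if chosen is not None else np.nan
        nll_n = float(-np.log(p[chosen] + epsilon)) if chosen is not None else np.nan
        records.append(ResidualRecord(board, mover, kl, nll_m, nll_n, chosen))
    records.sort(key=lambda r: -r.kl)
    return records


def residuals_to_frame(records: Iterable[ResidualRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        s1, s2 = r.board.to_strings()
        rows.append({"board_p1": s1, "board_p2": s2, "mover": r.mover,
                     "kl": r.kl, "nll_model": r.nll_model,
                     "nll_network": r.nll_network, "human_move": r.human_move})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Behavioral summary statistics
# --------------------------------------------------------------------------

def move_statistics(board: Board, mover: int, square: int) -> dict:
    """Per-move behavioral statistics for one chosen square.

    Distances are Euclidean on grid coordinates; "distance to pieces" is the
    minimum over pieces; statistics that need at least one own/opponent piece
    are NaN when no such pieces exist and are omitted from bin averages.
    """
    g = board.geometry
    r, c = g.coords(square)
    own = np.array(sorted(board.pieces(mover)), dtype=np.int64)
    opp = np.array(sorted(board.pieces(3 - mover)), dtype=np.int64)

    def dists(pieces):
        if pieces.size == 0:
            return None
        rows, cols = np.divmod(pieces, g.cols)
        return np.hypot(rows - r, cols - c)

    def com_dist(pieces):
        if pieces.size == 0:
            return np.nan
        rows, cols = np.divmod(pieces, g.cols)
        return float(np.hypot(rows.mean() - r, cols.mean() - c))

    d_own, d_opp = dists(own), dists(opp)
    neigh = [g.index(r + dr, c + dc)
             for dr in (-1, 0, 1) for dc in (-1, 0, 1)
             if (dr or dc) and 0 <= r + dr < g.rows and 0 <= c + dc < g.cols]
    after = apply_move(board, mover, square) if mover == board.mover else None
    makes = (len(threat_squares(after, mover)) > 0) if after is not None else np.nan
    return {
        "dist_center": float(np.hypot(r - g.center[0], c - g.center[1])),
        "dist_own": float(d_own.min()) if d_own is not None else np.nan,
        "dist_opp": float(d_opp.min()) if d_opp is not None else np.nan,
        "dist_own_com": com_dist(own),
        "dist_opp_com": com_dist(opp),
        "n_own_neighbors": int(sum(s in board.pieces(mover) for s in neigh)),
        "n_opp_neighbors": int(sum(s in board.pieces(3 - mover) for s in neigh)),
        "makes_threat": float(makes),
        "parries_threat": float(square in threat_squares(board, 3 - mover)),
    }

STATISTIC_NAMES = ("dist_center", "dist_own", "dist_opp", "dist_own_com",
                   "dist_opp_com", "n_own_neighbors", "n_opp_neighbors",
                   "makes_threat", "parries_threat")


def summary_statistics(moves: Sequence[MoveObservation],
                       chooser: Optional[Callable] = None,
                       rng: Optional[np.random.Generator] = None,
                       source: str = "data") -> pd.DataFrame:
    """Behavioral summary statistics averaged within move-number bins.

    With ``chooser=None`` the observed (data) moves are scored; otherwise
    ``chooser(board, mover, rng)`` supplies the move in each position —
    pass e.g. a policy sampler for an agent/network, or
    :func:`random_chooser` for the uniform-random reference.  Returns a long
    DataFrame: move_number, statistic, source, mean, sem, n.
    """
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    for ob in moves:
        sq = ob.chosen if chooser is None else chooser(ob.board, ob.mover, rng)
        st = move_statistics(ob.board, ob.mover, sq)
        st["move_number"] = ob.move_number
        rows.append(st)
    df = pd.DataFrame(rows)
    long = df.melt(id_vars="move_number", var_name="statistic", value_name="value")
    long = long.dropna(subset=["value"])
    agg = (long.groupby(["move_number", "statistic"])["value"]
           .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
                n="size")
           .reset_index())
    agg.insert(2, "source", source)
    return agg


def random_chooser(board: Board, mover: int, rng: np.random.Generator) -> int:
    legal = sorted(legal_moves(board))
    return int(legal[rng.integers(len(legal))])


# --------------------------------------------------------------------------
# Elo ratings
# --------------------------------------------------------------------------

@dataclass
class EloTable:
    ratings: dict
    games_played: dict

    def rating(self, player_id: str) -> float:
        return self.ratings[player_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"player_id": list(self.ratings),
             "rating": [self.ratings[p] for p in self.ratings],
             "games_played": [self.games_played[p] for p in self.ratings]})


def elo_ratings(games: Iterable[GameRecord], k_factor: float = 32.0,
                initial: float = 1500.0) -> EloTable:
    """Sequential Elo updates in game order; draws score 0.5.

    Unfinished games are skipped.  With equal K for both players the total
    rating mass is conserved per game.
    """
    ratings: dict = {}
    played: dict = {}
    for game in games:
        if game.outcome not in (P1_WIN, P2_WIN, DRAW):
            continue
        a, b = game.player_ids
        ra = ratings.setdefault(a, initial)
        rb = ratings.setdefault(b, initial)
        played.setdefault(a, 0)
        played.setdefault(b, 0)
        ea = 1.0 / (1.0 + 10.0 ** ((rb - ra) / 400.0))
        sa = {P1_WIN: 1.0, P2_WIN: 0.0, DRAW: 0.5}[game.outcome]
        ratings[a] = ra + k_factor * (sa - ea)
        ratings[b] = rb + k_factor * ((1.0 - sa) - (1.0 - ea))
        played[a] += 1
        played[b] += 1
    return EloTable(ratings, played)


def elo_quantile_bins(table: EloTable, n_bins: int = 5) -> pd.Series:
    """Quantile-bin player ratings; returns player_id -> bin index (0 = weakest)."""
    df = table.to_frame()
    bins = pd.qcut(df["rating"].rank(method="first"), q=n_bins, labels=False)
    return pd.Series(bins.values, index=df["player_id"].values, name="elo_bin")


# --------------------------------------------------------------------------
# Grouped NLL and paired comparisons
# --------------------------------------------------------------------------

def score_trials(trials: Sequence[MoveObservation], scorer,
                 n_sims: int = 200, rng: Optional[np.random.Generator] = None,
                 alpha: float = 0.5, epsilon: float = 1e-12) -> pd.DataFrame:
    """Per-trial log-likelihood and top-1 hit under any policy provider."""
    provider = _as_provider(scorer, n_sims=n_sims, rng=rng, alpha=alpha)
    rows = []
    for ob in trials:
        pol = provider(ob.board, ob.mover)
        rows.append({"move_number": ob.move_number, "player_id": ob.player_id,
                     "loglik": float(np.log(pol[ob.chosen] + epsilon)),
                     "hit": float(np.argmax(pol) == ob.chosen)})
    return pd.DataFrame(rows)


def nll_by_group(trials: Sequence[MoveObservation], scorer,
                 grouping: Union[str, Sequence] = "move_number",
                 n_sims: int = 200, rng: Optional[np.random.Generator] = None,
                 alpha: float = 0.5) -> pd.DataFrame:
    """Mean NLL and accuracy per group; ``grouping`` is 'move_number' or labels."""
    df = score_trials(trials, scorer, n_sims=n_sims, rng=rng, alpha=alpha)
    if isinstance(grouping, str):
        if grouping == "move_number":
            labels = df["move_number"]
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
    else:
        labels = pd.Series(list(grouping), name="group")
        if len(labels) != len(df):
            raise ValueError("grouping labels length mismatch")
    out = (df.assign(group=labels.values, nll=-df["loglik"])
           .groupby("group")
           .agg(n=("nll", "size"), nll=("nll", "mean"), accuracy=("hit", "mean"))
           .reset_index())
    return out


def paired_ll_comparison(trials: Sequence[MoveObservation], scorer_a, scorer_b,
                         n_sims: int = 200, seed: Optional[int] = None,
                         alpha: float = 0.5) -> dict:
    """Paired per-move log-likelihood difference (a minus b): mean, SEM, t, p.

    Both scorers are evaluated on identical trials with identically seeded
    simulation streams.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    lla = score_trials(trials, scorer_a, n_sims=n_sims,
                       rng=np.random.default_rng(s1), alpha=alpha)["loglik"]
    llb = score_trials(trials, scorer_b, n_sims=n_sims,
                       rng=np.random.default_rng(s1), alpha=alpha)["loglik"]
    diff = (lla - llb).to_numpy()
    mean = float(diff.mean())
    sem = float(diff.std(ddof=1) / np.sqrt(len(diff))) if len(diff) > 1 else 0.0
    t = mean / sem if sem > 0 else 0.0
    pval = float(2 * stats.t.sf(abs(t), df=len(diff) - 1)) if len(diff) > 1 and sem > 0 else 1.0
    return {"mean_diff": mean, "sem": sem, "t_statistic": float(t),
            "p_value": pval, "n": len(diff)}
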