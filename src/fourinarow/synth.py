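"""Synthetic self-play game logs, population simulation, splits and fixtures.

The proprietary behavioral dataset behind the original study is not
redistributable, so analyses here run on self-play logs: player 1 ("user")
uses one parameterization of the planning agent and always moves first
against an AI opponent using another.  A population simulator draws
per-player lapse rates and weight scales to create skill heterogeneity for
Elo and playing-strength analyses, recording the ground-truth parameters so
parameter-recovery studies can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .board import (
    Board, GameRecord, ONGOING, UNFINISHED, apply_move, is_terminal,
)
from .agent import ModelParams, sample_move
from .fitting import DEFAULT_BOUNDS

DEFAULT_USER_PARAMS = ModelParams()
DEFAULT_AI_PARAMS = ModelParams(lam=0.05, gamma=0.15, delta=0.1)


def self_play(user_params: ModelParams, ai_params: ModelParams, n_games: int,
              rng: np.random.Generator, game_id_prefix: str = "g",
              player_ids: tuple = ("user", "ai"),
              max_plies: int = 36) -> list[GameRecord]:
    """Play ``n_games`` full games; player 1 uses ``user_params``, player 2 ``ai_params``."""
    records = []
    for g in range(n_games):
        board = Board()
        moves = []
        status = ONGOING
        for ply in range(max_plies):
            status = is_terminal(board)
            if status != ONGOING:
                break
            mover = board.mover
            params = user_params if mover == 1 else ai_params
            sq = sample_move(board, mover, params, rng)
            moves.append((ply, mover, sq))
            board = apply_move(board, mover, sq)
        status = is_terminal(board)
        outcome = status if status != ONGOING else UNFINISHED
        records.append(GameRecord(
            game_id=f"{game_id_prefix}{g:06d}", moves=tuple(moves),
            outcome=outcome, player_ids=player_ids))
    return records


@dataclass
class PopulationSpec:
    """Skill-heterogeneous user population played against a fixed AI.

    Per player, the lapse rate is drawn log-uniformly in ``lam_range`` and
    all feature weights are scaled by a common log-uniform factor in
    ``weight_scale_range`` (stronger players lapse less and weigh features
    more sharply relative to the unit evaluation noise).  Draws are clipped
    to the fitting bounds.
    """

    n_players: int = 20
    base_params: ModelParams = field(default_factory=lambda: DEFAULT_USER_PARAMS)
    ai_params: ModelParams = field(default_factory=lambda: DEFAULT_AI_PARAMS)
    lam_range: tuple = (0.02, 0.4)
    weight_scale_range: tuple = (0.5, 2.0)

    def draw_player(self, rng: np.random.Generator) -> ModelParams:
        lam = float(np.exp(rng.uniform(*np.log(self.lam_range))))
        scale = float(np.exp(rng.uniform(*np.log(self.weight_scale_range))))
        b = self.base_params
        kw = {}
        for name in ("w_conn2", "w_unconn2", "w_three", "w_four", "w_center"):
            lo, hi = DEFAULT_BOUNDS[name]
            kw[name] = float(np.clip(getattr(b, name) * scale, lo, hi))
        kw["lam"] = float(np.clip(lam, *DEFAULT_BOUNDS["lam"]))
        return b.evolve(**kw)


def simulate_population(spec: PopulationSpec, games_per_player: int,
                        rng: np.random.Generator):
    """Self-play logs for every player plus a ground-truth parameter table."""
    records = []
    rows = []
    for i in range(spec.n_players):
        pid = f"player{i:03d}"
        params = spec.draw_player(rng)
        games = self_play(params, spec.ai_params, games_per_player, rng,
                          game_id_prefix=f"{pid}_g", player_ids=(pid, "ai"))
        records.extend(games)
        row = {"player_id": pid, "lam": params.lam, "gamma": params.gamma,
               "delta": params.delta}
        row.update({k: getattr(params, k) for k in
                    ("w_conn2", "w_unconn2", "w_three", "w_four", "w_center")})
        rows.append(row)
    return records, pd.DataFrame(rows)


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple
    validation: tuple
    test: tuple

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


def make_splits(game_ids: Sequence, fractions: tuple = (0.90, 0.05, 0.05),
                rng: Optional[np.random.Generator] = None) -> DatasetSplit:
    """Shuffled train/validation/test split.

    The two held-out partitions take the floor of their fractions and
    training takes the remainder, reproducing exact published partition
    sizes from a printed total.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = np.asarray(game_ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 games to split")
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    rng = rng if rng is not None else np.random.default_rng()
    order = rng.permutation(n)
    val = ids[order[:n_val]]
    test = ids[order[n_val:n_val + n_test]]
    train = ids[order[n_val + n_test:]]
    return DatasetSplit(tuple(train.tolist()), tuple(val.tolist()),
                        tuple(test.tolist()))


def split_sizes(n: int, fractions: tuple = (0.90, 0.05, 0.05)) -> tuple[int, int, int]:
    """Partition sizes only (train, validation, test) for a total of ``n`` games."""
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    return (n - n_val - n_test, n_val, n_test)


def fixture_boards() -> dict:
    """Named deterministic positions exercising the model's edge cases.

    Every fixture is a valid ongoing position with player 1 to move:

    * ``own_immediate_win``       — player 1 can complete a four,
    * ``opponent_immediate_threat`` — player 2 threatens a four, player 1 has
      no win of their own,
    * ``double_threat``           — player 2 threatens on two squares,
    * ``corner_opening``          — the empty board,
    * ``phantom_edge_triple``     — player 1 holds a corner-diagonal triple
      that cannot be completed to four,
    * ``pruning_trap``            — a tempting offensive cluster for player 1
      while player 2 threatens an immediate win elsewhere,
    * ``midgame_neutral``         — a quiet position with no threats.
    """
    def rc(r, c):
        return 9 * r + c

    boards = {
        "own_immediate_win": Board(
            p1=frozenset({rc(0, 0), rc(0, 1), rc(0, 2)}),
            p2=frozenset({rc(2, 4), rc(2, 5), rc(3, 7)})),
        "opponent_immediate_threat": Board(
            p1=frozenset({rc(2, 2), rc(3, 4), rc(1, 6)}),
            p2=frozenset({rc(0, 0), rc(0, 1), rc(0, 2)})),
        "double_threat": Board(
            p1=frozenset({rc(3, 0), rc(3, 2), rc(0, 7)}),
            p2=frozenset({rc(1, 2), rc(1, 3), rc(1, 4)})),
        "corner_opening": Board(),
        "phantom_edge_triple": Board(
            p1=frozenset({rc(1, 0), rc(2, 1), rc(3, 2)}),
            p2=frozenset({rc(0, 5), rc(0, 7), rc(1, 7)})),
        "pruning_trap": Board(
            p1=frozenset({rc(1, 4), rc(2, 5), rc(1, 6)}),
            p2=frozenset({rc(3, 0), rc(3, 1), rc(3, 2)})),
        "midgame_neutral": Board(
            p1=frozenset({rc(1, 3), rc(2, 6)}),
            p2=frozenset({rc(0, 4), rc(3, 5)})),
    }
    for name, b in boards.items():
        if is_terminal(b) != ONGOING or b.mover != 1:
            raise AssertionError(f"fixture {name} invalid")
    return boards
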