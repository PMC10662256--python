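"""KL residuals, summary statistics, Elo and paired comparisons."""

import numpy as np
import pytest

from fourinarow import (
    Board, GameRecord, ModelParams, MoveObservation, elo_ratings,
    elo_quantile_bins, kl_divergence, move_statistics, moves_from_games,
    nll_by_group, paired_ll_comparison, rank_residuals, self_play,
    summary_statistics, threat_squares,
)
from fourinarow.compare import random_chooser, residuals_to_frame

from conftest import random_board


def rc(r, c):
    return 9 * r + c


# -- KL divergence -----------------------------------------------------------

def test_kl_examples_and_nonnegativity(rng):
    p = np.zeros(36)
    p[:2] = [1.0, 0.0]
    q = np.zeros(36)
    q[:2] = [0.5, 0.5]
    legal = np.zeros(36, bool)
    legal[:2] = True
    assert kl_divergence(p, p, legal, epsilon=1e-9) == pytest.approx(0.0, abs=1e-6)
    assert kl_divergence(p, q, legal, epsilon=1e-12) == pytest.approx(np.log(2), abs=1e-6)
    for _ in range(300):
        n = int(rng.integers(2, 36))
        legal = np.zeros(36, bool)
        legal[rng.choice(36, n, replace=False)] = True
        a, b = np.zeros(36), np.zeros(36)
        a[legal] = rng.dirichlet(np.ones(n))
        b[legal] = rng.dirichlet(np.ones(n))
        assert kl_divergence(a, b, legal) >= 0.0


def test_kl_mask_mismatch_raises():
    p = np.full(36, 1 / 36)
    legal = np.ones(36, bool)
    legal[0] = False
    with pytest.raises(ValueError):
        kl_divergence(p, p, legal)


# -- residual ranking --------------------------------------------------------

def test_self_comparison_has_near_zero_kl(rng):
    params = ModelParams(gamma=1.0, delta=0.0, lam=0.3)
    obs = moves_from_games(self_play(params, params, 6, rng))[:25]
    recs = rank_residuals(obs, params, params, n_sims=800, rng=rng)
    assert np.median([r.kl for r in recs]) < 0.05


def test_residual_order_invariant_to_input_order(rng):
    baseline = ModelParams(gamma=1.0, delta=0.0, lam=0.2)
    defensive = baseline.evolve(threat=True, w_def=6.0)
    obs = moves_from_games(self_play(defensive, defensive, 5, rng))[:12]
    r1 = rank_residuals(obs, defensive, baseline, n_sims=150,
                        rng=np.random.default_rng(4))
    r2 = rank_residuals(obs[::-1], defensive, baseline, n_sims=150,
                        rng=np.random.default_rng(4))
    key = lambda r: (tuple(sorted(r.board.p1)), tuple(sorted(r.board.p2)))
    assert [key(r) for r in r1] == [key(r) for r in r2]
    assert [r.kl for r in r1] == [r.kl for r in r2]
    assert all(a.kl >= b.kl for a, b in zip(r1, r1[1:]))
    df = residuals_to_frame(r1)
    assert list(df.columns) == ["board_p1", "board_p2", "mover", "kl",
                                "nll_model", "nll_network", "human_move"]


# -- summary statistics -------------------------------------------------------

def oracle_move_stats(board, mover, square):
    r, c = divmod(square, 9)
    own = [divmod(s, 9) for s in board.pieces(mover)]
    opp = [divmod(s, 9) for s in board.pieces(3 - mover)]
    out = {"dist_center": np.hypot(r - 1.5, c - 4.0)}
    out["dist_own"] = min((np.hypot(r - a, c - b) for a, b in own), default=np.nan)
    out["dist_opp"] = min((np.hypot(r - a, c - b) for a, b in opp), default=np.nan)
    out["dist_own_com"] = (np.hypot(r - np.mean([a for a, _ in own]),
                                    c - np.mean([b for _, b in own]))
                           if own else np.nan)
    out["dist_opp_com"] = (np.hypot(r - np.mean([a for a, _ in opp]),
                                    c - np.mean([b for _, b in opp]))
                           if opp else np.nan)
    out["n_own_neighbors"] = sum(max(abs(r - a), abs(c - b)) == 1 for a, b in own)
    out["n_opp_neighbors"] = sum(max(abs(r - a), abs(c - b)) == 1 for a, b in opp)
    return out


def test_move_statistics_against_oracle(rng):
    checked = 0
    while checked < 120:
        b = random_board(rng, max_pieces=16)
        legal = sorted(set(range(36)) - b.p1 - b.p2)
        s = int(legal[rng.integers(len(legal))])
        got = move_statistics(b, b.mover, s)
        want = oracle_move_stats(b, b.mover, s)
        for k, v in want.items():
            if np.isnan(v):
                assert np.isnan(got[k])
            else:
                assert got[k] == pytest.approx(v), k
        checked += 1


def test_move_statistics_geometry_and_threats():
    st = move_statistics(Board(), 1, rc(1, 4))
    assert st["dist_center"] == pytest.approx(0.5)
    assert np.isnan(st["dist_own"])
    b = Board(p1=frozenset({rc(1, 3), rc(2, 4)}), p2=frozenset({rc(0, 0), rc(3, 8)}))
    st = move_statistics(b, 1, rc(1, 4))
    assert st["n_own_neighbors"] == 2
    assert st["n_opp_neighbors"] == 0
    # parry: choosing the opponent's completion square
    bt = Board(p1=frozenset({rc(2, 2), rc(3, 4), rc(1, 6)}),
               p2=frozenset({rc(0, 0), rc(0, 1), rc(0, 2)}))
    st = move_statistics(bt, 1, rc(0, 3))
    assert st["parries_threat"] == 1.0
    # make: completing three in a row creates a threat
    bm = Board(p1=frozenset({rc(1, 2), rc(1, 3)}), p2=frozenset({rc(3, 0), rc(3, 1)}))
    st = move_statistics(bm, 1, rc(1, 4))
    assert st["makes_threat"] == 1.0


def test_summary_statistics_aggregation(rng):
    params = ModelParams(lam=1.0)
    obs = moves_from_games(self_play(params, params, 12, rng))
    agg = summary_statistics(obs)
    assert set(agg["statistic"]) >= {"dist_center", "makes_threat", "parries_threat"}
    # random chooser on the empty board averages the exact 36-square distance
    first_moves = [o for o in obs if o.move_number == 0]
    exact = np.mean([np.hypot(r - 1.5, c - 4.0)
                     for r in range(4) for c in range(9)])
    many = [MoveObservation(Board(), 1, random_chooser(Board(), 1, rng), 0, "x")
            for _ in range(4000)]
    agg = summary_statistics(many)
    got = agg.loc[agg["statistic"] == "dist_center", "mean"].iloc[0]
    assert got == pytest.approx(exact, abs=0.05)


# -- Elo ----------------------------------------------------------------------

def game(pa, pb, outcome, gid="g"):
    return GameRecord(game_id=gid, moves=(), outcome=outcome, player_ids=(pa, pb))


def test_elo_closed_form_and_conservation():
    # equal priors, one win with K=32 -> 1516 / 1484
    table = elo_ratings([GameRecord("g", ((0, 1, 0), (1, 2, 9), (2, 1, 1),
                                          (3, 2, 10), (4, 1, 2), (5, 2, 11),
                                          (6, 1, 3)), "p1_win", ("a", "b"))])
    assert table.rating("a") == pytest.approx(1516.0)
    assert table.rating("b") == pytest.approx(1484.0)
    # draws between equals change nothing; totals conserved
    t2 = elo_ratings([game("a", "b", "draw"), game("a", "b", "draw")])
    assert t2.rating("a") == t2.rating("b") == 1500.0
    t3 = elo_ratings([game("a", "b", "p1_win"), game("b", "a", "p1_win"),
                      game("a", "b", "p2_win")])
    assert t3.rating("a") + t3.rating("b") == pytest.approx(3000.0)
    # unfinished games are skipped
    t4 = elo_ratings([game("a", "b", "unfinished")])
    assert t4.ratings == {}


def test_elo_quantile_bins():
    games = [game("a", "b", "p1_win"), game("c", "d", "p2_win"),
             game("a", "c", "p1_win"), game("b", "d", "p1_win")]
    table = elo_ratings(games)
    bins = elo_quantile_bins(table, n_bins=2)
    assert set(bins.index) == {"a", "b", "c", "d"}
    assert bins["a"] == 1  # two wins -> top bin


# -- grouped NLL and paired comparison ---------------------------------------

def uniform_scorer(board, mover):
    pol = np.zeros(36)
    legal = sorted(set(range(36)) - board.p1 - board.p2)
    pol[legal] = 1 / len(legal)
    return pol


def test_nll_by_group_partitions_and_uniform_value(rng):
    params = ModelParams(lam=1.0)
    obs = moves_from_games(self_play(params, params, 8, rng))
    out = nll_by_group(obs, uniform_scorer, grouping="move_number")
    assert out["n"].sum() == len(obs)
    for _, row in out.iterrows():
        sub = [o for o in obs if o.move_number == row["group"]]
        want = np.mean([np.log(36 - o.move_number) for o in sub])
        assert row["nll"] == pytest.approx(want)


def test_paired_comparison_antisymmetry_and_self_zero(rng):
    params = ModelParams(gamma=1.0, delta=0.0, lam=0.3)
    obs = moves_from_games(self_play(params, params, 4, rng))[:15]
    same = paired_ll_comparison(obs, uniform_scorer, uniform_scorer, seed=0)
    assert same["mean_diff"] == 0.0 and same["t_statistic"] == 0.0

    defensive = params.evolve(threat=True, w_def=6.0)
    ab = paired_ll_comparison(obs, defensive, params, n_sims=100, seed=1)
    ba = paired_ll_comparison(obs, params, defensive, n_sims=100, seed=1)
    assert ab["mean_diff"] == pytest.approx(-ba["mean_diff"])
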