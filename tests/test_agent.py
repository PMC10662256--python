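"""Planning agent: dropout, evaluation, search, sampling, policies."""

import numpy as np
import pytest
from scipy.stats import chisquare

from fourinarow import (
    Board, ModelParams, apply_move, best_first_search, depth1_policy_exact,
    draw_active_set, estimate_policy, heuristic_value, is_terminal,
    legal_moves, sample_move, threat_squares,
)
from fourinarow.agent import SearchNode, _backup, depth1_values
from fourinarow.features import get_feature_set
from fourinarow.synth import fixture_boards

from conftest import random_board


def rc(r, c):
    return 9 * r + c


DET = dict(sigma=1e-12, delta=0.0, lam=0.0, gamma=0.0, max_iterations=200)


def test_model_params_json_round_trip():
    p = ModelParams(w_four=7.5, corner=True, w_corner=(1.0, 0.5, 0.25, 0.1),
                    threat=True, w_def=3.0, lam=0.07)
    assert ModelParams.from_json(p.to_json()) == p
    with pytest.raises(ValueError):
        ModelParams(lam=1.5)
    with pytest.raises(ValueError):
        ModelParams(sigma=-1.0)


# -- dropout ---------------------------------------------------------------

def test_draw_active_set_rates(rng):
    fs = get_feature_set(ModelParams().flags)
    assert len(draw_active_set(ModelParams(delta=0.0), rng)) == fs.n_instances
    assert len(draw_active_set(ModelParams(delta=1.0), rng)) == 0
    fracs = [len(draw_active_set(ModelParams(delta=0.5), rng)) / fs.n_instances
             for _ in range(2000)]
    se = 0.5 / np.sqrt(2000 * fs.n_instances)
    assert abs(np.mean(fracs) - 0.5) < 3 * se


# -- heuristic evaluation ---------------------------------------------------

def test_heuristic_zero_and_linearity():
    p = ModelParams(sigma=0.0)
    assert heuristic_value(Board(), 1, None, p) == 0.0
    b = Board(p1=frozenset({rc(1, 4), rc(2, 2), rc(0, 7)}),
              p2=frozenset({rc(2, 4), rc(3, 3), rc(1, 1)}))
    v = heuristic_value(b, 1, None, p)
    scaled = p.evolve(w_conn2=3 * p.w_conn2, w_unconn2=3 * p.w_unconn2,
                      w_three=3 * p.w_three, w_four=3 * p.w_four,
                      w_center=3 * p.w_center)
    assert heuristic_value(b, 1, None, scaled) == pytest.approx(3 * v)


def test_defensive_weight_shifts_value_by_w_def():
    # one opponent immediate threat: threat-on value is lower by exactly w_def
    b = Board(p1=frozenset({rc(2, 2), rc(3, 4), rc(1, 6)}),
              p2=frozenset({rc(0, 0), rc(0, 1), rc(0, 2)}))
    assert len(threat_squares(b, 2)) == 1
    base = ModelParams(sigma=0.0)
    defense = base.evolve(threat=True, w_def=4.25)
    v0 = heuristic_value(b, 1, None, base)
    v1 = heuristic_value(b, 1, None, defense)
    assert v1 == pytest.approx(v0 - 4.25)


# -- search ----------------------------------------------------------------

def test_backup_min_at_opponent_max_at_root():
    # values from the search illustration: the opponent node backs up its
    # lowest child (0.3) and the root its highest child (1.8)
    leaf = lambda v: SearchNode(occ1=None, occ2=None, mover=1, value=v)
    opp = SearchNode(occ1=None, occ2=None, mover=2, value=2.3, expanded=True,
                     children=[leaf(0.3), leaf(0.9)])
    other = SearchNode(occ1=None, occ2=None, mover=2, value=1.8)
    root = SearchNode(occ1=None, occ2=None, mover=1, expanded=True,
                      children=[opp, other])
    _backup([root, opp], root_player=1)
    assert opp.value == pytest.approx(0.3)
    assert root.value == pytest.approx(1.8)


def test_gamma1_is_single_expansion_depth1(rng):
    p = ModelParams(gamma=1.0, delta=0.0, lam=0.0, sigma=1e-12)
    for _ in range(40):
        b = random_board(rng, max_pieces=12)
        root = best_first_search(b, b.mover, p, rng)
        kids = [c for c in root.children]
        assert all(not c.expanded for c in kids)  # exactly one expansion
        squares, vals = depth1_values(b, b.mover, p)
        got = {c.move: c.value for c in kids}
        for s, v in zip(squares, vals):
            assert got[int(s)] == pytest.approx(v, abs=1e-6)


def test_theta_inf_never_prunes(rng):
    p = ModelParams(theta=np.inf, gamma=0.5)
    b = random_board(rng, max_pieces=10)
    root = best_first_search(b, b.mover, p, rng)

    def no_pruned(node):
        return all(not c.pruned and no_pruned(c) for c in node.children)

    assert no_pruned(root)


def test_search_rejects_terminal_board():
    win = Board(p1=frozenset({0, 1, 2, 3}), p2=frozenset({9, 10, 11}))
    with pytest.raises(ValueError):
        best_first_search(win, 2, ModelParams(), np.random.default_rng(0))
    with pytest.raises(ValueError):
        sample_move(win, 2, ModelParams(), np.random.default_rng(0))


def test_two_ply_positions_match_minimax(rng):
    """On boards with two empty squares the search equals 2-ply minimax."""
    p = ModelParams(**{**DET, "theta": np.inf})
    # near-full no-win boards: a drawn position minus one piece per player
    from conftest import DRAWN_P1, DRAWN_P2
    full_p1, full_p2 = sorted(DRAWN_P1), sorted(DRAWN_P2)
    cases = [(i, j) for i in (0, 5, 9, 13) for j in (2, 7, 11)]
    for i, j in cases:
        b = Board(p1=frozenset(full_p1) - {full_p1[i]},
                  p2=frozenset(full_p2) - {full_p2[j]})
        empties = sorted(legal_moves(b))
        assert len(empties) == 2 and is_terminal(b) == "ongoing"
        mover = b.mover
        # exhaustive 2-ply minimax with noiseless heuristic leaf values
        vals = {}
        for s in empties:
            child = apply_move(b, mover, s)
            if is_terminal(child) != "ongoing":
                vals[s] = heuristic_value(child, mover, None, p)
            else:
                vals[s] = min(heuristic_value(apply_move(child, 3 - mover, t),
                                              mover, None, p)
                              for t in legal_moves(child))
        chosen = sample_move(b, mover, p, rng)
        assert vals[chosen] == pytest.approx(max(vals.values()), abs=1e-9)


# -- move sampling ----------------------------------------------------------

def test_full_lapse_is_uniform(rng):
    p = ModelParams(lam=1.0)
    draws = [sample_move(Board(), 1, p, rng) for _ in range(10000)]
    counts = np.bincount(draws, minlength=36)
    assert chisquare(counts).pvalue > 0.01


def test_takes_immediate_win(rng):
    p = ModelParams(**DET, w_four=50.0)
    fx = fixture_boards()
    b = fx["own_immediate_win"]
    wins = threat_squares(b, 1)
    assert sample_move(b, 1, p, rng) in wins


def test_defensive_extension_blocks_threats(rng):
    fx = fixture_boards()
    b = fx["opponent_immediate_threat"]
    block = threat_squares(b, 2)
    p = ModelParams(**DET, corner=True, threat=True, w_def=8.0)
    assert len(threat_squares(b, 1)) == 0
    for _ in range(5):
        assert sample_move(b, 1, p, rng) in block


def test_increasing_w_def_never_reduces_blocking(rng):
    fx = fixture_boards()
    boards = [fx["opponent_immediate_threat"], fx["double_threat"],
              fx["pruning_trap"]]
    rates = []
    for w_def in (0.5, 3.0, 8.0):
        p = ModelParams(lam=0.05, delta=0.1, corner=True, threat=True, w_def=w_def)
        hits = 0
        n = 0
        for b in boards:
            block = threat_squares(b, 2)
            r = np.random.default_rng(777)  # common random numbers
            for _ in range(150):
                hits += sample_move(b, 1, p, r) in block
                n += 1
        rates.append(hits / n)
    assert rates[0] <= rates[1] + 0.02 and rates[1] <= rates[2] + 0.02


def test_policy_normalization_and_reproducibility(rng):
    p = ModelParams()
    b = random_board(rng, max_pieces=9)
    pol1 = estimate_policy(b, b.mover, p, n_sims=100, rng=np.random.default_rng(3))
    pol2 = estimate_policy(b, b.mover, p, n_sims=100, rng=np.random.default_rng(3))
    assert np.array_equal(pol1, pol2)
    assert pol1.sum() == pytest.approx(1.0)
    occupied = sorted(b.p1 | b.p2)
    assert (pol1[occupied] == 0).all()
    m1 = sample_move(b, b.mover, p, np.random.default_rng(9))
    m2 = sample_move(b, b.mover, p, np.random.default_rng(9))
    assert m1 == m2


def test_estimate_policy_pseudocount_floor(rng):
    b = Board()
    p = ModelParams(**DET, w_center=5.0)
    pol = estimate_policy(b, 1, p, n_sims=50, rng=rng, alpha=0.5)
    assert pol.min() >= 0.5 / (50 + 0.5 * 36) - 1e-12
    # a noiseless agent with a forced win picks one square in every sim
    fx = fixture_boards()
    bw = fx["own_immediate_win"]
    pol0 = estimate_policy(bw, 1, ModelParams(**DET, w_four=50.0),
                           n_sims=50, rng=rng, alpha=0.0)
    assert pol0.max() == pytest.approx(1.0)


def test_exact_depth1_policy_matches_simulation(rng):
    p = ModelParams(gamma=1.0, delta=0.0, lam=0.15, sigma=1.0)
    fx = fixture_boards()
    b = fx["midgame_neutral"]
    exact = depth1_policy_exact(b, 1, p)
    emp = estimate_policy(b, 1, p, n_sims=4000, rng=rng)
    assert 0.5 * np.abs(exact - emp).sum() < 0.05
    assert exact.sum() == pytest.approx(1.0)
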