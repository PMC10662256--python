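"""Heuristic feature enumeration and counting against brute-force oracles."""

import numpy as np
import pytest

from fourinarow import (
    Board, apply_move, count_features, count_features_delta,
    enumerate_instances, is_win, legal_moves, threat_squares,
)
from fourinarow.features import (
    CENTER, CONN2, CORNER, ExtensionFlags, FOUR, PHANTOM3, THREAT, THREE,
    UNCONN2, center_value,
)
from fourinarow.board import DEFAULT_GEOMETRY

from conftest import random_board

ALL_FLAGS = ExtensionFlags(corner=True, threat=True, phantom=True)


def rc(r, c):
    return 9 * r + c


# ---------------------------------------------------------------------------
# independent brute-force classifier (windows and triples re-derived here)
# ---------------------------------------------------------------------------

def oracle_counts(board):
    """Window/triple classification written from the rules, loop by loop."""
    own = {1: board.p1, 2: board.p2}
    counts = {k: {1: 0.0, 2: 0.0}
              for k in (CONN2, UNCONN2, THREE, FOUR, CENTER, CORNER, THREAT, PHANTOM3)}
    windows = []
    for r in range(4):
        for c in range(9):
            for dr, dc in ((0, 1), (1, 0), (1, 1), (-1, 1)):
                cells = [(r + i * dr, c + i * dc) for i in range(4)]
                if all(0 <= rr < 4 and 0 <= cc < 9 for rr, cc in cells):
                    windows.append([rc(rr, cc) for rr, cc in cells])
    for w in windows:
        for p in (1, 2):
            mine = [i for i, s in enumerate(w) if s in own[p]]
            theirs = [s for s in w if s in own[3 - p]]
            if len(mine) == 4:
                counts[FOUR][p] += 1
            if theirs:
                continue
            if len(mine) == 3:
                counts[THREE][p] += 1
                counts[THREAT][p] += 1
            elif len(mine) == 2:
                if abs(mine[0] - mine[1]) == 1:
                    counts[CONN2][p] += 1
                else:
                    counts[UNCONN2][p] += 1
    for p in (1, 2):
        for s in own[p]:
            r, c = divmod(s, 9)
            counts[CENTER][p] += 1.0 / (1.0 + np.hypot(r - 1.5, c - 4.0))
            if (r, c) in ((0, 0), (0, 8), (3, 0), (3, 8)):
                counts[CORNER][p] += 1
    occupied = board.p1 | board.p2
    for r in range(4):
        for c in range(9):
            for dr, dc in ((0, 1), (1, 0), (1, 1), (-1, 1)):
                cells = [(r + i * dr, c + i * dc) for i in range(3)]
                if not all(0 <= rr < 4 and 0 <= cc < 9 for rr, cc in cells):
                    continue
                tri = [rc(rr, cc) for rr, cc in cells]
                exts = [(r - dr, c - dc), (r + 3 * dr, c + 3 * dc)]
                comps = [rc(rr, cc) for rr, cc in exts if 0 <= rr < 4 and 0 <= cc < 9]
                if any(s not in occupied for s in comps):
                    continue
                for p in (1, 2):
                    if all(s in own[p] for s in tri):
                        counts[PHANTOM3][p] += 1
    return counts


def test_instance_enumeration():
    inst = enumerate_instances(ALL_FLAGS)
    by_kind = {}
    for i in inst:
        by_kind.setdefault(i.kind, []).append(i)
    assert len(by_kind[CONN2]) == len(by_kind[THREE]) == len(by_kind[FOUR]) == 45
    assert len(by_kind[CENTER]) == 36
    assert len(by_kind[CORNER]) == 4
    assert len(by_kind[THREAT]) == 45
    # graded center value at (1,4): distance to (1.5, 4.0) is 0.5
    assert center_value(rc(1, 4)) == pytest.approx(2 / 3)
    # corner-diagonal triple is a phantom instance with no completion square
    phantoms = {i.squares: i.completions for i in by_kind[PHANTOM3]}
    assert (rc(1, 0), rc(2, 1), rc(3, 2)) in phantoms
    assert phantoms[(rc(1, 0), rc(2, 1), rc(3, 2))] == ()
    # baseline flags expose no extension instances
    base = enumerate_instances(ExtensionFlags())
    assert {i.kind for i in base} == {CONN2, UNCONN2, THREE, FOUR, CENTER}
    # deterministic: same flags give identical ids
    again = enumerate_instances(ALL_FLAGS)
    assert [(i.id, i.kind, i.squares) for i in inst] == \
        [(i.id, i.kind, i.squares) for i in again]


def test_count_examples():
    empty = count_features(Board(), 1, None, ALL_FLAGS)
    assert all(v[0] == v[1] == 0 for v in empty.counts.values())
    # three-in-a-row on the top edge: one three, one threat, window-level conn2
    b = Board(p1=frozenset({rc(0, 0), rc(0, 1), rc(0, 2)}),
              p2=frozenset({rc(2, 4), rc(2, 5)}))
    c = count_features(b, 1, None, ALL_FLAGS)
    assert c.get(THREE, 1) == 1
    assert c.get(THREAT, 1) == 1
    # corner-diagonal triple: phantom but no three
    bp = Board(p1=frozenset({rc(1, 0), rc(2, 1), rc(3, 2)}),
               p2=frozenset({rc(0, 5), rc(0, 7)}))
    cp = count_features(bp, 1, None, ALL_FLAGS)
    assert cp.get(PHANTOM3, 1) == 1
    assert cp.get(THREE, 1) == 0
    # blocked three: completions occupied -> phantom under the occupied-fourth rule
    bb = Board(p1=frozenset({rc(0, 3), rc(0, 4), rc(0, 5)}),
               p2=frozenset({rc(0, 2), rc(0, 6), rc(2, 2)}))
    cb = count_features(bb, 1, None, ALL_FLAGS)
    assert cb.get(PHANTOM3, 1) == 1
    assert cb.get(THREE, 1) == 0


def test_counts_match_oracle_on_random_boards(rng):
    for _ in range(150):
        b = random_board(rng, max_pieces=18, require_ongoing=False)
        got = count_features(b, 1, None, ALL_FLAGS)
        want = oracle_counts(b)
        for kind in want:
            for p in (1, 2):
                assert got.get(kind, p) == pytest.approx(want[kind][p]), (kind, p, b)


def test_active_subset_restricts_counts(rng):
    inst = enumerate_instances(ALL_FLAGS)
    b = random_board(rng, max_pieces=12)
    ids = [i.id for i in inst]
    half = frozenset(rng.choice(ids, size=len(ids) // 2, replace=False).tolist())
    all_counts = count_features(b, 1, None, ALL_FLAGS)
    sub_counts = count_features(b, 1, half, ALL_FLAGS)
    for kind in all_counts.counts:
        for p in (1, 2):
            assert sub_counts.get(kind, p) <= all_counts.get(kind, p) + 1e-12
    none_counts = count_features(b, 1, frozenset(), ALL_FLAGS)
    assert all(v[0] == v[1] == 0 for v in none_counts.counts.values())


def test_threat_squares_against_win_oracle(rng):
    b = Board(p1=frozenset({rc(0, 0), rc(0, 1), rc(0, 2)}),
              p2=frozenset({rc(2, 4), rc(2, 5), rc(3, 7)}))
    assert threat_squares(b, 1) == {rc(0, 3)}
    assert threat_squares(Board(), 1) == frozenset()
    bd = Board(p1=frozenset({rc(1, 2), rc(1, 3), rc(1, 4)}),
               p2=frozenset({rc(3, 0), rc(3, 2), rc(0, 8)}))
    assert threat_squares(bd, 1) == {rc(1, 1), rc(1, 5)}
    # oracle: a threat square is an empty square whose occupation wins
    for _ in range(60):
        b = random_board(rng, max_pieces=16)
        for p in (1, 2):
            want = set()
            for s in legal_moves(b):
                # parity-free oracle: place the piece directly
                pieces = set(b.pieces(p)) | {s}
                win = any(all(q in pieces for q in w)
                          for w, _ in DEFAULT_GEOMETRY.line_windows())
                if win:
                    want.add(s)
            assert threat_squares(b, p) == want


def test_delta_counts_equal_full_recount(rng):
    for _ in range(120):
        b = random_board(rng, max_pieces=16)
        legal = sorted(legal_moves(b))
        s = int(legal[rng.integers(len(legal))])
        delta = count_features_delta(b, b.mover, s, None, ALL_FLAGS)
        full = count_features(apply_move(b, b.mover, s), 1, None, ALL_FLAGS)
        for kind in full.counts:
            assert np.allclose(delta.counts[kind], full.counts[kind])


def test_four_and_center_monotone_under_own_pieces(rng):
    for _ in range(50):
        b = random_board(rng, max_pieces=14)
        p = b.mover
        before = count_features(b, 1, None, ALL_FLAGS)
        legal = sorted(legal_moves(b))
        s = int(legal[rng.integers(len(legal))])
        after = count_features(apply_move(b, p, s), 1, None, ALL_FLAGS)
        assert after.get(FOUR, p) >= before.get(FOUR, p)
        assert after.get(CENTER, p) >= before.get(CENTER, p)
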