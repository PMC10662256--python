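import numpy as np
import pytest

from fourinarow import Board, apply_move, is_terminal, legal_moves
from fourinarow.board import ONGOING


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_board(rng, max_pieces=14, require_ongoing=True):
    """Random reachable board built by replaying random legal moves."""
    while True:
        n = int(rng.integers(0, max_pieces + 1))
        b = Board()
        ok = True
        for _ in range(n):
            if is_terminal(b) != ONGOING:
                ok = False
                break
            legal = sorted(legal_moves(b))
            b = apply_move(b, b.mover, int(legal[rng.integers(len(legal))]))
        if not ok:
            continue
        if require_ongoing and is_terminal(b) != ONGOING:
            continue
        return b


# a full 4x9 board with 18 pieces each and no four-in-a-row (a drawn game)
DRAWN_P1 = frozenset({2, 3, 7, 9, 10, 12, 13, 14, 18, 19, 20, 22, 24, 27, 28,
                      29, 31, 35})
DRAWN_P2 = frozenset(range(36)) - DRAWN_P1


@pytest.fixture
def random_boards(rng):
    def make(n, max_pieces=14):
        return [random_board(rng, max_pieces) for _ in range(n)]
    return make
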