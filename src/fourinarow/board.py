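"""Rules, representation and serialization for the 4-in-a-row board game.

Two players alternate placing pieces anywhere on a 4x9 grid; the first to
occupy four collinear adjacent squares (horizontally, vertically or
diagonally) wins.  Squares are indexed row-major: ``index = cols*row + col``
with row 0 at the top.  Player 1 always moves first, so on any reachable
board ``|p1| - |p2|`` is 0 (player 1 to move) or 1 (player 2 to move).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

P1_WIN = "p1_win"
P2_WIN = "p2_win"
DRAW = "draw"
ONGOING = "ongoing"
UNFINISHED = "unfinished"

_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (-1, 1))  # E, S, SE, NE


class Geometry:
    """Board dimensions plus derived square/window tables.

    The default game is played on 4 rows x 9 columns; everything downstream
    (features, agent, census oracles) consumes windows through this object so
    other sizes work generically.
    """

    def __init__(self, rows: int = 4, cols: int = 9, k: int = 4):
        self.rows = rows
        self.cols = cols
        self.k = k
        self.n_squares = rows * cols
        self.center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
        self._windows = self._enumerate_windows()
        # (n_windows, k) square-index array for vectorized window scans
        self.window_array = np.array(
            [w[0] for w in self._windows], dtype=np.int64
        ).reshape(len(self._windows), k) if self._windows else np.zeros((0, k), np.int64)

    # -- coordinates ------------------------------------------------------
    def index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"square ({row},{col}) off board")
        return self.cols * row + col

    def coords(self, square: int) -> tuple[int, int]:
        if not (0 <= square < self.n_squares):
            raise ValueError(f"square index {square} out of range")
        return divmod(square, self.cols)

    def _enumerate_windows(self) -> list[tuple[tuple[int, ...], str]]:
        names = {(0, 1): "horizontal", (1, 0): "vertical",
                 (1, 1): "diagonal", (-1, 1): "antidiagonal"}
        out = []
        for dr, dc in _DIRECTIONS:
            for r in range(self.rows):
                for c in range(self.cols):
                    rr, cc = r + (self.k - 1) * dr, c + (self.k - 1) * dc
                    if 0 <= rr < self.rows and 0 <= cc < self.cols:
                        cells = tuple(
                            self.index(r + i * dr, c + i * dc) for i in range(self.k)
                        )
                        out.append((cells, names[(dr, dc)]))
        return out

    def line_windows(self) -> list[tuple[tuple[int, ...], str]]:
        """Every in-board set of ``k`` collinear adjacent squares.

        Returns ``(squares, orientation)`` pairs; on 4x9 there are 45
        (24 horizontal + 9 vertical + 6 + 6 diagonal).
        """
        return list(self._windows)


DEFAULT_GEOMETRY = Geometry()


def line_windows(geometry: Geometry = DEFAULT_GEOMETRY):
    return geometry.line_windows()


@dataclass(frozen=True)
class Board:
    """Occupancy of both players as square-index frozensets."""

    p1: frozenset = frozenset()
    p2: frozenset = frozenset()
    geometry: Geometry = field(default=DEFAULT_GEOMETRY, compare=False, repr=False)

    def __post_init__(self):
        if self.p1 & self.p2:
            raise ValueError("players overlap on squares " + str(sorted(self.p1 & self.p2)))
        n = self.geometry.n_squares
        for s in self.p1 | self.p2:
            if not (0 <= s < n):
                raise ValueError(f"square {s} off board")
        if len(self.p1) - len(self.p2) not in (0, 1):
            raise ValueError(
                f"piece counts {len(self.p1)}/{len(self.p2)} violate alternation"
            )

    @property
    def mover(self) -> int:
        """Player to move: 1 iff both players have equal piece counts."""
        return 1 if len(self.p1) == len(self.p2) else 2

    def pieces(self, player: int) -> frozenset:
        return self.p1 if player == 1 else self.p2

    def occupancy(self) -> np.ndarray:
        """(2, n_squares) boolean array, row 0 = player 1."""
        out = np.zeros((2, self.geometry.n_squares), dtype=bool)
        out[0, list(self.p1)] = True
        out[1, list(self.p2)] = True
        return out

    def to_strings(self) -> tuple[str, str]:
        occ = self.occupancy()
        return ("".join("1" if x else "0" for x in occ[0]),
                "".join("1" if x else "0" for x in occ[1]))

    @classmethod
    def from_strings(cls, p1: str, p2: str, geometry: Geometry = DEFAULT_GEOMETRY):
        return cls(frozenset(i for i, ch in enumerate(p1) if ch == "1"),
                   frozenset(i for i, ch in enumerate(p2) if ch == "1"), geometry)

    @classmethod
    def from_moves(cls, squares: Sequence[int], geometry: Geometry = DEFAULT_GEOMETRY):
        """Board after an alternating move sequence starting with player 1."""
        b = cls(geometry=geometry)
        for s in squares:
            b = apply_move(b, b.mover, s)
        return b


def legal_moves(board: Board) -> frozenset:
    """The empty squares."""
    return frozenset(range(board.geometry.n_squares)) - board.p1 - board.p2


def apply_move(board: Board, mover: int, square: int) -> Board:
    """Place a piece; returns a new board, the input is unchanged."""
    if mover not in (1, 2):
        raise ValueError(f"mover must be 1 or 2, got {mover}")
    if mover != board.mover:
        raise ValueError(f"player {mover} moved out of turn")
    if square in board.p1 or square in board.p2:
        raise ValueError(f"square {square} is occupied")
    if not (0 <= square < board.geometry.n_squares):
        raise ValueError(f"square {square} off board")
    if mover == 1:
        return replace(board, p1=board.p1 | {square})
    return replace(board, p2=board.p2 | {square})


def is_win(board: Board, player: int) -> bool:
    """True iff some window is fully occupied by ``player``.

    Lines longer than four contain a winning window, so they count.
    """
    pieces = board.pieces(player)
    if len(pieces) < board.geometry.k:
        return False
    for cells, _ in board.geometry.line_windows():
        if all(c in pieces for c in cells):
            return True
    return False


def is_terminal(board: Board) -> str:
    """One of p1_win / p2_win / draw / ongoing (win takes precedence over full)."""
    w1, w2 = is_win(board, 1), is_win(board, 2)
    if w1 and w2:
        raise ValueError("invalid board: both players have four in a row")
    if w1:
        return P1_WIN
    if w2:
        return P2_WIN
    if len(board.p1) + len(board.p2) == board.geometry.n_squares:
        return DRAW
    return ONGOING


def encode_planes(board: Board, mover: int) -> np.ndarray:
    """2 x rows x cols binary tensor: plane 0 = mover's pieces, plane 1 = opponent's."""
    g = board.geometry
    planes = np.zeros((2, g.rows, g.cols), dtype=np.float64)
    own = board.pieces(mover)
    opp = board.pieces(3 - mover)
    flat = planes.reshape(2, -1)
    flat[0, list(own)] = 1.0
    flat[1, list(opp)] = 1.0
    return planes


# --------------------------------------------------------------------------
# Game records and move observations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GameRecord:
    game_id: str
    moves: tuple  # of (move_index, player, square)
    outcome: str
    player_ids: tuple[str, str] = ("p1", "p2")

    def replay(self, geometry: Geometry = DEFAULT_GEOMETRY) -> Board:
        """Replay and validate the move list; returns the final board."""
        b = Board(geometry=geometry)
        for i, (idx, player, square) in enumerate(self.moves):
            if idx != i:
                raise ValueError(f"game {self.game_id}: move_index {idx} != {i}")
            if player != b.mover:
                raise ValueError(f"game {self.game_id}: player {player} out of turn at move {i}")
            if is_terminal(b) != ONGOING:
                raise ValueError(f"game {self.game_id}: move after terminal state")
            b = apply_move(b, player, square)
        status = is_terminal(b)
        expect = status if status != ONGOING else UNFINISHED
        if self.outcome != expect:
            raise ValueError(
                f"game {self.game_id}: outcome {self.outcome!r} inconsistent with replay ({expect!r})"
            )
        return b


@dataclass(frozen=True)
class MoveObservation:
    """A single (position, mover, chosen square) trial."""

    board: Board
    mover: int
    chosen: int
    move_number: int = 0
    player_id: str = ""

    def __post_init__(self):
        if self.chosen in self.board.p1 or self.chosen in self.board.p2:
            raise ValueError("chosen square is occupied")
        if self.mover != self.board.mover:
            raise ValueError("mover does not match board parity")


def moves_from_games(records: Iterable[GameRecord],
                     players: tuple[int, ...] = (1, 2),
                     geometry: Geometry = DEFAULT_GEOMETRY) -> list[MoveObservation]:
    """Expand games into per-move observations (board state before each move)."""
    out = []
    for rec in records:
        b = Board(geometry=geometry)
        for idx, player, square in rec.moves:
            if player in players:
                out.append(MoveObservation(
                    board=b, mover=player, chosen=square, move_number=idx,
                    player_id=rec.player_ids[player - 1]))
            b = apply_move(b, player, square)
    return out


# --------------------------------------------------------------------------
# ndjson game logs
# --------------------------------------------------------------------------

def write_games(path, records: Iterable[GameRecord]) -> None:
    """One JSON object per line: game_id, players, moves, outcome."""
    def _dump(fh):
        for rec in records:
            fh.write(json.dumps({
                "game_id": rec.game_id,
                "players": list(rec.player_ids),
                "moves": [[i, p, s] for i, p, s in rec.moves],
                "outcome": rec.outcome,
            }) + "\n")

    if hasattr(path, "write"):
        _dump(path)
    else:
        with open(path, "w") as fh:
            _dump(fh)


def read_games(path, geometry: Geometry = DEFAULT_GEOMETRY,
               validate: bool = True) -> Iterator[GameRecord]:
    """Stream GameRecords from an ndjson log, validating each by replay."""
    fh = path if hasattr(path, "read") else open(path)
    try:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                rec = GameRecord(
                    game_id=str(obj["game_id"]),
                    moves=tuple((int(i), int(p), int(s)) for i, p, s in obj["moves"]),
                    outcome=str(obj["outcome"]),
                    player_ids=tuple(obj.get("players", ("p1", "p2"))),
                )
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                raise ValueError(f"malformed game log line {lineno}: {exc}") from exc
            if validate:
                try:
                    rec.replay(geometry)
                except ValueError as exc:
                    raise ValueError(f"invalid game at line {lineno}: {exc}") from exc
            yield rec
    finally:
        if fh is not path:
            fh.close()


# --------------------------------------------------------------------------
# CSV move tables
# --------------------------------------------------------------------------

_MOVE_HEADER = ["game_id", "move_index", "player", "square", "board_p1", "board_p2"]


def write_move_table(path, records: Iterable[GameRecord],
                     geometry: Geometry = DEFAULT_GEOMETRY) -> None:
    """CSV of per-move rows; board_* columns hold the position before the move."""
    fh = path if hasattr(path, "write") else open(path, "w", newline="")
    try:
        w = csv.writer(fh)
        w.writerow(_MOVE_HEADER)
        for rec in records:
            b = Board(geometry=geometry)
            for idx, player, square in rec.moves:
                s1, s2 = b.to_strings()
                w.writerow([rec.game_id, idx, player, square, s1, s2])
                b = apply_move(b, player, square)
    finally:
        if fh is not path:
            fh.close()


def read_move_table(path, geometry: Geometry = DEFAULT_GEOMETRY) -> list[MoveObservation]:
    fh = path if hasattr(path, "read") else open(path, newline="")
    try:
        r = csv.DictReader(fh)
        out = []
        for lineno, row in enumerate(r, start=2):
            try:
                board = Board.from_strings(row["board_p1"], row["board_p2"], geometry)
                out.append(MoveObservation(
                    board=board, mover=int(row["player"]), chosen=int(row["square"]),
                    move_number=int(row["move_index"]), player_id=row["game_id"]))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed move table line {lineno}: {exc}") from exc
        return out
    finally:
        if fh is not path:
            fh.close()
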