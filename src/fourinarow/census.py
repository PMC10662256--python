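"""Exact census of non-terminal game states via a column transfer-matrix DP.

A state is a board assignment (each cell empty / player 1 / player 2) with

* no four-in-a-row for either player (any orientation),
* at least one empty cell (the game is not over by exhaustion), and
* piece counts consistent with alternating play starting at player 1
  (``n1 - n2`` in {0, 1}; whose turn it is follows from parity).

The DP sweeps the board column by column.  The state is the ternary content
of the three most recent columns (every horizontal/diagonal window spans
four consecutive columns; vertical windows live inside the new column), plus
the running piece-count difference.  Three virtual empty columns pad the
start so no window can complete early.  Counts are held in int64 (the grand
total is at most 3^36 < 2^63); the per-column transition is a batched
matrix product computed exactly on a 31-bit high/low split in float64.
The "at least one empty cell" condition is applied by subtracting a
full-board-only count obtained from the same recursion restricted to
columns without empty cells.

A brute-force enumerator over all 3^(rows*cols) assignments serves as an
independent oracle for boards with at most 16 cells.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .board import Geometry

_MASK31 = (1 << 31) - 1


def _column_digits(P: int, rows: int) -> np.ndarray:
    """(P, rows) ternary digits of every column pattern; digit r = cell in row r."""
    vals = np.arange(P)
    return np.stack([(vals // 3 ** r) % 3 for r in range(rows)], axis=1)


def _window_cells(rows: int):
    """Windows spanning the 4-column block (a, b2, b3, n) plus verticals in n.

    Returns (block_windows, vertical_starts): each block window is a list of
    (column_slot 0..3, row) cells; verticals are start rows within the new
    column.
    """
    block = []
    if rows >= 1:
        for r in range(rows):
            block.append([(0, r), (1, r), (2, r), (3, r)])  # horizontal
    if rows >= 4:
        for s in range(rows - 3):
            block.append([(0, s), (1, s + 1), (2, s + 2), (3, s + 3)])
            block.append([(0, s + 3), (1, s + 2), (2, s + 1), (3, s)])
    verticals = list(range(rows - 3)) if rows >= 4 else []
    return block, verticals


@lru_cache(maxsize=8)
def _transition_table(rows: int) -> tuple:
    """Validity of appending column n to last-3-columns state (a, b2, b3).

    Returns (valid, bad_col): ``valid`` is a (P, P*P, P) boolean array over
    (a, b, n) with b = b2*P + b3, true iff no horizontal/diagonal window
    among the four columns is monochrome; ``bad_col`` marks columns with a
    vertical four.
    """
    P = 3 ** rows
    dig = _column_digits(P, rows)
    block, verticals = _window_cells(rows)

    d_a = dig  # (P, rows)
    b_vals = np.arange(P * P)
    d_b2 = dig[b_vals // P]  # (P^2, rows)
    d_b3 = dig[b_vals % P]
    valid = np.ones((P, P * P, P), dtype=bool)
    slot_digits = {0: d_a, 1: d_b2, 2: d_b3, 3: dig}
    for cells in block:
        for v in (1, 2):
            # every block window has exactly one cell in each column slot
            conds = {slot: slot_digits[slot][:, r] == v for slot, r in cells}
            cb = conds[1] & conds[2]  # both live on the b axis
            mono = conds[0][:, None, None] & cb[None, :, None] & conds[3][None, None, :]
            valid &= ~mono
    bad_col = np.zeros(P, dtype=bool)
    for s in verticals:
        for v in (1, 2):
            bad_col |= np.all(dig[:, s:s + 4] == v, axis=1)
    valid &= ~bad_col[None, None, :]
    return valid, bad_col


def _diff_window(rows: int, cols: int, i: int) -> tuple[int, int]:
    """Reachable-and-useful diff range after ``i`` columns."""
    rem = cols - i
    return (max(-rows * i, -rows * rem), min(rows * i, rows * rem + 1))


def count_nonterminal(rows: int = 4, cols: int = 9) -> int:
    """Exact number of non-terminal states on a rows x cols board.

    Supports 1 <= rows <= 4 (the transfer state is 3^(3*rows)); the default
    4x9 game evaluates to about 1.2e16.
    """
    if not (1 <= rows <= 4):
        raise ValueError("rows must be between 1 and 4")
    if cols < 1:
        raise ValueError("cols must be >= 1")
    total = _dp_count(rows, cols)
    return total - _full_board_count(rows, cols)


def _dp_count(rows: int, cols: int) -> int:
    """All no-win assignments (including full boards) with diff in {0, 1}."""
    P = 3 ** rows
    valid, bad_col = _transition_table(rows)
    Vt = np.ascontiguousarray(valid.transpose(1, 2, 0)).astype(np.float64)  # (b, n, a)
    dig = _column_digits(P, rows)
    dcol = ((dig == 1).sum(axis=1) - (dig == 2).sum(axis=1)).astype(np.int64)

    OFF = rows * cols
    D = 2 * rows * cols + 2
    C = np.zeros((P, P * P, D), dtype=np.int64)
    C[0, 0, OFF] = 1
    lo_d, hi_d = 0, 0
    for i in range(cols):
        sl = slice(lo_d + OFF, hi_d + OFF + 1)
        Cs = C[:, :, sl]
        hi_part = (Cs >> 31).astype(np.float64)
        lo_part = (Cs & _MASK31).astype(np.float64)
        Da = Cs.shape[2]
        Ct = np.concatenate([hi_part, lo_part], axis=2).transpose(1, 0, 2)  # (b, a, 2Da)
        R = np.matmul(Vt, Ct)  # (b, n, 2Da)
        Rint = (np.rint(R[:, :, :Da]).astype(np.int64) << 31) \
            + np.rint(R[:, :, Da:]).astype(np.int64)
        Rv = Rint.reshape(P, P, P, Da)  # (b2, b3, n, d)
        newC = np.zeros_like(C)
        newC_v = newC.reshape(P, P, P, D)  # (a'=b2, b3, n, d)
        for n in range(P):
            if bad_col[n]:
                continue
            dn = int(dcol[n])
            newC_v[:, :, n, lo_d + dn + OFF:hi_d + dn + OFF + 1] = Rv[:, :, n, :]
        lo_d, hi_d = _diff_window(rows, cols, i + 1)
        newC[:, :, :lo_d + OFF] = 0
        newC[:, :, hi_d + OFF + 1:] = 0
        C = newC
    return int(C[:, :, OFF].sum()) + int(C[:, :, OFF + 1].sum())


def _full_board_count(rows: int, cols: int) -> int:
    """No-win assignments with every cell occupied and diff in {0, 1}.

    Same recursion restricted to full columns; the state space is tiny
    (2^rows column patterns), so plain dictionaries suffice.
    """
    P = 3 ** rows
    dig = _column_digits(P, rows)
    full_cols = [int(v) for v in range(P) if (dig[v] != 0).all()]
    valid, bad_col = _transition_table(rows)
    dcol = (dig == 1).sum(axis=1) - (dig == 2).sum(axis=1)

    OFF = rows * cols
    D = 2 * rows * cols + 2
    states = {(0, 0): np.zeros(D, dtype=np.int64)}
    states[(0, 0)][OFF] = 1
    for _ in range(cols):
        new_states: dict = {}
        for (a, b), vec in states.items():
            for n in full_cols:
                if bad_col[n] or not valid[a, b, n]:
                    continue
                key = (b // P, (b % P) * P + n)
                tgt = new_states.get(key)
                if tgt is None:
                    tgt = np.zeros(D, dtype=np.int64)
                    new_states[key] = tgt
                dn = int(dcol[n])
                if dn > 0:
                    tgt[dn:] += vec[:-dn]
                elif dn < 0:
                    tgt[:dn] += vec[-dn:]
                else:
                    tgt += vec
        states = new_states
    return int(sum(int(v[OFF]) + int(v[OFF + 1]) for v in states.values()))


def brute_force_count(rows: int, cols: int, batch: int = 1 << 21) -> int:
    """Oracle: enumerate all 3^(rows*cols) assignments (boards of <= 16 cells)."""
    cells = rows * cols
    if cells > 16:
        raise ValueError("brute force limited to boards with at most 16 cells")
    geom = Geometry(rows, cols)
    windows = geom.window_array  # (W, 4), row-major square indexing
    pows = 3 ** np.arange(cells, dtype=np.int64)
    total = 0
    n_all = 3 ** cells
    for start in range(0, n_all, batch):
        idx = np.arange(start, min(start + batch, n_all), dtype=np.int64)
        digits = (idx[:, None] // pows[None, :]) % 3  # (B, cells)
        n1 = (digits == 1).sum(axis=1)
        n2 = (digits == 2).sum(axis=1)
        ok = ((n1 - n2 == 0) | (n1 - n2 == 1)) & (n1 + n2 < cells)
        if len(windows):
            win = np.zeros(len(idx), dtype=bool)
            for v in (1, 2):
                occ = digits == v
                for w in windows:
                    win |= occ[:, w[0]] & occ[:, w[1]] & occ[:, w[2]] & occ[:, w[3]]
            ok &= ~win
        total += int(ok.sum())
    return total
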