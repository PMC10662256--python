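"""Value-function features for the planning model's heuristic evaluation.

The baseline heuristic counts, per player and per 4-square window: connected
two-in-a-rows, unconnected two-in-a-rows, three-in-a-rows and
four-in-a-rows (a window contributes a pattern for a player only when its
remaining cells are empty), plus a graded central-tendency feature on every
square.  Three extension kinds can be enabled cumulatively:

* ``corner``   — a bonus instance on each of the four corner squares,
* ``threat``   — one instance per window, realized when a player has three
  pieces and one empty cell there (an immediate threat to win); the agent
  weighs these asymmetrically, for the opponent only,
* ``phantom3`` — contiguous three-in-a-rows that can no longer be completed
  to four: every containing window's fourth square is occupied, or the
  extensions run off the board (the corner-diagonal case).

Pattern features are counted per window, so a pair of pieces lying in two
windows counts twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np

from .board import Board, Geometry, DEFAULT_GEOMETRY, apply_move, is_win

CONN2 = "conn2"
UNCONN2 = "unconn2"
THREE = "three"
FOUR = "four"
CENTER = "center"
CORNER = "corner"
THREAT = "threat"
PHANTOM3 = "phantom3"

PATTERN_KINDS = (CONN2, UNCONN2, THREE, FOUR)
BASELINE_KINDS = PATTERN_KINDS + (CENTER,)
ALL_KINDS = BASELINE_KINDS + (CORNER, THREAT, PHANTOM3)

# 4-bit occupancy masks (bit i = i-th cell of the window) of two adjacent pieces
_ADJACENT_PAIR_MASKS = frozenset({0b0011, 0b0110, 0b1100})


@dataclass(frozen=True)
class ExtensionFlags:
    corner: bool = False
    threat: bool = False
    phantom: bool = False

    @classmethod
    def for_model(cls, name: str) -> "ExtensionFlags":
        """Cumulative extension sets: baseline -> corner -> defensive -> phantom."""
        order = {"baseline": (False, False, False),
                 "corner": (True, False, False),
                 "defensive": (True, True, False),
                 "phantom": (True, True, True)}
        if name not in order:
            raise ValueError(f"unknown model variant {name!r}; choose from {sorted(order)}")
        return cls(*order[name])


@dataclass(frozen=True)
class FeatureInstance:
    id: int
    kind: str
    squares: tuple
    graded_value: float = 1.0
    # for phantom3: the in-board fourth squares of containing windows; all of
    # them must be occupied for the instance to be realized
    completions: tuple = ()


def center_value(square: int, geometry: Geometry = DEFAULT_GEOMETRY) -> float:
    """Graded central-tendency value 1/(1 + Euclidean distance to board center)."""
    r, c = geometry.coords(square)
    cr, cc = geometry.center
    return 1.0 / (1.0 + float(np.hypot(r - cr, c - cc)))


def corner_squares(geometry: Geometry = DEFAULT_GEOMETRY) -> tuple:
    return (geometry.index(0, 0), geometry.index(0, geometry.cols - 1),
            geometry.index(geometry.rows - 1, 0),
            geometry.index(geometry.rows - 1, geometry.cols - 1))


def _contiguous_triples(geometry: Geometry):
    """All collinear contiguous in-board triples with their completion squares."""
    triples = []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (-1, 1)):
        for r in range(geometry.rows):
            for c in range(geometry.cols):
                rr, cc = r + 2 * dr, c + 2 * dc
                if not (0 <= rr < geometry.rows and 0 <= cc < geometry.cols):
                    continue
                cells = tuple(geometry.index(r + i * dr, c + i * dc) for i in range(3))
                comps = []
                for er, ec in ((r - dr, c - dc), (r + 3 * dr, c + 3 * dc)):
                    if 0 <= er < geometry.rows and 0 <= ec < geometry.cols:
                        comps.append(geometry.index(er, ec))
                triples.append((cells, tuple(comps)))
    return triples


class FeatureSet:
    """Deterministic instance list plus vectorized lookup tables.

    Instance ids are assigned in a fixed order: window-pattern instances
    (4 kinds per window), then center instances (one per square), then —
    depending on the extension flags — corner, threat and phantom3 instances.
    """

    def __init__(self, flags: ExtensionFlags = ExtensionFlags(),
                 geometry: Geometry = DEFAULT_GEOMETRY):
        self.flags = flags
        self.geometry = geometry
        self.windows = geometry.window_array  # (W, 4)
        self.n_windows = len(self.windows)
        self.center_values = np.array(
            [center_value(s, geometry) for s in range(geometry.n_squares)])
        self.corners = np.array(corner_squares(geometry), dtype=np.int64)
        trip = _contiguous_triples(geometry)
        self.triples = np.array([t[0] for t in trip], dtype=np.int64)
        self.completions = [np.array(t[1], dtype=np.int64) for t in trip]
        self.instances = self._build_instances()
        self.n_instances = len(self.instances)
        self._offsets = self._build_offsets()

    def _build_instances(self) -> list[FeatureInstance]:
        g = self.geometry
        out = []
        nid = 0
        for w in range(self.n_windows):
            squares = tuple(int(s) for s in self.windows[w])
            for kind in PATTERN_KINDS:
                out.append(FeatureInstance(nid, kind, squares))
                nid += 1
        for s in range(g.n_squares):
            out.append(FeatureInstance(nid, CENTER, (s,), self.center_values[s]))
            nid += 1
        if self.flags.corner:
            for s in self.corners:
                out.append(FeatureInstance(nid, CORNER, (int(s),)))
                nid += 1
        if self.flags.threat:
            for w in range(self.n_windows):
                squares = tuple(int(s) for s in self.windows[w])
                out.append(FeatureInstance(nid, THREAT, squares))
                nid += 1
        if self.flags.phantom:
            for t in range(len(self.triples)):
                out.append(FeatureInstance(
                    nid, PHANTOM3, tuple(int(s) for s in self.triples[t]),
                    completions=tuple(int(s) for s in self.completions[t])))
                nid += 1
        return out

    def _build_offsets(self):
        off, nid = {}, 0
        off["pattern"] = nid
        nid += 4 * self.n_windows
        off[CENTER] = nid
        nid += self.geometry.n_squares
        if self.flags.corner:
            off[CORNER] = nid
            nid += len(self.corners)
        if self.flags.threat:
            off[THREAT] = nid
            nid += self.n_windows
        if self.flags.phantom:
            off[PHANTOM3] = nid
            nid += len(self.triples)
        return off

    def all_ids(self) -> frozenset:
        return frozenset(range(self.n_instances))

    def active_masks(self, active: Optional[Iterable[int]]) -> dict:
        """Split an active-id set into boolean masks per feature family."""
        if active is None:
            keep = np.ones(self.n_instances, dtype=bool)
        else:
            keep = np.zeros(self.n_instances, dtype=bool)
            idx = np.fromiter((int(i) for i in active), dtype=np.int64,
                              count=len(active) if hasattr(active, "__len__") else -1)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_instances):
                raise ValueError("active ids outside instance range")
            keep[idx] = True
        off = self._offsets
        masks = {
            "pattern": keep[off["pattern"]:off["pattern"] + 4 * self.n_windows]
            .reshape(self.n_windows, 4).copy(),
            CENTER: keep[off[CENTER]:off[CENTER] + self.geometry.n_squares].copy(),
        }
        masks[CORNER] = (keep[off[CORNER]:off[CORNER] + len(self.corners)].copy()
                         if self.flags.corner else np.zeros(len(self.corners), bool))
        masks[THREAT] = (keep[off[THREAT]:off[THREAT] + self.n_windows].copy()
                         if self.flags.threat else np.zeros(self.n_windows, bool))
        masks[PHANTOM3] = (keep[off[PHANTOM3]:off[PHANTOM3] + len(self.triples)].copy()
                           if self.flags.phantom else np.zeros(len(self.triples), bool))
        return masks


@lru_cache(maxsize=16)
def _cached_feature_set(flags: ExtensionFlags, geometry: Geometry) -> FeatureSet:
    return FeatureSet(flags, geometry)


def get_feature_set(flags: ExtensionFlags = ExtensionFlags(),
                    geometry: Geometry = DEFAULT_GEOMETRY) -> FeatureSet:
    return _cached_feature_set(flags, geometry)


def enumerate_instances(flags: ExtensionFlags = ExtensionFlags(),
                        geometry: Geometry = DEFAULT_GEOMETRY) -> list[FeatureInstance]:
    return list(get_feature_set(flags, geometry).instances)


@dataclass
class FeatureCounts:
    """Realized feature counts per kind, indexed by player (1 or 2)."""

    counts: dict  # kind -> np.ndarray([count_p1, count_p2])

    def get(self, kind: str, player: int) -> float:
        return float(self.counts[kind][player - 1])

    def as_dict(self) -> dict:
        return {k: (float(v[0]), float(v[1])) for k, v in self.counts.items()}


def _window_masks(board: Board, fs: FeatureSet) -> tuple[np.ndarray, np.ndarray]:
    """4-bit occupancy mask of each window for both players, (W,) each."""
    occ = board.occupancy()
    bits = 1 << np.arange(fs.windows.shape[1])
    m1 = (occ[0][fs.windows] * bits).sum(axis=1)
    m2 = (occ[1][fs.windows] * bits).sum(axis=1)
    return m1, m2


_POPCOUNT4 = np.array([bin(i).count("1") for i in range(16)])
_IS_ADJ_PAIR = np.array([i in _ADJACENT_PAIR_MASKS for i in range(16)])


def _pattern_indicators(m_self: np.ndarray, m_opp: np.ndarray) -> dict:
    """Per-window 0/1 indicators of each pattern kind for one player."""
    empty_rest = m_opp == 0
    n = _POPCOUNT4[m_self]
    return {
        CONN2: (empty_rest & (n == 2) & _IS_ADJ_PAIR[m_self]).astype(float),
        UNCONN2: (empty_rest & (n == 2) & ~_IS_ADJ_PAIR[m_self]).astype(float),
        THREE: (empty_rest & (n == 3)).astype(float),
        FOUR: (n == 4).astype(float),
    }


def count_features(board: Board, root_player: int = 1,
                   active: Optional[Iterable[int]] = None,
                   flags: ExtensionFlags = ExtensionFlags(),
                   geometry: Optional[Geometry] = None) -> FeatureCounts:
    """Realized feature counts for both players, restricted to ``active`` instances.

    ``root_player`` only orients convenience accessors; counts are reported
    for both players.  With ``active=None`` every instance is active.
    """
    fs = get_feature_set(flags, geometry or board.geometry)
    masks = fs.active_masks(active)
    m1, m2 = _window_masks(board, fs)
    occ = board.occupancy()

    counts: dict[str, np.ndarray] = {}
    ind1 = _pattern_indicators(m1, m2)
    ind2 = _pattern_indicators(m2, m1)
    for j, kind in enumerate(PATTERN_KINDS):
        act = masks["pattern"][:, j]
        counts[kind] = np.array([float(ind1[kind][act].sum()),
                                 float(ind2[kind][act].sum())])
    cv = fs.center_values * masks[CENTER]
    counts[CENTER] = np.array([float(cv[occ[0]].sum()), float(cv[occ[1]].sum())])
    if fs.flags.corner:
        act = masks[CORNER]
        counts[CORNER] = np.array(
            [float(occ[0][fs.corners][act].sum()), float(occ[1][fs.corners][act].sum())])
    if fs.flags.threat:
        act = masks[THREAT]
        counts[THREAT] = np.array([float(ind1[THREE][act].sum()),
                                   float(ind2[THREE][act].sum())])
    if fs.flags.phantom:
        act = masks[PHANTOM3]
        full = occ[0] | occ[1]
        vals = np.zeros(2)
        for t in np.nonzero(act)[0]:
            cells = fs.triples[t]
            comp = fs.completions[t]
            if comp.size and not full[comp].all():
                continue
            if occ[0][cells].all():
                vals[0] += 1.0
            elif occ[1][cells].all():
                vals[1] += 1.0
        counts[PHANTOM3] = vals
    return FeatureCounts(counts)


def count_features_delta(board: Board, mover: int, square: int,
                         active: Optional[Iterable[int]] = None,
                         flags: ExtensionFlags = ExtensionFlags()) -> FeatureCounts:
    """Counts after ``mover`` plays ``square``, via incremental recount.

    Only windows, triples and graded squares touching the move are
    re-classified; equals ``count_features`` on the post-move board.
    """
    fs = get_feature_set(flags, board.geometry)
    masks = fs.active_masks(active)
    pre = count_features(board, 1, active, flags)
    post_board = apply_move(board, mover, square)

    touched_w = np.any(fs.windows == square, axis=1)
    m1a, m2a = _window_masks(board, fs)
    m1b, m2b = _window_masks(post_board, fs)
    counts = {k: v.copy() for k, v in pre.counts.items()}

    ind = {p: (_pattern_indicators(m1a, m2a) if p == 1 else _pattern_indicators(m2a, m1a))
           for p in (1, 2)}
    ind_b = {1: _pattern_indicators(m1b, m2b), 2: _pattern_indicators(m2b, m1b)}
    for j, kind in enumerate(PATTERN_KINDS):
        sel = masks["pattern"][:, j] & touched_w
        for p in (1, 2):
            counts[kind][p - 1] += float(ind_b[p][kind][sel].sum() - ind[p][kind][sel].sum())
    if masks[CENTER][square]:
        counts[CENTER][mover - 1] += fs.center_values[square]
    if fs.flags.corner:
        hit = (fs.corners == square) & masks[CORNER]
        counts[CORNER][mover - 1] += float(hit.sum())
    if fs.flags.threat:
        sel = masks[THREAT] & touched_w
        for p in (1, 2):
            counts[THREAT][p - 1] += float(
                ind_b[p][THREE][sel].sum() - ind[p][THREE][sel].sum())
    if fs.flags.phantom:
        occ_a = board.occupancy()
        occ_b = post_board.occupancy()
        full_a = occ_a[0] | occ_a[1]
        full_b = occ_b[0] | occ_b[1]
        act = masks[PHANTOM3]
        for t in np.nonzero(act)[0]:
            cells = fs.triples[t]
            comp = fs.completions[t]
            if square not in cells and (comp.size == 0 or square not in comp):
                continue
            for occ, full, sign in ((occ_a, full_a, -1.0), (occ_b, full_b, 1.0)):
                if comp.size and not full[comp].all():
                    continue
                if occ[0][cells].all():
                    counts[PHANTOM3][0] += sign
                elif occ[1][cells].all():
                    counts[PHANTOM3][1] += sign
    return FeatureCounts(counts)


def threat_squares(board: Board, player: int) -> frozenset:
    """Empty squares that would complete a four-in-a-row for ``player``.

    Parity is ignored: threats are defined for either player in any position.
    """
    fs = get_feature_set(ExtensionFlags(), board.geometry)
    occ = board.occupancy()
    own = occ[player - 1][fs.windows]
    opp = occ[2 - player][fs.windows]
    hit = (own.sum(axis=1) == 3) & (opp.sum(axis=1) == 0)
    out = set()
    for w in np.nonzero(hit)[0]:
        for s in fs.windows[w]:
            if not occ[0][s] and not occ[1][s]:
                out.add(int(s))
    return frozenset(out)
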