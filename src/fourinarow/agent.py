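"""The planning agent: noisy heuristic evaluation plus best-first tree search.

The agent values a position as a weighted sum of realized feature counts,
own minus opponent (the opponent's counts scaled by ``c_opp``), with
zero-mean Gaussian noise added once per evaluated node.  Search repeatedly
follows the principal variation — the locally best move for both players —
to an unexpanded leaf, expands it with one child per legal move, prunes
children whose value falls more than ``theta`` behind the best sibling
(irreversibly), and backs values up the path (max at the agent's nodes, min
at the opponent's).  After every expansion the search stops with probability
``gamma``.  Moves are the best root child, except for a ``lam`` lapse rate
of uniformly random legal moves; before each move a random subset of feature
instances is dropped (probability ``delta`` each), modeling attentional
lapses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
from scipy.stats import norm

from .board import Board, ONGOING, is_terminal, legal_moves
from .features import (
    CENTER, CONN2, FOUR, PHANTOM3, THREAT, THREE, UNCONN2,
    ExtensionFlags, FeatureSet, count_features, get_feature_set,
)

WEIGHT_KINDS = (CONN2, UNCONN2, THREE, FOUR, CENTER)


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the planning model.

    Weights are the heuristic feature weights; ``c_opp`` scales the
    opponent's feature counts; ``theta`` is the pruning threshold; ``gamma``
    the per-iteration stopping probability; ``delta`` the per-instance
    feature-dropout probability; ``lam`` the lapse rate (uniform random
    moves); ``sigma`` the evaluation-noise SD (fixed to 1 by default — the
    weights absorb the value scale).  Extensions: a per-corner opening bonus,
    an opponent-threat (defensive) weight, and a phantom three-in-a-row
    weight, enabled cumulatively in the fitted model family.
    """

    w_conn2: float = 0.9
    w_unconn2: float = 0.45
    w_three: float = 3.5
    w_four: float = 8.0
    w_center: float = 0.6
    c_opp: float = 0.9
    theta: float = 2.0
    gamma: float = 0.25
    delta: float = 0.15
    lam: float = 0.1
    sigma: float = 1.0
    corner: bool = False
    w_corner: tuple = (0.0, 0.0, 0.0, 0.0)
    threat: bool = False
    w_def: float = 0.0
    phantom: bool = False
    w_phantom: float = 0.0
    max_iterations: int = 100

    def __post_init__(self):
        for name in ("gamma", "delta", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "w_corner", tuple(float(w) for w in self.w_corner))

    @property
    def flags(self) -> ExtensionFlags:
        return ExtensionFlags(self.corner, self.threat, self.phantom)

    @property
    def weights(self) -> dict:
        return {CONN2: self.w_conn2, UNCONN2: self.w_unconn2, THREE: self.w_three,
                FOUR: self.w_four, CENTER: self.w_center}

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        d = json.loads(text)
        d["w_corner"] = tuple(d.get("w_corner", (0.0,) * 4))
        return cls(**d)

    def evolve(self, **kw) -> "ModelParams":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# Feature dropout
# --------------------------------------------------------------------------

def _draw_keep_mask(fs: FeatureSet, delta: float, rng: np.random.Generator) -> np.ndarray:
    if delta <= 0.0:
        return np.ones(fs.n_instances, dtype=bool)
    if delta >= 1.0:
        return np.zeros(fs.n_instances, dtype=bool)
    return rng.random(fs.n_instances) >= delta


def draw_active_set(params: ModelParams, rng: np.random.Generator,
                    feature_set: Optional[FeatureSet] = None) -> frozenset:
    """Each instance kept independently with probability 1 - delta.

    The set is drawn once and held fixed for the whole search of one move.
    """
    fs = feature_set or get_feature_set(params.flags)
    keep = _draw_keep_mask(fs, params.delta, rng)
    return frozenset(int(i) for i in np.nonzero(keep)[0])


# --------------------------------------------------------------------------
# Heuristic evaluation
# --------------------------------------------------------------------------

def heuristic_value(board: Board, root_player: int,
                    active: Optional[frozenset], params: ModelParams,
                    rng: Optional[np.random.Generator] = None) -> float:
    """Noisy linear heuristic from the root player's perspective.

    Reference implementation over :func:`count_features`; the search uses a
    vectorized but numerically identical evaluator.  Noise is added only
    when ``rng`` is given and ``sigma`` > 0.
    """
    fs = get_feature_set(params.flags, board.geometry)
    counts = count_features(board, root_player, active, params.flags, board.geometry)
    opp = 3 - root_player
    v = sum(w * (counts.get(k, root_player) - params.c_opp * counts.get(k, opp))
            for k, w in params.weights.items())
    if params.corner:
        masks = fs.active_masks(active)
        own = board.pieces(root_player)
        for j, sq in enumerate(fs.corners):
            if masks["corner"][j] and int(sq) in own:
                v += params.w_corner[j]
    if params.threat:
        v -= params.w_def * counts.get(THREAT, opp)
    if params.phantom:
        v += params.w_phantom * (counts.get(PHANTOM3, root_player)
                                 - params.c_opp * counts.get(PHANTOM3, opp))
    if rng is not None and params.sigma > 0:
        v += params.sigma * rng.standard_normal()
    return float(v)


class _FastEvaluator:
    """Vectorized child evaluation used inside the search.

    Values every legal successor of a node in one batch of NumPy table
    lookups; agrees exactly (minus noise) with :func:`heuristic_value`.
    """

    def __init__(self, fs: FeatureSet):
        self.fs = fs
        g = fs.geometry
        W = fs.n_windows
        self.n_sq = g.n_squares
        # per-square window bit increments: add[s, w] = 1 << position
        add = np.zeros((self.n_sq, W), dtype=np.int64)
        for w in range(W):
            for pos, s in enumerate(fs.windows[w]):
                add[s, w] = 1 << pos
        self.add = add
        pc = np.array([bin(i).count("1") for i in range(16)])
        adj = np.array([i in (0b0011, 0b0110, 0b1100) for i in range(16)])
        empty = np.zeros((16, 16), dtype=np.float64)
        self.T = {}
        for kind in (CONN2, UNCONN2, THREE, FOUR):
            t = np.zeros((16, 16))
            for ms in range(16):
                for mo in range(16):
                    if kind == FOUR:
                        t[ms, mo] = float(pc[ms] == 4)
                    elif mo != 0:
                        t[ms, mo] = 0.0
                    elif kind == THREE:
                        t[ms, mo] = float(pc[ms] == 3)
                    elif kind == CONN2:
                        t[ms, mo] = float(pc[ms] == 2 and adj[ms])
                    else:
                        t[ms, mo] = float(pc[ms] == 2 and not adj[ms])
            self.T[kind] = t
        T_tri = len(fs.triples)
        self.tri_has = np.zeros((self.n_sq, T_tri), dtype=bool)
        self.comp_has = np.zeros((self.n_sq, T_tri), dtype=bool)
        for t in range(T_tri):
            self.tri_has[fs.triples[t], t] = True
            if fs.completions[t].size:
                self.comp_has[fs.completions[t], t] = True
        self.comp_total = np.array([c.size for c in fs.completions])

    def window_masks(self, occ1: np.ndarray, occ2: np.ndarray):
        m1 = occ1 @ self.add
        m2 = occ2 @ self.add
        return m1, m2

    def eval_children(self, occ1, occ2, m1, m2, mover, root_player, squares,
                      masks, params: ModelParams,
                      rng: Optional[np.random.Generator]):
        """Values (root perspective) of the boards after ``mover`` plays each square.

        Also returns whether each child is an immediate win for the mover.
        Returns (values, wins) arrays aligned with ``squares``.
        """
        fs, p = self.fs, params
        n = len(squares)
        d_m = self.add[squares]  # (n, W)
        if mover == 1:
            M1 = m1[None, :] + d_m
            M2 = np.broadcast_to(m2, M1.shape)
        else:
            M2 = m2[None, :] + d_m
            M1 = np.broadcast_to(m1, M2.shape)
        Mr, Mo = (M1, M2) if root_player == 1 else (M2, M1)

        wk = np.array([p.w_conn2, p.w_unconn2, p.w_three, p.w_four])
        wk_act = masks["pattern"] * wk[None, :]  # (W, 4)
        v = np.zeros(n)
        for j, kind in enumerate((CONN2, UNCONN2, THREE, FOUR)):
            t = self.T[kind]
            v += (t[Mr, Mo] - p.c_opp * t[Mo, Mr]) @ wk_act[:, j]

        cv = fs.center_values * masks[CENTER]
        occ_r, occ_o = (occ1, occ2) if root_player == 1 else (occ2, occ1)
        c_root = float(cv @ occ_r)
        c_opp = float(cv @ occ_o)
        if mover == root_player:
            v += p.w_center * ((c_root + cv[squares]) - p.c_opp * c_opp)
        else:
            v += p.w_center * (c_root - p.c_opp * (c_opp + cv[squares]))

        if p.corner:
            wc = np.asarray(p.w_corner) * masks["corner"]
            base = float(wc @ occ_r[fs.corners])
            v += base
            if mover == root_player:
                for j, sq in enumerate(fs.corners):
                    v[squares == sq] += wc[j]

        if p.threat:
            t3 = self.T[THREE]
            wt = masks["threat"].astype(float) * p.w_def
            v -= t3[Mo, Mr] @ wt

        if p.phantom and masks[PHANTOM3].any():
            v += p.w_phantom * self._phantom_term(
                occ_r, occ_o, mover == root_player, squares, masks[PHANTOM3], p.c_opp)

        if rng is not None and p.sigma > 0:
            v = v + p.sigma * rng.standard_normal(n)

        wins = (self.T[FOUR][Mr, Mo].any(axis=1) if mover == root_player
                else self.T[FOUR][Mo, Mr].any(axis=1))
        return v, wins

    def _phantom_term(self, occ_r, occ_o, mover_is_root, squares, act, c_opp):
        fs = self.fs
        own_in = occ_r.astype(np.int64) @ self.tri_has  # (T,)
        opp_in = occ_o.astype(np.int64) @ self.tri_has
        full = (occ_r | occ_o).astype(np.int64)
        comp_occ = full @ self.comp_has
        d_tri = self.tri_has[squares]  # (n, T)
        d_comp = self.comp_has[squares]
        comp_done = (comp_occ[None, :] + d_comp) >= self.comp_total[None, :]
        if mover_is_root:
            own3 = (own_in[None, :] + d_tri) == 3
            opp3 = np.broadcast_to(opp_in == 3, own3.shape)
        else:
            opp3 = (opp_in[None, :] + d_tri) == 3
            own3 = np.broadcast_to(own_in == 3, opp3.shape)
        actf = act.astype(float)
        return ((own3 & comp_done) @ actf) - c_opp * ((opp3 & comp_done) @ actf)


def _get_fast_evaluator(fs: FeatureSet) -> _FastEvaluator:
    ev = getattr(fs, "_fast_evaluator", None)
    if ev is None:
        ev = _FastEvaluator(fs)
        fs._fast_evaluator = ev
    return ev


# --------------------------------------------------------------------------
# Best-first search
# --------------------------------------------------------------------------

@dataclass
class SearchNode:
    """A node of the search tree; ``value`` is from the root player's perspective."""

    occ1: np.ndarray
    occ2: np.ndarray
    mover: int
    value: float = np.nan
    move: Optional[int] = None
    children: list = field(default_factory=list)  # of SearchNode
    pruned: bool = False
    expanded: bool = False
    is_win: bool = False
    is_full: bool = False

    @property
    def terminal(self) -> bool:
        return self.is_win or self.is_full

    @property
    def board(self) -> Board:
        return Board(frozenset(np.nonzero(self.occ1)[0].tolist()),
                     frozenset(np.nonzero(self.occ2)[0].tolist()))

    def unpruned_children(self) -> list:
        return [c for c in self.children if not c.pruned]


def _select_child(node: SearchNode, root_player: int) -> SearchNode:
    kids = node.unpruned_children()
    vals = [c.value for c in kids]
    i = int(np.argmax(vals)) if node.mover == root_player else int(np.argmin(vals))
    return kids[i]


def _backup(path: list, root_player: int) -> None:
    for node in reversed(path):
        if not node.expanded:
            continue
        vals = [c.value for c in node.unpruned_children()]
        node.value = max(vals) if node.mover == root_player else min(vals)


def _expand(node: SearchNode, root_player: int, ev: _FastEvaluator,
            masks, params: ModelParams, rng) -> None:
    occ1, occ2 = node.occ1, node.occ2
    empty = ~(occ1 | occ2)
    squares = np.nonzero(empty)[0]
    m1, m2 = ev.window_masks(occ1, occ2)
    vals, wins = ev.eval_children(occ1, occ2, m1, m2, node.mover, root_player,
                                  squares, masks, params, rng)
    full_after = squares.size == 1
    for i, s in enumerate(squares):
        c1, c2 = occ1, occ2
        if node.mover == 1:
            c1 = occ1.copy(); c1[s] = True
        else:
            c2 = occ2.copy(); c2[s] = True
        node.children.append(SearchNode(
            occ1=c1, occ2=c2, mover=3 - node.mover, value=float(vals[i]),
            move=int(s), is_win=bool(wins[i]), is_full=full_after and not wins[i]))
    # prune: drop children worse than the best sibling by more than theta
    if np.isfinite(params.theta):
        if node.mover == root_player:
            cut = vals.max() - params.theta
            for c, v in zip(node.children, vals):
                if v < cut:
                    c.pruned = True
        else:
            cut = vals.min() + params.theta
            for c, v in zip(node.children, vals):
                if v > cut:
                    c.pruned = True
    node.expanded = True


def best_first_search(board: Board, root_player: int, params: ModelParams,
                      rng: np.random.Generator,
                      active: Optional[frozenset] = None) -> SearchNode:
    """Run the stochastic best-first search; returns the root node.

    ``active`` is the dropout draw for this move (``None`` = all instances).
    The search stops after each expansion with probability ``gamma``, when a
    terminal node is reached on the principal variation, or at the
    ``max_iterations`` hard cap.
    """
    if is_terminal(board) != ONGOING:
        raise ValueError("cannot search from a terminal board")
    if root_player != board.mover:
        raise ValueError("root player must be the player to move")
    fs = get_feature_set(params.flags, board.geometry)
    ev = _get_fast_evaluator(fs)
    masks = fs.active_masks(active)
    occ = board.occupancy()
    root = SearchNode(occ1=occ[0], occ2=occ[1], mover=root_player)

    iterations = 0
    while True:
        path = [root]
        node = root
        while node.expanded:
            node = _select_child(node, root_player)
            path.append(node)
        iterations += 1
        if node.terminal:
            break  # the principal variation ends in a decided position
        _expand(node, root_player, ev, masks, params, rng)
        _backup(path, root_player)
        if iterations >= params.max_iterations:
            break
        if params.gamma > 0 and rng.random() < params.gamma:
            break
    return root


# --------------------------------------------------------------------------
# Move sampling and policy estimation
# --------------------------------------------------------------------------

def sample_move(board: Board, mover: int, params: ModelParams,
                rng: np.random.Generator) -> int:
    """One stochastic move: lapse uniformly with probability ``lam``, else search."""
    if is_terminal(board) != ONGOING:
        raise ValueError("cannot move on a terminal board")
    legal = sorted(legal_moves(board))
    if params.lam > 0 and rng.random() < params.lam:
        return int(legal[rng.integers(len(legal))])
    fs = get_feature_set(params.flags, board.geometry)
    keep = _draw_keep_mask(fs, params.delta, rng)
    active = None if keep.all() else frozenset(np.nonzero(keep)[0].tolist())
    root = best_first_search(board, mover, params, rng, active)
    kids = root.unpruned_children()
    vals = np.array([c.value for c in kids])
    best = np.nonzero(vals == vals.max())[0]
    pick = best[0] if best.size == 1 else best[rng.integers(best.size)]
    return int(kids[pick].move)


def estimate_policy(board: Board, mover: int, params: ModelParams,
                    n_sims: int = 200, rng: Optional[np.random.Generator] = None,
                    alpha: float = 0.0) -> np.ndarray:
    """Empirical move distribution from ``n_sims`` simulated moves.

    Returns a length-36 probability vector, exactly zero on occupied squares;
    ``alpha`` is a pseudocount added to every legal square.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    g = board.geometry
    counts = np.zeros(g.n_squares)
    for _ in range(n_sims):
        counts[sample_move(board, mover, params, rng)] += 1.0
    legal = sorted(legal_moves(board))
    probs = np.zeros(g.n_squares)
    denom = n_sims + alpha * len(legal)
    probs[legal] = (counts[legal] + alpha) / denom
    return probs


def depth1_values(board: Board, mover: int, params: ModelParams):
    """Deterministic (noise-free) child values of the depth-one agent.

    Returns (squares, values) for all legal moves, with all feature
    instances active.  For agents with ``gamma=1`` and ``delta=0`` the move
    distribution is the argmax of these values plus iid N(0, sigma^2) noise,
    mixed with a ``lam`` uniform lapse.
    """
    fs = get_feature_set(params.flags, board.geometry)
    ev = _get_fast_evaluator(fs)
    occ = board.occupancy()
    squares = np.nonzero(~(occ[0] | occ[1]))[0]
    m1, m2 = ev.window_masks(occ[0], occ[1])
    vals, _ = ev.eval_children(occ[0], occ[1], m1, m2, mover, mover,
                               squares, fs.active_masks(None), params, rng=None)
    return squares, vals


def depth1_policy_exact(board: Board, mover: int, params: ModelParams,
                        n_quad: int = 101) -> np.ndarray:
    """Closed-form move distribution of the depth-one agent (gamma=1, delta=0).

    With a single expansion the move is the argmax of deterministic child
    values plus iid Gaussian noise; the win probability of each square is a
    1-D Gaussian integral, evaluated by Gauss-Hermite quadrature.  Used as
    an analytic oracle for the simulator and as the cross-entropy floor of
    depth-one generators.
    """
    if params.delta != 0:
        raise ValueError("exact policy requires delta=0 (no feature dropout)")
    squares, vals = depth1_values(board, mover, params)
    n = squares.size
    probs = np.zeros(board.geometry.n_squares)
    if params.sigma == 0:
        top = vals == vals.max()
        p_search = top / top.sum()
    else:
        x, w = np.polynomial.hermite_e.hermegauss(n_quad)
        w = w / np.sqrt(2 * np.pi)
        z = x[None, :]  # (1, Q)
        p_search = np.empty(n)
        for i in range(n):
            gaps = (vals[i] - np.delete(vals, i)) / params.sigma
            p_search[i] = float(w @ np.prod(norm.cdf(z + gaps[:, None]), axis=0))
        p_search = p_search / p_search.sum()
    probs[squares] = params.lam / n + (1 - params.lam) * p_search
    return probs
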