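"""Move-prediction policy network with illegal-move masking.

Architecture: the 2x4x9 board encoding is flattened to 72 units and
projected to ``n_units``; each of ``n_layers`` residual blocks applies
affine -> ReLU -> affine and adds the block input (skip connection); a final
affine maps to 36 logits.  A large constant is subtracted from logits at
occupied squares before the softmax, after which those entries are set to
exactly zero and the legal entries renormalized — occupied squares therefore
receive zero probability and contribute zero gradient.

Training is behavioral cloning: minimize the mean negative log-likelihood of
observed moves with Adam and early stopping on a validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .board import MoveObservation, encode_planes


@dataclass(frozen=True)
class NetworkConfig:
    n_layers: int = 5
    n_units: int = 64
    n_input: int = 72
    n_output: int = 36
    mask_penalty: float = 1e9
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1 or self.n_units < 1:
            raise ValueError("n_layers and n_units must be >= 1")


@dataclass
class TrainConfig:
    batch_size: int = 256
    learning_rate: float = 1e-3
    max_epochs: int = 50
    patience: int = 5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


def dataset_from_observations(obs: Sequence[MoveObservation]):
    """(X, chosen, legal, move_number) arrays for a batch of observations."""
    n = len(obs)
    X = np.empty((n, 72))
    chosen = np.empty(n, dtype=np.int64)
    legal = np.empty((n, 36), dtype=bool)
    move_no = np.empty(n, dtype=np.int64)
    for i, ob in enumerate(obs):
        planes = encode_planes(ob.board, ob.mover)
        X[i] = planes.reshape(-1)
        chosen[i] = ob.chosen
        occ = planes[0].reshape(-1) + planes[1].reshape(-1)
        legal[i] = occ == 0
        move_no[i] = ob.move_number
    return X, chosen, legal, move_no


class PolicyNetwork:
    """Residual MLP policy over the 36 squares."""

    def __init__(self, config: NetworkConfig = NetworkConfig(),
                 init: str = "he"):
        self.config = config
        rng = np.random.default_rng(config.seed)
        H, L = config.n_units, config.n_layers
        if init == "zero":
            def w(a, b):
                return np.zeros((a, b))
        else:
            def w(a, b):
                return rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
        # zero-init output head: the initial policy is exactly uniform over
        # legal squares, so training starts at the uniform baseline
        self.params = {"W_in": w(config.n_input, H), "b_in": np.zeros(H),
                       "W_out": np.zeros((H, config.n_output)),
                       "b_out": np.zeros(config.n_output)}
        for l in range(L):
            self.params[f"A{l}"] = w(H, H)
            self.params[f"a{l}"] = np.zeros(H)
            self.params[f"B{l}"] = w(H, H)
            self.params[f"b{l}"] = np.zeros(H)

    # -- forward / backward ------------------------------------------------
    def _forward_raw(self, X: np.ndarray):
        p = self.params
        cache = {"X": X}
        h = X @ p["W_in"] + p["b_in"]
        cache["h0"] = h
        for l in range(self.config.n_layers):
            pre = h @ p[f"A{l}"] + p[f"a{l}"]
            mid = np.maximum(pre, 0.0)
            h = h + mid @ p[f"B{l}"] + p[f"b{l}"]
            cache[f"pre{l}"] = pre
            cache[f"mid{l}"] = mid
            cache[f"h{l + 1}"] = h
        logits = h @ p["W_out"] + p["b_out"]
        cache["logits"] = logits
        return logits, cache

    def forward(self, X: np.ndarray, legal: np.ndarray,
                return_cache: bool = False):
        """Masked move probabilities for a batch.

        ``X`` is (n, 72) flattened planes (or (n,2,4,9)); ``legal`` is an
        (n, 36) boolean mask of empty squares.  Occupied squares come back
        exactly zero.
        """
        X = np.asarray(X, dtype=float).reshape(len(X), -1)
        legal = np.asarray(legal, dtype=bool)
        logits, cache = self._forward_raw(X)
        masked = logits - self.config.mask_penalty * (~legal)
        masked = masked - masked.max(axis=1, keepdims=True)
        expl = np.exp(masked)
        expl[~legal] = 0.0  # exact zero on occupied squares
        probs = expl / expl.sum(axis=1, keepdims=True)
        if return_cache:
            return probs, cache
        return probs

    def policy(self, board, mover: int) -> np.ndarray:
        """Single-board convenience wrapper returning a 36-vector."""
        planes = encode_planes(board, mover)
        legal = (planes[0] + planes[1]).reshape(1, -1) == 0
        return self.forward(planes.reshape(1, -1), legal)[0]

    def _gradients(self, X, chosen, legal):
        probs, cache = self.forward(X, legal, return_cache=True)
        n = len(X)
        # d(mean NLL)/d logits = (p - onehot)/n on legal squares, 0 elsewhere
        dlogits = probs.copy()
        dlogits[np.arange(n), chosen] -= 1.0
        dlogits[~legal] = 0.0
        dlogits /= n
        p, g = self.params, {}
        L = self.config.n_layers
        h_last = cache[f"h{L}"]
        g["W_out"] = h_last.T @ dlogits
        g["b_out"] = dlogits.sum(axis=0)
        dh = dlogits @ p["W_out"].T
        for l in range(L - 1, -1, -1):
            mid, pre = cache[f"mid{l}"], cache[f"pre{l}"]
            h_in = cache[f"h{l}"]
            dmid = dh @ p[f"B{l}"].T
            g[f"B{l}"] = mid.T @ dh
            g[f"b{l}"] = dh.sum(axis=0)
            dpre = dmid * (pre > 0)
            g[f"A{l}"] = h_in.T @ dpre
            g[f"a{l}"] = dpre.sum(axis=0)
            dh = dh + dpre @ p[f"A{l}"].T  # skip connection
        g["W_in"] = cache["X"].T @ dh
        g["b_in"] = dh.sum(axis=0)
        nll = float(-np.log(probs[np.arange(n), chosen]).mean())
        return nll, g

    # -- training ----------------------------------------------------------
    def train(self, train_obs, val_obs, train_config: TrainConfig = TrainConfig(),
              rng: Optional[np.random.Generator] = None, verbose: bool = False):
        """Adam + early stopping; returns a per-epoch train/validation NLL table."""
        tc = train_config
        rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        Xt, ct, lt, _ = (train_obs if isinstance(train_obs, tuple)
                         else dataset_from_observations(train_obs))
        Xv, cv, lv, _ = (val_obs if isinstance(val_obs, tuple)
                         else dataset_from_observations(val_obs))
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(x) for k, x in self.params.items()}
        t = 0
        history = []
        best_val, best_params, since_best = np.inf, None, 0
        n = len(Xt)
        for epoch in range(tc.max_epochs):
            order = rng.permutation(n)
            epoch_nll = 0.0
            for start in range(0, n, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                nll, grads = self._gradients(Xt[idx], ct[idx], lt[idx])
                if not np.isfinite(nll):
                    raise FloatingPointError(
                        f"NaN/inf loss at epoch {epoch}, batch {start // tc.batch_size}")
                epoch_nll += nll * len(idx)
                t += 1
                for k, gk in grads.items():
                    m[k] = tc.adam_beta1 * m[k] + (1 - tc.adam_beta1) * gk
                    v[k] = tc.adam_beta2 * v[k] + (1 - tc.adam_beta2) * gk * gk
                    mhat = m[k] / (1 - tc.adam_beta1 ** t)
                    vhat = v[k] / (1 - tc.adam_beta2 ** t)
                    self.params[k] -= tc.learning_rate * mhat / (np.sqrt(vhat) + tc.adam_eps)
            val_nll = self.evaluate((Xv, cv, lv, None))["nll"]
            history.append({"epoch": epoch, "train_nll": epoch_nll / n,
                            "val_nll": val_nll})
            if verbose:
                print(f"epoch {epoch}: train {epoch_nll / n:.4f}  val {val_nll:.4f}")
            if val_nll < best_val - 1e-4:
                best_val = val_nll
                best_params = {k: x.copy() for k, x in self.params.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= tc.patience:
                    break
        if best_params is not None:
            self.params = best_params
        return pd.DataFrame(history)

    # -- evaluation --------------------------------------------------------
    def evaluate(self, obs, by_move_number: bool = False):
        """NLL/move (nats), top-1 accuracy and mean output entropy.

        With ``by_move_number`` a per-move-number breakdown DataFrame is
        added under key ``"groups"``.
        """
        X, chosen, legal, move_no = (obs if isinstance(obs, tuple)
                                     else dataset_from_observations(obs))
        probs = self.forward(X, legal)
        n = len(X)
        p_chosen = probs[np.arange(n), chosen]
        nll = -np.log(np.maximum(p_chosen, 1e-300))
        acc = (probs.argmax(axis=1) == chosen)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
        entropy = -plogp.sum(axis=1)
        out = {"nll": float(nll.mean()), "accuracy": float(acc.mean()),
               "entropy": float(entropy.mean()), "n": n}
        if by_move_number and move_no is not None:
            df = pd.DataFrame({"move_number": move_no, "nll": nll,
                               "accuracy": acc.astype(float), "entropy": entropy})
            out["groups"] = (df.groupby("move_number")
                             .agg(n=("nll", "size"), nll=("nll", "mean"),
                                  accuracy=("accuracy", "mean"),
                                  entropy=("entropy", "mean"))
                             .reset_index())
        return out

    # -- io ------------------------------------------------------------------
    def save(self, path) -> None:
        meta = np.array([self.config.n_layers, self.config.n_units,
                         self.config.n_input, self.config.n_output,
                         self.config.seed], dtype=np.int64)
        np.savez(path, __meta__=meta,
                 __penalty__=np.array([self.config.mask_penalty]), **self.params)

    @classmethod
    def load(cls, path) -> "PolicyNetwork":
        data = np.load(path)
        L, H, nin, nout, seed = (int(x) for x in data["__meta__"])
        cfg = NetworkConfig(n_layers=L, n_units=H, n_input=nin, n_output=nout,
                            mask_penalty=float(data["__penalty__"][0]), seed=seed)
        net = cls(cfg)
        net.params = {k: data[k] for k in net.params}
        return net


# --------------------------------------------------------------------------
# Board symmetries (4x9 grid): the game rules and the heuristic feature set
# are invariant under row and column reflection, so flipped copies of a move
# dataset are exact additional samples from the same policy.
# --------------------------------------------------------------------------

SYMMETRY_FLIPS = ((False, False), (True, False), (False, True), (True, True))


def flip_squares(squares: np.ndarray, flip_rows: bool, flip_cols: bool,
                 rows: int = 4, cols: int = 9) -> np.ndarray:
    r, c = np.divmod(np.asarray(squares), cols)
    if flip_rows:
        r = (rows - 1) - r
    if flip_cols:
        c = (cols - 1) - c
    return cols * r + c


def flip_planes(X: np.ndarray, legal: np.ndarray, flip_rows: bool,
                flip_cols: bool, rows: int = 4, cols: int = 9):
    Xp = X.reshape(-1, 2, rows, cols)
    Lp = legal.reshape(-1, rows, cols)
    if flip_rows:
        Xp, Lp = Xp[:, :, ::-1, :], Lp[:, ::-1, :]
    if flip_cols:
        Xp, Lp = Xp[:, :, :, ::-1], Lp[:, :, ::-1]
    return (np.ascontiguousarray(Xp).reshape(-1, 2 * rows * cols),
            np.ascontiguousarray(Lp).reshape(-1, rows * cols))


def augment_symmetries(dataset: tuple) -> tuple:
    """Quadruple a (X, chosen, legal, move_number) dataset by board reflections."""
    X, chosen, legal, move_no = dataset
    Xs, cs, ls, ms = [], [], [], []
    for fr, fc in SYMMETRY_FLIPS:
        x2, l2 = flip_planes(X, legal, fr, fc)
        Xs.append(x2)
        ls.append(l2)
        cs.append(flip_squares(chosen, fr, fc))
        ms.append(move_no)
    return (np.concatenate(Xs), np.concatenate(cs), np.concatenate(ls),
            None if move_no is None else np.concatenate(ms))


def symmetrized_probs(net: "PolicyNetwork", X: np.ndarray,
                      legal: np.ndarray) -> np.ndarray:
    """Average the network policy over the symmetry orbit of each board."""
    out = np.zeros((len(X), net.config.n_output))
    for fr, fc in SYMMETRY_FLIPS:
        x2, l2 = flip_planes(X, legal, fr, fc)
        p = net.forward(x2, l2)
        back = flip_squares(np.arange(net.config.n_output), fr, fc)
        out[:, back] += p
    return out / len(SYMMETRY_FLIPS)


def nll_loss(policy: np.ndarray, chosen: int) -> float:
    """Negative log probability of the chosen square under a move policy."""
    if policy[chosen] == 0.0:
        raise ValueError("chosen square has zero probability (occupied?)")
    return float(-np.log(policy[chosen]))
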