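"""Inverse-binomial-sampling likelihood estimation and parameter fitting.

The planning agent is a simulator without a tractable likelihood, so the log
probability of an observed move is estimated by inverse binomial sampling
(IBS): simulate moves in the observed position until one matches the choice;
if the first match is the K-th draw, ``log p`` is estimated by
``-sum_{k=1}^{K-1} 1/k``, which is unbiased.  A positive lapse rate
guarantees every legal move has positive probability, so the sampling
terminates (expected K equals the number of supported moves on
self-generated data).

Fitting follows a multi-start protocol: each run minimizes the mean IBS
negative log-likelihood over a fresh subsample of training moves with a
bound-constrained derivative-free optimizer (Nelder-Mead); by default each
run holds its random stream fixed across evaluations (common random
numbers), making the noisy objective a deterministic function of the
parameters within a run.  Finalists are re-scored with a common seed and
more repetitions, and the best run wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from .board import MoveObservation
from .features import ExtensionFlags
from .agent import ModelParams, depth1_values, sample_move


@dataclass(frozen=True)
class IBSEstimate:
    """One IBS log-likelihood estimate: ``loglik = -H_{K-1}`` (harmonic sum)."""

    loglik: float
    draws: int
    truncated: bool = False


def _harmonic(n: int) -> float:
    if n <= 0:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def ibs_from_sampler(sampler: Callable, target, rng: np.random.Generator,
                     max_draws: int) -> IBSEstimate:
    """Generic IBS estimator for any stochastic sampler and observed outcome."""
    if max_draws < 1:
        raise ValueError("max_draws must be >= 1")
    for k in range(1, max_draws + 1):
        if sampler(rng) == target:
            return IBSEstimate(-_harmonic(k - 1), k)
    return IBSEstimate(-_harmonic(max_draws - 1), max_draws, truncated=True)


def default_max_draws(params: ModelParams) -> int:
    """Cap on IBS draws: ten times the expected worst case 36/lam."""
    return int(np.ceil(10 * 36 / params.lam))


def _ibs_depth1(trial: MoveObservation, params: ModelParams,
                rng: np.random.Generator, max_draws: int,
                batch: int = 64) -> IBSEstimate:
    """Vectorized IBS for depth-one agents (gamma=1, no dropout).

    A single expansion makes the sampled move the argmax of fixed
    deterministic child values plus iid Gaussian noise (or a uniform lapse),
    so whole batches of draws reduce to one matrix argmax — identical in
    distribution to repeated :func:`sample_move` calls, without the
    per-draw tree construction.
    """
    squares, vals = depth1_values(trial.board, trial.mover, params)
    target = int(np.nonzero(squares == trial.chosen)[0][0])
    n = squares.size
    k = 0
    while k < max_draws:
        m = min(batch, max_draws - k)
        picks = np.empty(m, dtype=np.int64)
        lapse = rng.random(m) < params.lam if params.lam > 0 else np.zeros(m, bool)
        ns = int((~lapse).sum())
        if ns:
            if params.sigma > 0:
                noisy = vals[None, :] + params.sigma * rng.standard_normal((ns, n))
                picks[~lapse] = noisy.argmax(axis=1)
            else:
                top = np.nonzero(vals == vals.max())[0]
                picks[~lapse] = rng.choice(top, size=ns)
        if lapse.any():
            picks[lapse] = rng.integers(n, size=int(lapse.sum()))
        hits = np.nonzero(picks == target)[0]
        if hits.size:
            return IBSEstimate(-_harmonic(k + int(hits[0])), k + int(hits[0]) + 1)
        k += m
    return IBSEstimate(-_harmonic(max_draws - 1), max_draws, truncated=True)


def ibs_loglik(trial: MoveObservation, params: ModelParams,
               rng: np.random.Generator,
               max_draws: Optional[int] = None) -> IBSEstimate:
    """IBS estimate of the log probability that the agent makes the observed move."""
    if params.lam <= 0:
        raise ValueError("lam must be > 0 for IBS to terminate")
    cap = max_draws if max_draws is not None else default_max_draws(params)
    if params.gamma == 1.0 and params.delta == 0.0:
        return _ibs_depth1(trial, params, rng, cap)
    return ibs_from_sampler(
        lambda r: sample_move(trial.board, trial.mover, params, r),
        trial.chosen, rng, cap)


def repeated_ibs(trials: Sequence[MoveObservation], params: ModelParams,
                 R: int = 100, rng: Optional[np.random.Generator] = None,
                 max_draws: Optional[int] = None) -> float:
    """Mean negative log-likelihood per move, averaging R IBS repetitions per trial."""
    if len(trials) == 0:
        raise ValueError("empty trial set")
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    total = 0.0
    for trial in trials:
        for _ in range(R):
            total -= ibs_loglik(trial, params, rng, max_draws).loglik
    return total / (len(trials) * R)


def subsampled_objective(trials: Sequence[MoveObservation], params: ModelParams,
                         n_sub: int, rng: Optional[np.random.Generator] = None,
                         max_draws: Optional[int] = None) -> float:
    """Single-repetition IBS NLL on a fresh uniform subsample of the training moves."""
    if n_sub > len(trials):
        raise ValueError("n_sub exceeds number of trials")
    rng = rng if rng is not None else np.random.default_rng()
    if n_sub == len(trials):
        subset = list(trials)
    else:
        idx = rng.choice(len(trials), size=n_sub, replace=False)
        subset = [trials[i] for i in idx]
    return repeated_ibs(subset, params, R=1, rng=rng, max_draws=max_draws)


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

DEFAULT_BOUNDS = {
    "w_conn2": (0.0, 10.0), "w_unconn2": (0.0, 10.0), "w_three": (0.0, 10.0),
    "w_four": (0.0, 10.0), "w_center": (0.0, 10.0),
    "c_opp": (0.0, 2.0), "theta": (0.0, 10.0), "gamma": (0.01, 0.99),
    "delta": (0.0, 0.9), "lam": (0.005, 0.5),
    "w_corner_0": (0.0, 10.0), "w_corner_1": (0.0, 10.0),
    "w_corner_2": (0.0, 10.0), "w_corner_3": (0.0, 10.0),
    "w_def": (0.0, 10.0), "w_phantom": (0.0, 10.0),
}

_BASE_FREE = ("w_conn2", "w_unconn2", "w_three", "w_four", "w_center",
              "c_opp", "theta", "gamma", "delta", "lam")


@dataclass
class PlanningFitResults:
    """Fit output: best parameters, objective, and the per-run table."""

    params: ModelParams
    objective: float
    run_index: int
    n_evaluations: int
    runs: pd.DataFrame
    free_names: tuple
    model: "PlanningModel" = field(repr=False, default=None)

    def summary(self) -> str:
        lines = ["Planning model fit (IBS negative log-likelihood, nats/move)",
                 "=" * 60,
                 f"variant:            {self.model.extensions if self.model else '?'}",
                 f"runs:               {len(self.runs)}"
                 f" ({int(self.runs['success'].sum())} succeeded)",
                 f"best run:           {self.run_index}",
                 f"objective (rescored): {self.objective:.4f}",
                 f"objective evaluations: {self.n_evaluations}",
                 "-" * 60]
        for name in self.free_names:
            lines.append(f"{name:>12s}: {self._value(name):8.4f}")
        return "\n".join(lines)

    def _value(self, name: str) -> float:
        if name.startswith("w_corner_"):
            return self.params.w_corner[int(name[-1])]
        return float(getattr(self.params, name))


class PlanningModel:
    """Planning-agent likelihood model over a set of move observations.

    Statsmodels-style: construct from data, call :meth:`fit` to obtain a
    :class:`PlanningFitResults`.  ``extensions`` selects the cumulative model
    family: ``baseline``, ``corner`` (opening bias), ``defensive`` (adds
    opponent-threat weighting) or ``phantom`` (adds phantom features).
    ``fixed`` pins named parameters to constants (removing them from the
    search); ``bounds`` overrides the default fitting box.
    """

    def __init__(self, trials: Sequence[MoveObservation],
                 extensions: str = "baseline",
                 base_params: Optional[ModelParams] = None,
                 bounds: Optional[dict] = None,
                 fixed: Optional[dict] = None):
        if len(trials) == 0:
            raise ValueError("no trials")
        self.trials = list(trials)
        self.extensions = extensions
        self.flags = ExtensionFlags.for_model(extensions)
        self.base_params = base_params or ModelParams(
            corner=self.flags.corner, threat=self.flags.threat,
            phantom=self.flags.phantom)
        self.fixed = dict(fixed or {})
        names = [n for n in _BASE_FREE if n not in self.fixed]
        if self.flags.corner:
            names += [f"w_corner_{j}" for j in range(4) if f"w_corner_{j}" not in self.fixed]
        if self.flags.threat and "w_def" not in self.fixed:
            names.append("w_def")
        if self.flags.phantom and "w_phantom" not in self.fixed:
            names.append("w_phantom")
        self.free_names = tuple(names)
        b = dict(DEFAULT_BOUNDS)
        b.update(bounds or {})
        self.bounds = [b[n] for n in self.free_names]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "PlanningModel":
        """Build from a move-table DataFrame (columns as in the CSV interface)."""
        from .board import Board
        trials = [
            MoveObservation(
                board=Board.from_strings(r.board_p1, r.board_p2),
                mover=int(r.player), chosen=int(r.square),
                move_number=int(r.move_index), player_id=str(r.game_id))
            for r in df.itertuples()
        ]
        return cls(trials, **kw)

    def params_from_vector(self, x: Sequence[float]) -> ModelParams:
        kw = {}
        corner = list(self.base_params.w_corner)
        for name, v in list(self.fixed.items()) + list(zip(self.free_names, x)):
            if name.startswith("w_corner_"):
                corner[int(name[-1])] = float(v)
            else:
                kw[name] = float(v)
        kw["w_corner"] = tuple(corner)
        return self.base_params.evolve(**kw)

    def vector_from_params(self, params: ModelParams) -> np.ndarray:
        out = []
        for name in self.free_names:
            if name.startswith("w_corner_"):
                out.append(params.w_corner[int(name[-1])])
            else:
                out.append(getattr(params, name))
        return np.array(out, dtype=float)

    def objective(self, x: Sequence[float], n_sub: int,
                  rng: np.random.Generator, max_draws: Optional[int] = None) -> float:
        params = self.params_from_vector(np.asarray(x, dtype=float))
        return subsampled_objective(self.trials, params, n_sub, rng, max_draws)

    def fit(self, n_runs: int = 20, n_sub: Optional[int] = None,
            method: str = "de", maxfev: int = 200, seed=None, crn: bool = True,
            max_draws: Optional[int] = None, n_screen: int = 30,
            de_popsize: int = 8, de_maxiter: int = 20, polish_maxfev: int = 80,
            rescore_R: int = 10, rescore_n: Optional[int] = None,
            x0: Optional[Sequence[float]] = None) -> PlanningFitResults:
        """Multi-start derivative-free fit of the IBS objective.

        ``n_sub`` moves are re-subsampled per objective evaluation (default:
        all trials up to 100,000).  With ``crn`` each run re-seeds its
        objective stream identically on every evaluation, so the optimizer
        sees a deterministic surface.  ``method`` is ``"de"`` (differential
        evolution followed by a Nelder-Mead polish at double the subsample;
        the planning objective is multimodal enough that purely local
        restarts stall) or ``"neldermead"`` (screened multi-start local
        search; each run first evaluates ``n_screen`` uniform points and
        starts from the best).  ``x0`` pins the first run's start.
        """
        if n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        n_sub = n_sub if n_sub is not None else min(100_000, len(self.trials))
        rescore_n = rescore_n if rescore_n is not None else min(2000, len(self.trials))
        ss = np.random.SeedSequence(seed)
        run_seeds = ss.spawn(n_runs + 1)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])

        rows, candidates = [], []
        total_evals = 0
        for r in range(n_runs):
            init_rng = np.random.default_rng(run_seeds[r])
            crn_seed = run_seeds[r].spawn(1)[0]
            evals = [0]

            def make_obj(size):
                def obj(x):
                    evals[0] += 1
                    rng = (np.random.default_rng(crn_seed) if crn
                           else np.random.default_rng(run_seeds[r].spawn(1)[0]))
                    try:
                        return self.objective(np.clip(x, lo, hi), size, rng, max_draws)
                    except (ValueError, FloatingPointError):
                        return np.inf
                return obj

            obj = make_obj(n_sub)
            if method == "de":
                de = differential_evolution(
                    obj, self.bounds, seed=int(init_rng.integers(2**31)),
                    maxiter=de_maxiter, popsize=de_popsize, tol=1e-3,
                    polish=False, init="sobol")
                start, fun = de.x, de.fun
                if polish_maxfev > 0:
                    obj2 = make_obj(min(2 * n_sub, len(self.trials)))
                    res = minimize(obj2, start, method="Nelder-Mead",
                                   bounds=self.bounds,
                                   options={"maxfev": polish_maxfev,
                                            "xatol": 1e-3, "fatol": 1e-3,
                                            "adaptive": True})
                    best_x, fun = res.x, float(res.fun)
                else:
                    best_x = start
            elif method == "neldermead":
                if x0 is not None and r == 0:
                    start = np.asarray(x0, dtype=float)
                else:
                    start = init_rng.uniform(lo, hi)
                    if n_screen > 0:
                        draws = init_rng.uniform(lo, hi, size=(n_screen, len(lo)))
                        draws[0] = start
                        scores = [obj(x) for x in draws]
                        start = draws[int(np.argmin(scores))]
                res = minimize(obj, start, method="Nelder-Mead", bounds=self.bounds,
                               options={"maxfev": maxfev, "xatol": 1e-3,
                                        "fatol": 1e-3, "adaptive": True})
                best_x, fun = res.x, float(res.fun)
            else:
                raise ValueError(f"unknown method {method!r}")
            total_evals += evals[0]
            ok = np.isfinite(fun)
            rows.append({"run": r, "objective_train": fun,
                         "n_evaluations": evals[0], "success": ok})
            if ok:
                candidates.append((r, np.clip(best_x, lo, hi)))
        if not candidates:
            raise RuntimeError("all optimizer runs failed")

        # rescore finalists with a common seed and more repetitions
        score_seed = run_seeds[-1]
        best = None
        for r, x in candidates:
            params = self.params_from_vector(x)
            rng = np.random.default_rng(score_seed)
            if rescore_n == len(self.trials):
                sub = self.trials
            else:
                idx = rng.choice(len(self.trials), size=rescore_n, replace=False)
                sub = [self.trials[i] for i in idx]
            score = repeated_ibs(sub, params, R=rescore_R,
                                 rng=np.random.default_rng(score_seed), max_draws=max_draws)
            rows[r]["objective_rescored"] = score
            if best is None or score < best[0]:
                best = (score, r, params)
        runs = pd.DataFrame(rows)
        return PlanningFitResults(
            params=best[2], objective=float(best[0]), run_index=int(best[1]),
            n_evaluations=total_evals, runs=runs, free_names=self.free_names,
            model=self)


def fit(training_trials: Sequence[MoveObservation], n_runs: int = 20,
        optimizer_config: Optional[dict] = None,
        rng=None, extensions: str = "baseline", **model_kw) -> PlanningFitResults:
    """Functional wrapper over :class:`PlanningModel` + :meth:`fit`."""
    cfg = dict(optimizer_config or {})
    for key in ("bounds", "fixed", "base_params"):
        if key in cfg:
            model_kw[key] = cfg.pop(key)
    seed = cfg.pop("seed", None)
    if seed is None and rng is not None:
        seed = int(np.random.default_rng(rng).integers(2**31)) if not isinstance(rng, int) else rng
    model = PlanningModel(training_trials, extensions=extensions, **model_kw)
    return model.fit(n_runs=n_runs, seed=seed, **cfg)
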