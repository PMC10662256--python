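# Methods

## The game and its state space

4-in-a-row is played on a 4x9 grid. Two players alternate placing pieces on
any empty square; the first to occupy four collinear adjacent squares
(horizontally, vertically or diagonally) wins, and a full board with no four
is a draw. Squares are indexed row-major (`index = 9*row + col`). There are
45 four-square windows (24 horizontal, 9 vertical, 6 + 6 diagonal).

A *non-terminal state* is defined here as a board assignment with no four
for either player, at least one empty square, and piece counts consistent
with alternating first-player-start play (`n1 - n2` in {0, 1}; the player to
move follows from parity). `census.count_nonterminal` counts these exactly
with a column-sweep transfer-matrix dynamic program whose state is the
ternary content of the three most recent columns plus the running
piece-count difference; horizontal and diagonal windows close over four
consecutive columns, vertical windows inside the newest column. The
"at least one empty" condition is imposed by subtracting a full-board-only
count computed from the same recursion restricted to columns without
empties. All counts are integers throughout: totals fit in int64 (at most
3^36), and the batched per-column matrix product is evaluated exactly on a
31-bit high/low split in float64 (each half stays below 2^53) before integer
recombination. The 4x9 census is 11,845,419,993,497,427 ≈ 1.2e16 and runs in
about 20 s on one CPU; the DP is validated cell-for-cell against a
brute-force enumerator on every board shape up to 16 cells.

Whether drawn full boards or turn-marked states should additionally be
counted is a convention choice; with the definition above the count agrees
with the published order of magnitude at two significant figures, so the
convention is retained.

## The planning model

A position is valued by a weighted linear heuristic over realized feature
counts, from the perspective of the player at the root of the search:

    V(s) = sum_k  w_k * (N_k(self) - C * N_k(opponent)) + extensions + noise

Baseline feature kinds, counted per window (a pattern lying in two windows
counts twice; windows containing any opponent piece contribute nothing):

| kind     | realized when (within one window)                     |
|----------|-------------------------------------------------------|
| conn2    | exactly 2 own pieces, adjacent, 2 empties              |
| unconn2  | exactly 2 own pieces, non-adjacent, 2 empties          |
| three    | exactly 3 own pieces, 1 empty                          |
| four     | 4 own pieces                                           |
| center   | per occupied square: `1/(1 + distance to (1.5, 4.0))`  |

The center gradation is a bounded, parameter-free decreasing function of the
Euclidean distance to the board center; any strictly decreasing function
would serve.

Three extensions can be enabled, cumulatively in the fitted model family
(`baseline` → `corner` → `defensive` → `phantom`):

* **corner** — four separately weighted bonus instances on the corner
  squares, own pieces only, mirroring the center feature (players favor
  corner openings, especially the upper left).
* **defensive (threat) weighting** — a weight `w_def` that enters the value
  asymmetrically as `-w_def * N_threat(opponent)`, where a threat is a
  window holding exactly three opponent pieces and one empty. This
  explicitly values parrying immediate losses, which the baseline can prune
  away (below).
* **phantom three-in-a-rows** — contiguous own triples that can no longer be
  completed to four: every containing window's fourth square is occupied, or
  the extensions fall off the board (the corner-diagonal case). Both
  readings of "no empty completion square" are implemented as their union;
  instances are enumerated for all contiguous collinear triples and realize
  only when blocked or edge-bound.

Stochasticity enters in four places, mirroring human variability:
Gaussian noise (SD `sigma`, default fixed at 1 — the weights absorb the
value scale) added once per evaluated node and cached; feature dropout
(each instance independently omitted with probability `delta`, drawn once
per move before search — attentional lapses); a stochastic stopping rule;
and a lapse rate `lam` of uniformly random legal moves. `lam > 0` also
guarantees full support, which the fitting protocol requires.

Search is best-first: repeatedly follow the principal variation (argmax of
child values at own nodes, argmin at opponent nodes, values always from the
root player's perspective) to an unexpanded leaf; expand it with one child
per legal move, each evaluated by the noisy heuristic; prune children whose
value is worse than the best sibling's by more than `theta` (pruning is
applied once, at expansion, and is irreversible); back values up the path.
After every expansion the search stops with probability `gamma`; it also
stops when the principal variation reaches a terminal node (wins dominate
the root) or at a hard cap of `max_iterations` expansions (default 100, a
runtime bound). Terminal nodes are never expanded; reaching one counts as an
iteration. The sampled move is the best unpruned root child, ties uniform.

The irreversible pruning produces the model's characteristic defensive
failure: when offensive moves score more than `theta` above a blocking move
at the root, the block is pruned immediately; later expansions reveal that
the offensive lines lose, but the block can never be reconsidered, so the
model loses to an unanswered threat. The defensive weighting lifts blocking
moves above the pruning cut and repairs exactly this class of errors. The
test suite contains a constructed "pruning trap" position where the
noiseless baseline provably fails and the defensive model provably blocks.

Search child evaluation is vectorized (one batch of table lookups per
expansion over all legal moves); the vectorized evaluator is tested for
exact numerical agreement with the plain `count_features`-based reference
implementation.

## Policies and exact depth-one distributions

`estimate_policy` estimates the move distribution of a parameterization by
simulation (default 200 simulations per position, optional pseudocount
`alpha`), returning a vector that is exactly zero on occupied squares. For
depth-one agents (`gamma = 1`, `delta = 0`) the policy is also available in
closed form: the move is the argmax of fixed child values plus iid Gaussian
noise, so each move probability is a one-dimensional Gaussian orthant
integral, evaluated by Gauss-Hermite quadrature. The exact policy serves as
an oracle for the simulator and as the cross-entropy floor of depth-one
generators.

## Likelihood estimation and fitting

The agent is a simulator without a tractable likelihood. The log probability
of an observed move is estimated by inverse binomial sampling: simulate
moves in the observed position until one matches; if the first match is the
K-th draw, `log p` is estimated as `-sum_{k=1..K-1} 1/k`, which is unbiased.
Expected cost is `1/p` draws, i.e. roughly the number of supported moves on
self-generated data. A draw cap (default `10 * 36 / lam`) bounds the worst
case; capped estimates are flagged as truncated. For depth-one agents the
draw loop is vectorized into batched noisy argmaxes — identical in
distribution, roughly two orders of magnitude faster.

Fitting is statsmodels-shaped: `PlanningModel(trials, extensions=...)`
holds the data and the free-parameter box (weights in [0, 10], C in [0, 2],
theta in [0, 10], gamma in [0.01, 0.99], delta in [0, 0.9], lam in
[0.005, 0.5]; any parameter can be pinned with `fixed`), and `.fit()`
returns a `PlanningFitResults` with the best parameters, the re-scored
objective and a per-run table. The objective for each evaluation is the
mean single-repetition IBS negative log-likelihood on a fresh uniform
subsample of `n_sub` training moves. Within a run the random stream is
re-seeded identically on every evaluation (common random numbers), so the
optimizer sees a deterministic surface. The default optimizer is
differential evolution (bound-constrained, derivative-free, tolerant of the
residual objective noise) followed by a Nelder-Mead polish at double the
subsample; a screened multi-start Nelder-Mead is available as an
alternative. Finalists from all runs are re-scored with a common seed and
more repetitions per trial, and the best run is returned. Natural
logarithms are used throughout (a uniform policy over 36 squares scores
ln 36 ≈ 3.58 nats per move).

## Policy network

The move-prediction network flattens the 2x4x9 mover/opponent occupancy
planes to 72 inputs, projects to `n_units`, applies `n_layers` residual
blocks (affine → ReLU → affine, plus the block input), and maps to 36
logits. A large constant (1e9) is subtracted from logits at occupied squares
before the softmax; those probabilities are then set to exactly zero and the
legal entries renormalized, which also makes the gradients at occupied
squares exactly zero. The output head is zero-initialized so the initial
policy is exactly uniform over legal squares. Training is behavioral
cloning: mean NLL minimized with Adam (batch 256, learning rate 1e-3,
early stopping on validation NLL; all configurable). The desk-scale grid is
2-10 layers by 32-128 units rather than a production-scale sweep.

The game and the baseline model family are exactly invariant under row and
column reflection, so two symmetry utilities are provided: dataset
augmentation (each move appears in all four reflections — a bias-free 4x
sample multiplier that matters at desk-scale sample sizes) and symmetrized
evaluation (averaging the network's policy over the reflection orbit, which
can only reduce expected KL to an equivariant target by convexity). The raw
`forward` pass is untouched by either.

## Comparison pipeline

`kl_divergence(p, q)` is computed over legal squares with an epsilon mass
floor (default 1e-4 per legal square) added to `q` and renormalized, since
the simulated model policy can contain structural zeros. The residual
ranking uses KL(reference ‖ model): the reference (a trained network, or a
generator standing in for it) is the better-calibrated side. Each position's
simulation stream is seeded by the position's content, so the ranking is
invariant to input order. Summary statistics per move: distance from the
chosen square to the board center; minimum distance to own and to opponent
pieces ("distance to pieces" is read as the minimum — the standard proximity
statistic; undefined values are omitted from bin averages); distance to both
centers of mass; own/opponent counts among the 8 neighbors; whether the move
creates an own threat; whether it parries an opponent threat — averaged
within move-number bins. Elo ratings use standard sequential updates
(K = 32, initial 1500, draws 0.5, updates in game order) with a
quantile-binning helper. Paired scorer comparisons report the per-move
log-likelihood difference with its SEM and paired t statistic.

## Synthetic data

Self-play logs stand in for behavioral data: player 1 ("user") always moves
first against an AI opponent running the same model family. Default user
parameters — w_conn2 0.9, w_unconn2 0.45, w_three 3.5, w_four 8, w_center
0.6, C 0.9, theta 2, gamma 0.25, delta 0.15, lam 0.1, sigma 1 — are
plausible mid-skill settings chosen once: the feature-weight ordering puts
immediate wins far above threes above twos, the pruning threshold and
stopping rate give shallow-but-nontrivial trees (about four expansions per
move on average), and the dropout and lapse rates produce visible but not
dominant errors. The AI opponent is slightly stronger (lam 0.05,
gamma 0.15, delta 0.1). A population simulator draws per-player lapse rates
(log-uniform on [0.02, 0.4]) and a common log-uniform weight scale
([0.5, 2]) to create skill heterogeneity for Elo analyses, recording
ground-truth parameters per player. Splits follow the 90/5/5 rule with both
held-out partitions floored and training taking the remainder, which
reproduces published partition sizes exactly from the printed total.

What the generator does not emulate: learning within players over time,
individually different feature sets, the mobile platform's adaptive
matchmaking, and any real-data idiosyncrasies. Passing tests therefore
demonstrate that the algorithms and the closed fitting loop are correct at
desk scale, not that the model fits human data.

## Desk-scale study conditions

The published protocol (10.9M games, 100,000-trial objective evaluations, 20
optimizer runs, 25 networks up to 80x4000) is scaled to a single CPU. The
choices, made once:

* **Parameter recovery**: 20,000 moves from a depth-one generator
  (gamma = 1, delta = 0, lam = 0.1, sigma = 1, weights 1.8 / 0.3 / 4.0 /
  9.0 / 0.9 — adjacent weight ranks separated by at least 2x so rank
  recovery is meaningful). The five weights and the lapse rate are free;
  C, theta, gamma, delta are fixed at their true values. One differential-
  evolution run per replicate (population 36, 14 generations, 400-move
  subsamples, draw cap 300) plus a Nelder-Mead polish; three replicate
  seeds, aggregated by the median (the per-replicate metrics are
  stochastic).
* **Network demonstration**: a 5-layer, 64-unit network trained on 50,000
  moves from a depth-one generator (lam = 0.15), with symmetry-augmented
  training and symmetrized scoring. The comparison floor is *empirical*:
  the generator scoring its own held-out moves through the same
  200-simulation, pseudocount-0.5 policy estimator used everywhere else in
  the pipeline (the analytic floor is lower; finite simulation and
  smoothing inflate any scorer evaluated this way, network and generator
  alike).
* **Residual ranking**: 200 mid-game positions from defensive-generator
  self-play, 200 simulations per position, top 50 inspected.

## Numerical and degenerate-input choices

* Ties in move selection are broken uniformly at random; inside the search
  descent the first-best child is taken (evaluation noise makes exact ties
  measure-zero for sigma > 0).
* `sigma = 0` is allowed in the evaluator (useful for oracles); the exact
  depth-one policy then distributes mass uniformly over argmax ties.
* Terminal boards are rejected by search, sampling and policy estimation.
* `delta = 1` empties the active set; the heuristic is then pure noise.
* The IBS cap returns the capped estimate with a truncation flag rather
  than failing; `lam = 0` is rejected at fitting time.
* Boards are validated on construction (disjoint occupancy, alternation).

## Known limitations

* The full fitted protocol (all ten baseline parameters free on search-based
  generators) is substantially harder than the desk-scale recovery study;
  deep-search generators make IBS draws ~50x more expensive and the
  recovery experiment here deliberately conditions on the depth-one family.
* The pruning mechanics beyond the published description (noise re-sampling
  per node vs per iteration, candidate-move restriction before pruning) are
  underdetermined; the choices here (noise cached per node, no candidate
  restriction) are documented in the agent module.
* Elo constants and the ndjson/CSV log formats are package conventions, not
  reproductions of any published scheme.
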