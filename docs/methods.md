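# Methods

## The rating model

A competition network represents competitors as nodes and contests as
directed, asymmetrically weighted edges: `W[i, j]` is the total number of
points `i` scored against `j`, with repeated fixtures summed and the number
of meetings tracked separately (`games_played`). The contact graph is the
undirected graph of pairs that have met; its simple-graph degree `k_i`
counts *distinct* opponents, not meetings — repeated fixtures are already
merged into the cumulative weights, so multiplicity would double-count
information the weights carry.

The rating is the stationary occupancy of a random walk biased by score
gradients. On the edge `{i, j}` the walker at `j` moves toward `i` with
un-normalized weight

    g(j→i) = (w_ji + ε) / (w_ij + w_ji + 2ε),

the fraction of the pairing's points (regularized by ε on each side) that
were scored *against* `i`. The two directions of an edge sum to one, both
are strictly positive, and a tie gives ½/½. The regularizer serves two
purposes: a scoreless tie must not produce an undefined 0/0 edge, and a
competitor that lost every contest must not become an absorbing state —
real outcomes are stochastic, so "uphill" moves (upsets) keep positive
probability.

Degree neutralization: entry into node `i` is discounted by `k_i`, and the
resulting column is re-normalized,

    T[i, j] = ( g(j→i) / k_i ) / Z_j ,   Z_j = Σ_{i ~ j} g(j→i) / k_i ,

so that facing many distinct opponents is not by itself rewarded or
penalized, unlike in PageRank where in-degree drives centrality. `Z_j` is
read as a per-column normalizer (subscripted by the source node); an
alternative "lazy-walk" reading — one global normalizer with the deficit
placed on self-loops — is available behind `RankingConfig(lazy=True)`
because the two readings differ on degenerate 2-node networks, but the
per-column form is the default and the documented behaviour everywhere.

The stationary vector of the loser-seeking walk is the **weakness** `w`;
swapping the gradient orientation (`direction="toward_stronger"`) gives the
**strength** `s`. Neither picture is privileged a priori, so the final
rating is the symmetric difference `π = s − w`. This combination makes two
structural facts exact: on an all-tied network both walks coincide and every
π is zero (equal ranks), and transposing every pairing's scores swaps `s`
and `w`, negating π and exactly reversing the ranking. Any symmetric
monotone combination would share these properties; the difference is the
simplest and keeps π on an interpretable occupancy scale.

### Numerical choices

- **Stationary solve.** For up to 2000 nodes the balance equations
  `(I − T)π = 0, Σπ = 1` are solved directly as a dense linear system (one
  redundant balance row replaced by the normalization row) — deterministic,
  no iteration, residual at machine precision. Beyond that, a lazy-walk
  power iteration `v ← (Tv + v)/2` is used: it has the same fixed point,
  converges geometrically, and is aperiodic by construction, which matters
  because a two-team network is a deterministic 2-cycle on which a plain
  power step oscillates forever. Residual tolerance `eig_tol = 1e−12`
  (max-norm of `Tv − v`), iteration cap 10⁶.
- **Disconnected networks** (routine in early season weeks): each connected
  component of the contact graph is an irreducible chain, so the stationary
  vector is computed per component and scaled by the component's share of
  nodes; an isolated competitor receives exactly `1/N`. This avoids
  PageRank-style teleportation, which flattens genuine differences by
  linking everything to everything. A `teleport` probability is available
  as an explicit alternative but defaults to 0.
- **ε default 1.** Any positive value is admissible; on networks with no
  ties and no shutouts the ranking is insensitive to ε across {0.5, 1, 2}
  (asserted in the tests on a transitive triangle) — it is a regularizer,
  not a driver.
- **Ties in ranks.** Correlation statistics use average ranks (via
  `scipy.stats.rankdata`); displayed orderings break exact rating ties
  deterministically by net points, then lexicographic ID.
- **Jackknife.** Delete-one-*game* resampling over the n games:
  `err_i = sqrt((n−1)/n · Σ_g (π_i^(g) − π̄_i)²)`, with the node set held
  fixed across resamples so a competitor's only game being deleted leaves
  it isolated rather than absent. n = 1 gives zeros by the (n−1)/n factor.

## Baselines

- **Win–loss margin** (wins − losses, draws neutral) with a net-points
  tiebreak, encoded as the scalar `margin + net_points·1e−6` so the
  lexicographic order survives in a single column (season net-point totals
  are orders of magnitude below 10⁶).
- **Colley**: `C r = b` with `C_ii = 2 + t_i`, `C_ij = −n_ij`,
  `b_i = 1 + (wins − losses)/2`; strictly diagonally dominant, so uniquely
  solvable; mean rating is exactly ½ on any fixture.
- **Park–Newman**: generalized wins/losses from the attenuated path series
  on the win matrix `A`, `S = A(I − αA)^{-1}`; rating = row sums − column
  sums. α must stay below `1/λ_max(A)`; the default α = 0.9/λ_max is this
  package's choice (configurable, logged), as is PageRank's α = 0.85 and
  its use of point-weighted winner→loser edges (`pr_weighted=False` gives
  binary win edges). Wins and losses are always recovered from the
  individual game records, never from the cumulative weights, which lose
  per-game outcomes.
- **PageRank-as-weakness** delegates to `networkx.pagerank` on the
  points-weighted graph; low occupancy = strong.

## Evaluation protocol

Predictions are strictly out-of-sample in time: the rating entering round
`t` is fitted on rounds `1..t−1`, and each round-`t` game is predicted by
the higher rating. Credit: correct call 1, wrong 0, actually drawn game ½;
a game involving a yet-unrated competitor, or two exactly tied ratings,
also scores ½ (no informative call is possible — mirroring the drawn-game
rule). Round 1 has no prior data and is excluded from the aggregate;
aggregate accuracy is Σ credits / Σ games over rounds ≥ 2.

Convergence is tracked two ways: the Spearman correlation of each round's
cumulative ranking with the final one (average ranks; restricted to the
competitors already rated that round; by construction 1.0 at the final
round), reporting the first round at or above a threshold (default 0.9);
and the count of line crossings between consecutive weekly rankings —
discordant pairs, with pairs tied in either week not counted. Crossing
counts are fitted by `a·exp(−b·t)` via nonlinear least squares on the raw
counts (log-linear fitting would choke on the zero-crossing weeks that
normal late seasons produce); an all-zero series is reported as degenerate
with `a = 0`.

## Synthetic seasons

The generator emulates the two real-league topologies of interest:

- **round_robin × r** (circle-method matchings; every pair meets exactly
  `r` times, connectance = r; odd team counts get byes);
- **conference** (equal divisions; full intra-division round-robin, then
  cross-division bipartite matchings between circle-paired divisions until
  each team has exactly `games_per_team` games). 32 teams in 8 divisions at
  16 games each reproduce the sparse-league connectance 256/496 ≈ 0.52.

Scores are independent Poisson draws: team `i` facing `j` scores with mean
`μ·exp(β(θ_i − θ_j)/2)` and `j` the mirrored mean. Defaults, chosen once as
the study conditions: strengths θ evenly spaced on [0, 1]; `μ = 1.35`
(a typical association-football goals-per-team-game rate, giving realistic
tie frequencies); `β = 4`, the well-separated regime in which a full dense
season should essentially identify the true order. Each game draws from
`SeedSequence([seed, game_index])`, so a partial season is bit-identical to
the prefix of the full one.

What the generator deliberately omits: home advantage, within-season
strength drift, schedule imbalances beyond the division structure, and any
correlation between the two sides' scores in a game (real football scores
are mildly negatively correlated). Tests passing on these seasons therefore
demonstrate correctness of the machinery and qualitative behaviour
(recovery improving with connectance, crossings decaying, middle-tier churn)
— not calibrated accuracy percentages for any real league. Reproducing
published real-league values additionally requires the original season
result files, which are not redistributed here (see README).

## Problem sizes

The test suite and the acceptance script run seasons of 6–32 teams
(56–380 games), 50 seeds per stochastic summary, with one 2050-node random
network exercising the iterative stationary branch; the whole suite
completes in a few seconds on one core.

## Known limitations

- The walk requires each rated component to have at least one game; a
  competitor known to exist but never playing is rated exactly `1/N` by the
  node-share rule, carrying no information.
- The occupancy scale of π depends on N; compare ratings within one
  network, not across networks of different size.
- `winloss`'s scalar encoding assumes |net points| < 10⁶ per season.
- The jackknife treats games as the exchangeable unit; deleting whole weeks
  would give larger errors on schedules with strong weekly structure.
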