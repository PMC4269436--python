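"""Comparison rating methods: win-loss differential, Colley, Park-Newman,
and PageRank-as-weakness.

These are the standard paired-comparison baselines the degree-neutralized
walk is evaluated against. Wins and losses are derived from the individual
game records (cumulative point totals lose the per-game outcomes)."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .dnrw import ConfigurationError
from .network import CompetitionNetwork


@dataclass(frozen=True)
class BaselineConfig:
    """Parameters of the baseline rankers.

    pn_alpha
        Park-Newman path attenuation; must stay below 1/lambda_max of the
        win matrix for the path series to converge. ``None`` (default)
        resolves to 0.9 / lambda_max at fit time.
    pr_alpha
        PageRank damping ("the Google alpha"), in (0, 1).
    pr_weighted
        Weight the winner-to-loser edges by points scored (True) or use
        binary win edges (False).
    """

    pn_alpha: float | None = None
    pr_alpha: float = 0.85
    pr_weighted: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.pr_alpha < 1:
            raise ConfigurationError(f"pr_alpha must be in (0,1), got {self.pr_alpha}")
        if self.pn_alpha is not None and self.pn_alpha <= 0:
            raise ConfigurationError("pn_alpha must be positive")


def _win_loss_counts(net: CompetitionNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(wins, losses, wins_matrix) from the per-game records of the network."""
    n = net.n_teams
    wins = np.zeros(n)
    losses = np.zeros(n)
    A = np.zeros((n, n))  # A[i, j] = number of times i beat j
    for g in net.games:
        a, b = net.index[g.team_a], net.index[g.team_b]
        if g.score_a > g.score_b:
            wins[a] += 1
            losses[b] += 1
            A[a, b] += 1
        elif g.score_b > g.score_a:
            wins[b] += 1
            losses[a] += 1
            A[b, a] += 1
    return wins, losses, A


def winloss_rating(net: CompetitionNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Win-loss margin with a net-points tiebreak.

    Returns ``(margin, net_points)`` per competitor; ordering is
    lexicographic on the pair (higher margin first, then more net points).
    Draws contribute nothing to the margin.
    """
    wins, losses, _ = _win_loss_counts(net)
    return wins - losses, net.net_points()


def colley_rating(net: CompetitionNetwork) -> np.ndarray:
    """Colley's matrix ratings in (0, 1).

    Solves ``C r = b`` with ``C_ii = 2 + t_i`` (total games played),
    ``C_ij = -(head-to-head count)``, ``b_i = 1 + (wins_i - losses_i)/2``.
    The system is strictly diagonally dominant, hence uniquely solvable;
    with no games every rating is 1/2 and on any fixture the mean rating
    is 1/2.
    """
    wins, losses, _ = _win_loss_counts(net)
    t = net.games_played.sum(axis=1)
    C = np.diag(2.0 + t) - net.games_played
    b = 1.0 + (wins - losses) / 2.0
    return np.linalg.solve(C, b)


def park_newman_rating(
    net: CompetitionNetwork, cfg: BaselineConfig | None = None
) -> np.ndarray:
    """Park-Newman generalized wins minus losses.

    A directional Katz-type score on the win network ``A`` (``A[i, j]`` =
    wins of i over j): total wins count direct wins plus alpha-attenuated
    indirect wins along paths (beating someone who beat someone, ...), and
    symmetrically for losses on the transpose; the rating is their
    difference. As alpha -> 0 the ordering reduces to plain wins - losses.
    """
    cfg = cfg or BaselineConfig()
    _, _, A = _win_loss_counts(net)
    lam = np.max(np.abs(np.linalg.eigvals(A))) if A.any() else 0.0
    alpha = cfg.pn_alpha
    if alpha is None:
        alpha = 0.9 / lam if lam > 0 else 0.5
    elif lam > 0 and alpha >= 1.0 / lam:
        raise ConfigurationError(
            f"pn_alpha {alpha} >= 1/lambda_max = {1.0 / lam:.4g}; series diverges"
        )
    S = A @ np.linalg.inv(np.eye(net.n_teams) - alpha * A)
    ones = np.ones(net.n_teams)
    total_wins = S @ ones
    total_losses = S.T @ ones
    return total_wins - total_losses


def pagerank_weakness(
    net: CompetitionNetwork, cfg: BaselineConfig | None = None
) -> np.ndarray:
    """Damped random-walk occupancy on winner-to-loser edges.

    The walker follows edges pointing at the conceding side, so a high
    stationary occupancy marks a *weak* competitor: the ranking ascends in
    occupancy (lowest occupancy = strongest). Edges are weighted by points
    scored when ``pr_weighted``, else binary win edges.
    """
    cfg = cfg or BaselineConfig()
    G = nx.DiGraph()
    G.add_nodes_from(net.teams)
    if cfg.pr_weighted:
        M = net.W
    else:
        _, _, M = _win_loss_counts(net)
    for i, ti in enumerate(net.teams):
        for j, tj in enumerate(net.teams):
            if i != j and M[i, j] > 0:
                G.add_edge(ti, tj, weight=float(M[i, j]))
    pr = nx.pagerank(G, alpha=cfg.pr_alpha, weight="weight", tol=1e-12, max_iter=500)
    return np.array([pr[t] for t in net.teams])
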