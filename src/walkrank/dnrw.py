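"""Degree-neutralized random-walk rating.

The rating pictures a random walker travelling on the competition network
along gradients defined by the scores.  On the edge between ``i`` and ``j``
with cumulative points ``w_ij`` (scored by ``i`` against ``j``) and ``w_ji``,
the walker at ``j`` steps toward ``i`` with un-normalized weight

    g(j -> i) = (w_ji + eps) / (w_ij + w_ji + 2 eps),

i.e. it prefers to roll *downhill* toward the bigger loser of the pairing;
``eps > 0`` keeps both directions possible (upsets happen, and a scoreless
tie must not create an absorbing edge).  The two weights on an edge sum to 1.

A high contact-graph degree would by itself inflate a node's occupancy (more
ways in), so the probability of *entering* node ``i`` is discounted by its
degree ``k_i`` before the column is re-normalized:

    T[i, j] = g(j -> i) / k_i / Z_j,      Z_j = sum_i g(j -> i) / k_i.

The stationary occupancy of this column-stochastic chain measures *weakness*;
reversing the gradient orientation yields a *strength* occupancy ``s``, and
the final rating combines the two symmetric pictures as ``pi = s - w``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .network import (
    CompetitionNetwork,
    GameRecord,
    ValidationError,
    accumulate_network,
    opponent_degrees,
)


class ConfigurationError(ValueError):
    """An algorithm parameter is outside its valid range."""


class ConvergenceError(RuntimeError):
    """The stationary solve did not reach the requested residual."""


Direction = Literal["toward_loser", "toward_stronger"]


@dataclass(frozen=True)
class RankingConfig:
    """Parameters of the degree-neutralized walk.

    epsilon
        Gradient regularizer; must be positive so every edge stays
        two-way traversable even after a scoreless tie. Default 1.
    direction
        ``toward_loser`` (weakness walk) or ``toward_stronger`` (strength
        walk, the gradient orientation swapped).
    eig_tol
        Max-norm residual required of the stationary vector.
    max_iter
        Iteration cap for the (large-N) power-iteration path.
    teleport
        Optional uniform-jump probability, off by default: the walk is
        already ergodic on each connected component because every edge is
        bidirectional, and uniform jumps act as an indiscriminate equalizer
        of nodes.
    lazy
        Alternative reading of the normalizer: one global constant plus
        self-loops instead of per-column normalization. Default False
        (per-column), which is the documented behaviour everywhere.
    """

    epsilon: float = 1.0
    direction: Direction = "toward_loser"
    eig_tol: float = 1e-12
    max_iter: int = 1_000_000
    teleport: float = 0.0
    lazy: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ConfigurationError(f"epsilon must be > 0, got {self.epsilon}")
        if self.eig_tol <= 0:
            raise ConfigurationError("eig_tol must be > 0")
        if not 0 <= self.teleport < 1:
            raise ConfigurationError("teleport must lie in [0, 1)")
        if self.direction not in ("toward_loser", "toward_stronger"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic transition matrix of the degree-neutralized walk."""

    T: np.ndarray
    Z: np.ndarray
    direction: Direction
    teams: tuple[str, ...] = ()


@dataclass
class RatingResult:
    """Per-competitor weakness, strength, combined rating and ranks."""

    teams: list[str]
    weakness: np.ndarray
    strength: np.ndarray
    combined: np.ndarray
    errors: np.ndarray | None = None
    rank: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rank is None:
            self.rank = average_ranks(self.combined)


def average_ranks(scores: np.ndarray) -> np.ndarray:
    """Descending ranks (1 = best) with ties averaged."""
    return rankdata(-np.asarray(scores, dtype=float), method="average")


# ----------------------------------------------------------------------
# Eq.-level building blocks
# ----------------------------------------------------------------------

def gradient_pair(
    w_ij: float, w_ji: float, epsilon: float = 1.0
) -> tuple[float, float]:
    """Complementary gradient weights on one edge (loser-seeking walk).

    Returns ``(toward_j, toward_i)`` where ``toward_j`` is the weight for a
    step *toward* competitor ``j`` — proportional to the points scored
    against ``j`` — so the larger weight points at the side that scored
    fewer points. The two weights are strictly positive and sum to 1.
    """
    if epsilon <= 0:
        raise ConfigurationError(f"epsilon must be > 0, got {epsilon}")
    if w_ij < 0 or w_ji < 0:
        raise ValidationError("scores must be non-negative")
    total = w_ij + w_ji + 2 * epsilon
    return (w_ij + epsilon) / total, (w_ji + epsilon) / total


def _gradient_matrix(net: CompetitionNetwork, cfg: RankingConfig) -> np.ndarray:
    """G[i, j] = gradient weight of the step j -> i, zero off the contact graph."""
    A = net.games_played > 0
    total = net.W + net.W.T + 2 * cfg.epsilon
    if cfg.direction == "toward_loser":
        numer = net.W.T + cfg.epsilon  # toward i ~ points conceded by i
    else:
        numer = net.W + cfg.epsilon  # toward i ~ points scored by i
    G = np.where(A, numer / total, 0.0)
    np.fill_diagonal(G, 0.0)
    return G


def build_transition(
    net: CompetitionNetwork, cfg: RankingConfig | None = None
) -> TransitionMatrix:
    """Degree-neutralized, column-stochastic Markov matrix for a network.

    Every competitor must have played at least one game (isolated nodes have
    no transitions; :func:`combined_rating` strips them per component before
    calling this).
    """
    cfg = cfg or RankingConfig()
    if net.n_teams < 2:
        raise ValidationError("transition matrix requires at least 2 competitors")
    k = opponent_degrees(net).astype(float)
    if np.any(k == 0):
        isolated = [t for t, d in zip(net.teams, k) if d == 0]
        raise ValidationError(f"competitors with no games: {isolated}")
    G = _gradient_matrix(net, cfg)
    R = G / k[:, None]  # entering i is discounted by k_i
    col = R.sum(axis=0)
    if cfg.lazy:
        Z = np.full(net.n_teams, col.max())
        T = R / Z
        np.fill_diagonal(T, 1.0 - col / Z[0])
    else:
        Z = col
        T = R / Z[None, :]
    if cfg.teleport > 0:
        T = (1 - cfg.teleport) * T + cfg.teleport / net.n_teams
    return TransitionMatrix(T=T, Z=Z, direction=cfg.direction, teams=tuple(net.teams))


def stationary(
    T: TransitionMatrix | np.ndarray, cfg: RankingConfig | None = None
) -> np.ndarray:
    """Stationary occupancy of a column-stochastic chain: T v = v, sum v = 1.

    For moderate sizes the balance equations are solved directly as a linear
    system (deterministic, no iteration); very large chains fall back to a
    lazy-walk power iteration, which also converges on periodic chains such
    as a 2-cycle.
    """
    cfg = cfg or RankingConfig()
    M = T.T if isinstance(T, TransitionMatrix) else np.asarray(T, dtype=float)
    n = M.shape[0]
    if n == 1:
        return np.ones(1)
    if n <= 2000:
        A = np.eye(n) - M
        A[-1, :] = 1.0  # replace one redundant balance row with normalization
        b = np.zeros(n)
        b[-1] = 1.0
        try:
            v = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
    else:
        # lazy half-step iteration v <- (M v + v)/2: same fixed point, but
        # aperiodic by construction (handles 2-cycles) and geometrically
        # convergent, unlike a plain power step on a periodic chain
        v = np.full(n, 1.0 / n)
        for it in range(1, cfg.max_iter + 1):
            v = 0.5 * (M @ v + v)
            if it % 8 == 0 and np.max(np.abs(M @ v - v)) < cfg.eig_tol:
                break
        else:
            raise ConvergenceError(
                f"stationary solve: residual "
                f"{np.max(np.abs(M @ v - v)):.3e} after {cfg.max_iter} iterations"
            )
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    resid = np.max(np.abs(M @ v - v))
    if resid > cfg.eig_tol:
        raise ConvergenceError(f"stationary residual {resid:.3e} > {cfg.eig_tol:.1e}")
    return v


def occupancy(net: CompetitionNetwork, cfg: RankingConfig) -> np.ndarray:
    """Stationary occupancy over a whole network, one component at a time.

    Early-season networks are often disconnected; each connected component
    is an irreducible chain of its own, so the stationary vector is computed
    per component and scaled by the component's share of nodes (an isolated
    competitor simply receives 1/N). Avoids uniform teleportation.
    """
    n = net.n_teams
    out = np.zeros(n)
    for comp in net.components():
        if len(comp) == 1:
            out[comp] = 1.0 / n
            continue
        sub = CompetitionNetwork(
            [net.teams[i] for i in comp],
            net.W[np.ix_(comp, comp)],
            net.games_played[np.ix_(comp, comp)],
        )
        v = stationary(build_transition(sub, cfg), cfg)
        out[comp] = v * (len(comp) / n)
    return out


def combined_rating(
    net: CompetitionNetwork, cfg: RankingConfig | None = None
) -> RatingResult:
    """Weakness and strength occupancies and their combination pi = s - w.

    Higher combined rating means stronger. Ranks are descending with ties
    averaged.
    """
    cfg = cfg or RankingConfig()
    if net.n_teams == 0:
        raise ValidationError("empty network")
    w = occupancy(net, replace(cfg, direction="toward_loser"))
    s = occupancy(net, replace(cfg, direction="toward_stronger"))
    return RatingResult(
        teams=list(net.teams), weakness=w, strength=s, combined=s - w
    )


def jackknife_errors(
    games: Sequence[GameRecord], cfg: RankingConfig | None = None
) -> np.ndarray:
    """Delete-one-game jackknife standard errors of the combined rating.

    With n games and leave-one-out ratings ``pi^(g)``,

        err_i = sqrt( (n-1)/n * sum_g (pi_i^(g) - mean_g pi_i^(g))^2 ).

    Node set is held fixed across resamples. Returned in lexicographic team
    order. A single game yields zero errors.
    """
    cfg = cfg or RankingConfig()
    games = list(games)
    n = len(games)
    if n == 0:
        raise ValidationError("jackknife requires at least one game")
    teams = sorted({t for g in games for t in (g.team_a, g.team_b)})
    loo = np.empty((n, len(teams)))
    for g_idx in range(n):
        sub = games[:g_idx] + games[g_idx + 1 :]
        net = accumulate_network(sub, teams=teams)
        loo[g_idx] = combined_rating(net, cfg).combined
    mean = loo.mean(axis=0)
    return np.sqrt((n - 1) / n * ((loo - mean) ** 2).sum(axis=0))
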