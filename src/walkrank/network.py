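"""Competition networks built from pairwise contest results.

A season of pairwise contests (games) is represented as a weighted directed
network: competitors are nodes and the cumulative points competitor ``i``
scored against competitor ``j`` form the asymmetric edge weight ``W[i, j]``.
Repeated fixtures are merged by summing points, and the number of meetings is
kept separately so that topological quantities (degree, connectance) remain
well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class ValidationError(ValueError):
    """A game record or network violates a structural invariant."""


@dataclass(frozen=True)
class GameRecord:
    """One contest: a round (matchweek) label, two competitors, two scores.

    Competitor IDs are opaque strings; scores are non-negative numbers
    (integers for raw game data, but real values are accepted with a warning
    to support pre-aggregated inputs).
    """

    round: int
    team_a: str
    score_a: float
    team_b: str
    score_b: float

    def __post_init__(self) -> None:
        if self.team_a == self.team_b:
            raise ValidationError(
                f"game in round {self.round}: team_a == team_b ({self.team_a!r})"
            )
        if self.round < 1:
            raise ValidationError(f"round must be >= 1, got {self.round}")
        if self.score_a < 0 or self.score_b < 0:
            raise ValidationError(
                f"negative score in round {self.round}: "
                f"{self.team_a} {self.score_a} - {self.score_b} {self.team_b}"
            )
        for s in (self.score_a, self.score_b):
            if float(s) != int(s):
                warnings.warn(
                    f"non-integer score {s} accepted (aggregated data?)",
                    stacklevel=3,
                )
                break

    @property
    def draw(self) -> bool:
        return self.score_a == self.score_b

    def winner(self) -> str | None:
        if self.score_a > self.score_b:
            return self.team_a
        if self.score_b > self.score_a:
            return self.team_b
        return None


class CompetitionNetwork:
    """Cumulative score-weight network for a set of contests.

    Attributes
    ----------
    teams : list of str
        Competitor IDs in lexicographic order (matrix index order).
    W : ndarray, shape (N, N)
        ``W[i, j]`` = total points ``teams[i]`` scored against ``teams[j]``.
        The diagonal is zero.
    games_played : ndarray of int, shape (N, N)
        Symmetric count of meetings between each pair.
    games : tuple of GameRecord
        The individual contests the network was accumulated from (kept so
        that per-game outcomes — wins, losses, draws — remain available to
        rating methods that need them).
    """

    def __init__(
        self,
        teams: Sequence[str],
        W: np.ndarray,
        games_played: np.ndarray,
        games: Sequence[GameRecord] = (),
    ) -> None:
        self.teams = list(teams)
        self.index = {t: i for i, t in enumerate(self.teams)}
        self.W = np.asarray(W, dtype=float)
        self.games_played = np.asarray(games_played, dtype=int)
        self.games = tuple(games)
        self._validate()

    def _validate(self) -> None:
        n = len(self.teams)
        if self.W.shape != (n, n) or self.games_played.shape != (n, n):
            raise ValidationError("matrix shapes do not match team count")
        if np.any(np.diag(self.W) != 0):
            raise ValidationError("diagonal of W must be zero")
        if np.any(self.W < 0):
            raise ValidationError("W entries must be non-negative")
        if not np.array_equal(self.games_played, self.games_played.T):
            raise ValidationError("games_played must be symmetric")
        if np.any((self.W > 0) & (self.games_played == 0)):
            raise ValidationError("positive weight on a pair that never met")

    # ------------------------------------------------------------------
    @property
    def n_teams(self) -> int:
        return len(self.teams)

    @property
    def m(self) -> int:
        """Total number of contests."""
        return int(self.games_played.sum()) // 2

    def transpose(self) -> "CompetitionNetwork":
        """Network with every pair's scores swapped (W -> W^T)."""
        return CompetitionNetwork(self.teams, self.W.T, self.games_played, self.games)

    def net_points(self) -> np.ndarray:
        """Points scored minus points conceded, per competitor."""
        return self.W.sum(axis=1) - self.W.sum(axis=0)

    def components(self) -> list[np.ndarray]:
        """Connected components of the (undirected) contact graph.

        Returned as arrays of node indices, ordered by smallest member.
        """
        from scipy.sparse.csgraph import connected_components

        n = self.n_teams
        if n == 0:
            return []
        ncomp, labels = connected_components(
            (self.games_played > 0).astype(int), directed=False
        )
        return [np.flatnonzero(labels == c) for c in range(ncomp)]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CompetitionNetwork N={self.n_teams} games={self.m} "
            f"connectance={connectance(self) if self.n_teams >= 2 else float('nan'):.3g}>"
        )


def accumulate_network(
    games: Iterable[GameRecord],
    through_round: int | None = None,
    teams: Sequence[str] | None = None,
) -> CompetitionNetwork:
    """Accumulate contests into a cumulative score-weight network.

    Parameters
    ----------
    games : iterable of GameRecord
    through_round : int, optional
        If given, only games with ``round <= through_round`` are included.
    teams : sequence of str, optional
        Fix the node set (useful for leave-one-out resampling, where dropping
        a game must not drop a node). Defaults to the competitors appearing
        in the included games. Always stored in lexicographic order.

    The result is independent of the order of the game list.
    """
    if through_round is not None and through_round < 1:
        raise ValidationError(f"through_round must be >= 1, got {through_round}")
    included = [
        g for g in games if through_round is None or g.round <= through_round
    ]
    if teams is None:
        team_set: set[str] = set()
        for g in included:
            team_set.add(g.team_a)
            team_set.add(g.team_b)
        teams = sorted(team_set)
    else:
        teams = sorted(teams)
    index = {t: i for i, t in enumerate(teams)}
    n = len(teams)
    W = np.zeros((n, n))
    gp = np.zeros((n, n), dtype=int)
    for g in included:
        try:
            a, b = index[g.team_a], index[g.team_b]
        except KeyError as exc:
            raise ValidationError(
                f"game in round {g.round} references unknown team {exc.args[0]!r}"
            ) from None
        W[a, b] += g.score_a
        W[b, a] += g.score_b
        gp[a, b] += 1
        gp[b, a] += 1
    return CompetitionNetwork(teams, W, gp, included)


def connectance(net: CompetitionNetwork) -> float:
    """Games played divided by the number of competitor pairs, m / C(N, 2).

    Exceeds 1 when pairs meet repeatedly (a double round-robin has
    connectance exactly 2).
    """
    if net.n_teams < 2:
        raise ValidationError("connectance requires at least 2 competitors")
    return net.m / (net.n_teams * (net.n_teams - 1) / 2)


def opponent_degrees(net: CompetitionNetwork) -> np.ndarray:
    """Number of *distinct* opponents each competitor has faced.

    This is the simple-graph degree of the contact graph: repeated fixtures
    against the same opponent count once, since their points are already
    merged into the cumulative weights.
    """
    return (net.games_played > 0).sum(axis=1)
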