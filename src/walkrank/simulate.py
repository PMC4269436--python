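"""Synthetic seasons with known latent strengths.

Schedules come in two flavours mirroring the two real-league topologies the
rating methods are meant for: a (possibly repeated) round-robin — the dense,
connectance-``r`` case — and a sparse conference/division schedule in which
each team plays all of its division mates plus a fixed number of
cross-division games, giving NFL-like connectance around 0.5.

Scores are independent Poisson draws whose log-means tilt with the latent
strength difference, which yields natural ties and upsets. Per-game random
substreams are derived from the master seed, so a partial season is an
exact prefix of the full one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .network import GameRecord, ValidationError

Pair = tuple[str, str]


@dataclass
class SyntheticSeasonSpec:
    """Study conditions for one synthetic season.

    n_teams
        Number of competitors (>= 2).
    strengths
        Latent strengths theta; defaults to an evenly spaced grid on [0, 1]
        assigned to teams T01 < T02 < ... (so lexicographic order is also
        strength order, handy in tests).
    schedule
        ``"round_robin"`` (``r`` meetings per pair) or ``"conference"``
        (``divisions`` equal divisions, ``games_per_team`` games each).
    mu
        Baseline expected score per team per game (default 1.35, a typical
        association-football goal rate).
    beta
        Sensitivity of the score rate to the strength difference: team i
        facing j scores Poisson(mu * exp(beta (theta_i - theta_j) / 2)).
        The default 4.0 gives well-separated teams over a full season.
    seed
        Master seed; every game draws from its own derived substream.
    """

    n_teams: int = 20
    strengths: np.ndarray | None = None
    schedule: str = "round_robin"
    r: int = 2
    divisions: int | None = None
    games_per_team: int | None = None
    mu: float = 1.35
    beta: float = 4.0
    seed: int = 0
    teams: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_teams < 2:
            raise ValidationError("need at least 2 teams")
        width = max(2, len(str(self.n_teams)))
        self.teams = [f"T{i + 1:0{width}d}" for i in range(self.n_teams)]
        if self.strengths is None:
            self.strengths = np.linspace(0.0, 1.0, self.n_teams)
        else:
            self.strengths = np.asarray(self.strengths, dtype=float)
            if self.strengths.shape != (self.n_teams,):
                raise ValidationError("strengths length must equal n_teams")
        if self.schedule not in ("round_robin", "conference"):
            raise ValidationError(f"unknown schedule {self.schedule!r}")
        if self.mu <= 0:
            raise ValidationError("mu must be > 0")
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")

    def strength_of(self, team: str) -> float:
        return float(self.strengths[self.teams.index(team)])


def _circle_rounds(items: list[str]) -> list[list[Pair]]:
    """Circle-method round robin: each round is a (near-)perfect matching.

    Odd sizes get a phantom bye; every pair meets exactly once across the
    len-1 (even) or len (odd) rounds, and no item appears twice in a round.
    """
    items = list(items)
    bye = items.append(None) if len(items) % 2 else None  # noqa: F841
    n = len(items)
    fixed, rest = items[0], items[1:]
    rounds = []
    for _ in range(n - 1):
        order = [fixed] + rest
        pairs = [
            (order[i], order[n - 1 - i])
            for i in range(n // 2)
            if order[i] is not None and order[n - 1 - i] is not None
        ]
        rounds.append([tuple(sorted(p)) for p in pairs])
        rest = rest[-1:] + rest[:-1]
    return rounds


def make_schedule(spec: SyntheticSeasonSpec) -> list[tuple[int, Pair]]:
    """Expand the spec into (round, (team, team)) fixtures.

    round_robin: the circle-method rounds repeated ``r`` times; every pair
    meets exactly ``r`` times and each team plays once per round.

    conference: ``divisions`` equal divisions; every team plays each
    division mate once, then cross-division games (cyclic bipartite
    matchings between paired divisions, divisions paired by a circle method
    of their own) until it has exactly ``games_per_team`` games.
    """
    if spec.schedule == "round_robin":
        if spec.r < 1:
            raise ValidationError("round_robin needs r >= 1")
        base = _circle_rounds(spec.teams)
        out = []
        rnd = 0
        for _ in range(spec.r):
            for matches in base:
                rnd += 1
                out.extend((rnd, p) for p in matches)
        return out

    d = spec.divisions
    g = spec.games_per_team
    if d is None or g is None:
        raise ValidationError("conference schedule needs divisions and games_per_team")
    if spec.n_teams % d != 0:
        raise ValidationError(f"{spec.n_teams} teams do not split into {d} divisions")
    s = spec.n_teams // d
    extra = g - (s - 1)
    if extra < 0:
        raise ValidationError(
            f"games_per_team={g} below the {s - 1} intra-division games"
        )
    if extra > 0 and d % 2:
        raise ValidationError("cross-division play needs an even number of divisions")
    if extra > (d - 1) * s:
        raise ValidationError(
            f"games_per_team={g} infeasible: at most {(s - 1) + (d - 1) * s} "
            "distinct opponents"
        )
    divs = [spec.teams[i * s : (i + 1) * s] for i in range(d)]

    rounds: list[list[Pair]] = []
    # intra-division play: circle rounds of each division, aligned
    intra = [_circle_rounds(dv) for dv in divs]
    for matches in itertools.zip_longest(*intra, fillvalue=[]):
        rounds.append([p for div_round in matches for p in div_round])
    # cross-division play: pair divisions by circle method, then cyclic shifts
    if extra > 0:
        pairings = _circle_rounds([str(i) for i in range(d)])
        shift_rounds = []
        for block in pairings:
            for k in range(s):
                matches = []
                for da, db in block:
                    A, B = divs[int(da)], divs[int(db)]
                    matches.extend(
                        tuple(sorted((A[x], B[(x + k) % s]))) for x in range(s)
                    )
                shift_rounds.append(matches)
        rounds.extend(shift_rounds[:extra])
    out = []
    for rnd, matches in enumerate(rounds, start=1):
        out.extend((rnd, p) for p in matches)
    return out


def simulate_season(spec: SyntheticSeasonSpec) -> list[GameRecord]:
    """Draw one season of integer scores for the spec's schedule.

    Team ``i`` facing ``j`` scores ``Poisson(mu * exp(beta (th_i - th_j)/2))``
    and ``j`` the mirrored rate, independently: stronger teams pile on
    points, but any score line — including ties and upsets — has positive
    probability. Game ``g`` (in schedule order) uses the substream
    ``SeedSequence([seed, g])``, making partial seasons exact prefixes.
    """
    schedule = make_schedule(spec)
    th = {t: spec.strength_of(t) for t in spec.teams}
    records = []
    for g_idx, (rnd, (ta, tb)) in enumerate(schedule):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, g_idx]))
        diff = th[ta] - th[tb]
        lam_a = spec.mu * np.exp(spec.beta * diff / 2.0)
        lam_b = spec.mu * np.exp(-spec.beta * diff / 2.0)
        sa, sb = rng.poisson(lam_a), rng.poisson(lam_b)
        records.append(GameRecord(rnd, ta, float(sa), tb, float(sb)))
    return records
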