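"""Model/Results interface over the rating methods.

Each rating method is exposed as a model class built from a list of games
(or a tidy DataFrame), whose ``fit()`` returns a :class:`RatingResults`
carrying the per-competitor estimates, optional jackknife standard errors,
average ranks, a deterministic display order, and a ``summary()`` table —
the shape familiar from statsmodels.

>>> res = DegreeNeutralizedRandomWalk(games).fit()
>>> res.params          # combined rating pi = s - w, per team
>>> res.rank            # descending, ties averaged
>>> print(res.summary())
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import baselines as _bl
from . import dnrw as _dnrw
from .network import GameRecord, ValidationError, accumulate_network


def coerce_games(games: Iterable) -> list[GameRecord]:
    """Accept GameRecords or (round, team_a, score_a, team_b, score_b) tuples."""
    out = []
    for g in games:
        if isinstance(g, GameRecord):
            out.append(g)
        else:
            r, ta, sa, tb, sb = g
            out.append(GameRecord(int(r), str(ta), float(sa), str(tb), float(sb)))
    return out


class RatingResults:
    """Fitted ratings for one method on one (partial) season.

    Attributes
    ----------
    params : pd.Series
        The scalar rating per competitor (higher = stronger), on the
        method's own scale.
    frame : pd.DataFrame
        Method-specific columns plus ``rating`` and ``rank``.
    rank : pd.Series
        Descending rank with ties averaged (used for correlations).
    bse : pd.Series or None
        Jackknife standard errors where computed.
    """

    def __init__(
        self,
        model: "RatingModel",
        frame: pd.DataFrame,
        bse: pd.Series | None = None,
    ) -> None:
        self.model = model
        self.method = model.method
        self.frame = frame
        self.params = frame["rating"]
        self.rank = frame["rank"]
        self.bse = bse

    def ordering(self) -> list[str]:
        """Deterministic display order: rating desc, then net points desc,
        then lexicographic ID."""
        net_pts = pd.Series(
            self.model.network.net_points(), index=self.model.network.teams
        )
        df = pd.DataFrame(
            {"rating": self.params, "net": net_pts.reindex(self.params.index)}
        )
        df = df.sort_values(
            by=["rating", "net"], ascending=[False, False], kind="mergesort"
        )
        return list(df.index)

    def predict(self, team_a: str, team_b: str) -> int:
        """Predicted outcome sign: +1 if team_a is rated higher, -1 if
        lower, 0 if the ratings are exactly tied (or a team is unrated)."""
        ra = self.params.get(team_a)
        rb = self.params.get(team_b)
        if ra is None or rb is None or ra == rb:
            return 0
        return 1 if ra > rb else -1

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(0, "method", self.method)
        if self.bse is not None:
            out["error"] = self.bse
        return out

    def summary(self) -> str:
        df = self.to_frame().loc[self.ordering()]
        lines = [
            f"{type(self.model).__name__} rating results",
            f"  competitors: {self.model.network.n_teams}"
            f"   games: {self.model.network.m}",
            "",
            df.to_string(float_format=lambda x: f"{x:.6g}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<RatingResults {self.method} N={len(self.params)}>"


class RatingModel:
    """Base class: builds the cumulative competition network from games."""

    method = "base"

    def __init__(
        self,
        games: Iterable,
        through_round: int | None = None,
        teams: Sequence[str] | None = None,
    ) -> None:
        self.games = coerce_games(games)
        self.network = accumulate_network(self.games, through_round, teams)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        round_col: str = "round",
        team_a: str = "team_a",
        score_a: str = "score_a",
        team_b: str = "team_b",
        score_b: str = "score_b",
        **kwargs,
    ) -> "RatingModel":
        games = [
            GameRecord(
                int(r[round_col]),
                str(r[team_a]),
                float(r[score_a]),
                str(r[team_b]),
                float(r[score_b]),
            )
            for _, r in df.iterrows()
        ]
        return cls(games, **kwargs)

    def _columns(self) -> Mapping[str, np.ndarray]:
        raise NotImplementedError

    def fit(self, **kwargs) -> RatingResults:
        cols = dict(self._columns())
        frame = pd.DataFrame(cols, index=pd.Index(self.network.teams, name="team"))
        frame["rank"] = _dnrw.average_ranks(frame["rating"].to_numpy())
        return RatingResults(self, frame)


class DegreeNeutralizedRandomWalk(RatingModel):
    """The gradient random walk with degree-neutralized transitions.

    Parameters
    ----------
    epsilon : float
        Gradient regularizer (> 0).
    config : RankingConfig, optional
        Full configuration; overrides ``epsilon`` when given.
    """

    method = "dnrw"

    def __init__(
        self,
        games: Iterable,
        through_round: int | None = None,
        teams: Sequence[str] | None = None,
        epsilon: float = 1.0,
        config: _dnrw.RankingConfig | None = None,
    ) -> None:
        super().__init__(games, through_round, teams)
        self.config = config or _dnrw.RankingConfig(epsilon=epsilon)

    def _columns(self) -> Mapping[str, np.ndarray]:
        r = _dnrw.combined_rating(self.network, self.config)
        return {"weakness": r.weakness, "strength": r.strength, "rating": r.combined}

    def fit(self, jackknife: bool = False) -> RatingResults:
        res = super().fit()
        if jackknife:
            err = _dnrw.jackknife_errors(self.network.games, self.config)
            res.bse = pd.Series(err, index=res.params.index)
        return res


class WinLoss(RatingModel):
    """Win-loss margin with net-points tiebreak (the EPL's official scheme).

    The scalar ``rating`` encodes the lexicographic (margin, net points)
    order as ``margin + net_points * 1e-6`` — net-point totals in real
    seasons are far below the 1e6 that would take the tiebreak across a
    whole margin step."""

    method = "winloss"

    def _columns(self) -> Mapping[str, np.ndarray]:
        margin, net_pts = _bl.winloss_rating(self.network)
        return {
            "margin": margin,
            "net_points": net_pts,
            "rating": margin + net_pts * 1e-6,
        }


class Colley(RatingModel):
    """Colley's bias-free matrix ratings."""

    method = "colley"

    def _columns(self) -> Mapping[str, np.ndarray]:
        return {"rating": _bl.colley_rating(self.network)}


class ParkNewman(RatingModel):
    """Park-Newman generalized wins-losses (directional Katz centrality)."""

    method = "parknewman"

    def __init__(self, games, through_round=None, teams=None, pn_alpha=None):
        super().__init__(games, through_round, teams)
        self.config = _bl.BaselineConfig(pn_alpha=pn_alpha)

    def _columns(self) -> Mapping[str, np.ndarray]:
        return {"rating": _bl.park_newman_rating(self.network, self.config)}


class PageRankWeakness(RatingModel):
    """PageRank occupancy on winner-to-loser edges, read as weakness.

    ``rating`` is the negated occupancy so that, as for every other model,
    higher rating means stronger."""

    method = "pagerank"

    def __init__(
        self, games, through_round=None, teams=None, pr_alpha=0.85, pr_weighted=True
    ):
        super().__init__(games, through_round, teams)
        self.config = _bl.BaselineConfig(pr_alpha=pr_alpha, pr_weighted=pr_weighted)

    def _columns(self) -> Mapping[str, np.ndarray]:
        occ = _bl.pagerank_weakness(self.network, self.config)
        return {"occupancy": occ, "rating": -occ}


MODELS: dict[str, type[RatingModel]] = {
    m.method: m
    for m in (DegreeNeutralizedRandomWalk, WinLoss, Colley, ParkNewman, PageRankWeakness)
}


def get_model(method: str) -> type[RatingModel]:
    try:
        return MODELS[method]
    except KeyError:
        raise ValidationError(
            f"unknown rating method {method!r}; known: {sorted(MODELS)}"
        ) from None


def rate(games: Iterable, method: str = "dnrw", **kwargs) -> RatingResults:
    """One-call convenience: build the model for ``method`` and fit it."""
    jackknife = kwargs.pop("jackknife", False)
    model = get_model(method)(games, **kwargs)
    if method == "dnrw":
        return model.fit(jackknife=jackknife)
    return model.fit()
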