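"""Season evaluation protocol: weekly prediction accuracy, rank-convergence
(Spearman correlation with the final ranking), line crossings, and the
exponential decay fit of the crossing counts.

All quantities are computed on *cumulative* data: the rating entering round
``t`` uses every game from rounds ``1 .. t-1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import spearmanr

from .models import coerce_games, get_model
from .network import GameRecord, ValidationError


@dataclass
class ExpFit:
    """Least-squares fit of a * exp(-b t) to a per-round count series."""

    amplitude: float
    rate: float
    residual: float
    amplitude_se: float = float("nan")
    rate_se: float = float("nan")
    degenerate: bool = False


@dataclass
class WeeklySeries:
    """Per-round evaluation of one rating method over a season.

    ``table`` is indexed by round with columns ``n_games``, ``correct``
    (credited predictions, draws counting 1/2), ``accuracy``, ``src``
    (Spearman rank correlation of the cumulative ranking with the final
    one), and ``crossings`` (rank flips versus the previous round).
    Prediction columns are NaN for the first round (no prior data).
    """

    method: str
    table: pd.DataFrame
    ratings: dict[int, pd.Series]
    src_threshold: float = 0.9

    @property
    def aggregate_accuracy(self) -> float:
        t = self.table.dropna(subset=["accuracy"])
        return float(t["correct"].sum() / t["n_games"].sum())

    @property
    def threshold_round(self) -> int | None:
        """Earliest round whose SRC with the final ranking >= threshold."""
        ok = self.table.index[self.table["src"] >= self.src_threshold]
        return int(ok[0]) if len(ok) else None

    def exponential_fit(self) -> ExpFit:
        c = self.table["crossings"].dropna()
        return fit_exponential(c.to_numpy(), rounds=c.index.to_numpy())


def _cumulative_ratings(
    games: Sequence[GameRecord], method: str, cfg: Mapping | None
) -> tuple[list[int], dict[int, pd.Series]]:
    """Rating series after each round, on cumulative data through that round."""
    cfg = dict(cfg or {})
    cls = get_model(method)
    rounds = sorted({g.round for g in games})
    ratings: dict[int, pd.Series] = {}
    for t in rounds:
        ratings[t] = cls(games, through_round=t, **cfg).fit().params
    return rounds, ratings


def _credit(game: GameRecord, ratings: pd.Series) -> float:
    """Prediction credit for one game given the pre-round ratings.

    The higher-rated team is predicted to win; a correct call earns 1, a
    wrong one 0, and an actually drawn game 1/2.  A game involving a team
    without a rating yet, or two exactly tied ratings, also earns 1/2 (no
    informative call can be made)."""
    ra = ratings.get(game.team_a)
    rb = ratings.get(game.team_b)
    if ra is None or rb is None or ra == rb or game.draw:
        return 0.5
    predicted = game.team_a if ra > rb else game.team_b
    return 1.0 if predicted == game.winner() else 0.0


def season_series(
    games: Iterable,
    method: str = "dnrw",
    method_cfg: Mapping | None = None,
    src_threshold: float = 0.9,
) -> WeeklySeries:
    """Full per-round evaluation of one method on one season.

    For each round ``t >= 2`` the games of round ``t`` are predicted from
    the ratings fitted on rounds ``1..t-1``; the cumulative rating *after*
    each round is correlated (Spearman, average ranks) with the final one
    and compared with the previous round's ranking to count line crossings.
    """
    games = coerce_games(games)
    if not games:
        raise ValidationError("no games to evaluate")
    rounds, cum = _cumulative_ratings(games, method, method_cfg)
    final = cum[rounds[-1]]
    by_round: dict[int, list[GameRecord]] = {}
    for g in games:
        by_round.setdefault(g.round, []).append(g)

    rows = []
    for idx, t in enumerate(rounds):
        row: dict[str, float] = {"round": t}
        if idx == 0:
            row.update(n_games=np.nan, correct=np.nan, accuracy=np.nan)
        else:
            prev = cum[rounds[idx - 1]]
            credits = [_credit(g, prev) for g in by_round[t]]
            row.update(
                n_games=len(credits),
                correct=float(np.sum(credits)),
                accuracy=float(np.mean(credits)),
            )
        # SRC of the cumulative ranking after round t with the final one,
        # over the teams already rated at round t.
        common = cum[t].index
        x = cum[t].to_numpy()
        y = final.reindex(common).to_numpy()
        if len(common) >= 2 and np.ptp(x) > 0 and np.ptp(y) > 0:
            row["src"] = float(spearmanr(x, y)[0])
        else:
            row["src"] = np.nan  # undefined: <2 rated teams or an all-tied ranking
        if idx == 0:
            row["crossings"] = np.nan
        else:
            prev = cum[rounds[idx - 1]]
            row["crossings"] = line_crossings(
                prev, cum[t].reindex(prev.index)
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("round")
    return WeeklySeries(
        method=method, table=table, ratings=cum, src_threshold=src_threshold
    )


def weekly_accuracy(
    games: Iterable, method: str = "dnrw", method_cfg: Mapping | None = None
) -> WeeklySeries:
    """Per-round cumulative-data prediction accuracy of one method."""
    return season_series(games, method, method_cfg)


def src_convergence(
    games: Iterable,
    method: str = "dnrw",
    method_cfg: Mapping | None = None,
    threshold: float = 0.9,
) -> tuple[WeeklySeries, int | None]:
    """SRC-vs-final series and the first round at or above ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0,1], got {threshold}")
    series = season_series(games, method, method_cfg, src_threshold=threshold)
    return series, series.threshold_round


def line_crossings(rank_a: pd.Series | Mapping, rank_b: pd.Series | Mapping) -> int:
    """Number of competitor pairs whose relative order differs between two
    rankings (discordant pairs). Pairs tied in either ranking do not count.

    Accepts scores or ranks; only the pairwise order matters, so the count
    is symmetric in its arguments and invariant under relabeling."""
    a = pd.Series(rank_a)
    b = pd.Series(rank_b)
    if set(a.index) != set(b.index):
        raise ValidationError("rankings cover different competitor sets")
    b = b.reindex(a.index)
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    da = np.sign(av[:, None] - av[None, :])
    db = np.sign(bv[:, None] - bv[None, :])
    discordant = (da * db) < 0
    return int(discordant.sum() // 2)


def fit_exponential(
    crossings: Sequence[float], rounds: Sequence[float] | None = None
) -> ExpFit:
    """Nonlinear least-squares fit of ``a * exp(-b t)`` to raw crossing
    counts (raw, not log-transformed: late-season rounds routinely have
    zero crossings).

    Returns amplitude, decay rate per round, the residual norm, and the
    asymptotic standard errors of the two parameters. An all-zero series is
    degenerate and reported as ``a = 0``."""
    y = np.asarray(crossings, dtype=float)
    if len(y) < 3:
        raise ValidationError("exponential fit requires at least 3 rounds")
    t = np.arange(1, len(y) + 1, dtype=float) if rounds is None else np.asarray(
        rounds, dtype=float
    )
    if not y.any():
        return ExpFit(0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)

    def f(t, a, b):
        return a * np.exp(-b * t)

    # start from a log-linear fit on the positive entries
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(-slope))
    else:
        p0 = (float(y.max()), 0.1)
    popt, pcov = optimize.curve_fit(f, t, y, p0=p0, maxfev=20000)
    resid = float(np.linalg.norm(y - f(t, *popt)))
    se = np.sqrt(np.diag(pcov))
    return ExpFit(float(popt[0]), float(popt[1]), resid, float(se[0]), float(se[1]))
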