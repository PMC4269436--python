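import numpy as np
import pytest

from walkrank import GameRecord, accumulate_network


def make_games(rows):
    return [GameRecord(r, a, sa, b, sb) for r, a, sa, b, sb in rows]


@pytest.fixture
def tie_chain():
    """Three teams in a chain, both games scoreless ties (A-B-C)."""
    return make_games([(1, "A", 0, "B", 0), (1, "B", 0, "C", 0)])


@pytest.fixture
def transitive_triangle():
    """A beats B, B beats C, A beats C, all 2:0."""
    return make_games(
        [(1, "A", 2, "B", 0), (1, "B", 2, "C", 0), (2, "A", 2, "C", 0)]
    )


def random_fixture(rng, n_teams=None, n_games=None, max_score=5, n_rounds=4):
    """Random connected season: a random spanning tree of contests plus
    extra random pairings, with uniform integer scores (ties included)."""
    n = int(n_teams if n_teams is not None else rng.integers(3, 9))
    teams = [f"T{i:02d}" for i in range(n)]
    games = []
    order = rng.permutation(n)
    for i in range(1, n):
        a, b = teams[order[i]], teams[int(order[rng.integers(0, i)])]
        games.append(
            GameRecord(
                int(rng.integers(1, n_rounds + 1)),
                a,
                int(rng.integers(0, max_score + 1)),
                b,
                int(rng.integers(0, max_score + 1)),
            )
        )
    extra = int(n_games - (n - 1)) if n_games is not None else int(rng.integers(0, 2 * n))
    for _ in range(max(extra, 0)):
        a, b = rng.choice(n, size=2, replace=False)
        games.append(
            GameRecord(
                int(rng.integers(1, n_rounds + 1)),
                teams[a],
                int(rng.integers(0, max_score + 1)),
                teams[b],
                int(rng.integers(0, max_score + 1)),
            )
        )
    return games


def eig_stationary(T):
    """Independent oracle: leading eigenvector of a column-stochastic matrix
    via dense eigendecomposition, normalized to a probability vector."""
    vals, vecs = np.linalg.eig(T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    v = np.abs(v)
    return v / v.sum()
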