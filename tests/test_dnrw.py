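import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from walkrank import (
    ConfigurationError,
    GameRecord,
    RankingConfig,
    accumulate_network,
    build_transition,
    combined_rating,
    gradient_pair,
    jackknife_errors,
    stationary,
)

from conftest import eig_stationary, make_games, random_fixture

scores = st.integers(min_value=0, max_value=60)
epsilons = st.floats(min_value=0.01, max_value=10)


class TestGradientPair:
    @settings(derandomize=True, max_examples=200)
    @given(scores, scores, epsilons)
    def test_weights_positive_and_sum_to_one(self, wij, wji, eps):
        gj, gi = gradient_pair(wij, wji, eps)
        assert gj > 0 and gi > 0
        assert gj + gi == pytest.approx(1.0, abs=1e-14)

    @settings(derandomize=True, max_examples=100)
    @given(scores, scores, epsilons)
    def test_larger_weight_points_at_bigger_loser(self, wij, wji, eps):
        gj, gi = gradient_pair(wij, wji, eps)
        if wij > wji:  # j conceded more -> walker prefers j
            assert gj > gi
        elif wij < wji:
            assert gi > gj
        else:
            assert gj == gi == pytest.approx(0.5)

    def test_two_one_with_unit_regularizer(self):
        # i beat j 2:1 -> 3/5 of the gradient points at the 1-point side j
        assert gradient_pair(2, 1, 1.0) == pytest.approx((3 / 5, 2 / 5))

    def test_scoreless_tie_stays_two_way(self):
        assert gradient_pair(0, 0, 1.0) == (0.5, 0.5)

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ConfigurationError):
            gradient_pair(1, 0, 0.0)
        with pytest.raises(ConfigurationError):
            RankingConfig(epsilon=-1)


class TestBuildTransition:
    def test_tie_chain_columns(self, tie_chain):
        T = build_transition(accumulate_network(tie_chain)).T
        # A, B, C lexicographic; column B splits evenly, A and C feed B
        np.testing.assert_allclose(T[:, 1], [0.5, 0.0, 0.5])
        np.testing.assert_allclose(T[:, 0], [0.0, 1.0, 0.0])
        np.testing.assert_allclose(T[:, 2], [0.0, 1.0, 0.0])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_columns_stochastic_and_support_matches_contacts(self, seed):
        rng = np.random.default_rng(seed)
        net = accumulate_network(random_fixture(rng))
        tm = build_transition(net)
        np.testing.assert_allclose(tm.T.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(tm.T >= 0)
        off = ~np.eye(net.n_teams, dtype=bool)
        np.testing.assert_array_equal(
            (tm.T > 0)[off], (net.games_played > 0)[off]
        )

    def test_transitive_triangle_matches_hand_substitution(
        self, transitive_triangle
    ):
        net = accumulate_network(transitive_triangle)
        T = build_transition(net, RankingConfig(epsilon=1.0)).T
        # Hand substitution: per-pair gradients (2:0, eps=1) are 3/4 toward
        # the loser, 1/4 toward the winner; all degrees are 2; columns
        # renormalize. Column A: toward B 3/4, toward C 3/4 -> 1/2 each.
        np.testing.assert_allclose(T[:, 0], [0, 0.5, 0.5])
        # Column B: toward A 1/4, toward C 3/4 -> 1/4, 3/4.
        np.testing.assert_allclose(T[:, 1], [0.25, 0, 0.75])
        # Column C: toward A 1/4, toward B 1/4 -> 1/2 each.
        np.testing.assert_allclose(T[:, 2], [0.5, 0.5, 0])

    def test_isolated_competitor_rejected(self):
        net = accumulate_network(
            make_games([(1, "A", 1, "B", 0)]), teams=["A", "B", "C"]
        )
        with pytest.raises(Exception, match="C"):
            build_transition(net)


class TestStationary:
    def test_tie_chain_balance(self, tie_chain):
        tm = build_transition(accumulate_network(tie_chain))
        np.testing.assert_allclose(stationary(tm), [0.25, 0.5, 0.25], atol=1e-14)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_dense_eigensolver_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = accumulate_network(random_fixture(rng, n_teams=int(rng.integers(3, 9))))
        tm = build_transition(net)
        v = stationary(tm)
        assert np.all(v >= 0)
        assert v.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(tm.T @ v - v)) < 1e-10
        np.testing.assert_allclose(v, eig_stationary(tm.T), atol=1e-10)

    def test_periodic_two_cycle(self):
        # A-B only: the chain alternates deterministically; the stationary
        # distribution is still uniform.
        tm = build_transition(
            accumulate_network(make_games([(1, "A", 3, "B", 1)]))
        )
        np.testing.assert_allclose(stationary(tm), [0.5, 0.5], atol=1e-12)

    def test_iterative_branch_on_large_network(self):
        # above the direct-solve size threshold the lazy power iteration
        # takes over; spot-check its output on a well-connected instance
        rng = np.random.default_rng(11)
        n = 2050
        games = random_fixture(rng, n_teams=n, n_games=4 * n, n_rounds=2)
        tm = build_transition(accumulate_network(games))
        v = stationary(tm)
        assert v.shape == (n,)
        assert v.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.max(np.abs(tm.T @ v - v)) < 1e-12


class TestCombinedRating:
    def test_tie_chain_combined_ratings_equal(self, tie_chain):
        res = combined_rating(accumulate_network(tie_chain))
        np.testing.assert_allclose(res.combined, res.combined[0], atol=1e-15)
        assert set(res.rank) == {2.0}

    @pytest.mark.parametrize("eps", [0.5, 1.0, 2.0])
    def test_triangle_order_stable_across_epsilon(self, transitive_triangle, eps):
        res = combined_rating(
            accumulate_network(transitive_triangle), RankingConfig(epsilon=eps)
        )
        assert res.teams == ["A", "B", "C"]
        assert res.combined[0] > res.combined[1] > res.combined[2]

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_duality_strength_is_weakness_of_transpose(self, seed):
        rng = np.random.default_rng(seed)
        net = accumulate_network(random_fixture(rng))
        res = combined_rating(net)
        res_t = combined_rating(net.transpose())
        np.testing.assert_array_equal(res.strength, res_t.weakness)
        np.testing.assert_array_equal(res.weakness, res_t.strength)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_transposing_scores_reverses_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        net = accumulate_network(random_fixture(rng))
        res = combined_rating(net)
        res_t = combined_rating(net.transpose())
        np.testing.assert_allclose(res_t.combined, -res.combined, atol=1e-15)
        n = net.n_teams
        np.testing.assert_allclose(res.rank + res_t.rank, n + 1)

    @settings(derandomize=True, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        games = random_fixture(rng)
        relabel = {
            t: f"X{rng.integers(0, 10**9):09d}"
            for t in {x for g in games for x in (g.team_a, g.team_b)}
        }
        renamed = [
            GameRecord(g.round, relabel[g.team_a], g.score_a, relabel[g.team_b], g.score_b)
            for g in games
        ]
        res = combined_rating(accumulate_network(games))
        res2 = combined_rating(accumulate_network(renamed))
        lookup = dict(zip(res2.teams, res2.combined))
        np.testing.assert_allclose(
            [lookup[relabel[t]] for t in res.teams], res.combined, atol=1e-15
        )

    def test_disconnected_components_rated_by_node_share(self):
        games = make_games(
            [(1, "A", 2, "B", 0), (1, "C", 1, "D", 1)]
        )
        res = combined_rating(accumulate_network(games))
        # each 2-node component carries half the occupancy mass
        assert res.weakness.sum() == pytest.approx(1.0)
        assert res.weakness[2] == res.weakness[3] == pytest.approx(0.25)


class TestJackknife:
    def test_single_game_has_zero_errors(self):
        err = jackknife_errors([GameRecord(1, "A", 2, "B", 1)])
        np.testing.assert_array_equal(err, [0.0, 0.0])

    def test_symmetric_fixture_gives_equal_errors(self):
        games = make_games([(1, "A", 1, "B", 1), (2, "A", 2, "B", 2)])
        err = jackknife_errors(games)
        assert err[0] == pytest.approx(err[1])

    def test_matches_leave_one_out_formula_on_six_game_fixture(self):
        rng = np.random.default_rng(5)
        games = random_fixture(rng, n_teams=4, n_games=6)
        assert len(games) == 6
        teams = sorted({t for g in games for t in (g.team_a, g.team_b)})
        # independent brute-force application of the delete-one formula
        loo = []
        for i in range(6):
            net = accumulate_network(games[:i] + games[i + 1 :], teams=teams)
            loo.append(combined_rating(net).combined)
        loo = np.array(loo)
        expected = np.sqrt(5 / 6 * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))
        np.testing.assert_allclose(jackknife_errors(games), expected, atol=1e-14)
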