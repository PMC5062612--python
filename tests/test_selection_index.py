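"""Index algebra: P/G construction, weights, per-environment accuracy."""

import numpy as np
import pytest

from rnbreed import (
    RNParams,
    build_env_grid,
    gebv_G,
    gebv_P,
    gebv_accuracy,
    genetic_covariance_matrix,
    progeny_G,
    progeny_P,
    proportional_goal,
    solve_index,
    env_accuracy,
    accuracy_profile,
    conventional_collapse_progeny,
    conventional_progeny_accuracies,
    conventional_gebv_accuracies,
)
from rnbreed.rn_model import genetic_variance, heritability
from rnbreed.selection_index import (
    DegenerateIndexError,
    PopulationState,
    genetic_correlation_matrix,
    gebv_sources,
    progeny_sources,
    source_matrices,
)


@pytest.fixture(scope="module")
def n_per_env(grid2=None):
    g = build_env_grid()
    return g.proportions * 100


class TestProgenyP:
    def test_single_record_diagonal(self, grid, basic_params):
        P = progeny_P(grid, basic_params, np.ones(13))
        for i, x in enumerate(grid.x_means):
            expected = genetic_variance(basic_params, x) + basic_params.var_e
            assert P[i, i] == pytest.approx(expected)

    def test_large_group_limit_is_quarter_genetic_variance(
        self, grid, basic_params
    ):
        P = progeny_P(grid, basic_params, np.full(13, 1e9))
        for i, x in enumerate(grid.x_means):
            assert P[i, i] == pytest.approx(
                0.25 * genetic_variance(basic_params, x), rel=1e-6
            )

    def test_center_class_value_at_allocated_group_size(
        self, grid, basic_params, n_per_env
    ):
        P = progeny_P(grid, basic_params, n_per_env)
        n7 = n_per_env[6]
        expected = (0.3 + 0.7 + (n7 - 1) * 0.25 * 0.3) / n7
        assert P[6, 6] == pytest.approx(expected)
        assert P[6, 6] == pytest.approx(0.13910, abs=5e-5)

    def test_off_diagonal_quarter_covariance(
        self, grid, basic_params, n_per_env
    ):
        from rnbreed import genetic_covariance

        P = progeny_P(grid, basic_params, n_per_env)
        assert P[0, 12] == pytest.approx(
            0.25 * genetic_covariance(basic_params, -2.3732, 2.3732), abs=1e-4
        )

    def test_nonpositive_group_size_rejected(self, grid, basic_params):
        with pytest.raises(ValueError):
            progeny_P(grid, basic_params, np.zeros(13))


class TestProgenyG:
    def test_half_covariance_entries(self, grid, basic_params):
        G = progeny_G(grid, basic_params)
        assert G[6, 6] == pytest.approx(0.15)
        # classes at x = -1.08 and +1.08: 0.5 * (0.3 - 0.05 * 1.08^2)
        i, j = 3, 9
        xi, xj = grid.x_means[i], grid.x_means[j]
        assert G[i, j] == pytest.approx(0.5 * (0.3 + xi * xj * 0.05))

    def test_no_gxe_gives_constant_matrix(self, grid):
        p = RNParams(var_sl=0.0)
        G = progeny_G(grid, p)
        assert np.allclose(G, 0.5 * 0.3)


class TestGebvAccuracy:
    def test_boundary_and_closed_form(self):
        assert gebv_accuracy(0, 0.3, 1200) == 0.0
        assert gebv_accuracy(1200 / 0.3, 0.3, 1200) == pytest.approx(
            np.sqrt(0.5)
        )
        assert gebv_accuracy(721.37, 0.3, 1200) == pytest.approx(
            0.3909, abs=5e-5
        )

    def test_monotone_in_reference_size(self):
        acc = [gebv_accuracy(n, 0.3, 1200) for n in (100, 1000, 1e7)]
        assert acc == sorted(acc)
        assert acc[-1] > 0.999

    @pytest.mark.parametrize(
        "args", [(-1, 0.3, 1200), (100, 0.0, 1200), (100, 0.3, 0)]
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            gebv_accuracy(*args)


class TestGebvMatrices:
    def test_perfect_accuracies_give_genetic_correlations(
        self, grid, basic_params
    ):
        rg = genetic_correlation_matrix(basic_params, grid)
        P = gebv_P(np.ones(13), rg)
        np.testing.assert_allclose(P, rg)

    def test_zero_accuracy_zeroes_row(self, grid, basic_params):
        rg = genetic_correlation_matrix(basic_params, grid)
        acc = np.full(13, 0.5)
        acc[4] = 0.0
        P = gebv_P(acc, rg)
        off = np.delete(P[4], 4)
        assert np.allclose(off, 0.0)
        assert P[4, 4] == 1.0

    def test_off_diagonal_product(self, basic_params, grid):
        rg = genetic_correlation_matrix(basic_params, grid)
        acc = np.zeros(13)
        acc[6], acc[12] = 0.39, 0.74
        P = gebv_P(acc, rg)
        assert P[6, 12] == pytest.approx(0.719 * 0.39 * 0.74, abs=1e-3)

    def test_g_matrix_scaling(self, grid, basic_params):
        acc = np.full(13, 0.3909)
        G = gebv_G(acc, basic_params, grid)
        assert G[6, 6] == pytest.approx(0.3909 * np.sqrt(0.3), abs=1e-4)
        assert G[6, 6] == pytest.approx(0.21411, abs=1e-4)
        G0 = gebv_G(np.zeros(13), basic_params, grid)
        assert np.allclose(G0, 0.0)


class TestSolveIndex:
    def test_single_source_is_univariate_regression(self, grid, basic_params):
        n = grid.proportions * 100
        P = progeny_P(grid, basic_params, n)[:1, :1]
        G = progeny_G(grid, basic_params)[:1, :]
        v = np.zeros(13)
        v[0] = 1.0
        system = solve_index(P, G, v)
        assert system.weights[0] == pytest.approx(G[0, 0] / P[0, 0])

    def test_identity_system(self):
        eye = np.eye(3)
        v = np.ones(3)
        system = solve_index(eye, eye, v, goal_cov=eye)
        np.testing.assert_allclose(system.weights, v)
        assert system.r_IH == pytest.approx(1.0)

    def test_duplicate_source_pruned(self, grid, basic_params):
        P = progeny_P(grid, basic_params, grid.proportions * 100)
        G = progeny_G(grid, basic_params)
        P2 = np.block([[P, P[:, :1]], [P[:1, :], P[:1, :1]]])
        G2 = np.vstack([G, G[:1, :]])
        v = proportional_goal(grid).values
        base = solve_index(P, G, v)
        dup = solve_index(P2, G2, v)
        assert dup.pruned == [13]
        assert dup.sigma_I == pytest.approx(base.sigma_I)

    def test_zero_variance_goal_degenerate(self):
        with pytest.raises(DegenerateIndexError):
            solve_index(np.zeros((2, 2)), np.ones((2, 1)), np.ones(1))


class TestEnvAccuracy:
    def test_perfect_single_source(self, grid, basic_params):
        # an error-free record of the class-7 breeding value
        var7 = genetic_variance(basic_params, 0.0)
        P = np.array([[var7]])
        G = genetic_covariance_matrix(basic_params, grid.x_means)[6:7, :]
        v = np.zeros(13)
        v[6] = 1.0
        system = solve_index(P, G, v)
        assert env_accuracy(system, basic_params, grid, 6) == pytest.approx(
            1.0
        )

    def test_adding_information_never_hurts(self, grid, basic_params):
        v = proportional_goal(grid).values
        C = genetic_covariance_matrix(basic_params, grid.x_means)
        n = grid.proportions * 100
        accs = []
        for k in (3, 7, 13):
            srcs = progeny_sources(grid, n)[:k]
            P, G = source_matrices(srcs, basic_params, grid.x_means)
            accs.append(solve_index(P, G, v, goal_cov=C).r_IH)
        assert accs[0] <= accs[1] + 1e-12 <= accs[2] + 2e-12


class TestConventionalCollapse:
    def test_pooling_weights(self, grid, basic_params):
        n = grid.proportions * 100
        P = progeny_P(grid, basic_params, n)
        G = progeny_G(grid, basic_params)
        P_bar, G_bar = conventional_collapse_progeny(P, G, n)
        w = n / n.sum()
        assert P_bar == pytest.approx(float(w @ P @ w))
        np.testing.assert_allclose(G_bar, w @ G)

    def test_lossless_without_gxe(self, grid):
        p = RNParams(var_sl=0.0)
        n = grid.proportions * 100
        P, G = progeny_P(grid, p, n), progeny_G(grid, p)
        rn = accuracy_profile(P, G, p, grid)
        conv = conventional_progeny_accuracies(P, G, n, p, grid)
        np.testing.assert_allclose(rn, conv, atol=1e-9)

    def test_conventional_accuracy_factorizes_through_rg(
        self, grid, basic_params
    ):
        """Ignoring GxE, the class-i accuracy is the pooled-intercept
        accuracy times the genetic correlation with the average
        environment (zero intercept-slope covariance)."""
        from rnbreed import genetic_correlation

        n = grid.proportions * 100
        P, G = progeny_P(grid, basic_params, n), progeny_G(grid, basic_params)
        conv = conventional_progeny_accuracies(P, G, n, basic_params, grid)
        r_int = conv[6]  # center class: x = 0
        for i, x in enumerate(grid.x_means):
            rg = genetic_correlation(basic_params, x, 0.0)
            assert conv[i] == pytest.approx(r_int * rg, abs=1e-4)

    def test_conventional_gebv_below_rn_at_extremes(self, grid, basic_params):
        acc = np.array(
            [
                gebv_accuracy(5000 * p, heritability(basic_params, x), 1200)
                for p, x in zip(grid.proportions, grid.x_means)
            ]
        )
        rg = genetic_correlation_matrix(basic_params, grid)
        rn = accuracy_profile(
            gebv_P(acc, rg), gebv_G(acc, basic_params, grid), basic_params, grid
        )
        conv = conventional_gebv_accuracies(acc, basic_params, grid)
        assert np.all(rn >= conv - 1e-9)
        assert rn[0] - conv[0] > 0.01
        assert rn[12] - conv[12] > 0.01

    def test_equal_accuracies_give_equal_conventional_weights(
        self, grid, basic_params
    ):
        from rnbreed import conventional_collapse_gebv

        system = conventional_collapse_gebv(
            np.full(13, 0.5), basic_params, grid
        )
        kept = np.delete(system.weights, system.pruned)
        assert np.allclose(kept, kept[0])


class TestPopulationState:
    def test_unselected_state_reproduces_classic_formulas(
        self, grid, basic_params
    ):
        n = grid.proportions * 100
        srcs = progeny_sources(grid, n)
        state = PopulationState.unselected(basic_params)
        P_state, _ = source_matrices(srcs, targets=(), state=state)
        np.testing.assert_allclose(
            P_state, progeny_P(grid, basic_params, n)
        )

    def test_selection_erodes_between_family_covariance(
        self, grid, basic_params
    ):
        C = basic_params.bv_covariance
        shrunk = PopulationState(
            params=basic_params, C_sel_m=0.5 * C, C_sel_f=C.copy()
        )
        srcs = progeny_sources(grid, grid.proportions * 100)
        # half-sib groups through a selected sire carry C_sel_m
        hs = [
            s.__class__(**{**s.__dict__, "group": "hs", "relationship": 0.25})
            for s in srcs
        ]
        P_sel, _ = source_matrices(hs, targets=(), state=shrunk)
        P_base, _ = source_matrices(
            hs, targets=(), state=PopulationState.unselected(basic_params)
        )
        assert P_sel[0, 12] == pytest.approx(0.5 * P_base[0, 12])
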