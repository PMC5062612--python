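"""Breeding-scheme engine: intensities, equilibrium, responses."""

import numpy as np
import pytest
from scipy import stats

from rnbreed import (
    RNParams,
    SchemeConfig,
    bulmer_equilibrium,
    predict_response,
    selection_intensity,
)
from rnbreed.scheme_engine import _variance_reduction_factor, build_scheme_index


class TestSelectionIntensity:
    def test_no_selection_gives_zero(self):
        assert selection_intensity(1.0) == 0.0

    def test_infinite_population_truncation_intensity(self):
        z = stats.norm.ppf(0.95)
        assert selection_intensity(0.05) == pytest.approx(
            stats.norm.pdf(z) / 0.05
        )
        assert selection_intensity(0.05) == pytest.approx(2.063, abs=1e-3)

    def test_finite_population_and_correlation_reduce_intensity(self):
        i_inf = selection_intensity(0.05)
        i_fin = selection_intensity(0.05, n_candidates=1000)
        i_cor = selection_intensity(0.05, n_candidates=1000, rho_index=0.1)
        assert i_cor < i_fin < i_inf

    @pytest.mark.parametrize(
        "kwargs",
        [dict(p=1.5), dict(p=0.0), dict(p=0.1, rho_index=1.0)],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            selection_intensity(**kwargs)

    def test_variance_reduction_factor(self):
        # k = i (i - z) for p = 0.05
        assert _variance_reduction_factor(0.05) == pytest.approx(
            0.862, abs=1e-3
        )
        assert _variance_reduction_factor(1.0) == 0.0


class TestBulmerEquilibrium:
    def test_no_selection_keeps_base_parameters(self, grid, basic_params, prop_goal):
        cfg = SchemeConfig(
            scheme="genomic", goal=prop_goal, p_male=1.0, p_female=1.0
        )
        eq, _, _ = bulmer_equilibrium(cfg, basic_params, grid)
        np.testing.assert_allclose(
            eq.bv_covariance, basic_params.bv_covariance, atol=1e-10
        )

    @pytest.mark.parametrize("scheme", ["sib", "progeny", "genomic"])
    def test_selection_reduces_genetic_variance(
        self, grid, basic_params, prop_goal, scheme
    ):
        cfg = SchemeConfig(scheme=scheme, goal=prop_goal)
        eq, _, _ = bulmer_equilibrium(cfg, basic_params, grid)
        assert eq.var_int < basic_params.var_int

    @pytest.mark.parametrize("scheme", ["sib", "progeny", "genomic"])
    def test_convergence_within_twenty_iterations(
        self, grid, basic_params, resil_goal, scheme
    ):
        cfg = SchemeConfig(scheme=scheme, goal=resil_goal)
        res = predict_response(cfg, basic_params, grid)
        assert res.iterations < 20


class TestPredictResponse:
    def test_responses_lie_on_a_line_in_x(self, grid, basic_params, resil_goal):
        for scheme in ("sib", "progeny", "genomic"):
            res = predict_response(
                SchemeConfig(scheme=scheme, goal=resil_goal),
                basic_params,
                grid,
            )
            reconstructed = res.R_int + grid.x_means * res.R_sl
            np.testing.assert_allclose(
                res.response_per_env, reconstructed, atol=1e-6
            )

    def test_flat_profile_for_proportional_goal_without_gxe_correlation(
        self, grid, basic_params, prop_goal
    ):
        """With symmetric economic weights and no intercept-slope
        covariance, sib/progeny/genomic testing all move every
        environment equally (reduced indices without nucleus sources)."""
        for scheme in ("sib", "progeny", "genomic"):
            res = predict_response(
                SchemeConfig(
                    scheme=scheme,
                    goal=prop_goal,
                    nucleus_information=False,
                ),
                basic_params,
                grid,
            )
            assert abs(res.R_sl) / abs(res.R_int) < 1e-6

    def test_genomic_beats_traditional_everywhere(
        self, grid, basic_params, resil_goal
    ):
        results = {
            scheme: predict_response(
                SchemeConfig(scheme=scheme, goal=resil_goal),
                basic_params,
                grid,
            )
            for scheme in ("sib", "progeny", "genomic")
        }
        for trad in ("sib", "progeny"):
            ratio = (
                results["genomic"].response_per_env
                / results[trad].response_per_env
            )
            assert np.all(ratio > 1.0)

    def test_zero_goal_rejected_upstream(self, grid, basic_params):
        import pytest as _pytest

        from rnbreed import BreedingGoal

        with _pytest.raises(ValueError):
            BreedingGoal(values=np.zeros(13))

    def test_progeny_sires_carry_longer_generation_interval(
        self, grid, basic_params, prop_goal
    ):
        cfg = SchemeConfig(scheme="progeny", goal=prop_goal)
        assert cfg.L_male == pytest.approx(1.6)
        assert SchemeConfig(scheme="sib", goal=prop_goal).L_male == 1.0


class TestSchemeIndices:
    def test_genomic_index_identical_for_both_sexes(
        self, grid, basic_params, prop_goal
    ):
        cfg = SchemeConfig(scheme="genomic", goal=prop_goal)
        m = build_scheme_index(cfg, basic_params, grid, "male")
        f = build_scheme_index(cfg, basic_params, grid, "female")
        np.testing.assert_allclose(m.weights, f.weights)
        assert m.r_IH == pytest.approx(f.r_IH)

    def test_female_sib_index_contains_own_performance(
        self, grid, basic_params, prop_goal
    ):
        cfg = SchemeConfig(scheme="sib", goal=prop_goal)
        labels_f = [
            s.label for s in build_scheme_index(
                cfg, basic_params, grid, "female"
            ).sources
        ]
        labels_m = [
            s.label for s in build_scheme_index(
                cfg, basic_params, grid, "male"
            ).sources
        ]
        assert "own_performance" in labels_f
        assert "own_performance" not in labels_m

    def test_male_progeny_index_replaces_halfsib_means(
        self, grid, basic_params, prop_goal
    ):
        cfg = SchemeConfig(scheme="progeny", goal=prop_goal)
        labels = [
            s.label for s in build_scheme_index(
                cfg, basic_params, grid, "male"
            ).sources
        ]
        assert any(lab.startswith("progeny_mean") for lab in labels)
        assert not any(lab.startswith("halfsib_mean") for lab in labels)

    def test_accuracy_profile_symmetric_without_covariance(
        self, grid, basic_params, prop_goal
    ):
        from rnbreed import env_accuracy

        cfg = SchemeConfig(
            scheme="genomic", goal=prop_goal, nucleus_information=False
        )
        system = build_scheme_index(cfg, basic_params, grid, "male")
        acc = np.array(
            [env_accuracy(system, basic_params, grid, i) for i in range(13)]
        )
        np.testing.assert_allclose(acc, acc[::-1], atol=1e-9)

    def test_invalid_scheme_config(self, prop_goal):
        with pytest.raises(ValueError):
            SchemeConfig(scheme="clonal", goal=prop_goal)
        with pytest.raises(ValueError):
            SchemeConfig(scheme="sib", goal=prop_goal, p_male=0.0)
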