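"""Unit and property tests for the causal-judgment models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import betaln

from causalq.causal_models import (
    ContingencyTable,
    Grid,
    MarginError,
    NotApplicableError,
    PriorSpec,
    causal_attribution,
    causal_power,
    contingency_stats,
    data_likelihood,
    default_registry,
    enumerate_variants,
    marginal_likelihood,
    mle_params,
    posterior_strength,
    predict_one,
    query_probability,
    ss_prior_density,
    structure_induction_predict,
    structure_posterior,
)
from causalq.synthetic import build_contingency

tables = st.builds(
    ContingencyTable,
    st.integers(1, 15),
    st.integers(1, 15),
    st.integers(1, 15),
    st.integers(1, 15),
)


class TestContingencyStats:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((8, 8, 4, 12), (0.5, 0.25, 0.25)),  # C1 generative, text-authoritative
            ((4, 4, 4, 4), (0.5, 0.5, 0.0)),
            ((12, 4, 4, 12), (0.75, 0.25, 0.5)),  # C3 generative
        ],
    )
    def test_conditional_probabilities(self, counts, expected):
        s = contingency_stats(ContingencyTable(*counts))
        assert (s["p_e_given_c"], s["p_e_given_notc"], s["delta_p"]) == pytest.approx(expected)

    def test_empty_margin_identified(self):
        with pytest.raises(MarginError, match="cause-present"):
            contingency_stats(ContingencyTable(0, 0, 4, 4))
        with pytest.raises(MarginError, match="cause-absent"):
            contingency_stats(ContingencyTable(4, 4, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 4, 4, 4)


class TestCausalPower:
    def test_c3_generative(self, c3_generative):
        assert causal_power(c3_generative) == pytest.approx(0.5 / 0.75)

    def test_null_contingency_is_zero(self):
        assert causal_power(ContingencyTable(4, 12, 4, 12)) == 0.0

    def test_preventive(self):
        # P(e|c)=0.25, P(e|not c)=0.75 -> -(-0.5)/0.75
        t = ContingencyTable(4, 12, 12, 4)
        assert causal_power(t, "preventive") == pytest.approx(2 / 3)

    def test_boundary_base_rates_raise(self):
        with pytest.raises(ValueError):
            causal_power(ContingencyTable(4, 4, 8, 0), "generative")
        with pytest.raises(ValueError):
            causal_power(ContingencyTable(4, 4, 0, 8), "preventive")

    @given(n_e1c0=st.integers(0, 15))
    @settings(deadline=None, derandomize=True)
    def test_generative_power_antitone_in_base_rate(self, n_e1c0):
        """At fixed P(e|c), raising P(e|not c) cannot raise generative power."""
        lo = ContingencyTable(12, 4, n_e1c0, 16 - n_e1c0)
        hi = ContingencyTable(12, 4, n_e1c0 + 1, 15 - n_e1c0)
        if contingency_stats(hi)["p_e_given_notc"] >= 1.0:
            return
        assert causal_power(hi) <= causal_power(lo) + 1e-12


class TestDataLikelihood:
    def test_g1_with_zero_strength_equals_g0(self, c3_generative):
        l1 = data_likelihood(c3_generative, 0.3, 0.0, "generative", "G1")
        l0 = data_likelihood(c3_generative, 0.3, 0.9, "generative", "G0")
        assert l1 == pytest.approx(l0)

    def test_noisy_or_cell_probability(self):
        # w0=0.25, w1=2/3 -> P(e|c) = 0.25 + 2/3 - 0.25*2/3 = 0.75
        t = ContingencyTable(1, 0, 0, 1)
        lik = data_likelihood(t, 0.25, 2 / 3, "generative", "G1")
        assert lik == pytest.approx(0.75 * 0.75)

    def test_grid_maximizer_matches_closed_form_mle(self, c3_generative):
        """Brute-force grid search over the likelihood lands on (P(e|not c), power)."""
        w = np.arange(0.0, 1.0 + 5e-3, 5e-3)
        w0, w1 = np.meshgrid(w, w, indexing="ij")
        ll = data_likelihood(c3_generative, w0, w1, "generative", "G1", log=True)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        w0_hat, w1_hat = mle_params(c3_generative)
        assert w[i] == pytest.approx(w0_hat, abs=5e-3)
        assert w[j] == pytest.approx(w1_hat, abs=5e-3)

    @pytest.mark.parametrize("condition", ["C1", "C2", "C3"])
    @pytest.mark.parametrize("valence", ["generative", "preventive"])
    def test_grid_mle_for_every_stimulus(self, condition, valence):
        t = build_contingency(condition, valence)
        w = np.arange(0.0, 1.0 + 5e-3, 5e-3)
        w0, w1 = np.meshgrid(w, w, indexing="ij")
        ll = data_likelihood(t, w0, w1, valence, "G1", log=True)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        w0_hat, w1_hat = mle_params(t, valence)
        assert w[i] == pytest.approx(w0_hat, abs=5e-3)
        assert w[j] == pytest.approx(w1_hat, abs=5e-3)


class TestSSPrior:
    def test_alpha_zero_is_flat(self, grid):
        dens = ss_prior_density(grid, "generative", 0.0)
        assert np.allclose(dens, 1.0)

    def test_density_ratio_at_corners(self):
        g = Grid(0.01)
        dens = ss_prior_density(g, "generative", 5.0)
        # (w0, w1) = (0, 1) vs (1, 0): exp(0) / exp(-10)
        assert dens[0, -1] / dens[-1, 0] == pytest.approx(math.exp(10.0))

    def test_normalized_on_grid(self, grid, fine_grid):
        for g in (grid, fine_grid):
            dens = ss_prior_density(g, "preventive", 5.0)
            total = np.trapezoid(np.trapezoid(dens, g.nodes, axis=1), g.nodes)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_negative_alpha_rejected(self, grid):
        with pytest.raises(ValueError):
            ss_prior_density(grid, "generative", -1.0)


class TestMarginalLikelihood:
    def test_g0_uniform_matches_beta_function(self, grid, uniform_prior):
        """G0 with a flat prior integrates to the Beta function of the pooled counts."""
        t = ContingencyTable(8, 8, 4, 12)  # pooled: 12 successes of 32
        m = marginal_likelihood(t, "G0", uniform_prior, grid)
        assert m == pytest.approx(math.exp(betaln(13, 21)), rel=1e-4)

    def test_g1_stable_under_grid_refinement(self, c3_generative, uniform_prior):
        m_coarse = marginal_likelihood(c3_generative, "G1", uniform_prior, Grid(0.01))
        m_fine = marginal_likelihood(c3_generative, "G1", uniform_prior, Grid(0.0025))
        assert abs(m_coarse - m_fine) / m_fine < 1e-3

    def test_ss_alpha_zero_equals_uniform(self, c3_generative, grid, uniform_prior):
        m_ss = marginal_likelihood(c3_generative, "G1", PriorSpec("SS", 0.0), grid)
        m_u = marginal_likelihood(c3_generative, "G1", uniform_prior, grid)
        assert abs(m_ss - m_u) < 1e-10


class TestStructurePosterior:
    def test_probabilities_sum_to_one(self, all_tables, grid, ss_prior):
        for (cond, val), t in all_tables.items():
            sp = structure_posterior(t, ss_prior, grid, val)
            assert sp["p_g1"] + sp["p_g0"] == pytest.approx(1.0, abs=1e-12)

    def test_strong_contingency_favors_link(self, c3_generative, grid, uniform_prior):
        assert structure_posterior(c3_generative, uniform_prior, grid)["p_g1"] > 0.5

    def test_null_contingency_favors_null_graph(self, grid, uniform_prior):
        t = ContingencyTable(8, 8, 8, 8)
        assert structure_posterior(t, uniform_prior, grid)["p_g1"] < 0.5

    def test_degenerate_structure_prior(self, c3_generative, grid):
        sp = structure_posterior(c3_generative, PriorSpec("uniform", structure_prior_g1=1.0), grid)
        assert sp["p_g1"] == 1.0


class TestPosteriorStrength:
    def test_no_data_returns_prior_mean(self, grid, uniform_prior):
        t = ContingencyTable(0, 0, 0, 0)
        assert posterior_strength(t, uniform_prior, grid) == pytest.approx(0.5, abs=1e-6)

    def test_near_mle_and_refinement_stable(self, c3_generative, grid, fine_grid, uniform_prior):
        est = posterior_strength(c3_generative, uniform_prior, grid)
        assert abs(est - causal_power(c3_generative)) < 0.15
        est_fine = posterior_strength(c3_generative, uniform_prior, fine_grid)
        assert abs(est - est_fine) < 1e-3

    def test_ss_prior_pulls_strength_up(self, c3_generative, grid, uniform_prior, ss_prior):
        assert posterior_strength(c3_generative, ss_prior, grid) > posterior_strength(
            c3_generative, uniform_prior, grid
        )

    @pytest.mark.parametrize("alpha_pair", [(0.0, 1.0), (1.0, 3.0), (3.0, 5.0)])
    def test_monotone_in_alpha(self, c3_generative, grid, alpha_pair):
        lo, hi = alpha_pair
        assert posterior_strength(c3_generative, PriorSpec("SS", hi), grid) >= posterior_strength(
            c3_generative, PriorSpec("SS", lo), grid
        )


class TestQueryProbability:
    def test_diagnostic_bayes_rule(self):
        # P(e|c)=0.75, P(e|not c)=0.25, P(c)=0.5 -> 0.75/(0.75+0.25)
        assert query_probability(0.25, 2 / 3, "G1", "diagnostic") == pytest.approx(0.75)

    def test_null_graph_diagnostic_is_base_rate(self):
        assert query_probability(0.7, 0.0, "G0", "diagnostic", base_rate_c=0.3) == 0.3

    def test_deterministic_cause_predictive(self):
        assert query_probability(0.0, 1.0, "G1", "predictive") == 1.0

    def test_zero_effect_probability_raises(self):
        with pytest.raises(ZeroDivisionError):
            query_probability(0.0, 0.0, "G1", "diagnostic")


class TestStructureInduction:
    def test_convex_combination_of_graph_values(self, all_tables, grid, uniform_prior):
        """Prediction lies between the G0- and G1-conditional query values."""
        for (cond, val), t in all_tables.items():
            if val != "generative":
                continue
            for direction in ("diagnostic", "predictive"):
                pred = structure_induction_predict(t, direction, uniform_prior, grid)
                assert 0.0 <= pred <= 1.0

    def test_structure_prior_interpolates_between_graph_values(self, c3_generative, grid):
        """As the prior weight on the causal link goes 0 -> 1, the diagnostic
        prediction moves monotonically from the base-rate anchor (G0) to the
        G1-conditional value."""
        preds = [
            structure_induction_predict(
                c3_generative, "diagnostic",
                PriorSpec("uniform", structure_prior_g1=g), grid,
            )
            for g in (1e-9, 0.5, 1.0 - 1e-9)
        ]
        assert preds[0] == pytest.approx(0.5, abs=1e-6)  # G0: independence anchor
        assert preds[0] < preds[1] < preds[2]
        # degenerate-weight limit: certain link -> pure G1 posterior-mean query
        certain = structure_induction_predict(
            c3_generative, "diagnostic", PriorSpec("uniform", structure_prior_g1=1.0), grid
        )
        assert certain == pytest.approx(preds[2], abs=1e-6)

    def test_refinement_stable(self, c3_generative, grid, fine_grid, uniform_prior):
        for direction in ("diagnostic", "predictive"):
            a = structure_induction_predict(c3_generative, direction, uniform_prior, grid)
            b = structure_induction_predict(c3_generative, direction, uniform_prior, fine_grid)
            assert abs(a - b) < 1e-3

    def test_preventive_not_applicable(self, grid, uniform_prior):
        t = build_contingency("C3", "preventive")
        with pytest.raises(NotApplicableError):
            structure_induction_predict(t, "diagnostic", uniform_prior, grid, valence="preventive")


class TestCausalAttribution:
    def test_c3_mle_closed_form(self, c3_generative):
        assert causal_attribution(c3_generative) == pytest.approx(8 / 9)

    def test_no_background_cause_gives_certainty(self):
        # P(e|not c) = 0 with effect present under the cause -> attribution 1
        t = ContingencyTable(12, 4, 0, 16)
        assert causal_attribution(t) == pytest.approx(1.0)

    def test_bayes_refinement_stable(self, c3_generative, grid, fine_grid):
        a = causal_attribution(c3_generative, "bayes_uniform", grid)
        b = causal_attribution(c3_generative, "bayes_uniform", fine_grid)
        assert abs(a - b) < 1e-3

    def test_preventive_not_applicable(self):
        t = build_contingency("C3", "preventive")
        with pytest.raises(NotApplicableError):
            causal_attribution(t, valence="preventive")


class TestVariantRegistry:
    def test_default_registry_has_sixteen_variants(self):
        assert len(default_registry()) == 16

    def test_predictions_in_unit_interval(self, all_tables):
        preds = enumerate_variants(all_tables, grid=Grid(0.02))
        assert preds["prediction"].between(0.0, 1.0).all()

    def test_generative_only_families_skip_preventive(self, all_tables):
        preds = enumerate_variants(all_tables, grid=Grid(0.02))
        gen_only = preds[preds["family"].isin(
            ["attribution", "structure_induction_diagnostic", "structure_induction_predictive"]
        )]
        assert (gen_only["valence"] == "generative").all()
        # 7 both-valence variants x 6 cells + 9 generative-only x 3 cells
        assert len(preds) == 7 * 6 + 9 * 3

    def test_power_mle_variant_composes_causal_power(self, all_tables):
        from causalq.causal_models import ModelVariant

        preds = enumerate_variants(all_tables, [ModelVariant("power", "MLE")])
        assert preds["variant"].nunique() == 1
        for row in preds.itertuples():
            t = all_tables[(row.condition, row.valence)]
            assert row.prediction == pytest.approx(causal_power(t, row.valence))

    def test_unknown_family_rejected(self, c3_generative):
        from causalq.causal_models import ModelVariant

        with pytest.raises(ValueError):
            predict_one(ModelVariant("magic", "MLE"), c3_generative, "generative")

    def test_deterministic_row_order(self, all_tables):
        a = enumerate_variants(all_tables, grid=Grid(0.02))
        b = enumerate_variants(all_tables, grid=Grid(0.02))
        assert a.equals(b)
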