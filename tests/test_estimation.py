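"""EM estimation: oracle equivalence, monotonicity, scoring, reliability."""

import numpy as np
import pytest
from scipy import integrate, stats

from mixgpcm.model import (
    EstimationOptions,
    MixedGPCM,
    posterior_class_probabilities,
)
from mixgpcm.parameters import (
    ClassParams,
    ModelParameters,
    QuadratureGrid,
    RatingScale,
    ResponseMatrix,
)
from mixgpcm.simulate import SyntheticDesign, simulate_responses

from test_kernel import pcm_reference


def pattern_probability_quad(params, pattern):
    """Independent oracle: P(pattern) = sum_g pi_g Int prod_i P(x_i|theta,g) phi."""
    total = 0.0
    for g, cp in enumerate(params.classes):
        def integrand(theta):
            val = stats.norm.pdf(theta, scale=cp.trait_sd)
            for i, x in enumerate(pattern):
                val *= pcm_reference(theta, cp.thresholds[i], params.discriminations[i])[x]
            return val
        val, _ = integrate.quad(integrand, -10 * cp.trait_sd, 10 * cp.trait_sd,
                                epsabs=1e-13, epsrel=1e-12)
        total += params.weights[g] * val
    return total


def class_pattern_probability_quad(params, pattern, g):
    cp = params.classes[g]
    def integrand(theta):
        val = stats.norm.pdf(theta, scale=cp.trait_sd)
        for i, x in enumerate(pattern):
            val *= pcm_reference(theta, cp.thresholds[i], params.discriminations[i])[x]
        return val
    val, _ = integrate.quad(integrand, -10 * cp.trait_sd, 10 * cp.trait_sd,
                            epsabs=1e-13, epsrel=1e-12)
    return val


ALL_PATTERNS = [(0, 0), (0, 1), (1, 0), (1, 1)]


class TestLikelihoodOracles:
    def test_marginal_likelihood_matches_enumeration(self, toy_two_class):
        data = ResponseMatrix(np.array(ALL_PATTERNS * 3), toy_two_class.scale)
        model = MixedGPCM(data, n_classes=2)
        ll = model.loglike(toy_two_class, QuadratureGrid.gauss_hermite(49))
        oracle = 3 * sum(
            np.log(pattern_probability_quad(toy_two_class, p)) for p in ALL_PATTERNS
        )
        np.testing.assert_allclose(ll, oracle, atol=1e-8)

    def test_pattern_probabilities_sum_to_one(self, toy_two_class):
        total = sum(pattern_probability_quad(toy_two_class, p) for p in ALL_PATTERNS)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_label_switching_invariance(self, toy_two_class):
        data = ResponseMatrix(np.array(ALL_PATTERNS * 5), toy_two_class.scale)
        model = MixedGPCM(data, n_classes=2)
        grid = QuadratureGrid.gauss_hermite(31)
        ll = model.loglike(toy_two_class, grid)
        ll_perm = model.loglike(toy_two_class.relabel([1, 0]), grid)
        np.testing.assert_allclose(ll, ll_perm, atol=1e-10)


class TestPosteriors:
    def test_single_class_posterior_is_one(self):
        data = ResponseMatrix(np.array([[0, 1], [1, 1]]), RatingScale(2))
        params = ModelParameters(
            RatingScale(2),
            [ClassParams(np.array([[0.0], [0.3]]), 1.0)],
            np.array([1.0]),
            np.array([1.0, 1.0]),
        )
        post = posterior_class_probabilities(params, data)
        np.testing.assert_allclose(post, 1.0, atol=1e-14)

    def test_identical_classes_split_evenly(self):
        cp = ClassParams(np.array([[0.2], [-0.4]]), 1.0)
        params = ModelParameters(
            RatingScale(2),
            [cp, ClassParams(cp.thresholds.copy(), 1.0)],
            np.array([0.5, 0.5]),
            np.array([1.0, 1.0]),
        )
        data = ResponseMatrix(np.array(ALL_PATTERNS), RatingScale(2))
        post = posterior_class_probabilities(params, data)
        np.testing.assert_allclose(post, 0.5, atol=1e-12)

    def test_bayes_posterior_matches_enumeration(self, toy_two_class):
        data = ResponseMatrix(np.array(ALL_PATTERNS), toy_two_class.scale)
        post = posterior_class_probabilities(params=toy_two_class, data=data)
        for k, pattern in enumerate(ALL_PATTERNS):
            joint = np.array(
                [
                    toy_two_class.weights[g]
                    * class_pattern_probability_quad(toy_two_class, pattern, g)
                    for g in range(2)
                ]
            )
            np.testing.assert_allclose(post[k], joint / joint.sum(), atol=1e-8)

    def test_all_missing_row_gets_prior(self, toy_two_class):
        data = ResponseMatrix(np.array([[0, 1], [-1, -1]]), toy_two_class.scale)
        with pytest.warns(UserWarning):
            post = posterior_class_probabilities(toy_two_class, data)
        np.testing.assert_allclose(post[1], toy_two_class.weights, atol=1e-12)


class TestEMBehaviour:
    def test_loglikelihood_monotone_over_iterations(self, rng):
        d = SyntheticDesign(n_persons=300, n_categories=3, n_items=4, seed=10)
        sim = simulate_responses(d)
        model = MixedGPCM(sim.responses, n_classes=2)
        grid = QuadratureGrid.gauss_hermite(15)
        params = model._initial_params(np.random.default_rng(0))
        prev = -np.inf
        from mixgpcm.model import replace_weights

        for _ in range(12):
            ll, R = model._estep(params, grid)
            assert ll >= prev - 1e-8
            prev = ll
            pi = np.einsum("p,pgq->g", model._pat.counts, R)
            pi = pi / pi.sum()
            W = model._expected_counts(R)
            params = model._mstep(params, W, grid, maxiter=10)
            params = replace_weights(params, pi)

    def test_refit_from_estimate_is_stationary(self):
        d = SyntheticDesign(n_persons=400, n_categories=3, n_items=4,
                            class_templates=("ORS",), seed=11)
        sim = simulate_responses(d)
        opts = EstimationOptions(n_starts=1, burnin_iterations=10, n_quadrature_nodes=15,
                                 max_em_iterations=500, rel_tolerance=1e-11, seed=2)
        model = MixedGPCM(sim.responses, 1)
        res = model.fit(opts)
        res2 = model.fit(opts, start_params=res.params)
        assert abs(res2.log_likelihood - res.log_likelihood) < 1e-6

    def test_single_category_item_rejected(self):
        data = ResponseMatrix(np.array([[0, 1], [0, 0], [0, 1]]), RatingScale(2))
        with pytest.raises(ValueError, match="item1"):
            MixedGPCM(data, n_classes=1)

    def test_single_class_parameter_recovery(self):
        d = SyntheticDesign(n_persons=5000, n_categories=4,
                            class_templates=("ORS",), seed=3)
        sim = simulate_responses(d)
        true = d.to_model_parameters()
        opts = EstimationOptions(n_starts=2, burnin_iterations=20, n_quadrature_nodes=21,
                                 max_em_iterations=400, seed=1)
        res = MixedGPCM(sim.responses, 1).fit(opts)
        rmse = np.sqrt(np.mean((res.params.threshold_array - true.threshold_array) ** 2))
        assert res.converged
        assert rmse <= 0.1

    def test_classes_ordered_by_decreasing_weight(self):
        d = SyntheticDesign(n_persons=800, n_categories=3, n_items=4, seed=21)
        sim = simulate_responses(d)
        opts = EstimationOptions(n_starts=2, burnin_iterations=15, n_quadrature_nodes=15,
                                 max_em_iterations=120, seed=5)
        res = MixedGPCM(sim.responses, 2).fit(opts)
        assert res.params.weights[0] >= res.params.weights[1]
        np.testing.assert_allclose(res.posterior.sum(axis=1), 1.0, atol=1e-10)


class TestAssignmentSummary:
    def test_mean_assignment_probability_bounds(self):
        d = SyntheticDesign(n_persons=900, n_categories=4, seed=33)
        sim = simulate_responses(d)
        opts = EstimationOptions(n_starts=2, burnin_iterations=20, n_quadrature_nodes=15,
                                 max_em_iterations=150, seed=3)
        res = MixedGPCM(sim.responses, 3).fit(opts)
        summary = res.assignment_summary()
        probs = summary["mean_assignment_probability"].dropna()
        assert ((probs >= 1.0 / 3.0 - 1e-9) & (probs <= 1.0 + 1e-9)).all()
        np.testing.assert_allclose(summary["modal_share"].sum(), 1.0, atol=1e-12)


class TestEAPScores:
    def _fit_symmetric_binary(self):
        # two identical symmetric binary items: category reversal maps the
        # model to itself, so balanced patterns must score exactly zero
        params = ModelParameters(
            RatingScale(2),
            [ClassParams(np.zeros((2, 1)), 1.0)],
            np.array([1.0]),
            np.array([1.0, 1.0]),
        )
        data = ResponseMatrix(
            np.array([[0, 1], [1, 0], [0, 0], [1, 1]]), RatingScale(2)
        )
        model = MixedGPCM(data, n_classes=1)
        res = model.fit(
            EstimationOptions(n_starts=1, max_em_iterations=1, n_quadrature_nodes=31, seed=0),
            start_params=params,
        )
        # overwrite with the symmetric parameters (fit() may have moved them)
        res.params = params
        return res

    def test_self_reversal_pattern_scores_zero(self):
        res = self._fit_symmetric_binary()
        scores = res.eap_scores()
        # patterns with equal numbers of 0s and 1s are reversal-invariant
        np.testing.assert_allclose(scores["eap"].iloc[:2], 0.0, atol=1e-10)

    def test_matches_direct_integration(self):
        params = ModelParameters(
            RatingScale(2),
            [ClassParams(np.array([[0.4]]), 1.3)],
            np.array([1.0]),
            np.array([1.0]),
        )
        data = ResponseMatrix(np.array([[1], [0]]), RatingScale(2))
        model = MixedGPCM(data, n_classes=1)
        res = model.fit(
            EstimationOptions(n_starts=1, max_em_iterations=1, n_quadrature_nodes=49, seed=0),
            start_params=params,
        )
        res.params = params
        eap = res.eap_scores()["eap"].iloc[0]

        def joint(theta):
            return stats.norm.pdf(theta, scale=1.3) * pcm_reference(theta, [0.4])[1]

        num, _ = integrate.quad(lambda t: t * joint(t), -13, 13, epsabs=1e-13)
        den, _ = integrate.quad(joint, -13, 13, epsabs=1e-13)
        np.testing.assert_allclose(eap, num / den, atol=1e-7)

    def test_monotone_in_raw_score_within_class(self):
        # with equal discriminations the raw sum score is sufficient for theta,
        # so the EAP must be a strictly increasing function of it
        params = ModelParameters(
            RatingScale(3),
            [ClassParams(np.array([[-0.5, 0.6], [0.0, 0.8], [-1.0, 0.3]]), 1.0)],
            np.array([1.0]),
            np.array([1.0, 1.0, 1.0]),
        )
        patterns = np.array(
            [[x1, x2, x3] for x1 in range(3) for x2 in range(3) for x3 in range(3)]
        )
        data = ResponseMatrix(patterns, RatingScale(3))
        model = MixedGPCM(data, n_classes=1)
        res = model.fit(
            EstimationOptions(n_starts=1, max_em_iterations=1, n_quadrature_nodes=31, seed=0),
            start_params=params,
        )
        res.params = params
        eap = res.eap_scores()["eap"].to_numpy()
        raw = patterns.sum(axis=1)
        for r in range(raw.max() + 1):
            group = eap[raw == r]
            np.testing.assert_allclose(group, group[0], atol=1e-9)  # sufficiency
        means = np.array([eap[raw == r].mean() for r in range(raw.max() + 1)])
        assert np.all(np.diff(means) > 0)


class TestReliability:
    def test_vanishing_trait_signal_gives_near_zero(self):
        d = SyntheticDesign(
            n_persons=600,
            n_categories=3,
            n_items=4,
            class_templates=(ClassParams(np.tile([-0.5, 0.5], (4, 1)), 0.05),),
            threshold_shift=0.0,
            seed=8,
        )
        sim = simulate_responses(d)
        model = MixedGPCM(sim.responses, 1)
        res = model.fit(
            EstimationOptions(n_starts=1, max_em_iterations=1, n_quadrature_nodes=31, seed=0),
            start_params=d.to_model_parameters(),
        )
        res.params = d.to_model_parameters()
        assert res.model_based_reliability() < 0.05

    def test_bounded_between_zero_and_one(self):
        d = SyntheticDesign(n_persons=700, n_categories=4, seed=9)
        sim = simulate_responses(d)
        opts = EstimationOptions(n_starts=1, burnin_iterations=10, n_quadrature_nodes=15,
                                 max_em_iterations=80, seed=4)
        res = MixedGPCM(sim.responses, 2).fit(opts)
        rel = res.model_based_reliability()
        assert 0.0 < rel < 1.0

    def test_close_to_squared_correlation_with_truth(self):
        d = SyntheticDesign(n_persons=8000, n_categories=4,
                            class_templates=("ORS",), seed=14)
        sim = simulate_responses(d)
        opts = EstimationOptions(n_starts=1, burnin_iterations=15, n_quadrature_nodes=21,
                                 max_em_iterations=200, seed=6)
        res = MixedGPCM(sim.responses, 1).fit(opts)
        rel = res.model_based_reliability()
        eap = res.eap_scores()["eap"].to_numpy()
        r2 = np.corrcoef(eap, sim.true_theta)[0, 1] ** 2
        assert abs(rel - r2) < 0.05
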