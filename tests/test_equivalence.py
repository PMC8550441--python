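"""Model fits, the permutation variance test, IEQ/J-tests, the combined
decision, and the discrete-toy accuracy computation."""

import numpy as np
import pytest

from equiset import (
    Dataset,
    SearchConfig,
    Solution,
    TestCounter,
    bayes_expected_accuracy,
    equivalence_decision,
    generate,
    ieq_test,
    jtest,
    permutation_variance_test,
    toy_discrete,
    vuong_variance_statistic,
)
from equiset.equivalence import LoglikVector, fit_model, loglik_vector
from equiset.synth import SyntheticSpec


def _near_copy_dataset(seed, n=1000, eps=1e-3):
    """T linear in a latent with two near-copies (features 0 and 1) plus an
    independent noise feature (2)."""
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    X = np.column_stack(
        [
            latent + eps * rng.standard_normal(n),
            latent + eps * rng.standard_normal(n),
            rng.standard_normal(n),
        ]
    )
    y = latent + rng.standard_normal(n)
    return Dataset(X=X, feature_names=("x", "x_copy", "noise"), y=y,
                   outcome_type="continuous")


class TestFitAndLoglik:
    def test_empty_feature_set_closed_form(self, small_continuous):
        model = fit_model(small_continuous, ())
        assert model.coefficients[0] == pytest.approx(np.mean(small_continuous.y))
        assert model.sigma2 == pytest.approx(np.var(small_continuous.y))

    def test_exact_recovery_of_noiseless_line(self):
        x = np.linspace(-2, 2, 50)
        ds = Dataset(X=x[:, None], feature_names=("x",), y=2 * x + 1,
                     outcome_type="continuous")
        model = fit_model(ds, (0,))
        np.testing.assert_allclose(model.coefficients, [1.0, 2.0], atol=1e-8)

    def test_logistic_loglik_matches_statsmodels(self, small_binary):
        sm = pytest.importorskip("statsmodels.api")
        model = fit_model(small_binary, (0, 2))
        ll = loglik_vector(model, small_binary).total
        D = np.column_stack([np.ones(small_binary.n_samples), small_binary.X[:, [0, 2]]])
        oracle = sm.GLM(small_binary.y, D, family=sm.families.Binomial()).fit().llf
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_loglik_vector_sums_to_total(self, small_continuous):
        model = fit_model(small_continuous, (0, 1))
        vec = loglik_vector(model, small_continuous)
        # Gaussian MLE identity: total log-likelihood at the fit equals
        # -n/2 (log(2 pi sigma2) + 1)
        n = small_continuous.n_samples
        assert vec.total == pytest.approx(
            -0.5 * n * (np.log(2 * np.pi * model.sigma2) + 1), rel=1e-10
        )

    def test_half_probability_gives_log_half(self):
        rng = np.random.default_rng(0)
        y = (rng.random(100) < 0.5).astype(float)
        y[:2] = [0, 1]
        ds = Dataset(X=rng.standard_normal((100, 1)), feature_names=("a",), y=y,
                     outcome_type="binary")
        from equiset.equivalence import FittedModel

        model = FittedModel(family="logistic", feature_set=(), coefficients=np.zeros(1))
        vec = loglik_vector(model, ds)
        np.testing.assert_allclose(vec.values, np.log(0.5))

    def test_gaussian_density_oracle(self, small_continuous):
        model = fit_model(small_continuous, (0,))
        vec = loglik_vector(model, small_continuous)
        pred = model.predict(small_continuous)
        manual = -0.5 * np.log(2 * np.pi * model.sigma2) - (
            small_continuous.y - pred
        ) ** 2 / (2 * model.sigma2)
        np.testing.assert_allclose(vec.values, manual, atol=1e-12)


class TestVarianceStatistic:
    def test_identical_models_give_zero(self):
        v = LoglikVector(np.arange(10.0))
        assert vuong_variance_statistic(v, v) == 0.0

    def test_hand_computed_example(self):
        assert vuong_variance_statistic(
            LoglikVector(np.array([1.0, 0.0])), LoglikVector(np.array([0.0, 1.0]))
        ) == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self, rng):
        a = LoglikVector(rng.standard_normal(200))
        b = LoglikVector(rng.standard_normal(200))
        d = a.values - b.values
        oracle = float(np.sum((d - d.mean()) ** 2) / len(d))
        assert vuong_variance_statistic(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vuong_variance_statistic(
                LoglikVector(np.zeros(3)), LoglikVector(np.zeros(4))
            )


class TestPermutationTest:
    def test_degenerate_null_gives_pvalue_one(self):
        v = LoglikVector(np.linspace(0, 1, 50))
        res = permutation_variance_test(v, v, B=200, seed=0)
        assert res.observed == 0.0
        assert np.all(res.permuted == 0.0)
        assert res.pvalue == 1.0

    def test_pvalue_always_positive(self, rng):
        a = LoglikVector(rng.standard_normal(100))
        b = LoglikVector(rng.standard_normal(100) + 5.0)
        res = permutation_variance_test(a, b, B=300, seed=1)
        assert 0.0 < res.pvalue <= 1.0
        assert res.pvalue >= 1.0 / 301

    def test_mean_shift_is_rejected(self, rng):
        """A systematic per-sample difference makes sign swaps inflate the
        variance, so the observed statistic falls in the left tail."""
        d = 0.5 + 0.05 * rng.standard_normal(400)
        a = LoglikVector(d)
        b = LoglikVector(np.zeros(400))
        res = permutation_variance_test(a, b, B=500, seed=2)
        assert res.pvalue < 0.01
        assert np.mean(res.permuted > res.observed) > 0.95

    def test_true_predictor_vs_noise_power(self):
        rejections = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            y = x + rng.standard_normal(n)
            ds = Dataset(X=np.column_stack([x, noise]), feature_names=("x", "z"),
                         y=y, outcome_type="continuous")
            ll_x = loglik_vector(fit_model(ds, (0,)), ds)
            ll_z = loglik_vector(fit_model(ds, (1,)), ds)
            res = permutation_variance_test(ll_x, ll_z, B=300, seed=seed)
            rejections += res.pvalue < 0.05
        assert rejections >= 38


class TestIEQAndJTest:
    def test_identical_sets_trivially_equivalent(self, small_continuous):
        res_xy, res_yx, ok = ieq_test(small_continuous, {0, 1}, {0, 1}, 0.05, TestCounter())
        assert (res_xy.pvalue, res_yx.pvalue, ok) == (1.0, 1.0, True)

    def test_symmetry_up_to_swapping_results(self, small_continuous):
        a = ieq_test(small_continuous, {0}, {1}, 0.05, TestCounter())
        b = ieq_test(small_continuous, {1}, {0}, 0.05, TestCounter())
        assert a[0].pvalue == pytest.approx(b[1].pvalue)
        assert a[1].pvalue == pytest.approx(b[0].pvalue)
        assert a[2] == b[2]

    def test_near_copy_sets_found_equivalent(self):
        # two directional tests at level 0.05 each: ~90% joint acceptance
        hits = 0
        for seed in range(50):
            ds = _near_copy_dataset(seed)
            _, _, ok = ieq_test(ds, {0}, {1}, 0.05, TestCounter())
            hits += ok
        assert hits >= 42

    def test_complementary_signals_not_equivalent(self):
        """Continuous two-signal construction: {X} and {Y} each predict half
        of T, so each adds information given the other (not IEQ even though
        performance-equivalent by symmetry)."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1000
            x, y_feat = rng.standard_normal((2, n))
            t = x + y_feat + 0.5 * rng.standard_normal(n)
            ds = Dataset(X=np.column_stack([x, y_feat]), feature_names=("x", "y"),
                         y=t, outcome_type="continuous")
            _, _, ok = ieq_test(ds, {0}, {1}, 0.05, TestCounter())
            hits += not ok
        assert hits >= 18

    def test_jtest_identity_and_planted_cases(self):
        ds = _near_copy_dataset(0)
        assert jtest(ds, {0}, {0}, 0.05)[2]
        equivalent = sum(jtest(_near_copy_dataset(s), {0}, {1}, 0.05)[2] for s in range(50))
        assert equivalent >= 42
        distinguished = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            n = 1000
            x = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            t = x + 0.7 * rng.standard_normal(n)
            ds = Dataset(X=np.column_stack([x, noise]), feature_names=("x", "z"),
                         y=t, outcome_type="continuous")
            distinguished += not jtest(ds, {0}, {1}, 0.05)[2]
        assert distinguished >= 18


class TestEquivalenceDecision:
    def test_candidate_equal_to_reference(self, small_continuous):
        verdict = equivalence_decision(
            small_continuous, Solution({0, 1}), Solution({0, 1}),
            SearchConfig(n_permutations=200), TestCounter(),
        )
        assert verdict.equivalent

    def test_near_copy_swap_accepted(self):
        hits = 0
        for seed in range(10):
            ds, truth = generate(
                SyntheticSpec(n_samples=2000, n_indispensable=2, class_sizes=(2,), seed=seed)
            )
            members = sorted(truth.classes[0])
            base = truth.indispensable | {members[0]}
            swap = truth.indispensable | {members[1]}
            verdict = equivalence_decision(
                ds, Solution(swap), Solution(base), SearchConfig(seed=seed), TestCounter()
            )
            hits += verdict.equivalent
        assert hits >= 8

    def test_superset_of_reference_passes_by_design(self):
        """A reference plus an extra noise feature contains the reference's
        information, so both IEQ directions pass; minimality is enforced by
        the backward phase, not by the equivalence decision."""
        ds, truth = generate(
            SyntheticSpec(n_samples=2000, n_indispensable=2, class_sizes=(), seed=5)
        )
        noise = sorted(truth.irrelevant)[0]
        verdict = equivalence_decision(
            ds, Solution(truth.indispensable | {noise}), Solution(truth.indispensable),
            SearchConfig(seed=5), TestCounter(),
        )
        assert verdict.equivalent

    def test_accepting_verdict_implies_stagewise_pass(self):
        config = SearchConfig(seed=2)
        ds, truth = generate(
            SyntheticSpec(n_samples=1500, n_indispensable=1, class_sizes=(2,), seed=2)
        )
        members = sorted(truth.classes[0])
        verdict = equivalence_decision(
            ds, Solution(truth.indispensable | {members[1]}),
            Solution(truth.indispensable | {members[0]}), config, TestCounter(),
        )
        if verdict.equivalent:
            assert verdict.peq_pvalue >= config.alpha_eq
            assert min(verdict.ieq_pvalue_xy, verdict.ieq_pvalue_yx) >= config.alpha_eq


class TestBayesAccuracy:
    def test_printed_toy_distribution(self):
        joint, _ = toy_discrete("peq_accuracy_toy")
        assert bayes_expected_accuracy(joint) == pytest.approx(0.75)

    def test_deterministic_relation(self):
        joint = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert bayes_expected_accuracy(joint) == 1.0

    def test_independent_fair_coin(self):
        joint = np.full((2, 2), 0.25)
        assert bayes_expected_accuracy(joint) == pytest.approx(0.5)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            bayes_expected_accuracy(np.array([[0.5, 0.2], [0.1, 0.1]]))
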