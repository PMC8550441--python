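"""Statistical equivalence of feature sets.

Three notions of equivalence are supported, from loosest to strictest:

* **Performance equivalence (PEQ)** - the optimal models on the two sets
  achieve the same expected loss.
* **Model equivalence (MEQ)** - the optimal models make identical
  predictions.
* **Information equivalence (IEQ)** - each set renders the outcome
  conditionally independent of the other (the sets are interchangeable).

PEQ/MEQ are tested with a permutation variant of Vuong's variance test: the
statistic is the sample variance of the per-sample log-likelihood (or
prediction) differences, and its null distribution is generated by randomly
swapping, per paired sample, which model each value came from. IEQ is tested
with the comprehensive approach - multi-degree-of-freedom likelihood-ratio
tests of each set against the union model. The recommended combined decision
runs the cheap permutation filter first and the IEQ test second.

The permutation test is one-sided, rejecting for a SMALL observed variance
relative to the sign-swapped distribution (the p-value counts permuted
statistics <= the observed one). This detects mean shifts: when the mean
per-sample difference is nonzero, random sign swaps move mass from the mean
into the variance, so permuted variances stochastically dominate the
observed variance and the p-value becomes small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._glm import (
    GaussianFit,
    LogisticFit,
    bernoulli_loglik_vector,
    fit_gaussian,
    fit_logistic,
    fit_logistic_pair,
    gaussian_loglik_vector,
)
from .cond_independence import TestCounter, TestResult
from .data_model import OutcomeType, View
from .single_fbs import SearchConfig, Solution

__all__ = [
    "FittedModel",
    "LoglikVector",
    "PermutationResult",
    "EquivalenceVerdict",
    "fit_model",
    "loglik_vector",
    "vuong_variance_statistic",
    "permutation_variance_test",
    "ieq_test",
    "jtest",
    "equivalence_decision",
    "bayes_expected_accuracy",
]


@dataclass(frozen=True)
class FittedModel:
    """A model fit on one feature set: the learner's family, coefficients
    (intercept first), and for the linear family the MLE residual variance."""

    family: str  # "linear_gaussian" or "logistic"
    feature_set: tuple
    coefficients: np.ndarray
    sigma2: float | None = None
    flagged: bool = False

    def __post_init__(self):
        if len(self.coefficients) != len(self.feature_set) + 1:
            raise ValueError("coefficient length must be |feature_set| + 1")
        if self.family == "linear_gaussian" and not (self.sigma2 and self.sigma2 > 0):
            raise ValueError("linear family requires sigma2 > 0")

    def predict(self, view: View) -> np.ndarray:
        Z = view.X[:, list(self.feature_set)]
        eta = self.coefficients[0] + Z @ self.coefficients[1:]
        if self.family == "logistic":
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        return eta


@dataclass(frozen=True)
class LoglikVector:
    """Per-sample log-likelihood contributions; their sum is the model
    log-likelihood."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise ValueError("log-likelihood contributions must be finite")

    @property
    def total(self) -> float:
        return float(np.sum(self.values))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    permuted: np.ndarray
    pvalue: float
    B: int
    seed: int


@dataclass(frozen=True)
class EquivalenceVerdict:
    peq_pvalue: float
    ieq_pvalue_xy: float
    ieq_pvalue_yx: float
    equivalent: bool


def fit_model(view: View, features) -> FittedModel:
    """Fit the view's learner (OLS + Gaussian likelihood, or logistic MLE)
    on the given feature set."""
    features = tuple(sorted({int(f) for f in features}))
    if not set(features) <= set(view.active):
        raise ValueError("features must be active in the view")
    Z = view.X[:, list(features)]
    if view.outcome_type is OutcomeType.CONTINUOUS:
        fit = fit_gaussian(Z, view.y)
        return FittedModel(
            family="linear_gaussian",
            feature_set=features,
            coefficients=fit.coef,
            sigma2=fit.sigma2,
            flagged=fit.flagged,
        )
    fit = fit_logistic(Z, view.y)
    return FittedModel(
        family="logistic",
        feature_set=features,
        coefficients=fit.coef,
        flagged=fit.flagged,
    )


def loglik_vector(model: FittedModel, view: View) -> LoglikVector:
    """Per-sample log-density of the outcome under the fitted model."""
    pred = model.predict(view)
    if model.family == "linear_gaussian":
        return LoglikVector(gaussian_loglik_vector(view.y, pred, model.sigma2))
    return LoglikVector(bernoulli_loglik_vector(view.y, pred))


def vuong_variance_statistic(ll_x: LoglikVector, ll_y: LoglikVector) -> float:
    """Sample variance (denominator n) of the per-sample log-likelihood
    differences - the variance-test statistic for model equivalence."""
    if len(ll_x) != len(ll_y):
        raise ValueError("log-likelihood vectors must have equal length")
    d = ll_x.values - ll_y.values
    return float(np.mean(d**2) - np.mean(d) ** 2)


def permutation_variance_test(
    ll_x: LoglikVector, ll_y: LoglikVector, B: int, seed: int
) -> PermutationResult:
    """Paired sign-swap permutation test of the variance statistic.

    Each permutation independently swaps, with probability 0.5 per sample,
    which model the paired values came from; the p-value is
    ``(1 + #{s_i <= s}) / (B + 1)``, counting the observed statistic among
    the permutations.
    """
    if B < 100:
        raise ValueError("need at least 100 permutations")
    if len(ll_x) != len(ll_y):
        raise ValueError("log-likelihood vectors must have equal length")
    d = ll_x.values - ll_y.values
    observed = float(np.mean(d**2) - np.mean(d) ** 2)
    rng = np.random.default_rng(seed)
    # Swapping (x_i, y_i) flips the sign of the difference d_i; the second
    # moment is invariant, so only the permuted means need recomputing.
    signs = rng.choice([-1.0, 1.0], size=(B, len(d)))
    means = signs @ d / len(d)
    permuted = np.mean(d**2) - means**2
    pvalue = (1.0 + float(np.sum(permuted <= observed))) / (B + 1.0)
    return PermutationResult(
        observed=observed, permuted=permuted, pvalue=pvalue, B=B, seed=seed
    )


def permutation_meq_test(
    pred_x: np.ndarray, pred_y: np.ndarray, B: int, seed: int
) -> PermutationResult:
    """Variance permutation test on prediction differences instead of
    log-likelihood differences (the model-equivalence variant); one
    permutation engine serves both."""
    return permutation_variance_test(
        LoglikVector(np.asarray(pred_x, float)),
        LoglikVector(np.asarray(pred_y, float)),
        B=B,
        seed=seed,
    )


def _nested_lrt(view: View, small: tuple, big: tuple, counter: TestCounter) -> TestResult:
    """Multi-dof likelihood-ratio test of the features in big minus small."""
    added = len(big) - len(small)
    if added == 0:
        return TestResult(0.0, 1.0, 0, "lrt")
    counter.bump()
    if view.outcome_type is OutcomeType.CONTINUOUS:
        fit_small = fit_gaussian(view.X[:, list(small)], view.y)
        fit_big = fit_gaussian(view.X[:, list(big)], view.y)
        statistic = max(0.0, -2.0 * (fit_small.loglik - fit_big.loglik))
        flagged = fit_small.flagged or fit_big.flagged
    else:
        fit_small, fit_big = fit_logistic_pair(
            view.X[:, list(small)], view.X[:, list(big)], view.y
        )
        statistic = max(0.0, fit_small.deviance - fit_big.deviance)
        flagged = fit_small.flagged or fit_big.flagged
    pvalue = float(stats.chi2.sf(statistic, df=added))
    return TestResult(float(statistic), pvalue, added, "lrt", flagged=flagged)


def ieq_test(
    view: View, set_x, set_y, alpha_eq: float, counter: TestCounter
) -> tuple:
    """Information-equivalence test via the comprehensive approach.

    Fits the union model and tests Test(T; Y \\ X | X) and Test(T; X \\ Y | Y)
    as multi-degree-of-freedom likelihood-ratio tests (dof = number of added
    features). The sets are equivalent iff neither test rejects at
    ``alpha_eq``.
    """
    sx = tuple(sorted({int(f) for f in set_x}))
    sy = tuple(sorted({int(f) for f in set_y}))
    union = tuple(sorted(set(sx) | set(sy)))
    with counter.scoped("equiv"):
        res_xy = _nested_lrt(view, sx, union, counter)  # adds Y \ X given X
        res_yx = _nested_lrt(view, sy, union, counter)  # adds X \ Y given Y
    equivalent = res_xy.pvalue >= alpha_eq and res_yx.pvalue >= alpha_eq
    return res_xy, res_yx, equivalent


def jtest(view: View, set_x, set_y, alpha_eq: float, counter: TestCounter | None = None) -> tuple:
    """J-test: use each model's in-sample predictions as a single synthetic
    feature and test whether it adds information given the other set.

    Cheaper than the comprehensive approach (no union model), at the price of
    missing interactions between the sets.
    """
    counter = counter if counter is not None else TestCounter()
    sx = tuple(sorted({int(f) for f in set_x}))
    sy = tuple(sorted({int(f) for f in set_y}))
    if sx == sy:
        r = TestResult(0.0, 1.0, 0, "jtest")
        return r, r, True
    pred_x = fit_model(view, sx).predict(view)
    pred_y = fit_model(view, sy).predict(view)

    def _one(pred: np.ndarray, other: tuple) -> TestResult:
        with counter.scoped("equiv"):
            counter.bump()
        Z_small = view.X[:, list(other)]
        Z_big = np.column_stack([Z_small, pred])
        if view.outcome_type is OutcomeType.CONTINUOUS:
            f_small = fit_gaussian(Z_small, view.y)
            f_big = fit_gaussian(Z_big, view.y)
            statistic = max(0.0, -2.0 * (f_small.loglik - f_big.loglik))
            flagged = f_small.flagged or f_big.flagged
        else:
            f_small, f_big = fit_logistic_pair(Z_small, Z_big, view.y)
            statistic = max(0.0, f_small.deviance - f_big.deviance)
            flagged = f_small.flagged or f_big.flagged
        return TestResult(
            float(statistic), float(stats.chi2.sf(statistic, df=1)), 1, "jtest",
            flagged=flagged,
        )

    res_xy = _one(pred_x, sy)  # do X's predictions add information given Y?
    res_yx = _one(pred_y, sx)
    equivalent = res_xy.pvalue >= alpha_eq and res_yx.pvalue >= alpha_eq
    return res_xy, res_yx, equivalent


def _candidate_seed(config: SearchConfig, candidate, reference) -> int:
    # Deterministic per-candidate seed: identical candidates get identical
    # permutation draws no matter which search algorithm proposes them or in
    # what order.
    ss = np.random.SeedSequence(
        [int(config.seed) & 0x7FFFFFFF, *sorted(candidate), *sorted(reference)]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def equivalence_decision(
    view: View,
    candidate: Solution,
    reference: Solution,
    config: SearchConfig,
    counter: TestCounter,
) -> EquivalenceVerdict:
    """The recommended two-stage equivalence decision.

    Stage 1 (filter): permutation variance test on the per-sample
    log-likelihoods of the models fit on each set; rejection at ``alpha_eq``
    ends the decision (not equivalent) without running the costlier stage.
    Stage 2: the comprehensive IEQ test. Equivalent iff both stages pass.

    A candidate that is a strict superset of the reference passes both IEQ
    directions by construction; minimality is the backward phase's
    responsibility, not this decision's.
    """
    cand = candidate.as_set if isinstance(candidate, Solution) else frozenset(candidate)
    ref = reference.as_set if isinstance(reference, Solution) else frozenset(reference)
    ll_c = loglik_vector(fit_model(view, cand), view)
    ll_r = loglik_vector(fit_model(view, ref), view)
    perm = permutation_variance_test(
        ll_c, ll_r, B=config.n_permutations,
        seed=_candidate_seed(config, cand, ref),
    )
    if perm.pvalue < config.alpha_eq:
        return EquivalenceVerdict(
            peq_pvalue=perm.pvalue, ieq_pvalue_xy=float("nan"),
            ieq_pvalue_yx=float("nan"), equivalent=False,
        )
    res_xy, res_yx, ieq_ok = ieq_test(view, cand, ref, config.alpha_eq, counter)
    return EquivalenceVerdict(
        peq_pvalue=perm.pvalue,
        ieq_pvalue_xy=res_xy.pvalue,
        ieq_pvalue_yx=res_yx.pvalue,
        equivalent=bool(ieq_ok),
    )


def make_equivalence_fn(view: View, config: SearchConfig, counter: TestCounter):
    """Build the candidate-vs-reference decision used by the searches.

    The returned callable maps ``(candidate, reference)`` solutions to a
    boolean via :func:`equivalence_decision` on the full dataset. Verdicts
    are memoized per feature-set pair, so a candidate reached through
    different search branches - or by a different search algorithm - always
    receives the same answer.
    """
    cache: dict = {}

    def decide(candidate: Solution, reference: Solution) -> bool:
        key = (candidate.features, reference.features)
        if key not in cache:
            verdict = equivalence_decision(view, candidate, reference, config, counter)
            cache[key] = verdict.equivalent
        return cache[key]

    return decide


def bayes_expected_accuracy(joint: np.ndarray) -> float:
    """Best expected 0-1 accuracy of any deterministic rule X -> T.

    ``joint`` is a matrix of joint probabilities with rows indexing outcome
    values and columns indexing (possibly vector-valued) feature
    configurations. The optimal rule picks, per column, the outcome with the
    largest joint mass, so the value is the sum of columnwise maxima.
    """
    joint = np.asarray(joint, dtype=float)
    if joint.ndim != 2:
        raise ValueError("joint must be a 2-D table of probabilities")
    if np.any(joint < 0) or not np.isclose(joint.sum(), 1.0, atol=1e-9):
        raise ValueError("joint probabilities must be nonnegative and sum to 1")
    return float(np.sum(joint.max(axis=0)))
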