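"""Conditional-independence tests Test(T; X | Z) with a global test counter.

Two tests are provided, dispatched on the outcome type:

* **Fisher-z partial correlation** for continuous outcomes. The sample
  partial correlation r of a feature with the outcome given a conditioning
  set is computed from the inverse of the covariance submatrix; the
  statistic sqrt(n - |Z| - 3) * atanh(r) is referred to the standard normal
  (two-sided).
* **Logistic likelihood-ratio** for binary outcomes. Nested logistic models
  with and without the feature are fit; the deviance difference is referred
  to a chi-square with one degree of freedom.

Every call increments a :class:`TestCounter`. Counted tests are the
hardware-independent runtime proxy used to compare search algorithms, with
search-phase and equivalence-phase tests tallied separately (equivalence
tests are common to all algorithms).
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._glm import fit_logistic_pair
from .data_model import OutcomeType, View

__all__ = ["TestResult", "TestCounter", "fisher_z_test", "logistic_lrt", "ci_test"]

# Near-duplicate features (the very signal this package hunts) make
# near-singular conditioning covariances common; above this condition
# number a small ridge jitter is added and the result flagged.
_COND_LIMIT = 1e10
_COV_JITTER = 1e-8
# Partial correlations are clipped away from +-1 so atanh stays finite on
# (near-)deterministic relations.
_R_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest collectible

    statistic: float
    pvalue: float
    dof: int
    test_name: str
    flagged: bool = False

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")
        if self.dof < 0:
            raise ValueError("negative degrees of freedom")
        if not np.isfinite(self.statistic):
            raise ValueError("non-finite statistic")


@dataclass
class TestCounter:
    """Counts of conditional-independence tests, by phase.

    ``search`` covers tests issued by the variable-ordering and backward
    phases of the selection algorithms; ``equiv`` covers tests issued while
    deciding statistical equivalence of candidate solutions.
    """

    __test__ = False  # not a pytest collectible

    search: int = 0
    equiv: int = 0
    _scope: str = field(default="search", repr=False)

    @property
    def ci_tests(self) -> int:
        return self.search + self.equiv

    def bump(self, by: int = 1) -> None:
        if self._scope == "equiv":
            self.equiv += by
        else:
            self.search += by

    def reset(self) -> None:
        self.search = 0
        self.equiv = 0

    @contextmanager
    def scoped(self, scope: str):
        if scope not in ("search", "equiv"):
            raise ValueError(f"unknown counter scope {scope!r}")
        previous = self._scope
        self._scope = scope
        try:
            yield self
        finally:
            self._scope = previous


def partial_correlation(view: View, x: int, cond) -> tuple:
    """Sample partial correlation of feature ``x`` with the outcome given
    ``cond``, via the precision matrix over {x, T} union cond.

    Returns ``(r, flagged)``; a zero-variance ``x`` yields ``(nan, True)``.
    """
    cond = sorted(cond)
    data = np.column_stack([view.X[:, x], view.y] + [view.X[:, j] for j in cond])
    if np.var(data[:, 0]) <= 0.0 or np.var(data[:, 1]) <= 0.0:
        return float("nan"), True
    cov = np.cov(data, rowvar=False)
    flagged = False
    cond_number = np.linalg.cond(cov)
    if not np.isfinite(cond_number) or cond_number > _COND_LIMIT:
        cov = cov + _COV_JITTER * np.eye(cov.shape[0])
        flagged = True
    precision = np.linalg.inv(cov)
    r = -precision[0, 1] / np.sqrt(precision[0, 0] * precision[1, 1])
    return float(r), flagged


def fisher_z_test(view: View, x: int, cond, counter: TestCounter) -> TestResult:
    """Fisher-z test of the partial correlation of ``x`` with the outcome.

    Requires a continuous outcome, ``x`` active, ``x`` not in ``cond``, and
    ``n > |cond| + 3`` for a positive effective sample size.
    """
    cond = frozenset(int(j) for j in cond)
    _check_args(view, x, cond, OutcomeType.CONTINUOUS)
    n = view.n_samples
    if n <= len(cond) + 3:
        raise ValueError(f"need n > |cond| + 3, got n={n}, |cond|={len(cond)}")
    counter.bump()
    r, flagged = partial_correlation(view, x, cond)
    if not np.isfinite(r):
        # degenerate (zero-variance) input: report no evidence of dependence
        return TestResult(0.0, 1.0, len(cond), "fisher_z", flagged=True)
    r = float(np.clip(r, -_R_CLIP, _R_CLIP))
    z = np.sqrt(n - len(cond) - 3) * np.arctanh(r)
    pvalue = 2.0 * stats.norm.sf(abs(z))
    return TestResult(float(z), float(pvalue), len(cond), "fisher_z", flagged=flagged)


def logistic_lrt(view: View, x: int, cond, counter: TestCounter) -> TestResult:
    """Likelihood-ratio test of ``x`` against a binary outcome given ``cond``.

    The statistic is deviance(cond) - deviance(cond + {x}), chi-square with
    one degree of freedom. The empty conditioning set compares against the
    intercept-only model.
    """
    cond = frozenset(int(j) for j in cond)
    _check_args(view, x, cond, OutcomeType.BINARY)
    counter.bump()
    cols = sorted(cond)
    Z_small = view.X[:, cols]
    Z_big = view.X[:, cols + [x]]
    if np.var(view.X[:, x]) <= 0.0:
        return TestResult(0.0, 1.0, 1, "logistic_lrt", flagged=True)
    small, big = fit_logistic_pair(Z_small, Z_big, view.y)
    statistic = max(0.0, small.deviance - big.deviance)
    pvalue = float(stats.chi2.sf(statistic, df=1))
    return TestResult(
        float(statistic),
        pvalue,
        1,
        "logistic_lrt",
        flagged=small.flagged or big.flagged,
    )


def ci_test(view: View, x: int, cond, counter: TestCounter) -> TestResult:
    """Dispatch to the appropriate test for the view's outcome type."""
    if view.outcome_type is OutcomeType.CONTINUOUS:
        return fisher_z_test(view, x, cond, counter)
    return logistic_lrt(view, x, cond, counter)


def _check_args(view: View, x: int, cond: frozenset, required: OutcomeType) -> None:
    if view.outcome_type is not required:
        raise ValueError(
            f"test requires a {required.value} outcome, got {view.outcome_type.value}"
        )
    active = set(view.active)
    if x not in active:
        raise ValueError(f"feature {x} is not active in the view")
    if not cond <= active:
        raise ValueError(f"conditioning features {sorted(cond - active)} not active")
    if x in cond:
        raise ValueError(f"feature {x} cannot appear in its own conditioning set")
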