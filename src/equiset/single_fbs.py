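"""Greedy forward-backward feature selection (the single-solution engine).

The template (TFBS) alternates two pluggable components: an ``OrderVariables``
function returning the admissible candidates in order of preference, and a
``BackwardPhase`` removing false positives after the forward phase ends. The
concrete instantiation here (FBS) orders candidates by ascending p-value of
the conditional-independence test with the outcome given the currently
selected set, and the backward phase repeatedly drops the selected feature
least dependent on the outcome given the others.

The admissibility contract for ``OrderVariables``: (a) empty iff no variable
should be selected, (b) disjoint from the selected set, and (c) containing
every variable that could be selected at this iteration, in order of
preference - equivalently, dropping a prefix of the ordering yields exactly
the ordering that would be computed on the correspondingly embedded dataset.
That tail property is what makes the multiple-solutions search sound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .cond_independence import TestCounter, ci_test
from .data_model import Dataset, View

__all__ = [
    "Solution",
    "CandidateOrdering",
    "SearchConfig",
    "order_variables_fbs",
    "backward_phase_fbs",
    "run_tfbs",
    "FBS_PAIR",
]


@dataclass(frozen=True)
class Solution:
    """A minimal feature set, stored canonically sorted by base index."""

    features: tuple

    def __init__(self, features: Iterable[int]):
        object.__setattr__(self, "features", tuple(sorted({int(f) for f in features})))

    @property
    def as_set(self) -> frozenset:
        return frozenset(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, item: int) -> bool:
        return item in self.as_set

    def __iter__(self):
        return iter(self.features)

    def names(self, dataset: Dataset) -> list:
        return [dataset.feature_names[i] for i in self.features]


@dataclass(frozen=True)
class CandidateOrdering:
    """Candidates for selection, in order of preference (ascending p-value).

    Tie-break: equal p-values are ordered by base-dataset feature index, so
    runs are reproducible.
    """

    features: tuple
    pvalues: tuple

    def __post_init__(self):
        if len(self.features) != len(self.pvalues):
            raise ValueError("features and pvalues must be parallel")
        if any(b < a for a, b in zip(self.pvalues, self.pvalues[1:])):
            raise ValueError("pvalues must be ascending")

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class SearchConfig:
    """Knobs shared by all search and equivalence routines.

    alpha
        Significance level for the selection CI tests.
    alpha_eq
        Level for the equivalence tests (both the permutation filter and the
        information-equivalence likelihood-ratio tests).
    n_permutations
        Number of sign-swap permutations B for the variance test.
    max_solutions / max_visited_states
        Search budget; hitting either sets ``limit_hit`` in the run stats
        rather than raising.
    pruning
        Enable flags for pruning rules 1-3 of the multiple-solutions search.
    """

    alpha: float = 0.05
    alpha_eq: float = 0.05
    n_permutations: int = 1000
    max_solutions: int = 1000
    max_visited_states: int = 100_000
    seed: int = 0
    pruning: tuple = (True, True, True)

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if not 0.0 < self.alpha_eq <= 1.0:
            raise ValueError("alpha_eq must be in (0, 1]")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.max_solutions < 1 or self.max_visited_states < 1:
            raise ValueError("search limits must be positive")
        if len(self.pruning) != 3:
            raise ValueError("pruning must hold three booleans (rules 1-3)")


def order_variables_fbs(
    view: View, selected: Solution, config: SearchConfig, counter: TestCounter
) -> CandidateOrdering:
    """Rank the active non-selected features by their conditional p-value.

    Only features with p < alpha are returned; ties break toward the lower
    base-dataset index (stable sort).
    """
    sel = selected.as_set
    active = set(view.active)
    if not sel <= active:
        raise ValueError("selected features must be active in the view")
    scored = []
    for f in sorted(active - sel):
        result = ci_test(view, f, sel, counter)
        p = 1.0 if result.flagged else result.pvalue
        if p < config.alpha:
            scored.append((p, f))
    scored.sort(key=lambda t: (t[0], t[1]))
    return CandidateOrdering(
        features=tuple(f for _, f in scored), pvalues=tuple(p for p, _ in scored)
    )


def backward_phase_fbs(
    view: View, selected: Solution, config: SearchConfig, counter: TestCounter
) -> Solution:
    """Drop, one at a time, the least dependent selected feature.

    At each pass the feature with the highest p-value of
    Test(T; X | selected - {X}) strictly above alpha is removed; the loop
    stops when every survivor is conditionally dependent at level alpha.
    """
    current = set(selected.as_set)
    if not current <= set(view.active):
        raise ValueError("selected features must be active in the view")
    while current:
        worst, worst_p = None, -1.0
        # ascending feature order + strict '>' keeps ties deterministic
        # (lowest base index removed first)
        for f in sorted(current):
            result = ci_test(view, f, current - {f}, counter)
            p = 1.0 if result.flagged else result.pvalue
            if p > worst_p:
                worst, worst_p = f, p
        if worst_p > config.alpha:
            current.remove(worst)
        else:
            break
    return Solution(current)


def run_tfbs(
    view: View,
    config: SearchConfig,
    counter: Optional[TestCounter] = None,
    order_variables: Callable = None,
    backward_phase: Callable = None,
) -> Solution:
    """Run the forward-backward template to a single (reference) solution.

    The forward phase repeatedly selects the top-ranked candidate until the
    ordering is empty; one backward pass then removes false positives.
    Alternative ``OrderVariables``/``BackwardPhase`` pairs may be supplied;
    the default pair is FBS.
    """
    counter = counter if counter is not None else TestCounter()
    order_variables = order_variables or order_variables_fbs
    backward_phase = backward_phase or backward_phase_fbs
    selected = Solution(())
    while True:
        ordering = order_variables(view, selected, config, counter)
        if len(ordering) == 0:
            break
        selected = Solution(selected.as_set | {ordering.features[0]})
    return backward_phase(view, selected, config, counter)


#: The default admissible (OrderVariables, BackwardPhase) pair.
FBS_PAIR = (order_variables_fbs, backward_phase_fbs)
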