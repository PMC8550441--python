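"""Backtracking search for all statistically equivalent minimal solutions.

The forward phase of the greedy template is a search over feature sets;
instead of following only the top-ranked candidate, the multiple-solutions
search explores every candidate by backtracking. Repeated states are avoided
by the sibling-exclusion strategy: once candidate ``C_i`` has been explored,
it is excluded from the dataset seen by all subsequent siblings, which is
equivalent to re-running the algorithm on the embedded dataset without
``C_i``. The first solution reached (the leftmost path) coincides with the
single-solution algorithm's output and becomes the reference; every later
candidate is kept iff the equivalence decision accepts it against the
reference.

Three sound pruning rules cut the search space. They rest on one fact: if a
dataset contains no equivalent solution, neither does any dataset embedded
in it.

* **Rule 1** - if a child search contributes no new equivalent solution,
  abandon its remaining siblings (their datasets are embedded in the
  child's) and remember the failed exclusion set.
* **Rule 2** - before descending, stop if the child's exclusion set extends
  a remembered failed exclusion set.
* **Rule 3** - if a child search found new solutions but none contains the
  branching candidate, that candidate was a forward-phase false positive
  removed by the backward phase; the remaining siblings would repeat the
  child's results and are skipped.

Rule 2 is checked immediately before each descent; Rules 1 and 3 depend on
the child's results and are checked immediately after it returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

from .cond_independence import TestCounter
from .data_model import Dataset, View, embed
from .equivalence import make_equivalence_fn
from .single_fbs import (
    SearchConfig,
    Solution,
    backward_phase_fbs,
    order_variables_fbs,
)

__all__ = [
    "SolutionSet",
    "FailureCache",
    "SearchStats",
    "rule2_applies",
    "record_failure",
    "run_tmfbs",
]


@dataclass
class SolutionSet:
    """An ordered family of distinct solutions; the first element is the
    reference that defines the equivalence class."""

    solutions: List[Solution] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for s in self.solutions:
            if s.features in seen:
                raise ValueError(f"duplicate solution {s.features}")
            seen.add(s.features)

    @property
    def reference(self) -> Solution:
        if not self.solutions:
            raise ValueError("empty solution set has no reference")
        return self.solutions[0]

    def as_frozensets(self) -> frozenset:
        return frozenset(s.as_set for s in self.solutions)

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)

    def __contains__(self, solution: Solution) -> bool:
        return any(s.features == solution.features for s in self.solutions)


@dataclass
class FailureCache:
    """Minimal antichain of exclusion sets whose embedded datasets yielded
    no equivalent solution (so neither can any further-embedded dataset)."""

    failed_exclusions: List[frozenset] = field(default_factory=list)


def rule2_applies(cache: FailureCache, exclusion) -> bool:
    """True iff some recorded failed exclusion set is contained in
    ``exclusion`` (the proposed dataset is embedded in a failed one)."""
    exclusion = frozenset(exclusion)
    return any(f <= exclusion for f in cache.failed_exclusions)


def record_failure(cache: FailureCache, exclusion) -> FailureCache:
    """Insert a failed exclusion set, keeping the cache a minimal antichain.

    A superset of a stored set is redundant (already implied) and is not
    inserted; stored supersets of the new set are discarded.
    """
    exclusion = frozenset(exclusion)
    if any(f <= exclusion for f in cache.failed_exclusions):
        return cache
    cache.failed_exclusions = [
        f for f in cache.failed_exclusions if not exclusion <= f
    ]
    cache.failed_exclusions.append(exclusion)
    return cache


@dataclass
class SearchStats:
    nodes_visited: int = 0
    ci_tests_search: int = 0
    ci_tests_equiv: int = 0
    solutions_found: int = 0
    limit_hit: bool = False

    def to_dict(self) -> dict:
        return {
            "nodes_visited": self.nodes_visited,
            "ci_tests_search": self.ci_tests_search,
            "ci_tests_equiv": self.ci_tests_equiv,
            "solutions_found": self.solutions_found,
            "limit_hit": self.limit_hit,
        }


@dataclass
class _Frame:
    exclusions: frozenset
    selected: frozenset
    candidates: Optional[list] = None
    next_child: int = 0
    child_before: int = 0


def run_tmfbs(
    dataset: Dataset,
    config: SearchConfig,
    equivalence_fn: Optional[Callable] = None,
    counter: Optional[TestCounter] = None,
    order_variables: Callable = order_variables_fbs,
    backward_phase: Callable = backward_phase_fbs,
    on_state: Optional[Callable] = None,
) -> tuple:
    """Depth-first multiple-solutions search.

    Parameters
    ----------
    equivalence_fn
        ``(candidate, reference) -> bool``; defaults to the memoized
        two-stage decision (permutation variance filter + IEQ test) on the
        full dataset.
    on_state
        Optional instrumentation hook called with each visited selected set
        (used to verify that no state repeats).

    Returns
    -------
    (SolutionSet, SearchStats)
    """
    counter = counter if counter is not None else TestCounter()
    if equivalence_fn is None:
        equivalence_fn = make_equivalence_fn(dataset, config, counter)
    rule1, rule2, rule3 = config.pruning
    start_search, start_equiv = counter.search, counter.equiv

    solutions: List[Solution] = []
    cache = FailureCache()
    stats = SearchStats()
    stack: List[_Frame] = [_Frame(exclusions=frozenset(), selected=frozenset())]
    aborted = False

    def consider(candidate: Solution) -> None:
        nonlocal aborted
        if any(s.features == candidate.features for s in solutions):
            return  # duplicate: silently dropped, contributes nothing new
        if not solutions:
            solutions.append(candidate)  # the reference defines the class
            return
        if len(solutions) >= config.max_solutions:
            stats.limit_hit = True
            aborted = True
            return
        if equivalence_fn(candidate, solutions[0]):
            solutions.append(candidate)

    while stack and not aborted:
        frame = stack[-1]

        if frame.candidates is None:
            stats.nodes_visited += 1
            if on_state is not None:
                on_state(frame.selected)
            if stats.nodes_visited > config.max_visited_states:
                stats.limit_hit = True
                break
            view = embed(dataset, frame.exclusions)
            ordering = order_variables(view, Solution(frame.selected), config, counter)
            frame.candidates = list(ordering.features)
            if not frame.candidates:
                consider(backward_phase(view, Solution(frame.selected), config, counter))
                stack.pop()
            continue

        if frame.next_child > 0:
            # a child just returned: apply Rules 1 and 3
            i = frame.next_child - 1
            child_exclusions = frame.exclusions | frozenset(frame.candidates[:i])
            added = solutions[frame.child_before:]
            if not added:
                # true regardless of pruning flags; feeds Rule 2
                record_failure(cache, child_exclusions)
                if rule1:
                    stack.pop()
                    continue
            elif rule3:
                branching = frame.candidates[i]
                if not any(branching in sol for sol in added):
                    stack.pop()
                    continue

        if frame.next_child >= len(frame.candidates):
            stack.pop()
            continue

        i = frame.next_child
        child_exclusions = frame.exclusions | frozenset(frame.candidates[:i])
        if rule2 and rule2_applies(cache, child_exclusions):
            stack.pop()
            continue
        frame.child_before = len(solutions)
        frame.next_child = i + 1
        stack.append(
            _Frame(
                exclusions=child_exclusions,
                selected=frame.selected | {frame.candidates[i]},
            )
        )

    stats.solutions_found = len(solutions)
    stats.ci_tests_search = counter.search - start_search
    stats.ci_tests_equiv = counter.equiv - start_equiv
    return SolutionSet(solutions=solutions), stats
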