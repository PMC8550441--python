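"""TIE* with the IGS embedded-dataset generator, as a comparison baseline.

TIE* finds the reference solution on the full dataset, then repeatedly runs
the single-solution algorithm on embedded datasets produced by the
incremental generation strategy (IGS): for every solution ``S_j`` found on a
dataset with exclusion set ``E_j``, propose ``E_j + {X}`` for each
``X in S_j``. Proposals already processed, or extending an exclusion set
that yielded no equivalent solution, are filtered out. The baseline shares
the conditional-independence tests, significance levels, equivalence
decision and counters with the backtracking search, so their test counts
are directly comparable.
"""

from __future__ import annotations

from collections import deque
from typing import Callable, List, Optional

from .cond_independence import TestCounter
from .data_model import Dataset, embed
from .equivalence import make_equivalence_fn
from .multi_tmfbs import (
    FailureCache,
    SearchStats,
    SolutionSet,
    record_failure,
    rule2_applies,
)
from .single_fbs import (
    SearchConfig,
    Solution,
    backward_phase_fbs,
    order_variables_fbs,
    run_tfbs,
)

__all__ = ["igs_generate", "run_tie_star_igs"]


def _sort_key(exclusion: frozenset):
    return (len(exclusion), tuple(sorted(exclusion)))


def igs_generate(
    M: SolutionSet,
    processed,
    cache: FailureCache,
    exclusions: Optional[List[frozenset]] = None,
) -> list:
    """Propose new embedded datasets from the current solution family.

    For each solution ``S_j`` (found with exclusion set ``exclusions[j]``,
    empty if not given), propose excluding additionally one of its members.
    Proposals already processed, or extending a failed exclusion set, are
    filtered. Survivors are returned sorted by (size, lexicographic).
    """
    if len(M) == 0:
        raise ValueError("need at least the reference solution")
    if exclusions is None:
        exclusions = [frozenset() for _ in M.solutions]
    if len(exclusions) != len(M):
        raise ValueError("one exclusion set per solution required")
    processed = {frozenset(e) for e in processed}
    proposals = set()
    for solution, base_exclusion in zip(M.solutions, exclusions):
        for x in solution:
            proposal = frozenset(base_exclusion) | {x}
            if proposal in processed:
                continue
            if rule2_applies(cache, proposal):
                continue
            proposals.add(proposal)
    return sorted(proposals, key=_sort_key)


def run_tie_star_igs(
    dataset: Dataset,
    config: SearchConfig,
    equivalence_fn: Optional[Callable] = None,
    counter: Optional[TestCounter] = None,
    order_variables: Callable = order_variables_fbs,
    backward_phase: Callable = backward_phase_fbs,
) -> tuple:
    """Run TIE*-IGS; returns ``(SolutionSet, SearchStats)``.

    Each embedded dataset is run at most once per invocation. No test
    results are cached across runs of the inner algorithm, so the search
    counter reflects the genuine cost of restarting it per candidate.
    """
    counter = counter if counter is not None else TestCounter()
    if equivalence_fn is None:
        equivalence_fn = make_equivalence_fn(dataset, config, counter)
    start_search, start_equiv = counter.search, counter.equiv
    stats = SearchStats()
    cache = FailureCache()

    def run_single(exclusion: frozenset) -> Solution:
        stats.nodes_visited += 1
        return run_tfbs(
            embed(dataset, exclusion),
            config,
            counter,
            order_variables=order_variables,
            backward_phase=backward_phase,
        )

    reference = run_single(frozenset())
    solutions = [reference]
    solution_exclusions = [frozenset()]
    processed = {frozenset()}

    worklist = deque(
        igs_generate(
            SolutionSet(solutions), processed, cache, exclusions=solution_exclusions
        )
    )
    while worklist:
        if stats.nodes_visited >= config.max_visited_states:
            stats.limit_hit = True
            break
        exclusion = worklist.popleft()
        if exclusion in processed or rule2_applies(cache, exclusion):
            continue
        processed.add(exclusion)
        candidate = run_single(exclusion)
        known = any(s.features == candidate.features for s in solutions)
        if known:
            continue
        if len(solutions) >= config.max_solutions:
            stats.limit_hit = True
            break
        if equivalence_fn(candidate, reference):
            solutions.append(candidate)
            solution_exclusions.append(exclusion)
            fresh = igs_generate(
                SolutionSet([candidate]),
                processed | set(worklist),
                cache,
                exclusions=[exclusion],
            )
            worklist.extend(fresh)
        else:
            record_failure(cache, exclusion)

    stats.solutions_found = len(solutions)
    stats.ci_tests_search = counter.search - start_search
    stats.ci_tests_equiv = counter.equiv - start_equiv
    return SolutionSet(solutions=solutions), stats
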