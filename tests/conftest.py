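"""Shared fixtures: small seeded datasets and the synthetic evaluation suite.

The suite is 50 datasets (five class structures x ten seeds) at n = 2000
with two indispensable features, one redundant and three irrelevant ones.
The searches run it at a strict selection level (alpha = 0.001): with unit
strength signals at this sample size, true predictors are overwhelmingly
significant, and the strict level plays the role of the tuned significance
threshold the full protocol selects by validation. Session-scoped fixtures
run each search once per instance so several acceptance properties can
share the computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from equiset import (
    SearchConfig,
    SyntheticSpec,
    TestCounter,
    enumerate_true_solutions,
    generate,
    run_tie_star_igs,
    run_tmfbs,
)

SUITE_ALPHA = 0.001
SUITE_CLASS_CONFIGS = [(), (2,), (3,), (2, 2), (2, 3)]
SUITE_SEEDS = range(10)


def suite_specs():
    return [
        SyntheticSpec(
            n_samples=2000,
            n_indispensable=2,
            class_sizes=cs,
            n_redundant=1,
            n_irrelevant=3,
            seed=seed,
        )
        for cs in SUITE_CLASS_CONFIGS
        for seed in SUITE_SEEDS
    ]


def suite_config(seed: int, pruning=(True, True, True)) -> SearchConfig:
    return SearchConfig(seed=seed, alpha=SUITE_ALPHA, pruning=pruning)


def oracle_equivalence(truth):
    """Ground-truth equivalence decision: a candidate is equivalent iff it
    is one of the planted solutions (the oracle regime of the completeness
    and pruning-soundness guarantees)."""
    family = enumerate_true_solutions(truth).as_frozensets()

    def decide(candidate, reference) -> bool:
        return candidate.as_set in family

    return decide


@pytest.fixture(scope="session")
def suite_runs():
    """TMFBS and TIE*-IGS run once per suite instance with the full
    statistical equivalence pipeline."""
    runs = []
    for spec in suite_specs():
        dataset, truth = generate(spec)
        config = suite_config(spec.seed)
        m_tm, st_tm = run_tmfbs(dataset, config, counter=TestCounter())
        m_tie, st_tie = run_tie_star_igs(dataset, config, counter=TestCounter())
        runs.append(
            {
                "spec": spec,
                "dataset": dataset,
                "truth": truth,
                "config": config,
                "tmfbs": (m_tm, st_tm),
                "tiestar": (m_tie, st_tie),
            }
        )
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_continuous():
    """n=400, two strong predictors (x0, x1), three noise features."""
    from equiset import Dataset

    rng = np.random.default_rng(7)
    X = rng.standard_normal((400, 5))
    y = X[:, 0] + X[:, 1] + 0.5 * rng.standard_normal(400)
    return Dataset(
        X=X, feature_names=tuple(f"F{i}" for i in range(5)), y=y,
        outcome_type="continuous",
    )


@pytest.fixture
def small_binary():
    from equiset import Dataset

    rng = np.random.default_rng(11)
    X = rng.standard_normal((400, 4))
    eta = 1.5 * X[:, 0] - 1.0 * X[:, 2]
    y = (rng.random(400) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return Dataset(
        X=X, feature_names=("a", "b", "c", "d"), y=y, outcome_type="binary"
    )
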