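"""Synthetic data with known multiple-Markov-blanket ground truth.

The generator plants four kinds of features around a linear (or logistic)
outcome:

* **indispensable** features - independent standard normals entering the
  outcome directly; they belong to every minimal solution.
* **equivalence classes** - groups of near-deterministic copies of a latent
  signal (each member equals the latent plus small independent noise of
  standard deviation ``epsilon``), the latent entering the outcome; any one
  member screens off the rest, so each minimal solution picks exactly one
  member per class. Exact copies would make covariance matrices singular
  and partial correlations undefined, so copies are near-exact; the
  deterministic-copy ideal is the ``epsilon -> 0`` limit.
* **redundant** features - noisy proxies of the linear predictor:
  marginally informative, but independent of the outcome once the true
  predictors are conditioned on, hence in no minimal solution.
* **irrelevant** features - independent noise.

The true solution family is the Cartesian product "all indispensables plus
one member per class", enumerable in closed form, which makes the generator
the test bed for the completeness and agreement properties of the searches.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import Dataset, OutcomeType
from .multi_tmfbs import SolutionSet
from .single_fbs import Solution

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "enumerate_true_solutions", "toy_discrete"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``class_sizes`` lists the equivalence-class sizes (each >= 1);
    ``epsilon`` is the copy-noise standard deviation; ``beta`` the common
    coefficient magnitude of the true predictors.
    """

    n_samples: int = 2000
    n_indispensable: int = 2
    class_sizes: tuple = ()
    n_redundant: int = 1
    n_irrelevant: int = 3
    epsilon: float = 1e-3
    beta: float = 1.0
    outcome: OutcomeType = OutcomeType.CONTINUOUS
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "class_sizes", tuple(int(k) for k in self.class_sizes))
        object.__setattr__(self, "outcome", OutcomeType(self.outcome))
        if min([self.n_indispensable, self.n_redundant, self.n_irrelevant] or [0]) < 0:
            raise ValueError("feature counts must be nonnegative")
        if any(k < 1 for k in self.class_sizes):
            raise ValueError("class sizes must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive (exact copies are degenerate)")
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")

    @property
    def n_features(self) -> int:
        return (
            self.n_indispensable
            + sum(self.class_sizes)
            + self.n_redundant
            + self.n_irrelevant
        )


@dataclass(frozen=True)
class GroundTruth:
    """The planted structure: four groups partitioning the feature universe."""

    indispensable: frozenset
    classes: tuple  # of frozensets, mutually exclusive alternatives
    redundant: frozenset
    irrelevant: frozenset

    def __post_init__(self):
        groups = [self.indispensable, *self.classes, self.redundant, self.irrelevant]
        union = set().union(*groups)
        if sum(len(g) for g in groups) != len(union):
            raise ValueError("ground-truth groups must be disjoint")
        if any(not c for c in self.classes):
            raise ValueError("each equivalence class needs at least one member")

    @property
    def universe(self) -> frozenset:
        return frozenset().union(
            self.indispensable, *self.classes, self.redundant, self.irrelevant
        )

    def to_dict(self, feature_names=None) -> dict:
        def conv(fs):
            return sorted(feature_names[i] if feature_names else int(i) for i in fs)

        return {
            "indispensable": conv(self.indispensable),
            "classes": [conv(c) for c in self.classes],
            "redundant": conv(self.redundant),
            "irrelevant": conv(self.irrelevant),
        }

    def save(self, path, feature_names=None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(feature_names), indent=1) + "\n")


def generate(spec: SyntheticSpec) -> tuple:
    """Draw one dataset according to ``spec``; returns ``(Dataset, GroundTruth)``.

    The linear predictor is ``beta * (sum of indispensables + sum of class
    latents)``; the continuous outcome adds unit Gaussian noise, the binary
    outcome passes it through a logistic link. Redundant features equal the
    linear predictor plus Gaussian noise of standard deviation 2. Column
    order is shuffled by the seed so feature role is independent of position.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    columns = []
    roles = []  # parallel list of (kind, class_index)

    indisp = rng.standard_normal((n, spec.n_indispensable))
    for j in range(spec.n_indispensable):
        columns.append(indisp[:, j])
        roles.append(("indispensable", None))

    latents = rng.standard_normal((n, len(spec.class_sizes)))
    for k, size in enumerate(spec.class_sizes):
        for _ in range(size):
            columns.append(latents[:, k] + spec.epsilon * rng.standard_normal(n))
            roles.append(("class", k))

    linpred = spec.beta * (indisp.sum(axis=1) + latents.sum(axis=1))
    if spec.outcome is OutcomeType.CONTINUOUS:
        y = linpred + rng.standard_normal(n)
    else:
        prob = 1.0 / (1.0 + np.exp(-linpred))
        y = (rng.random(n) < prob).astype(float)
        if y.min() == y.max():  # pathological draw; flip one sample
            y[0] = 1.0 - y[0]

    # Redundant features are noisy proxies of the linear predictor: they are
    # marginally informative for the outcome but exactly independent of it
    # given the true predictors, so they sit in no minimal solution. (A noisy
    # copy of the outcome itself would NOT be redundant: it would stay
    # dependent on the outcome given the predictors, i.e. be part of every
    # blanket.)
    for _ in range(spec.n_redundant):
        columns.append(linpred + 2.0 * rng.standard_normal(n))
        roles.append(("redundant", None))
    for _ in range(spec.n_irrelevant):
        columns.append(rng.standard_normal(n))
        roles.append(("irrelevant", None))

    order = rng.permutation(len(columns))
    X = np.column_stack([columns[j] for j in order])
    names = tuple(f"F{i + 1}" for i in range(len(columns)))
    dataset = Dataset(X=X, feature_names=names, y=y, outcome_type=spec.outcome)

    placed = {}  # role -> indices after shuffling
    class_members = {k: set() for k in range(len(spec.class_sizes))}
    for new_pos, old_pos in enumerate(order):
        kind, cls = roles[old_pos]
        if kind == "class":
            class_members[cls].add(new_pos)
        else:
            placed.setdefault(kind, set()).add(new_pos)
    truth = GroundTruth(
        indispensable=frozenset(placed.get("indispensable", set())),
        classes=tuple(
            frozenset(class_members[k]) for k in range(len(spec.class_sizes))
        ),
        redundant=frozenset(placed.get("redundant", set())),
        irrelevant=frozenset(placed.get("irrelevant", set())),
    )
    return dataset, truth


def enumerate_true_solutions(truth: GroundTruth) -> SolutionSet:
    """The exact minimal-solution family: all indispensables plus one member
    per equivalence class (Cartesian product; a single solution if there are
    no classes)."""
    choices = [sorted(c) for c in truth.classes]
    solutions = [
        Solution(set(truth.indispensable) | set(pick))
        for pick in itertools.product(*choices)
    ]
    solutions.sort(key=lambda s: s.features)
    return SolutionSet(solutions)


def toy_discrete(name: str) -> tuple:
    """Small printed discrete joints used to illustrate equivalence notions.

    ``peq_accuracy_toy``: binary T, X with P(T=1|X=1)=0.9, P(T=1|X=0)=0.6,
    P(X=1)=0.5 - the accuracy-optimal rule ignores X, so accuracy is an
    improper criterion for equivalence.
    ``xor_toy``: fair independent coins W, X, Y with T = W or (X xor Y) -
    {X, W} and {Y, W} are model-equivalent but not information-equivalent.

    Returns ``(joint, labels)`` where ``joint`` is a 2 x m array (rows: T=0,
    T=1; columns: feature configurations) and ``labels`` names the columns.
    """
    if name == "peq_accuracy_toy":
        # columns: X=0, X=1
        joint = np.array(
            [
                [0.5 * 0.4, 0.5 * 0.1],  # T=0
                [0.5 * 0.6, 0.5 * 0.9],  # T=1
            ]
        )
        return joint, [(0,), (1,)]
    if name == "xor_toy":
        labels = list(itertools.product((0, 1), repeat=3))  # (W, X, Y)
        joint = np.zeros((2, len(labels)))
        for j, (w, x, y) in enumerate(labels):
            t = int(bool(w) or bool(x ^ y))
            joint[t, j] = 1.0 / 8.0
        return joint, labels
    raise ValueError(f"unknown toy distribution {name!r}")
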