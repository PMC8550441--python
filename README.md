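# equiset

**Discovery, statistical testing and compact representation of multiple
equivalent minimal predictive feature sets (Markov blankets).**

Most feature-selection methods return a single solution. In domains with
built-in redundancy — molecular biology and epidemiology above all — several
feature sets are often *statistically equivalent*: each is minimal and each
predicts the outcome as well as the others. Reporting one of them and
discarding the rest is misleading for knowledge discovery (a biomarker left
out of the one reported signature is not "superfluous", it may sit in an
equally good signature). `equiset` finds the whole family.

## What it computes

For a dataset with features **F** and outcome *T*, a **solution** (Markov
blanket) is a minimal set **S** ⊆ **F** with *T* ⊥ **F**∖**S** | **S**. The
package implements:

* **FBS** — greedy forward–backward selection driven by conditional-
  independence tests: the Fisher-z partial-correlation test for continuous
  outcomes, a logistic likelihood-ratio test for binary ones. Returns the
  *reference* solution **S**.
* **TMFBS** — a backtracking extension of the same search that visits every
  admissible branch exactly once (each explored candidate is excluded from
  the datasets seen by its later siblings, which provably equals re-running
  on the embedded dataset) and returns every candidate that a statistical
  equivalence decision accepts against the reference. Three sound pruning
  rules, all consequences of "a dataset without an equivalent solution has
  no equivalent solution in any of its embedded datasets", cut the search.
* **Equivalence testing** — the recommended two-stage decision: a paired
  sign-swap permutation test on the variance of the per-sample
  log-likelihood differences (Vuong's variance statistic) as a cheap
  filter, then *information equivalence* via two likelihood-ratio tests of
  each set against the model on the union (*T* ⊥ **X** | **Y** and
  *T* ⊥ **Y** | **X**). A J-test variant and a predictions-based
  model-equivalence permutation test are also provided.
* **TIE\*-IGS** — the classical alternative algorithm with the same
  guarantees, sharing tests, levels and counters, as a head-to-head
  baseline. Counted CI tests are the hardware-independent runtime proxy.
* **MSG** — the *multiple solutions graph*, a single-root single-leaf DAG
  that losslessly compresses the family: every root-to-leaf path with one
  feature-set choice per node is a solution. Built greedily (star graph,
  forward/backward factoring of shared features, OR-merging of
  interchangeable nodes) and exportable to Graphviz DOT.
* A **synthetic generator** that plants indispensable features,
  near-deterministic equivalence classes, redundant and irrelevant
  features, with the exact solution family enumerable in closed form.

## Worked example

```python
import equiset as eq

spec = eq.SyntheticSpec(n_samples=2000, n_indispensable=2, class_sizes=(2, 3), seed=3)
dataset, truth = eq.generate(spec)
config = eq.SearchConfig(alpha=0.001, seed=3)

family, stats = eq.run_tmfbs(dataset, config, counter=eq.TestCounter())
baseline, tie_stats = eq.run_tie_star_igs(dataset, config, counter=eq.TestCounter())
```

Two indispensable features plus one equivalence class of 2 near-copies and
one of 3 are planted, so 2 × 3 = 6 minimal solutions exist. The run prints:

```
reference : ['F3', 'F4', 'F6', 'F8']
equivalent: ['F3', 'F4', 'F5', 'F8']
equivalent: ['F3', 'F4', 'F8', 'F11']
equivalent: ['F3', 'F4', 'F6', 'F10']
equivalent: ['F3', 'F4', 'F5', 'F10']
equivalent: ['F3', 'F4', 'F10', 'F11']
search CI tests: 236
TIE*-IGS identical: True | TIE* search CI tests: 467
indispensable: ['F3', 'F4']
replaceable  : ['F5', 'F6', 'F8', 'F10', 'F11']
MSG nodes: 5 | decoded: 6
```

All six planted solutions are found; F3 and F4 appear in every solution
(indispensable), the class members are replaceable, and the baseline
returns the identical family at roughly twice the number of search tests.
The six solutions compress into an MSG with three inner nodes, and decoding
the graph recovers exactly the six sets.

A command-line layer exposes the same steps
(`equiset select | multi | msg | simulate | benchmark`); see
`equiset --help`.

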