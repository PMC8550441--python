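# Methods

## Problem and model

Given an n × p numeric data matrix and an outcome *T* (continuous or binary
{0,1}), a *solution* to the feature-selection problem is a Markov blanket of
*T*: a minimal-size set **S** with *T* ⊥ **F**∖**S** | **S**. When the data
contain interchangeable features — copies, near-deterministic transforms,
biologically redundant measurements — the blanket is not unique, and the
object of interest is the family **M** of all minimal sets statistically
equivalent to a reference solution **S**. All model fitting is by linear
Gaussian regression (continuous outcomes) or logistic regression (binary
outcomes); the conditional-independence tests and the equivalence tests are
exact within these model families and are asymptotic likelihood-ratio or
Fisher-z tests otherwise. Correct specification is assumed throughout;
no misspecification-robust corrections are attempted (degenerate or
ill-conditioned fits are flagged and treated conservatively instead).

## Conditional-independence tests

*Continuous outcome* — Fisher-z: the sample partial correlation r of
feature x with T given conditioning set **Z** is read off the inverse of
the covariance matrix over {x, T} ∪ **Z**; the statistic
√(n − |**Z**| − 3) · atanh(r) is referred to N(0,1), two-sided. Because the
package deliberately hunts near-duplicate features, near-singular
covariances are routine: above condition number 1e10 a ridge jitter of
1e-8·I is added and the result flagged; r is clipped to ±(1 − 1e-12)
before atanh.

*Binary outcome* — nested logistic likelihood-ratio: deviance(Z) −
deviance(Z ∪ {x}) against χ²(1). Logistic fitting is Newton–IRLS with
step-halving, tolerance 1e-8 on the log-likelihood, at most 100 iterations;
on non-convergence both nested models are refit once with an L2 penalty of
1e-6 on slopes (the same penalty on both keeps the LRT comparison fair) and
flagged. Slopes exceeding 15 in absolute value are treated as
(quasi-)separation and flagged; probabilities are clipped to
[1e-12, 1 − 1e-12] before logs so likelihood vectors stay finite.

Flagged tests contribute p = 1 wherever the search consumes p-values: a
feature is never selected, and never retained by the backward phase, on the
strength of a degenerate test.

Every test call increments a counter with separate search-phase and
equivalence-phase tallies. Counted tests, not wall-clock time, are the
comparison metric between search algorithms: equivalence tests are common
to all algorithms, so only search tests are compared.

## The searches

**FBS.** Forward phase: repeatedly test every active unselected feature
given the current selection, keep those with p < α sorted ascending (ties
broken toward the lower column index, making runs reproducible), select the
first, until no candidate remains. One backward pass then repeatedly drops
the selected feature with the largest conditional p-value strictly above α.
The ordering satisfies the admissibility contract that deleting a prefix of
it equals recomputing it on the dataset with that prefix excluded; this
tail property is load-bearing for the multiple-solutions search and is
tested directly.

**TMFBS.** The forward phase is a search over feature sets; instead of
following only the top candidate, the search backtracks over all of them,
excluding each explored candidate from the datasets seen by its later
siblings (equivalent to re-running on the embedded dataset, so no selected
set is ever visited twice — verified by instrumentation). The first leaf
reached is exactly the FBS output and becomes the reference; later
candidates join **M** iff the equivalence decision accepts them. Pruning:

* *Rule 2* (checked before each descent): skip a branch whose exclusion set
  extends one already known to yield no equivalent solution. Failed
  exclusion sets are kept as a minimal antichain — supersets are implied
  and discarded.
* *Rule 1* (after a child returns): if the child's subtree contributed no
  new solution, its remaining siblings — whose datasets are embedded in the
  child's — are abandoned, and the child's exclusion set is recorded as
  failed.
* *Rule 3* (after a child returns): if the child contributed solutions but
  none contains the branching candidate, that candidate was a forward-phase
  false positive removed by the backward phase, and the remaining siblings
  would reproduce the child's results; they are skipped.

The rules' soundness is a corollary of the completeness theorem for the
search, which presumes a *correct* equivalence decision. That conditionality
matters in practice: with the finite-sample statistical decision, a type-I
rejection of a true equivalent makes Rule 1 abandon siblings that would
have produced accepted solutions. The pruning-soundness tests therefore run
under an exact (planted ground-truth) equivalence oracle, the regime the
theory covers, and that distinction is deliberate. Duplicate candidates
(reachable through backward-phase convergence from different branches) are
silently dropped and count as "nothing new" for Rules 1 and 3.

The search is an explicit-stack depth-first traversal (identical behavior
to the recursive formulation, no recursion-depth limit). `max_solutions`
(default 1000) and `max_visited_states` (default 100000) bound the search;
hitting either sets a `limit_hit` flag in the run statistics rather than
raising, because a potentially exponential number of solutions is a
property of the problem, not a failure of the program.

**TIE\*-IGS baseline.** Finds the reference on the full data, then
maintains a worklist of embedded datasets generated incrementally: each
accepted solution found under exclusion set E proposes E ∪ {x} for each of
its members, filtered against already-processed exclusion sets and the
failed-exclusion cache. Proposals are processed FIFO after sorting by
(size, lexicographic), each at most once. No test results are cached across
inner runs, so the counter comparison reflects the genuine cost of
restarting the single-solution algorithm per candidate. Non-equivalent
candidates are not expanded (the stricter reading of the generator; with
erroneous tests a looser reading could only add candidates, not remove
any).

Both searches share the same equivalence decision, memoized per candidate
set with permutation seeds derived deterministically from
(config seed, sorted candidate, sorted reference); identical candidates
therefore receive identical verdicts in either algorithm and in any
discovery order, which is what makes family-level agreement between the two
algorithms a meaningful test.

## Equivalence of feature sets

Three nested notions: *performance* equivalence (equal expected loss),
*model* equivalence (identical optimal predictions) and *information*
equivalence (*T* ⊥ **X** | **Y** and *T* ⊥ **Y** | **X**). Information
equivalence is the strictest, is learner-independent, and is the right
criterion when candidates are Markov blankets; the two weaker notions admit
pathologies (complementary signals are performance-equivalent without being
interchangeable; improper losses such as accuracy can equate a genuinely
informative set with the empty set — the package's discrete-toy
computation of the best deterministic-rule accuracy exists to exhibit
exactly that case).

The implemented decision is the recommended two-stage pipeline:

1. **Permutation variance filter.** Fit one model per set, take per-sample
   log-likelihood vectors, and test Vuong's variance statistic — the
   sample variance (denominator n) of the per-sample differences — by
   pairwise sign-swap permutation: each of B permutations independently
   swaps, with probability 1/2 per sample, which model each paired value
   came from, and the p-value is (1 + #{sᵢ ≤ s})/(B + 1), counting the
   observed statistic among the permutations so the p-value is never zero.
   The test is one-sided, rejecting for *small* observed variance relative
   to the sign-swapped distribution: if the mean per-sample difference is
   nonzero, random sign flips move that mean into the variance, the
   permuted statistics stochastically dominate the observed one, and the
   p-value collapses — so the left-tail count detects exactly the
   systematic model differences the filter is meant to catch. Under the
   exactly-degenerate null (identical vectors) the p-value is 1.
2. **Information-equivalence test** via the comprehensive approach: fit the
   union model and run two multi-degree-of-freedom likelihood-ratio tests,
   adding all of **Y**∖**X** at once (dof = number of added features) and
   vice versa. Equivalent iff both directions have p ≥ α_eq.

The candidate is equivalent iff both stages pass. A candidate that is a
strict superset of the reference passes by construction — minimality is the
backward phase's responsibility, not the equivalence decision's. The J-test
(model predictions appended as single synthetic features, avoiding the
union fit) and a predictions-based variant of the permutation test are
provided as cheaper alternatives but are not part of the default decision.
Losses that cannot be computed per sample (AUC) are out of scope for the
permutation filter.

## Synthetic data

The generator plants, around a linear predictor β·(Σ indispensables +
Σ class latents): *indispensable* features (iid N(0,1)); *equivalence
classes* whose members are latent + ε·N(0,1) near-copies; *redundant*
features equal to the linear predictor plus N(0, 2²) noise; *irrelevant*
iid N(0,1) noise. The continuous outcome adds N(0,1) noise; the binary
outcome uses a logistic link on the same predictor. Columns are shuffled
per seed. The true family is the Cartesian product "indispensables plus one
member per class", enumerated in closed form.

Parameter defaults and rationale: ε = 1e-3 — exact copies make covariance
matrices singular and partial correlations undefined, while 1e-3 keeps the
copies statistically indistinguishable at the sample sizes used (the
deterministic-copy ideal is the ε → 0 limit); β = 1 — equal magnitudes
avoid near-cancellation pathologies; redundant noise sd 2 — marginally
detectable, conditionally null. Redundant features are proxies of the
*linear predictor*, not of the outcome: a noisy copy of the outcome itself
would remain dependent on the outcome given the true predictors (it would
be a blanket member, not a redundant feature), which is easy to verify and
is the reason this construction was chosen.

What the generator does not emulate: heavy tails, nonlinear links,
interactions (in particular the XOR-style construction in which two sets
are model-equivalent but not information-equivalent — it violates the
main-effects model class of the tests and is represented only as an exact
discrete distribution for enumeration), correlated noise across features,
and missing data. Passing tests on this generator therefore demonstrate
the search and decision machinery under the tests' own model assumptions,
not robustness to their violation.

## Evaluation suite and problem sizes

The synthetic evaluation suite is 50 datasets — class structures [], [2],
[3], [2,2], [2,3] crossed with ten seeds — at n = 2000 with two
indispensable, one redundant and three irrelevant features. The searches
run it at α = 0.001: with unit-strength signals at n = 2000 every true
predictor is overwhelmingly significant, and the strict level plays the
role of the tuned selection threshold that the full protocol chooses by
validation-set search (at α = 0.05 a noise feature slips into the
reference in roughly a fifth of runs, which is a property of unadjusted
multiple testing, not of the search). α_eq = 0.05 and B = 1000 throughout.
Calibration checks use 1000 null replicates (Kolmogorov–Smirnov at level
0.001), 500 type-I replicates and 200 power replicates at n = 500; the
sample-size trend uses ε = 0.05 copies over n ∈ {200, 500, 1000, 2000}
with 20 seeds per size.

## Known limitations

* **Exact-family recovery degrades geometrically with family size.** Each
  non-reference candidate must pass one permutation filter and two
  directional LRTs, each at level α_eq = 0.05, so a true equivalent is
  rejected with probability ≈ 0.12; a six-solution family survives intact
  in only about half of the runs, and the suite-wide exact-recovery rate
  measured here is ~0.86. This is inherent to the decision levels, not to
  the search: under an exact equivalence oracle the search recovers every
  planted family. Applications that need higher per-family recall should
  lower α_eq, at the cost of more falsely accepted solutions.
* Pruning Rules 1–3 are sound relative to the equivalence decision they
  are given; with noisy decisions, pruned and unpruned runs can return
  different families (observed on a few percent of suite instances).
* The MSG construction is greedy and lossless but not minimal; only
  losslessness and the per-operation accounting (a forward/backward merge
  of k nodes sharing F′ removes (k−1)·|F′| stored features; an OR merge
  removes k−1 nodes and no features) are claimed and tested. Decoding is
  exponential in the worst case and guarded by a 10,000-combination cap.
* Classifying features *outside* all solutions into redundant vs irrelevant
  requires deciding an existential over all conditioning contexts; no
  tractable procedure exists, so they are reported as a single bucket.
* Only main-effects linear/logistic tests are provided; under model
  misspecification the tests' levels are not guaranteed.
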