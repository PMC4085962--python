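# Methods

`ordevo` measures how well standard phylogenetic comparative machinery can
detect *ordered* (stepwise) evolution of a four-state discrete trait — a
trajectory `1 → 2 → 3 → 4` in which "skip" transitions (1→3, 1→4, 2→4) are
forbidden — using only a phylogeny and the trait values of its living tips.
Everything is simulation: trees, characters, inference and classification are
generated and evaluated inside the package.

## Model and procedure

**Trees.** Substrate trees are Kingman-coalescent genealogies: starting from
`n` lineages, the waiting time while `k` lineages persist is
`Exponential(k(k-1)/2)` and a uniformly chosen pair merges; the result is
rooted, binary and ultrametric with expected depth `2(1 − 1/n)` coalescent
units. Branch lengths are used as-is (no rescaling): the generating rates
below are per coalescent time unit, so a depth-2 tree sees on the order of a
few expected events per lineage at rate 1.

**Generating models.** Character change is a continuous-time Markov chain
with generator `Q` (rows sum to zero; off-diagonal cell `(i,j)` is the i→j
rate). The generating catalog crosses ordered/unordered ×
reversible/non-reversible × four rate-pattern classes (equal rates, all rates
different, symmetric pairs, high exit rates from the intermediate states
2 and 3), 16 matrices in all, with allowed cells holding the integers 1–3 as
*relative* rates. Non-reversible matrices forbid every backward transition,
which makes state 4 absorbing (a zero row). The equal-rates matrices are
fully determined by their class; for the other three classes the integer
assignments are a convention, frozen in `qmatrices.py` and chosen to honour
the class definitions while keeping all 16 matrices numerically distinct — in
particular the non-reversible "symmetric pairs" slot, where no reverse rates
exist, is filled with all allowed rates = 2 so it does not collide with the
equal-rates (all 1) or all-rates-different (1,2,3) matrices. Substituting
different assignments is a one-file edit.

**Character simulation.** Each branch's transition matrix is
`P(t) = expm(Q t)` (scipy). Simulation samples branch endpoints in one
preorder pass — the root takes state 1, each child is drawn from the
parent-state row of its branch's `P(t)` — which has exactly the marginal law
of the full jump process (verified against a Gillespie oracle in the tests).
Root state 1 is the trajectory's origin and the only state from which
non-reversible ordered chains can reach all four states. A simulated dataset
is *retained* only if all four states appear among the tips; per (tree,
matrix) the first 10 retained of at most 200 attempts are kept, and
shortfalls are logged and counted, never padded.

**Taxon-sampling sensitivity.** The pruned regime removes
`floor(n/2)` tips uniformly at random (state-blind) together with their
data, splices out the resulting degree-2 nodes by summing branch lengths,
and keeps the original root so depths are unchanged. Pruning is *paired*:
each retained dataset is refit after pruning with a seed derived from the
same design cell, so the accuracy drop is estimated within-dataset. Pruned
datasets that lose a state are dropped and counted. The 15-taxon group is
exempt (already small), enforced by `prune_exempt_sizes` in the config
rather than silently.

**Inference.** The analysis step pretends no knowledge of the generating
model: it fits the 12-parameter all-rates-different (ARD) 4-state Markov
model by maximum likelihood. The likelihood is the Felsenstein pruning
algorithm with per-node rescaling (accumulated log factors) so 1000-tip
trees do not underflow; the root prior is flat (1/4 per state, the
conventional default; configurable). The 4×4 matrix exponential inside the
optimizer is a scaling-and-squaring Taylor kernel (numba): several catalog
matrices are defective (the non-reversible equal-rates generator is a
Jordan block), so an eigendecomposition route would be numerically unsafe
exactly where it matters. Optimization is box-constrained L-BFGS-B on the
raw rates, bounds `[0, 100]`, five restarts from log-uniform initial values
on `[0.01, 10]`, function/gradient tolerances `1e-8`, at most 2000
evaluations per restart; the best converged optimum wins, ties broken by
first occurrence. Rates estimated at zero land exactly on the lower bound —
deliberate, because the strictest classification rule asks whether the skip
rates *are* zero. Fits for which no restart converges are flagged, counted
in the run manifest and excluded from classification, the same treatment
the retention rule gives datasets that never realize all four states.

**Classification.** Only the forward rates are judged: skip cells B (1→3),
C (1→4), F (2→4) against trajectory cells A (1→2), E (2→3), I (3→4), using
the letter layout of the estimated-rate table. Three thresholds call a fit
"ordered": *strict* — B, C, F all ≤ `zero_tol` (default `1e-5`, absorbing
optimizer round-off at the bound; `sweep_zero_tol` quantifies the
sensitivity); *absolute* — all < 0.1; *relative magnitude* — each at least
one order of magnitude below `mean(A, E, I)`. Accuracy is the proportion of
ordered-generated datasets called ordered; type-I error the proportion of
unordered-generated datasets called ordered; both are pooled over matrices,
trees and replicates within a (tree size × threshold × regime) cell, with
counts reported and empty cells reported as missing rather than 0/0.

## Seeding and determinism

Every stage draws from a stream derived from the master seed via
`numpy.random.SeedSequence` spawn keys indexed by design-cell coordinates
(stage, tree size, ordering, tree index, matrix index, replicate). Any
single simulation or fit is therefore re-runnable in isolation, results are
independent of execution order, and two runs with the same master seed are
identical.

## Problem sizes

The full design (20 trees × 8 matrices × 10 retained datasets per ordering
per size, four sizes, paired pruning) is what `ExperimentConfig()` defaults
to. The test suite and `scripts/acceptance.py` run the design scaled down:
5 trees × 5 datasets for the 15-taxon group, 20 trees × 5 datasets for the
50-taxon pruning comparison, one tree × 4 datasets per matrix for the
1000-taxon checks (run qualitatively — ordering against the 15-taxon
values — rather than against absolute percentages), and 1000-replicate
Monte-Carlo checks for distributional properties. At these sizes the pooled
proportions carry sampling error of several percentage points, which the
test tolerances reflect.

## Known limitations

- The synthetic data emulate the study conditions, not empirical datasets:
  clock-like ultrametric trees, a single character, no rate heterogeneity
  across branches, no state-biased taxon sampling (missing taxa are removed
  uniformly at random — empirical sampling is often biased toward fully
  evolved phenotypes, which this design cannot speak to).
- Absolute proportions under the looser thresholds are sensitive to
  optimizer conventions. Under box constraints the skip-rate estimates
  either sit exactly at zero or are of order one; small-but-positive
  residual estimates — which an unconstrained optimizer leaves and the
  relative-magnitude threshold is designed to absorb — are rare here
  (under 3% of skip cells in the 15-taxon runs). The relative-magnitude
  proportions therefore track the strict ones much more closely than in
  analyses built on unconstrained rate estimation; the strict-threshold
  and pruning results are robust to this choice. The same applies, more
  weakly, to the root-prior convention.
- The model-comparison alternative (fitting competing constrained models
  and selecting by likelihood score), stochastic-mapping transition
  tallies, and parsimony reconstructions are out of scope.
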