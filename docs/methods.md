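# Methods

## Model and procedure

`dxopt` treats a diagnostic rule as a pair (criterion subset, threshold T):
a subject is diagnosed when at least T of the subset's criteria are
endorsed. For K criteria the candidate space contains every nonempty subset
(2^K − 1 of them) at every feasible threshold, K·2^(K−1) rules in total —
11,264 for the 11 DSM-IV AUD criteria. The search is exhaustive by design;
no greedy or heuristic pruning is offered, because the rule space at K ≤ 11
is cheap to scan and heuristics would reintroduce exactly the arbitrariness
the method is meant to remove. Enumeration is guarded at K ≤ 24.

Three validity metrics are computed per rule from two-wave panel data:
persistence P(dx₂ | dx₁), Axis I comorbidity (the median Jaccard agreement
J = a/(a+b+c) between the Wave-1 diagnosis and each of the Axis I
disorders), and Axis II comorbidity (cluster medians combined with fixed
weights .1/.7/.2 for clusters A/B/C, reflecting the stronger association of
dramatic/erratic personality disorders with alcohol problems). These
metrics are unweighted subject counts: survey weights deliberately enter
only the external-validation stage, where population generalizability is
the question. The .5/.5 Axis I/Axis II split and the cluster weights are
configuration constants, not estimated quantities; freeing them would
explode the search space and change the question being asked.

Rules with zero Wave-1 prevalence have undefined persistence and vacuous
comorbidity; they are flagged invalid, carry no metric values (None, never
zero), and are excluded from ranking — they can never be selected. All
even-length medians use the mean of the two middle order statistics
(relevant for cluster B's four disorders).

## Scoring and optimization

The three metrics live on incommensurable scales, so each is replaced by a
rank-based inverse-normal score: ascending ranks with average ties,
percentile p = r/(N_valid + 1), z = Φ⁻¹(p). The r/(N+1) convention keeps
percentiles strictly inside (0, 1), so no infinite quantiles arise at the
extremes; with all values tied every rank equals (N+1)/2 and the transform
collapses to z = 0 rather than erroring. The composite is

    S = α₁·z_persistence + (1 − α₁)·(.5·z_ax1 + .5·z_ax2)

on an 11-point α₁ grid (0 to 1 by .10). The S-maximizing valid rule wins at
each α. Exact ties (rules with identical diagnosis vectors have identical
metrics, hence identical S) break parsimony-first: fewer criteria, then
lower threshold, then lexicographically smallest bitmask. S percentiles
(used downstream) are descending ranks of S divided by the number of valid
rules, so the winner holds the smallest percentile.

A note on the transform: at α₁ ∈ {0, 1} the argmax is invariant to
replacing z by the raw rank, since a monotone transform cannot change a
single-metric argmax. For interior α the inverse-normal stretch of the
rank extremes *can* change the argmax of the linear combination relative
to raw ranks; the test suite asserts the invariance only where it is a
theorem.

## Internal validation

The sample is split into k = 5 seeded folds (sizes differing by at most
one; 15,773 subjects split 3,154/3,154/3,155/3,155/3,155) and the
optimization runs per fold per α — 55 candidate solutions. Two selectors:

* **Min-max cross-validation.** Each discovered rule is re-scored in every
  fold that did not discover it; the cell percentile is computed against
  that fold's full ranking of all 11,264 rules. A rule discovered under an
  α-range is evaluated at each α in its range and the cell takes the mean
  (the evaluation-α convention is genuinely open; the mean is the least
  arbitrary summary of a range). A rule invalid in an evaluation fold takes
  the worst percentile, 100. The row score is the maximum cell and the
  winner minimizes it ("least worst"). Reference rules (DSM-IV dependence
  3-of-7, DSM-5 2-of-11) can be appended to the matrix for comparison but
  do not compete for the winner.
* **Consensus voting.** Each criterion's vote is the share of the 55
  solutions containing it; duplicated rules within a fold count once per α
  combination, keeping the denominator at k·|grid|. Criteria with votes ≥
  cutoff (default .60) form the final set; the final threshold is a fixed
  configuration constant (default 2) rather than a searched quantity, to
  rule out single-criterion diagnoses. Fewer retained criteria than the
  minimum threshold raises a selection error prompting a cutoff change.

## External validation

Two rules are compared by cross-classifying Wave-1 diagnoses into
Both / A-only / B-only / Neither and testing three planned contrasts
(A-only vs B-only, A-only vs Both, B-only vs Both) on each validator.
The test is a weighted Welch comparison: weighted means, weighted variances
normalized so unit weights reproduce the sample variance, effective sample
sizes n_eff = (Σw)²/Σw², and Welch–Satterthwaite degrees of freedom. With
unit weights this is exactly the ordinary Welch t test (verified against
`scipy.stats.ttest_ind`). This is a model-based use of the weights, not
design-based survey inference: Taylor-linearization or replicate-weight
variance estimation is out of scope, and p-values under informative
clustered designs will be anticonservative to an unknown degree — a known
limitation. Binary validators run through the same machinery as 0/1
values (differences of weighted proportions). Planned comparisons are
reported unadjusted; a Benjamini–Hochberg flag is available.
Validator missingness is handled pairwise; groups with n_eff < 2 are
marked non-estimable rather than raising.

## Synthetic-data generator

The generator emulates the structure of a two-wave epidemiological alcohol
survey. Latent severity θ₁ ~ N(0,1) persists as θ₂ = ρθ₁ + √(1−ρ²)·ε with
ρ = .85 by default — chosen so that dependence-style rules show the
roughly 40–50% one-wave persistence typical of AUD diagnoses. Criterion j
is endorsed at wave w with probability logistic(a_j(latent_w − b_j)).
Six criteria (Cut Down, Time Drinking, Continue, Withdrawal, Home/Job,
Fight/Trouble) load on θ at discrimination 1.5; the other five load on a
*shared transient factor redrawn each wave* at discrimination 0.8, so they
carry within-wave correlation but no cross-wave stability — this is
precisely the signal that lets the optimizer prune them. Difficulties b_j
are solved by Gauss–Hermite quadrature root-finding so marginal endorsement
rates hit their targets, which default to the Wave-1 endorsement
percentages of the 11 DSM-IV criteria in the survey application (from 9.0%
for Larger/Longer down to 0.66% for Give Up).

Comorbid disorders are thresholded liabilities λ·θ₁ + √(1−λ²)·ε at target
lifetime prevalences (e.g. major depression .20, dependent PD .005), with
cluster B loading hardest (λ = .45 vs .30–.35), matching the rationale for
the cluster weights. External scales are 50 + γθ₂ + noise with total SD 10
(γ = −3 for health scales, +4 for consumption); binary validators are
Wave-2 disorder indicators plus a rare craving item driven by θ₂. Weights
default to a unit-mean gamma(4) family to mimic survey-weight dispersion.
A prevalence target with |Φ⁻¹(p)| > 6 is rejected as unreachable.

What the generator does *not* emulate: the survey's sampling design and
oversampling, item-level measurement error, criterion-specific residual
correlations, informative weight–outcome coupling, and secular drift in
endorsement between waves. Passing tests therefore demonstrate that the
machinery recovers planted structure under a well-specified latent-severity
model, not that it would recover the same rule from the real survey.

## Problem sizes and numerical choices

Profiling all 11,264 rules is vectorized by grouping rules by subset and
comparing endorsed-criterion counts against all thresholds at once
(~1 s per fold of 2,000–3,000 subjects); a full 5-fold pipeline at
N = 10,000 runs in a few seconds. The test suite uses N = 10,000 with 10
replicate seeds for planted-structure recovery, N = 50,000 for one-shot
calibration checks of the generator, and 250–1,500 subjects for oracle
comparisons against a plain-Python brute-force reimplementation at K ≤ 4
(32 rules). Weight/float tolerances: cluster and α weights validated to
1e-9; consensus cutoff comparison uses a 1e-12 slack so a vote printed as
.60 survives a .60 cutoff. All simulation entry points take a mandatory
seed and are byte-reproducible; the pipeline manifest records seed,
package version, and a configuration hash.

## Design choices where the design was open

* **Percentile convention** r/(N+1) for the inverse-normal transform
  (avoids ±∞ at the extremes).
* **Tie-breaking** parsimony-first (size, threshold, bitmask) — fixed so
  results are reproducible across runs and platforms.
* **Evaluation α in cross-validation**: mean percentile across the
  discovering α-range per cell.
* **Missing data**: complete-case on criterion and comorbidity columns
  only (dropped rows are counted and reported); pairwise deletion for
  external validators.
* **Past-year-drinker filtering** is left to the caller/schema rather than
  enforced: the package analyzes whatever rows the input provides.
* **Alternative agreement measures** (Yule's Q/Y, phi) are exposed behind
  the same counts interface for exploration, but Jaccard is the default
  and the only measure used by the optimizer.

## Known limitations

Weighted comparisons are model-based, not design-based (above). The
consensus threshold is a constant, not optimized. Axis II aggregation
across waves is delegated to the input schema (the package does not decide
which wave's lifetime measures feed the clusters). Graded severity output
and craving-based criterion sets are out of scope.
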