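# Methods

This note records the statistical procedures implemented in `mokkenpy`,
the defaults and numerical choices, what the synthetic generator does and
does not emulate, and the places where the classical Mokken-scaling
literature leaves details open and the package had to commit to one
construction.

## Models

Items are assumed to measure a single latent trait θ. The **monotone
homogeneity model (MHM)** assumes unidimensionality, local independence
(responses independent given θ) and monotone nondecreasing item (step)
response functions P(X_i ≥ s | θ). For binary items the MHM licenses
ordering respondents by the total score X₊. The **double monotonicity
model (DMM)** adds non-intersection of the response functions, which for
binary items yields an invariant item ordering (IIO): the same difficulty
ordering at every θ. For polytomous items non-intersection of the item
step response functions does not by itself imply IIO, which is why the
manifest MIIO check below operates on the items' conditional means.

## Scalability coefficients

`coef_h` computes H_ij = Cov(X_i, X_j) / Cov_max(X_i, X_j), with item and
scale coefficients as ratios of the summed numerators and denominators.
Numerical choices:

- Both covariance and maximum covariance use the population divisor N so
  the ratio is exactly the one an exhaustive enumeration over joint
  contingency tables with fixed marginals would produce; the test suite
  verifies this equivalence against such an enumeration oracle on random
  small instances.
- Cov_max is realized by the comonotonic (sorted, Guttman-ordered)
  coupling of the two marginal score distributions, which attains the
  Fréchet upper bound for any number of categories.
- Zero-variance items are an error, not silently dropped: an item whose
  responses do not vary cannot scale and silently excluding it would
  change the reported scale without the user noticing.
- Because H is a ratio of sums, it always lies between min H_i and
  max H_i when all pairwise denominators are positive (mediant property);
  this is asserted in the tests.

H^T applies `coef_h` to the transposed matrix. Respondents with constant
response patterns are dropped first: they carry no information about item
ordering and would be zero-variance "items" of the transposed problem.
Memory and time are quadratic in the number of respondents, so H^T is
intended for data sets of at most a few thousand respondents. The
polytomous H^T here is the transpose-based definition; no claim of exact
parity with other software's polytomous generalization is made.

The strength bands (0.3 / 0.4 / 0.5 for H, the same cut points for H^T)
are the conventional rules of thumb and are attached to the results as
labels, not enforced.

### Significance screen for H_ij > 0

The item-selection search needs a one-sided test of positive pairwise
association. The package uses the normal approximation
z = r_ij·√(N−1) on the item-pair correlation (positive correlation and
positive H_ij coincide whenever Cov_max > 0). This is a deliberate,
replaceable choice: any asymptotic test of positive association would do,
and the test object returned by `hij_positivity_test` exposes the raw z
and p values so a different rule can be applied. Pairs with Cov_max = 0
are flagged degenerate and not tested; samples with N < 10 are flagged.

## Automated item selection (aisp)

The bottom-up ("normal") search: among unassigned items, start a scale
from the pair with the largest H_ij that is significantly positive and at
or above the lower bound c (a two-item scale has H_i = H_ij, so the start
pair must clear c for the partition invariant to hold); then repeatedly
add the candidate that maximizes the scale's H subject to (a) significant
positive H_ij with every selected item and (b) *every* member's
within-scale H_i remaining ≥ c after the addition — enforcing the
invariant for all members, not only the newcomer, so a finished scale can
never contain an item below the bound. Ties on the resulting H are broken
by the larger summed Cov_max with the selected items, then by the lowest
item index, making the search deterministic. Items left when no valid
start pair exists are reported as unscalable (id 0). A genetic-search
strategy is not implemented; requesting one falls back to "normal" with a
warning.

Defaults c = 0.3 and α = 0.05 follow standard practice. `cutoff_sweep`
reruns the search over an ascending list of bounds to show fragmentation.

## Monotonicity diagnostics

For each focal item the restscore (total over the other items) replaces
θ. Groups are built ascending from the lowest restscore; a bucket smaller
than `minsize` merges into its right neighbour and a final undersized
group merges left — deterministic, and faithful to "adjacent groups are
joined". The default minsize rule is N/10 for N > 500, N/5 for
250 < N ≤ 500 and N/3 (at least 50) for N ≤ 250, truncated; the boundary
values 250 and 500 fall to the lower branch.

Per item step and ordered group pair, a decrease of the endorsement
proportion counts as a violation when it is strictly positive and at
least `minvi` (default 0.03). Each flagged decrease is tested with a
one-sided two-proportion z-test with pooled variance at the
per-comparison α (no multiplicity correction — the counts are
descriptive, and that is how the #zsig column is conventionally read).
The #ac count is R(R−1)/2 per step for R groups regardless of degenerate
proportions.

### The crit composite

The literature uses `crit` only through the screening rule "below 40 is
not serious" and publishes no formula. The package implements an
MSP-style weighted composite,

    crit = 50(0.30 − H_i) + √#vi + 100·#vi/#ac + 100·max vi
         + 10·√Σvi + 1000·Σvi/#ac + 5·max z + 10·√Σz + 100·Σz/#ac,

rounded, floored at 0, and defined as 0 when there are no violations.
This is the single under-specified statistic in the package: its
components (max/summed violation magnitudes and z statistics) are all
exported in the report so users can apply any rule they prefer, and no
bit-compatibility with other software is claimed.

## Invariant item ordering (MIIO)

Items are ordered by overall mean. For every pair with a strict expected
order, conditional means are compared within restscore groups, the
restscore excluding *both* items of the pair (otherwise the conditioning
score would mechanically depend on the compared items). A reversal of at
least `minvi` is a violation for both items; #ac counts one comparison
per group per pair. Pairs with exactly tied overall means are skipped
entirely: without a strict expected order there is nothing to violate.

Flagged reversals are tested one-sided with a **paired** t-test on the
within-respondent score difference. The two compared samples are the same
respondents' scores on the two items, so the paired test is the correct
one; a two-sample test would ignore the within-person correlation and
lose power. If the differences have zero variance the reversal is treated
as significant exactly when its mean is positive.

Backward selection removes one item per step — the item with the most
significant violations, ties broken by the lowest H_i — until no
significant violations remain or fewer than three items are left (a
warning). The trace reports each step's per-item significant-violation
counts with removed items marked NA, and H^T of the survivors is attached
with its accuracy band. Because each step removes exactly one item and at
least three must remain, the procedure terminates in at most k−2 steps;
the surviving set re-checks clean by construction (fixed point), which
the tests assert.

The binary non-intersection check is the same computation restricted to
dichotomous input. The MSCPM and IT method variants are not implemented.
The worked-example configurations ship `minvi = 0.18` for the IIO step
(a conventional choice for mean comparisons on published analyses of
this kind) while the programmatic default stays at 0.03.

## Molenaar–Sijtsma reliability

Rho estimates the reliability of X₊ as Cov(X₊, X₊′)/Var(X₊) for a
hypothetical independent replication X₊′. Writing p_a for the popularity
of binary step indicator a and π_ab for the joint endorsement proportion,
local independence makes the cross-replication covariance of steps of
*different* items equal to their observed covariance; for steps of the
same item — including each step with itself, the diagonal — the required
E[P_a(θ)P_b(θ)] is unobservable and must be inferred from the
popularity-ordered joint-proportion matrix, which is where
non-intersection enters: it justifies treating popularity neighbours as
surrogates.

The interpolation, isolated in one function for auditability, works on
steps sorted by descending popularity:

- **Interior diagonal entries** blend two estimators: the multiplicative
  stencil π_{a−1,a}·π_{a,a+1}/π_{a−1,a+1}, which is exact for
  deterministic Guttman (scalogram) data, and linear interpolation of the
  joint proportion in the two neighbours' popularities, which is accurate
  for smooth stochastic response functions. The blend weight is the
  observed scalability of the flanking pair (its pairwise H clipped to
  [0, 1]) — the data's own measure of how close the scale sits to the
  deterministic extreme, equal to 1 exactly there.
- **The most popular entry** is extrapolated log-linearly in popularity
  through its two nearest neighbours; on Guttman data the fitted slope is
  exactly 1, making the rule exact there. **The least popular entry**
  applies the same rule to reversed scorings.
- **Same-item off-diagonal entries** (polytomous data only) use the
  multiplicative stencil, with stencil entries that are themselves
  unobservable resolved by Gauss–Seidel sweeps to a fixed point.
- Every estimate is clamped to [p_a·p_b, min(p_a, p_b)], the band implied
  by monotone response functions.

Consequences verified by the tests: Rho = 1 exactly on deterministic
Guttman data (binary and polytomous); Rho ≈ 0 for independent items; and
on simulated DMM data (six binary items, N = 2000, 200 replications) the
mean Rho lies within ±0.02 of a parallel-replication oracle that
regenerates responses twice from the same θ draws, while Cronbach's alpha
stays below the oracle value, as theory says it must. Polytomous items
enter through their step indicators; the total score is unchanged.
Rho requires at least three non-constant items (the interpolation needs
two neighbours); alpha only two. `ms_rho` attaches a warning note unless
the caller declares that DMM diagnostics were run (`dmm_checked=True`),
since the estimate is only meaningful under non-intersection.

No exact numerical parity with any particular software implementation of
Rho is claimed — the construction above is the package's own, chosen for
the two verifiable anchors (scalogram exactness and replication-oracle
calibration).

## Synthetic data generator

The generator emulates the structure the diagnostics assume or violate:

- θ ~ N(0, 1) by default (standard IRT convention; a uniform option
  exists). Responses are drawn independently given θ, so local
  independence holds by construction.
- `logistic` items are graded-response style cumulative logistic steps
  with ordered thresholds; equal discriminations give non-intersecting
  response functions (a DMM scale), unequal discriminations cross.
- `step` items give deterministic (probabilistic-Guttman) responses;
  `generate_guttman` builds exact scalogram patterns directly.
- `unimodal` items rise then fall — the canonical monotonicity violation.
- `table` items have constant step probabilities — independent items with
  no trait signal.
- `inject_crossing_pair` forces two binary logistic items through the same
  probability at a chosen θ with different slopes; crossings placed beyond
  ±3 SD of the trait draw a low-power warning. `generate_blocks`
  concatenates blocks driven by independent traits to plant multi-scale
  structure.
- Seeds fully determine output (numpy `default_rng`; θ first, then one
  uniform block per item).

Default study conditions used across the tests: six binary items with
common discrimination 1.5 and locations −1.5 … 1.5 at N = 2000 — a
medium-strength scale (H ≈ 0.45) of the kind short mental-health
screening scales typically show; detection experiments use N = 4000 and
deviant discriminations 0.35 / 4.0 for planted crossings.

What the generator does *not* emulate: missing data mechanisms,
differential item functioning between groups, local dependence
(testlets), and respondent-level response styles. Passing tests therefore
show the diagnostics behave correctly under clean model conditions and
detect the planted violations; they do not show robustness to those
real-data complications.

`population_scalability` computes infinite-N coefficients by
Gauss–Hermite quadrature over θ (61 nodes by default) with the
comonotonic coupling applied to the population category distributions;
the tests check that sample H converges to it and that the population
coefficients are nonnegative under the MHM.

## Data handling

Input is a headered delimited file of integer category scores with a
configurable missing token. Missing responses are removed listwise before
any coefficient or diagnostic computation — every formula above assumes a
complete rectangle, and imputation is out of scope. Each item's scores
are shifted so the observed minimum is 0 (the shift is recorded);
scalability, monotonicity, IIO and reliability statistics are invariant
to such shifts, and a single 0..m convention removes ambiguity in
restscores and report tables. Per-item recode maps (e.g. the screening
dichotomization 1-2-3-4 → 0-0-1-1) must be total over the observed codes
and map onto consecutive scores starting at 0.

## Known limitations

- No standard errors or confidence intervals for H (deliberately out of
  scope).
- The H_ij positivity screen and the monotonicity z-tests are asymptotic
  and per-comparison; no multiplicity control.
- `crit` is a heuristic composite with no distribution theory.
- H^T is quadratic in respondents.
- Backward IIO selection is greedy; like all stepwise procedures it is
  not guaranteed to find the largest IIO-satisfying subset.
- The `aisp` search is the classical greedy bottom-up procedure; the
  monotone-fragmentation behaviour across cutoffs holds for structured
  data but is not a theorem for adversarial inputs.
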