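# Methods

## Model and estimation

The analysis treats p ordinal behavioral facets as nodes of a Gaussian
graphical model.  Facet scores are means of four 0–3 Likert items, so each
column takes at most 13 discrete values with pervasive ties and skew; the
estimator therefore works on nonparanormal-transformed data.

**Nonparanormal transform.** Per column: empirical CDF as rank/n with
average ranks for ties, truncated to [δ_n, 1 − δ_n] with
δ_n = 1/(4 n^{1/4} √(π log n)), then the standard-normal quantile
function.  The map is strictly increasing in the ranks, so it is invariant
to any strictly monotone transform of a column.  Pearson correlations are
computed on the transformed data (a Spearman option exists); polychoric
estimation is deliberately out of scope.  Correlation matrices estimated
from complete data are PSD by construction, but the eigenvalue-clipping
repair (`nearest_psd_correlation`) is exposed for externally supplied
matrices.

**Graphical lasso + EBIC.** The penalized problem
max log det Θ − tr(SΘ) − λ‖Θ‖₁(offdiag) is solved by the coordinate-descent
implementation in scikit-learn over 100 log-spaced penalties from
λ_max = max offdiag |S| (provably edge-free) down to 0.01·λ_max.  The
inner solver is treated as replaceable: the test suite checks the
solutions against an independent ADMM maximizer of the same objective to
1e−4, and against the closed-form limits (λ ≥ λ_max ⇒ empty graph;
λ = 0 ⇒ S⁻¹).  Selection minimizes

EBIC(Θ) = n·[tr(SΘ) − log det Θ] + E·log n + 4·E·γ·log p,

where E counts nonzero upper-triangle off-diagonal entries.  Constant
likelihood terms are dropped identically across the path, so selection is
unaffected; γ defaults to 0.5 (γ = 0 is ordinary BIC, larger γ sparser
networks); EBIC ties resolve toward the larger penalty (parsimony).
Edge weights are signed partial correlations −Θ_ij/√(Θ_ii Θ_jj).

**Centrality and communities.** One-step expected influence
EI_i = Σ_j w_ij is the centrality measure: unlike strength it preserves
edge sign, which is what makes "negatively embedded" nodes visible.  A
two-step variant (adding weight-propagated neighbor influence) sits behind
a flag.  Z-scoring uses the sample (n−1) standard deviation; an
all-zero-edge network is assigned EI_z = 0 by convention.  The "top third"
is the round(p/3) highest-EI nodes, boundary ties broken by node label
order so the set is reproducible.  Communities come from walktrap
(random-walk distances, agglomerative merging, cut at maximum modularity)
run on absolute weights — random-walk transition probabilities require
non-negative weights, and estimated networks here are almost entirely
positive.  Walk length defaults to the algorithm's conventional 4.
Isolated nodes cannot host a random walk; they are removed before the walk
and re-attached as singleton communities.  The reported modularity is
recomputed directly from the membership and |w|, and is checked against
igraph's own value in the tests.

**Stability.** The case-dropping bootstrap refits the entire pipeline
(transform → correlation → path → EBIC → EI) on subsamples drawn without
replacement at drop proportions {0.1, …, 0.7, 0.75}, B = 1000 by default
(tests and the acceptance script use far smaller B; see below), and
correlates each subsample EI with the full-sample EI (Spearman by default,
Pearson by flag; the convention varies in practice).  The CS coefficient is
the largest drop proportion at which ≥ 95% of replicates reach ≥ 0.7;
failed or degenerate refits count as failures.  A proportion whose retained
sample would fall below p + 1 is skipped with a warning.

**Two-step linkage and relevance flags.** Step 1 computes Spearman
correlations between *raw* facet scores and each condition's T scores
(rank-based, matching the ordinal facet scale; Pearson by flag); rows with
a missing condition value are dropped per condition.  Step 2 correlates,
across the p nodes, standardized expected influence with each Step-1
column (Spearman, two-sided p from the t approximation).  Note the Step-2
correlation lives on node-level points — p observations, df p − 2 —
regardless of the participant count that produced them.  The relevance
threshold is the mean of all signed p×q Step-1 entries, rounded to 4
decimals before comparison so flags are exactly reproducible; cells with
step1 ≥ threshold are "clinically relevant" when the node is in the top
third and "differential-diagnosis" markers otherwise.  The two flag sets
exactly partition the above-threshold cells.

**Redundancy screen.** For each node pair correlating at |r| ≥ 0.50, every
third node contributes a Hittner–May–Silver back-transformed-average
Fisher-z test of ρ(i,k) = ρ(j,k); the pair is flagged redundant when fewer
than 25% of those tests are significant at α = 0.05.  The default pipeline
only reports the screen and keeps all p nodes (the facets are constructs of
a standardized instrument); `reduce_nodes` applies the suggestion, dropping
from each flagged pair the lower-variance member (ties drop the
lexicographically later label).

## Synthetic data generator

The generator emulates the data structure the analysis assumes, not any
particular instrument's norms.

- **True network.** Off-diagonal support is Bernoulli(within_prob) inside
  and Bernoulli(between_prob) between 4 near-equal communities; nonzero
  partial correlations have magnitude uniform in `weight_range` and are
  90% positive (estimated facet networks are dominated by positive
  partials).  Positive definiteness is enforced by a diagonal-dominance
  repair (diagonal raised to the absolute off-diagonal row sum + 0.1 where
  needed) followed by rescaling so the implied covariance is a correlation
  matrix; reported `true_partials` always refer to the post-repair matrix,
  which the tests verify by recomputation.
- **Facets.** Latent MVN draws from the inverse precision; each facet
  observed as the mean of 4 conditionally independent items (latent +
  N(0, 0.3) noise) discretized at latent cut points (−0.5, 0.5, 1.5),
  which induces the right skew typical of problem-behavior ratings.
- **Conditions.** T-score-like columns: standardized
  (loadings-weighted facet sum + Gaussian noise), affinely mapped to mean
  60, SD 12.  Each condition loads on 3 facets; residual noise is set so
  the loading combination explains R² ≈ 0.5 of each score.

**Default scenario (study scale).** n = 280, p = 27, q = 10,
within_prob = 0.4, between_prob = 0.02, weights U(0.28, 0.45).  The weight
range is chosen so post-repair partials clear the EBIC detectability bound
at this sample size: an edge is worth keeping only when its per-edge
likelihood gain ≈ n·ρ²/2 exceeds log n + 4γ·log p, i.e. ρ ≳ 0.30 at
n = 280, γ = 0.5, p = 27.  Weaker edges are real but undetectable at this
scale, which would make "recovery" tests measure the criterion rather than
the code.  **Well-separated scenario** (community recovery):
within_prob = 0.6, between_prob = 0.01, weights U(0.30, 0.45), making the
planted partition unambiguous.

What the generator does *not* emulate: instrument-specific facet
distributions and floor effects, age and sex structure, informant effects,
item-level factor structure beyond a single latent per facet.  Passing
recovery tests therefore show the estimator chain is correct under its own
assumptions — not that those assumptions hold for any particular cohort.

## Numerical choices

- Solver tolerance 1e−4 (duality gap and inner lasso), 200 iterations;
  the oracle comparison runs both solvers far tighter.
- λ = 0 is special-cased to the matrix inverse; a diagonal S short-circuits
  the path.
- EBIC edge counts use exact zeros from the coordinate-descent solver (no
  thresholding).
- Degenerate inputs: constant columns abort the nonparanormal transform
  with the column named; undefined correlations are recorded as missing
  with warnings; an edge-free network yields singleton communities and
  zero centrality rather than an error.
- One master seed; per-stage seeds derive from it via `SeedSequence`, so
  facet generation, condition noise and the bootstrap use independent
  reproducible streams.  Fixed seed ⇒ bit-identical artifacts.

## Problem sizes in tests and the acceptance script

Recovery checks run 20 seeds at the full study scale (n = 280, p = 27).
Bootstrap-heavy checks use reduced settings chosen to exercise the same
code paths at tractable cost: the reproducibility test uses p = 8,
n = 120, B = 100 on a 2-point drop grid; the acceptance script's CS uses
B = 50 on the full 8-point grid with a 20-point penalty path.  B = 1000
remains the library default for real analyses.

## Known limitations

- The Step-2 linkage p-values use the t approximation across p nodes;
  with p = 27 points they are indicative, not exact.
- The CS coefficient is grid-valued; values between grid points require a
  finer drop grid.
- Polychoric correlations, mixed graphical models (e.g. sex moderation),
  edge-weight bootstrap CIs and network plotting are out of scope; the
  network exports to GraphML/edge-list CSV for external visualization.
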