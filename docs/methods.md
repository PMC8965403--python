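# Methods

This note records the models, the numerical choices, and the places where the
design was genuinely open — and what the synthetic-data tests do and do not
demonstrate about real data.

## Constrained tree pseudo-posterior

**Model.** The input taxonomy is a rooted classification with polytomies;
every internal node is a monophyly constraint.  A sampled tree resolves each
polytomy independently by sequential uniform pair joining: while more than
one lineage remains under a node, a uniformly random pair is merged.  This
draws uniformly from the labeled histories of the polytomy, so each pairing
of a trichotomy appears with probability 1/3, and a designated pair among
five free lineages forms a clade with probability 1/6.  Constrained clades
therefore have frequency exactly 1 in the sample and unresolved groupings
have the uniform labeled-history frequencies — the two properties a
data-free MCMC over a constraint tree converges to, obtained directly.

**Branch lengths.** Node heights are assigned bottom-up: each join sits an
increment above the higher of the two merged lineages, with the increment
drawn Exp(1) (`yule`, default) or U(0,1) (`uniform-order`); the tree is then
rescaled so the root height is exactly 1.  A data-free relaxed-clock prior
has no identified time scale, so the unit is a convention: all rates in this
package are **per root height**.  Absolute rate values are therefore only
comparable across analyses that share the convention; rate *orderings* and
log-scale *bins* are insensitive to it.  For the study-shaped taxonomy
(60 tips) this yields total tree lengths around 40, i.e. a rate of 1.0
implies roughly 40 expected transitions on a fully heated lineage set.

**Determinism.** Tree k uses generator seed `master + k`, so any prefix of a
sample is reproducible and independent of the total sample size.

## D statistic

d_obs is the sum over internal nodes of |left − right| where nodal values
are unweighted means of the two daughters (branch lengths deliberately do
not enter the estimator; they enter only the Brownian null).  The scaling
between the shuffle null (prevalence-preserving permutations) and the
Brownian-threshold null (unit-rate Brownian motion cut at the rank matching
the observed prevalence) cancels any multiplicative constant in the
estimator, which the affine-invariance test enforces.

Defaults: 1000 null simulations per null per tree, configurable downward
(the scaled-down preset uses 100).  Tips with missing values are pruned per
feature before computation; the pruned tree keeps its branch lengths.  The
result is flagged rather than computed when fewer than 4 informative tips
remain, when only one state survives pruning, or when the two null means
coincide within 1e-12.  Rank ties in the Brownian threshold (possible only
with zero-length branches) are broken by a sub-numerical (1e-12) jitter
drawn from the replicate generator, keeping replicates deterministic.

## Hidden-rates model

States are ordered (0S, 0F, 1S, 1F).  Eight rates: gain and loss within each
class, and class switching within each observed value; transitions changing
value and class simultaneously are structurally zero, and the diagonal makes
rows sum to zero.  Rates are bounded to [1e-10, 100]; on the log10 reporting
scale the floor prints as −10 and the ceiling as 2.

**Likelihood.** Felsenstein pruning with per-node rescaling.  Tip partials:
present → (0,0,1,1), absent → (1,1,0,0), missing → (1,1,1,1).  The root is
combined with the conditional-likelihood weighting (prior proportional to
the root partials), under which a tree with no data has likelihood exactly 1.
Transition matrices for all branches come from one eigendecomposition of the
shared generator (P(t) = V e^{wt} V⁻¹), falling back to `scipy.linalg.expm`
per branch when the eigenbasis is ill-conditioned (row-sum error > 1e-8).
The pruning pass is verified against exhaustive enumeration over all
ancestral and ambiguous-tip assignments on ≤ 6-tip fixtures (1e-10).

**Fitting.** L-BFGS-B in log-rate space, 5 random log-uniform multi-starts
(seeds derived from the call seed) plus one start at the collapsed 2-state
ML solution.  Two numerical policies deserve explanation:

* *Floor snapping.*  The likelihood is flat in a rate whose true value is
  zero, so the optimizer stops at arbitrary small values.  After
  optimization, any rate that can be moved to the lower bound at a
  likelihood cost below 1e-6 is pinned there; zero rates are then reported
  as exactly 0 (−10 on the log scale) rather than as optimizer noise.

* *AIC gating (default).*  A single binary character rarely identifies all
  8 rates: the surface has a near-flat ridge along which class-specific
  rates drift to the bounds at a likelihood gain of < 2 log units, and the
  resulting point estimates err by an order of magnitude.  `fit` therefore
  also fits the collapsed 2-state all-rates-differ model and returns the
  8-rate solution only when it beats the collapsed fit by 6 log-likelihood
  units (the AIC margin for its 6 extra parameters); otherwise the
  tied-classes embedding of the 2-state ML is returned.  `select="ml"`
  disables the gate.  On simulated tied-class data the gate essentially
  always selects the collapsed model, and the median estimate over 20
  replicates is within a few percent of the generating rates; the ungated
  ML's median relative error on the same data is several times larger.

**Rate summaries.** The per-feature scalar gain (resp. loss) rate is the
occupancy-weighted average of the slow- and fast-class rates, with occupancy
the mean marginal probability of the fast class over all tips and internal
nodes from the ancestral reconstruction at the optimum.  How 8 rates should
collapse to 2 is genuinely open; all 8 rates are always exported so other
conventions can be evaluated.  Per-posterior summaries are medians of the
per-tree values, per feature.

## Marginal ancestral reconstruction

Down (postorder) partials and up (preorder) partials are combined per node,
marginal ∝ down × up, with the same conditional-likelihood root weighting;
both passes carry log-scale accumulators so the marginal identity
(Σ_states down × up recombines to the full-tree likelihood at *every* node)
is checked to 1e-9 rather than assumed.  Observed tips keep probability 1 on
their projection pair; missing tips are reconstructed like internal nodes.

Family-root ("proto-language") presence is the marginal p(1S) + p(1F) at the
MRCA of the family's tips; with family constraints this node is the
constraint node in every sampled tree.  Reconstructability is reported both
as cumulative tails (≥ 0.95, ≥ 0.75, ≤ 0.25, ≤ 0.05) and as five exclusive
bands partitioning [0,1]; pairwise family overlaps are percentages of the
full feature set, with raw counts retained alongside because percentage
denominators are a reporting convention.

## Binning and correlation conventions

D bins: D < 0 overclumped, 0 ≤ D ≤ 0.5 signal, 0.5 < D ≤ 1 random,
D > 1 overdispersed.  Rate bins on the log10 scale: < −0.5 slow,
[−0.5, 0.5] medium, > 0.5 fast.  The closed/open boundary assignment (closed
on the signal/medium side) makes the verbal ranges exhaustive; it is a
convention, stated here because descriptions of such bins rarely pin the
endpoints.  Kendall's τ between median D and median log rate is computed
both including and excluding features floored to −10, since floored features
are a qualitatively different population (never gained or never lost).

## Synthetic data

The generator emulates a five-family, 60-tip typological survey
(family sizes 12/2/14/11/21), with nested, partly unresolved subgroupings
(half of the within-family nodes collapsed by default) and ~10% missing
cells, injected either completely at random or family-blocked (whole
families uncodable for a feature, mimicking documentation gaps).  Trait
regimes: exact event-time CTMC simulation under a known 2- or 4-state
generator (true node states retained for recovery tests), single-origin
clumping, uniform shuffles, and thresholded Brownian motion.  Matrix columns
are generated on a designated tree of the posterior (the first, by
convention).

What passing tests show — and do not.  The synthetic regimes bracket the
clumping spectrum and validate calibration, likelihood exactness, regime
ordering, and seed-reproducibility.  They do not model horizontal transfer
(borrowing), autocorrelated missingness beyond family blocks, or coding
error, so test performance bounds real-data performance only under those
idealizations.

## Problem sizes used in validation

Calibration and recovery runs use study-scale problems chosen to finish on a
single CPU: 200 replicate traits with 100 null simulations each for the D
calibration (60-tip tree); 20 replicates of a 200-tip tree at the reference
rate pair (gain 0.5, loss 1.0) for rate recovery; 10,000 sampled trees for
the polytomy-resolution frequencies.  The pipeline's scaled-down preset
(100 trees, 100 null simulations, 3 starts) matches the same philosophy.

## Known limitations

* Absolute rates depend on the root-height-1 convention (see above).
* The hidden-rates model with one character is weakly identified by design;
  the AIC gate trades a small amount of asymptotic efficiency for large
  finite-sample robustness.
* Polytomy resolution is uniform over labeled histories, not over
  topologies; the two differ for ≥ 4-way polytomies (this matches the
  coalescent-style construction, and the labeled-history distribution is
  what the acceptance checks verify).
* No model of language contact/borrowing; traits evolve independently.
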