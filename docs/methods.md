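# Methods

## The problem

Sequencing-derived abundance tables (16S, shotgun metagenomics, metabolite
and microRNA panels) are compositional: the library size is an artifact of
the instrument, so only the ratios between features carry information.
Feeding raw proportions to a classifier entangles every feature with every
other through the closure, and normalization heuristics reintroduce the
very scale they claim to remove.  This package implements a
normalization-free alternative: recast the data as *balances* — normalized
log contrasts between groups of features defined by a serial binary
partition (SBP) — and let a sparse linear classifier pick the informative
ones.  The discriminative balance analysis (DBA) construction additionally
arranges the partition so that the most group-separating contrasts involve
only 2 or 3 features, giving directly interpretable biomarker ratios.

## Transformations

For a table `x` of N samples by D positive parts:

* **closure**: `ACOMP(x_i) = x_i / sum_j(x_ij)` — the proportion baseline.
* **CLR**: `log(x_ij / g(x_i))` with `g` the row geometric mean; rows sum
  to zero.
* **balances**: for an SBP column z with numerator block C+ (d+ parts) and
  denominator block C- (d- parts),

      b_iz = sqrt(d+ d- / (d+ + d-)) * log( g(x_i, C+) / g(x_i, C-) )

  The D-1 balance rows of a full SBP form an orthonormal basis of the CLR
  hyperplane, so squared distances and the Aitchison total variance (sum of
  CLR component variances) are conserved.  All logarithms are natural.

All variances in the package use the population convention (denominator
N).  This makes the differential-proportionality statistic an exact
within-SS / total-SS ratio in [0, 1] and makes the per-balance
between + within = total decomposition hold to machine precision, at the
cost of a negligible small-sample bias that cancels in every ratio we
report.

## Pairwise statistics

* **Variation matrix T**: `T[j,k] = var_i( log(x_ij / x_ik) )`, computed
  via `var(a-b) = var(a) + var(b) - 2 cov(a,b)` in O(N D^2); a brute-force
  double loop is kept as the test oracle.  `T = 0` exactly for proportional
  pairs, and T is invariant to per-sample rescaling.
* **Differential proportionality theta**:
  `theta[j,k] = (N1 T1 + N2 T2) / ((N1 + N2) T)` for groups of sizes N1,
  N2 with within-group variation matrices T1, T2.  Under the population
  convention this is the within-group share of the pair's log-ratio sum of
  squares; 0 means the ratio separates the groups maximally, 1 means the
  grouping explains nothing.  Pairs with zero total variation (and the
  diagonal) are set to 1 — "no discrimination" — which keeps degenerate
  pairs harmless when theta is clustered.

## SBP construction

PBA clusters T (proportional pairs merge first, the trunk carries the most
variance), ABA clusters `max_offdiag(T) - T`, DBA clusters theta (the most
discriminative pairs merge first and land distally), and RBA draws a
uniformly random binary topology from a seed (each nonempty proper
bipartition of a block equally likely), as an unsupervised null.  A
`1 - theta` variant of DBA is available for ordination use: it moves the
largest between-group-variance contrasts to the trunk instead.

Clustering is agglomerative with Lance-Williams updates (ward by default;
average and complete available).  Ward is applied directly to the supplied
dissimilarities.  No linkage is canonical for these matrices; the choice
changes which contrasts become distal, so it is exposed as a parameter,
and exact reproduction of any particular published dendrogram should not
be expected across linkage choices.  Ties are broken toward the smallest
(row, column) node-index pair, which makes every partition deterministic
and permutation-stable.  Columns of the sign matrix are ordered root-first
(descending merge height); within a column the block containing the
smallest feature index is oriented +1.  Orientation only flips the sign of
a balance coordinate and never affects any variance or AUC (tested).

The distal subset keeps columns with 2 or 3 nonzero parts: the cherries
and singleton-versus-cherry nodes at the leaves of the dendrogram.  Only
these enter the "-distal" classifier variants and the discriminant
ordination.

## Preprocessing

Applied once to the full table, in fixed order: (1) optional top-decile
abundance filter — keep the ceil(D/10) features with the largest column
totals, retaining all features tied at the threshold; (2) drop features
whose zero fraction strictly exceeds 0.9; (3) multiplicative zero
replacement on the count scale — zeros become delta (default 0.5, half a
count) and the nonzero entries of the row are shrunk by a common factor so
the row total is preserved.  Replacement preserves the rank order of
nonzero entries; a warning is emitted if delta is not below the smallest
observed count.  Bayesian-multiplicative replacement is deliberately out
of scope (it degrades on heavily zero-laden tables).  Only the SBP is
training-set-specific; the filters are global, the per-row transforms leak
nothing.

## Classification benchmark

50 stratified random splits with round(0.33 N) validation samples.  Per
split and representation: build features (SBPs from the training rows
only; the frozen "balance rule" is then applied to validation rows), tune
the L1 penalty by stratified 5-fold cross-validation over the 100-point
grid `exp(linspace(log 0.001, log 5, 100))`, refit at the chosen penalty,
and score the validation rows by AUC (Mann-Whitney form, ties counted
half).  All representations see identical splits and folds, so paired
comparisons are meaningful.  Pairwise method comparison reports the
Hodges-Lehmann shift estimate of the AUC difference with a rank-sum
confidence interval (the construction behind R's `wilcox.test` interval).

The penalized objective is `mean logistic loss + lambda * ||w||_1` with an
unpenalized intercept; features are standardized to unit variance
internally (weights are reported on the original scale).  It is solved by
IRLS with coordinate descent, Gram-matrix updates, and warm starts along
the decreasing penalty path; scikit-learn's saga solver serves as an
independent correctness check in the tests.  The CV selection criterion is
the minimum mean binomial deviance, with ties broken toward the larger
penalty (sparser model); deviance is smoother than accuracy at n around
100 and selects the same region of the path.

## Ordination

Each balance's variance splits exactly into between-group
(`sum_g n_g (mean_g - mean)^2 / N`) and within-group (`sum_g n_g var_g / N`)
parts.  Fractions are reported against the grand totals over the supplied
balances; over a full SBP the totals equal the Aitchison total variance.
The discriminant projection takes the top-k distal DBA balances by total
variance (default, k = 3) or by between-group variance; ranking ties break
toward the earlier balance.  The underlying basis is orthonormal, but
balance coordinates across samples are generally correlated, so the
projection axes are interpretable, not independent.

## Synthetic data generator

A logistic-normal-multinomial model: baseline log-abundances are drawn
N(0, base_sigma^2) with base_sigma = 2 (feature means spanning roughly
±1.7 decades, as in real surveys); each sample adds N(0, sigma^2) noise
(sigma = 0.5 by default); proportions are the softmax of the latent
log-abundances; counts are multinomial at a log-normal depth (median
about 5000 reads, log-sd 0.5).  Low depth plus a wide baseline range
yields the sparsity and overdispersion the preprocessing exists to
handle, and zero fraction rises monotonically as depth falls (tested).

Planted signal is a set of disjoint *differentially proportional modules*:
the two members of a planted pair share a latent noise component
(correlation pair_rho = 0.5), so they covary within groups, and the second
group receives ±delta/2 mean offsets on the members, shifting the pair's
log-ratio mean by delta.  Two deliberate design choices make the ground
truth operationally identifiable.  First, planted features are anchored at
the centre of the baseline abundance range: a signal planted in a feature
that is almost never sequenced cannot be recovered by any method, so its
"recovery" would measure depth, not discrimination.  Second, the shared
noise component is what distinguishes the planted pair from cross-pairings
of up- and down-shifted features across modules — those cross ratios shift
by the same delta, but with larger within-group variance, so the planted
pair is the uniquely most discriminative one.  This mirrors the module
structure the theta statistic was designed to detect.

What the generator does **not** emulate: phylogenetic correlation
structure, batch effects, heavy-tailed taxon distributions beyond the
log-normal, contamination, or group-dependent sequencing depth.  Passing
tests therefore demonstrate correctness of the machinery and sensible
behavior under a standard compositional count model, not performance
claims about any particular real cohort.

## Problem sizes and numerics

The packaged end-to-end checks use D = 30 features and 100 samples per
group with three planted modules (delta = 2), 50 splits, and the full
100-point penalty grid — sizes at which every property the package
guarantees (orthonormality to 1e-10, isometry to 1e-8 relative, theta
against the brute-force oracle to 1e-12) is testable in seconds.  Under
these conditions the classification task is easy by design (median AUCs
near 1 for all representations; the interesting assertions are the
equalities and the permuted-label null at 0.5).  Degenerate inputs fail
loudly: all-zero rows in zero replacement, single-class label vectors,
groups smaller than 2 for theta, non-binary trees, non-finite
dissimilarities.  IRLS clamps the logistic weights at 1e-5 and coordinate
descent iterates to a 1e-8 coefficient tolerance.
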