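# Methods

This note documents the statistical model behind `mtmat`, the estimators
and numerical choices in the implementation, the synthetic-data generator
used by the test suite and the acceptance script, and the limitations of
both.

## Model

### Covariate construction

For a taxa × sample count table `c_ijm` (subject *i*, visit *j*, taxon
*m*), the log₂ counts-per-million transform is

    r_ijm = log2( (c_ijm + c_ij./2) / (L_ij + c_ij.) * 1e6 + 1 )

with `L_ij` the library size and `c_ij.` a per-sample pseudo-count.  Two
pseudo-count policies are provided (`prior_policy`):

- `constant` (default): `c_ij. = 1`, i.e. a prior count of 0.5 per taxon.
- `library_scaled`: `c_ij. = L_ij / mean(L)`, which scales the prior with
  sequencing depth so that deep and shallow samples are shrunk comparably.

A genus with `M1` member taxa contributes `M1` association covariates: the
pooled log ratio `x(0) = log(E/G)` of the genus log-CPM sum `E` against a
reference aggregate `G`, and one per internal node of the genus subtree,
`x(k) = log(C/D)` with `C` and `D` the pooled log-CPM sums of the node's
left and right child leaf sets.  Internal nodes are numbered in pre-order
from the genus subtree root; left/right follows Newick child order.  The
test statistics are invariant to the left/right convention up to the sign
of the estimated effect.  Natural log is used for the ratios (the base
cancels from the test statistics; it affects only the scale of reported
effects).

Three choices of the pooled reference `G` are implemented: the sum over
all retained taxa outside the genus (default), the `E` of one named
reference genus (the additive log-ratio, ALR), and the geometric mean of
the `E` of every genus (the centered log-ratio, CLR).

### Marginal regression and tests

Each covariate vector `x`, stacked over subjects and visits, follows the
marginal model

    E(x | Z, y) = Z a + y b,   var(x | Z, y) = Sigma,

with `Z` the covariate design (intercept first), `y` the phenotype, and
`Sigma` block-diagonal with per-subject blocks
`Sigma_i = sigma * D^{1/2} R_i D^{1/2}`.  `R_i` is the working correlation
— identity, compound symmetry (CS), first-order autoregressive (AR1, with
distance = visit-index difference so gaps decay as `rho^|dv|`), or
unstructured (UN, balanced designs only).  `D = I` by default; the
`visit_variances` option estimates a separate variance per visit index.

`H0: b = 0` is tested two ways:

- **Generalized score test.**  `a` is estimated under the null by iterated
  GLS; the score `U`, evaluated at `(a_hat, 0)`, enters
  `T = U' H^-1 L' (L H^-1 B H^-1 L')^-1 L H^-1 U ~ chi2(c)`
  with `H` the quasi-information of the joint design `[Z y]`, `B` the
  empirical score covariance, and `L` a contrast matrix (default
  `[0' 1]`; arbitrary contrasts are accepted, enabling multi-parameter
  tests).
- **Robust Wald test.**  `(a, b)` are fitted jointly;
  `T = b_hat^2 / V_hat ~ chi2(1)` with `V_hat` a sandwich built from the
  per-subject robust covariance of `x_i`.  The phenotype enters the
  sandwich with the `Z`-covariates partialled out under the working metric
  (`ytilde = y - Z (Z'S^-1 Z)^-1 Z'S^-1 y`); with the raw `y` the scalar
  `y'S^-1 y` overstates the information about `b` by the phenotype's R² on
  `Z` and the test is anticonservative (measured: null rejection 0.16
  instead of 0.05 at N = 100 with an intercept-only `Z`).  By
  Frisch–Waugh the point estimate `b_hat` is unchanged.

Both tests apply a small-sample adjustment by default: each subject's
residual is inflated by `(I - P_ii)^{-1}`, where `P_ii` is the subject's
leverage under the null-constrained information (score path) or under the
partialled phenotype metric (Wald path).  This undoes the downward bias of
the sandwich at small numbers of subjects.  The quasi-information is used
in its positive-definite orientation throughout; the test statistics are
unchanged by that orientation, and the leverage correction requires it to
inflate rather than deflate.

### Combination

Per-node p-values are asymptotically independent, so under the genus null
the minimum of `M1` uniform p-values is Beta(1, M1)-distributed and

    combined_p = 1 - (1 - min p)^M1

is uniform.  The **IM** variant applies the rank-based inverse-normal
transform `z_i = ndtri((rank_i - 0.5)/n)` (average ranks for ties, ranks
over all samples jointly) to each covariate before testing; this keeps the
per-node tests calibrated when `n` is small or the covariate is heavily
tied, and makes the genus p-value invariant to monotone transforms of the
covariates.  The **M** variant tests the raw covariates.  Across genera,
Benjamini–Hochberg (default) or Bonferroni adjustment is applied.

## Estimation and numerics

- **Iteration.**  Coefficients start at OLS; each cycle solves GLS under
  the current `(sigma, R)` and re-estimates them by moment formulas from
  Pearson residuals, with `sigma = sum(e^2)/(n - p - 1)`, CS `rho` from
  all within-subject pairs, AR1 `rho` from lag-1 pairs, and UN entries from
  per-visit-pair averages (eigenvalue-clipped to stay positive definite).
  Parameter updates are damped (averaged with the previous iterate): the
  undamped fixed-point map can 2-cycle on small samples.  Tolerance 1e-8,
  maximum 200 iterations.  The unstructured matrix is frozen at its
  initial estimate from the OLS residuals — iterating its O(n²) free
  entries jointly with the mean can diverge at small N, and the sandwich
  keeps inference valid under any fixed working correlation.
- **Parameter bounds.**  CS `rho` is clipped to
  (−1/(max N_i − 1) + 1e-3, 0.99), AR1 to (−0.99, 0.99).
- **Degenerate inputs.**  A constant covariate (e.g. a node whose leaves
  are never observed) carries no information: the node is dropped and, by
  default, the realized number of valid nodes is used as the Beta
  parameter (`nominal_M1_on_failure` keeps the nominal `M1`, which is
  conservative).  A constant phenotype, a rank-deficient design, or a zero
  residual variance raise errors.
- **Filters.**  Taxa with mean relative abundance below 0.001 across all
  samples are removed; samples with fewer than 3000 reads are removed
  (subjects losing every visit disappear).  Library sizes are frozen at
  construction so the taxon filter does not change the CPM denominator.
  Genus clades are checked for monophyly; taxa removed by the abundance
  filter are tolerated inside a genus clade, other foreign leaves are an
  error in strict mode (lenient mode restricts to the minimal spanning
  clade with a warning).
- **Trees.**  Newick with named leaves; branch lengths ignored;
  multifurcations rejected by default or resolved deterministically into a
  left-leaning caterpillar.

## Synthetic data generator

`simulate.generate_synthetic` emulates a repeatedly measured 16S study.
Its defaults are the study conditions used throughout the tests: 50
subjects at 3 visits, 10 genera of 1–6 species plus 3 always-present
dominant background taxa, 64 % zero cells, compound-symmetry dependence
(rho = 0.3) across visits, log-normal library sizes centred at 2×10⁴
reads, and a binary phenotype independent of the counts and constant
within subject.

The model: each taxon has a fixed log-abundance effect (sd 1; background
taxa lifted by +5), plus a latent noise field with the chosen visit
correlation structure (identity/CS/AR1); a per-sample presence indicator
is thresholded from a second latent field with the same correlation
structure, so both the zero pattern and the magnitudes carry the
dependence; counts are Poisson draws of the library size times the
presence-masked softmax weights.  Sparsity is calibrated by bisection on
the presence-probability logit against the analytically expected zero
fraction, and lands within ±5 points of the target at default sizes.  The
tree is built genus-subtree-first, so genera are clades by construction.

Two structural choices matter and are deliberate.  First, zeros come
mostly from the presence layer rather than from extreme log-normal swings:
at this table size, producing 64 % zeros from magnitude swings alone makes
several genus taxa permanently absent (their node covariates collapse to
rank-identical vectors and the minimum-p combination becomes severely
conservative) and gives the remaining taxa enormous variances (the
spike-in `delta = beta * var` then saturates power at the smallest effect).
Real species-level tables scatter zeros across samples per taxon, which is
what the presence layer reproduces.  Second, a dominant background flora
absorbs most of the library, so that tested genera sit at realistic
relative abundances (counts of tens, not thousands).

`genus_rich_config()` provides a 70-genus (~300 taxa) variant used by the
compositional-bias experiment: with only a handful of genera every
log-ratio denominator is small and volatile and the relative robustness of
the denominator choices cannot be resolved; at 70 genera the ranking is
stable across seeds.

What the generator does **not** emulate: taxonomic signal in the tree
(topologies are random), overdispersion beyond Poisson-lognormal,
visit-varying library-size trends, covariate-dependent abundances, and
unbalanced visit schedules (the generator is balanced; the engine itself
handles unbalanced data and is tested on it).  Calibration and power
results on these tables therefore demonstrate the statistical machinery
under controlled dependence and sparsity, not performance on any
particular real cohort.

## Experiments

- **Type-1 error / power** (`type1_power_experiment`): per replicate the
  phenotype is permuted at subject level, `N` subjects are subsampled
  without replacement at the case:control ratio (cases rounded down,
  controls up), a test node of the target genus is chosen at random, and
  causal taxa (a single taxon, or 50 %/90 % of the node's descendant
  leaves, rounded half-up, minimum 1) receive `delta = beta * var_m` added
  to every case sample's count (rounded to the nearest integer so counts
  stay integral; `var_m` is the taxon's count variance over the base
  table, computed once).  `beta = 0` gives type-1 error; power uses the
  empirical-null quantile as an adjusted threshold so methods are compared
  at a calibrated size.  Default 500 power replicates (configurable);
  the calibration checks use 2000.
- **Compositional bias** (`compositional_bias_experiment`): a multi-taxon
  genus is spiked (`beta = 0.15`, 50 % causal), one external taxon is
  inflated in case samples by its count standard deviation times a
  multiplier in {0, 1, 5, 10, 50, 100}, and the pooled-covariate effect
  estimate of the genus is recorded per multiplier for each denominator
  mode.  Compositional bias appears as drift of the mean estimate with the
  multiplier.  The CLR geometric mean drifts most — a single inflated
  genus moves it at weight 1/T — while the all-other-taxa default and the
  ALR reference drift little and, at desk scale, comparably: the default
  dilutes the inflated taxon over every retained taxon, and the ALR
  reference is only hit when the external taxon lands in the reference
  genus.

## Known limitations

- The unstructured working correlation requires balanced visit grids.
- Depth-scaling invariance of log-CPM holds where counts dwarf the
  pseudo-count; zero cells shift by ~log2 of the scale factor under the
  constant prior (the library-scaled prior removes most of this).  On
  sparse tables the IM variant additionally quantizes through ranks, so
  p-values respond discretely to perturbations that reorder near-tied
  samples.
- The leverage correction assumes no single subject dominates the
  phenotype information; with one case subject the correction factor is
  ill-conditioned (the engine raises an error rather than returning a
  misleading statistic, and the node-failure policy downgrades `M1`).
- Minimum-p combination relies on the asymptotic independence of node
  statistics; heavily rank-degenerate genera (many identical node
  covariates) push it toward conservatism, not inflation.
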