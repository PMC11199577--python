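# Methods

## Model

### Sparse PLS-DA (single block)

The binary outcome is dummy-coded as a samples × 2 indicator matrix
(case, control) and column-centered; for two classes this matrix has rank
one, so the PLS-DA solution is driven by a single outcome direction. Each
component is estimated by NIPALS: alternate `a ∝ X^T u` (truncated to the
`keep_x` largest magnitudes, renormalized) and `u ∝ Y Y^T X a` until the
weight change falls below `tol = 1e-9` (at most 500 iterations, error on
failure — silent non-convergence is never accepted). After convergence the
block is deflated by the regression of X on the score (`X ← X − t c^T`,
`c = X^T t / t^T t`) and the outcome likewise, which makes successive
scores exactly orthogonal. With `keep_x = "all"` and one component the
weight vector equals the dominant left singular vector of `X^T Y` — the
test suite checks this against an independent SVD on random 50 × 30
matrices to 1e-6.

Classification is nearest class centroid (class means of the training
scores) in the cumulative k-component score space, Euclidean metric; the
decision value `d(control centroid) − d(case centroid)` (> 0 ⇒ case) feeds
the ROC. Exact ties go to the majority training class. "Component k"
metrics always use components 1..k cumulatively; the marginal reading is
available by transforming scores directly.

### Multi-block integration

Blocks are combined by block-coordinate ascent on the design-weighted sum
of score covariances (see README for the objective). Design weights default
to 1 between every block pair and to the outcome ("full" design); the
phenotype block participates as an ordinary fourth block but with
`keep_x = None` (dense) and is exempt from pre-selection, since four
clinical variables need no sparsity. Covariance rather than correlation is
maximized: on autoscaled blocks the two coincide up to scale and the
covariance form avoids per-iteration renormalization. Each block is
deflated by its own score; the outcome is deflated by the consensus score,
the simplest scheme consistent with per-block orthogonality. The solver
records the objective after every sweep; because each update is the exact
maximizer of its coordinate subproblem, the path is non-decreasing (a
property test asserts this to 1e-10), and `max_iter = 2000` accommodates
the slow tail of power-iteration convergence when the leading eigengap is
small.

### Sparsity operator

`keep_x` retains exactly that many nonzero weights per component by
truncating all smaller magnitudes to zero and renormalizing, with ties
resolved toward the lower feature index. The lasso-style variant (subtract
the threshold magnitude from the survivors) selects the *same* feature set
but shrinks the surviving weights; it is not the exact maximizer of the
coordinate subproblem and can make the block solver's objective
non-monotone, so truncation is used throughout. Feature "importance" is
the maximum absolute weight across components; sparse selection ("nonzero
on any component") and top-K-by-importance are both exposed.

### Sign convention

NIPALS weights are defined up to sign. Components are oriented toward the
case class: the outcome score is flipped so it points from controls to
cases, and every block score is aligned with it. The common alternative —
making the largest-magnitude weight entry positive — is equally
deterministic for a single block but can anti-align blocks of a joint fit,
and an anti-aligned consensus average cancels the class signal; orientation
toward the outcome preserves both the consensus geometry and the exact
reduction of the one-block model to ordinary PLS-DA.

## Resampling harness

Splits are uniform random partitions into floor(0.8·n) train /
complement test, *unstratified* (the case/control ratio varies across
splits, which widens metric spreads and is the more conservative design).
Each split draws from `seed + split_index`, so any split can be
regenerated alone. Per split and per omic block, the train portion is
autoscaled (test rows always scaled with train statistics; zero-variance
train features dropped) and a 2-component sparse PLS-DA is fitted with
per-omic budgets defaulting to expression 50, methylation 50, genotype 20
per component. A feature is "selected" in a split when any component gives
it a nonzero weight; the persistent panel keeps features selected in at
least 70% of splits (inclusive boundary: 70/100 is in, 69/100 out). Splits
whose train set contains one class are skipped with a warning and counted —
essentially impossible at n = 110 with 32 cases, but handled.

Metrics: accuracy; Matthews correlation (defined 0 when a denominator
factor vanishes, mapping the always-majority predictor to 0); ROC AUC via
the midrank (Mann–Whitney) identity, which equals the brute-force count of
correctly ordered case–control pairs with half-credit for ties. The
Mann–Whitney U test between per-split metric distributions uses exhaustive
enumeration of label assignments (two-sided by deviation from the null
mean) when min(n_a, n_b) ≤ 8, otherwise the tie-corrected normal
approximation. Summary-table t-tests use the pooled-variance form by
default (this reproduces printed two-decimal p-values from mean/SD/n
summaries); Welch is a flag.

## Synthetic cohort

The generator emulates the structure of the motivating islet study:
n = 110, case fraction 32/110, and four aligned blocks.

- **Expression**: per-gene log2 baseline ~ N(5, 2); library factors
  log-uniform on [0.7, 1.4]; counts negative binomial with dispersion 0.2
  (variance μ + 0.2 μ²). Informative genes shift their case log2-mean by
  `effect_size × sigma_log` with `sigma_log = 0.7`, the approximate
  per-gene log2-count noise SD at this dispersion, so `effect_size` is
  roughly a standardized shift.
- **Methylation**: per-CpG mean uniform on [0.1, 0.9]; draws from
  Beta(mc, (1−m)c) with concentration c = 50; informative CpGs shift the
  case mean by `effect_size` on the (natural-log) logit scale — so the
  downstream M-value transform is exercised non-trivially.
- **Genotype**: MAF uniform on [0.05, 0.5]; Hardy–Weinberg binomial
  dosages; informative variants shift the case allele frequency by
  `effect_size × 0.1` (clipped inside (0,1)); 1% of entries missing at
  random to exercise QC and imputation. Note this makes genotypes the
  weakest planted layer by construction — at `effect_size = 2` the
  per-variant standardized mean difference is ≈ 0.6–1.2 depending on MAF,
  so realized selection frequencies vary and per-variant recovery is
  partial, as in real GWAS-scale data.
- **Phenotypes**: class-conditional normals — age 62.9 ± 7.7 (cases) vs
  61.5 ± 8.0, BMI 27.8 ± 3.8 vs 26.0 ± 3.9, stimulatory index 6.3 ± 5.2 vs
  8.0 ± 7.0; sex Bernoulli at the observed per-class male fractions
  (20/32, 48/78).

Defaults use reduced dimensions (2000 genes, 3000 CpGs, 1000 variants —
three orders below array scale) so the complete 100-split workflow runs in
seconds; all sizes scale up by config. Everything is a pure function of
the seed; two runs are bit-identical.

`simulate_split_signal` builds the canonical "integration wins"
construction: two latent axes z₁, z₂, cases shifted on both, each block's
informative features loading on only one axis — either block alone sees
half the separation, the joint model sees all of it.

**What the generator does not emulate**: linkage disequilibrium, CpG
spatial correlation, gene–gene co-expression modules, cell-type
composition, batch effects, covariate confounding, or any coupling
*between* omic layers beyond the shared class label. Passing recovery
tests therefore demonstrates that the pipeline finds the kind of signal it
was built for under clean conditions; it does not certify performance on
real islet (or any other) data, where effect sizes are smaller and
correlated structure can defeat both selection and integration.

## Preprocessing conventions

- M-values clip β into [eps, 1−eps] with eps = 1e-6 before the logit, so
  boundary betas stay finite.
- The expression filter keeps genes with unnormalized median count ≥ 1
  (strict "less than 1" removal); size factors are the median across
  all-positive genes of the count/geometric-mean ratio. Note the estimator
  is invariant to a *global* rescaling of all counts (the geometric-mean
  reference absorbs it), while rescaling a single sample moves only that
  sample's factor — the per-sample, not global, bias is what it removes.
  PLS receives log2(normalized + 1); the linear scale is available.
- Genotype QC thresholds default to missingness > 5% and HWE p < 1e-6
  (PLINK-conventional), both configurable; variants with a single observed
  dosage class are routed to the monomorphism filter rather than the
  degenerate χ² test; residual missing entries get the variant's mean
  observed dosage (PLS needs complete data; mean imputation is the
  simplest unbiased single imputation). The QC report's removal counts
  always reconcile input and output dimensions.
- Autoscaling is always estimated on training samples only and applied to
  test samples — the scaling leak is the classic way to overstate hold-out
  accuracy.

## Numerical choices and edge cases

- Convergence: weight-change tolerance 1e-9; deterministic initialization
  from the outcome indicator, so fitting involves no randomness at all.
- Ties: feature ranking and the sparsity operator break ties by ascending
  feature index; exact centroid ties predict the majority class.
- Degenerate inputs fail loudly: single-class outcomes, zero-norm weight
  updates (fully deflated blocks), out-of-range component requests,
  non-dosage genotype entries, out-of-range betas.
- Serialization: model weights, loadings, centroids and train statistics
  round-trip through JSON; matrices are written at %.17g so file
  round-trips are bit-exact.

## Problem sizes

Default analyses in this package use the reduced-dimension synthetic
cohort (110 × 2000/3000/1000) with 100 splits; the full workflow including
persistence selection, per-model evaluation and interpretation completes
in well under a minute on a single core, and the test suite exercises
every stage at these or smaller sizes.

## Known limitations

- Two-class outcomes only; no O2PLS/kernel variants; no weighted-vote
  prediction across blocks (consensus-centroid only).
- `keep_x` is not tuned (no nested cross-validation); the persistence
  threshold, not the budget, is the intended selection control.
- The block solver is not numerically identical to mixOmics' block.splsda
  (different deflation of the outcome, truncation instead of shrinkage);
  it reproduces the method's structure, not that implementation's digits.
- Cross-omics association uses the component-space product formula, a
  rank-H approximation that understates associations orthogonal to the
  retained components.
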