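# Methods

`wlgenes` re-implements, as a tested library, a consensus procedure for
finding stress-responsive genes in a two-condition RNA-seq experiment — the
motivating case is waterlogging stress in cucumber, with 18 control and 18
stress samples pooled from three studies.  The pipeline has five analysis
stages plus a synthetic-data generator that makes every stage testable
without external data.

## Normalization

Counts are normalized with the median-of-ratios method.  For sample *j*,

    s_j = median_i ( K_ij / mu_i ),   mu_i = geometric mean of gene i across samples,

where the median runs only over genes with strictly positive counts in every
sample (a single zero makes the geometric mean zero and the ratio
undefined).  Size factors are rescaled so their geometric mean is 1, keeping
normalized values on the counts scale; the reference scale is otherwise
arbitrary and the published procedure does not fix one.  Downstream stages
consume `log2(K_ij / s_j + 1)` by default; the raw normalized matrix is
available via `log_transform=False`.  The log transform is a package choice —
correlation and margin-based selectors behave better on roughly homoskedastic
inputs — and any stage can be run on either scale.

## Attribute weighting

Four per-gene relevance scores, each min–max normalized to [0, 1] so the top
gene scores exactly 1 (the convention evident in the published weight tables,
where every method's top weight is exactly 1):

* **correlation** — |Pearson r| between the gene and the 0/1 condition label;
  constant genes score 0.
* **symmetric uncertainty** — `2·I(G;Y) / (H(G)+H(Y))` after equal-frequency
  discretization of the gene into 5 bins (duplicate quantile edges merged; a
  degenerate single-bin gene scores 0, not an error).  The published
  description's printed "relevance" formula is not implementable as printed
  (an unbracketed denominator over probabilities of a continuous attribute);
  standard symmetric uncertainty is what the phrase denotes.
* **Relief** — one deterministic pass over all samples in index order.
  Features are min–max scaled, nearest hit and nearest miss are found by
  Manhattan distance with ties going to the lowest sample index, and
  `W[g] += (|x_g - miss_g| - |x_g - hit_g|) / n`.  A full pass instead of
  random sampling makes the result reproducible without a seed.
* **SVM** — absolute coefficients of a linear hinge-loss support-vector
  classifier (regularization C = 1.0) on per-gene standardized expression.

Selection keeps genes with weight **> 0.90** plus any gene with weight
exactly 1 (the per-method top gene always passes).

Because of the min–max normalization, the *number* of genes passing the
threshold is not by itself informative — some gene always has weight 1, even
on permuted labels.  The meaningful property, verified in the tests, is
precision: with planted differential expression the selected genes are
essentially all planted (precision 1.0 across seeds), while with permuted
labels selection precision collapses to chance.

## L1-penalized logistic selection

The selector minimizes mean binomial deviance plus `lambda * ||beta||_1`
(intercept unpenalized) on per-gene standardized inputs.  The path solver is
our own coordinate-descent implementation in the glmnet style — IRLS
quadratic approximation, cyclic soft-thresholding, warm starts along a
descending grid of 100 log-spaced penalties from `lambda_max =
max_g |sum_j x_gj (y_j - ybar)| / n` down to `1e-4 * lambda_max`, with
active-set screening against the full KKT conditions.  Solutions are exactly
sparse and exactly all-zero at `lambda_max`.  The solver is cross-checked
against R glmnet in the test suite (coefficients agree to ~1e-3 outside the
quasi-separated small-penalty tail, support agreement ~99.9%); the bundled
solver exists because a 100-point path must be fit 11 times per
cross-validation and thousands of times across the property tests.

Ten-fold stratified cross-validation scores each penalty by held-out mean
binomial deviance.  `lambda_min` minimizes the curve; `lambda_1se` is the
largest penalty within one standard error of that minimum and defines the
reported gene set (the sparser, more conservative choice).

Two behaviors of the 1-SE rule are worth knowing and are documented by
tests rather than hidden:

* On pure noise the selected set is empty in only ~70–80% of seeds, not
  always — cv.glmnet reproduces the same rate on identical matrices.  The
  rule is conservative, not a guarantee.
* When several strong genes individually separate the classes, the logistic
  deviance saturates and the sparse 1-SE fit may legitimately drop one of
  them.  With negative-binomial count noise the all-five recovery rate for
  five 4-fold planted genes is ~55–65% (again matched by cv.glmnet); on the
  latent (gaussian-mode) expression it is ~92%.  Recovery properties are
  therefore tested in latent mode, which is exactly what that mode exists
  for.

## Differential gene correlation analysis

For a gene pair, per-condition correlations (Pearson by default, Spearman
optional) get t-based two-tailed p-values (`t = r*sqrt(n-2)/sqrt(1-r^2)`,
n−2 df).  Each correlation is Fisher-transformed, `z = atanh(r)`, with
variance `1/(n-3)` (Pearson) or `1.06/(n-3)` (Spearman), and the
between-condition change is

    dz = (z_stress - z_control) / sqrt(var_control + var_stress),

with a two-tailed standard-normal p-value.  The pooled-sum denominator is
the standard two-sample Fisher-z comparison; a difference of variances would
vanish for equal group sizes and cannot produce the worked examples this
package reproduces, so the sum is used.  Class labels render per-condition
signs as `control/stress` (e.g. `0/+`): a side is `0` when that condition's
correlation is non-significant at `sig_threshold` (default 0.05), otherwise
the sign of r.  |r| at or beyond 1 is clamped to 1 − 1e-12 with a warning.

Pairs are ranked by `pValDiff` ascending with ties broken by |dz| descending
then gene ids; the scan of an m-gene panel emits exactly m(m−1)/2 records.
Raw p-values with a 0.01 cutoff follow the published protocol;
Benjamini–Hochberg adjustment is available but off by default.

Type-I error of the dz test is verified on 2000 independent null pairs
(n = 18/18): the fraction below 0.01 sits within binomial error of nominal.
Detection power at the published design scale: a planted block whose
correlation moves from 0 to 0.9 gives dz ≈ atanh(0.9)/sqrt(2/15) ≈ 4.0 with
unit standard deviation, while the maximum of hundreds of null pairs reaches
2.5–3.1.  The top-ranked pair is therefore planted in ~98% of seeds, but
*every* planted pair out-ranking *every* null pair is a coin flip — a
genuine limitation of the statistic at n = 18, which the tests assert as
"top pair planted, majority of the top six planted" rather than pretending
otherwise.

## Validation

A random forest (100 trees, bootstrap, sqrt-p features per split) classifies
control vs stress on the selected panel.  Reported metrics: out-of-bag
misclassification, accuracy, and AUC with ROC points — by default from
out-of-bag votes (the published figures do not state a protocol; OOB is the
conservative choice and reports label the protocol), with stratified k-fold
refitting available.

Per-gene contributions are **exact path-dependent tree Shapley values**
computed directly from the fitted trees' structure and cover counts
(`_treeshap.py`); additivity — base value plus the sum of a sample's
attributions equals the forest's predicted stress probability — holds to
machine precision and is asserted on every fixture.  The global importance
ranking orders genes by mean |phi| with ties broken by gene id.

The shadow-feature loop (Boruta) runs up to 100 iterations: each run
appends a column-shuffled shadow copy of every undecided gene (padded to at
least five shadows), fits a forest, and scores a hit for each gene whose
importance exceeds the best shadow's.  Hit counts are tested two-sidedly
against a fair coin with Bonferroni correction over the initial panel at
alpha = 0.01; the loop stops early only when no gene is left undecided.
Remaining Tentative genes are adjudicated by the median rule
(TentativeRoughFix): confirmed iff the gene's median importance across its
runs exceeds the median per-run maximum shadow importance.  The default
importance is Gini (mean decrease impurity), the default of the reference
Python implementation and fast enough for hundred-seed property tests;
permutation importance is available via `importance="permutation"`.  Note
that Boruta tests in-sample relevance: with tens of samples, a noise feature
whose chance correlation with the label is large enough is *correctly*
confirmed (it does predict, in that sample), so "zero confirmations on pure
noise" is not an attainable contract and the tests assert rarity instead.

## Synthetic data

`simdata` generates gene × sample matrices emulating the pooled design:
18 + 18 samples from three studies (3/9/6 per condition, matching the
published accession table), ~20,144 genes at full scale.  The latent log2
expression is

    l_ij = b_i + batch(study_j, i) + lfc_i * [stress] + latent_sd * u_ij

with baseline `b_i ~ N(5, 2)` (log2 scale), per-(study, gene) batch shifts
`N(0, 0.25)`, and planted log2 fold changes on a `de_fraction` of genes
(`lfc ~ N(0, lfc_sd)`, default sd 2.0 — the source study publishes no effect
sizes, so these are calibration choices fixed once).  Correlation blocks
replace the standardized residual by `sign_g * (sqrt(|rho|) f_j +
sqrt(1-|rho|) eps_ij)` with a shared per-sample factor, making the
population correlation of a within-block pair exactly `sign_1 sign_2 |rho|`
per condition; negative rho uses alternating per-gene signs (a block larger
than two cannot be mutually negative).  Block genes carry no batch shift —
an independent per-gene batch pattern would attenuate every planted
correlation and break the exactness contract.  With `blocks_are_de` the
block genes also receive fold changes of magnitude exactly `lfc_sd` (random
sign), giving an equally strong planted panel that reliably passes the
upstream selectors.

`counts` mode draws `K_ij ~ NB(mean = s_j 2^{l_ij}, var = mu + alpha mu^2)`
via a gamma–Poisson mixture with per-sample size factors
`s_j ~ U(0.5, 2)` and dispersion alpha = 0.1 (alpha = 0 degenerates to
Poisson exactly).  `gaussian` mode returns `l_ij` itself — no count noise,
no size factors — for sharp numerical tests of the correlation and selection
machinery.  What the generator does **not** emulate: gene–gene correlation
outside declared blocks, count outliers, library-preparation artifacts, and
mean–dispersion trends; passing tests show the machinery is correct under
the stated model, not that the model captures everything in real data.

All randomness flows from one seeded generator per dataset; identical
configurations produce byte-identical files.

## Pipeline and defaults

`run_pipeline` chains normalize → four weightings → L1 selection → union U →
all-pairs DGCA on U → top 10 pairs → top-pair gene set D → forest validation
with attributions on D → shadow-feature confirmation.  Every published
protocol constant is a config key with that value as default: weight
threshold 0.90, per-condition significance 0.05, differential-correlation
cutoff 0.01, 10 CV folds, 100 trees, 100 shadow-loop runs.  The
shadow-feature stage defaults to the full gene matrix (`boruta_scope =
"full"`, as in the published protocol) and can be restricted to U or D.
Stage seeds derive from one master seed; reruns are byte-identical.

## Problem sizes in the tests

The test suite and the acceptance script run on simulated data scaled so
the whole suite completes comfortably on one CPU: panels of 12–500 genes,
the published 18 + 18 sample design, 2000 null pairs, and 100-seed
repetitions for the statistical guarantees (the acceptance script uses
20–50 seeds per property and records the count in each result's `n`).
Full-size runs (20,144 genes) use the same code paths; only the shadow-loop
on the full matrix is slow at that scale (~10⁴ forest fits).
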