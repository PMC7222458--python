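# Methods

This note records the statistical model behind each stage of `instdiffs`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical and design decisions that were
genuinely open.

## The setting

All analyses operate on aggregates: each row of the data matrix is an
institution (a medical school in the motivating application), each column
an aggregate measure such as a mean examination mark or a percentage of
graduates entering a specialty.  Two features dominate the statistics:

1. **n is small and p exceeds n** (29 institutions, 50 measures).  The
   sample correlation matrix is singular with at most n positive
   eigenvalues, classical multiple imputation is ill-posed, and any
   regression of one measure on many others must control model complexity
   aggressively.
2. **The measures admit a causal ordering.**  Historical output of
   specialists precedes current curricula; selection precedes teaching;
   teaching precedes student perceptions; all precede postgraduate
   outcomes.  The registry encodes this as an integer `causal_rank`
   (group order × 100 + within-group position).  Within groups the
   ordering is conventional rather than demonstrable; it only matters that
   an order is fixed before fitting.

## Imputation

Missing cells (about 11% in the motivating data, mostly structural: new
schools lacking historical measures) are completed by a single
k-nearest-neighbour hotdeck.  The distance between two institutions is the
mean absolute difference over the measures both observe, each measure
scaled to unit SD (a Gower-style distance for all-numeric data); the
missing value is replaced by the **median** of the k nearest donors that
observe the measure.  Defaults: k = 5, the conventional default of kNN
hotdeck implementations; the method family, not a specific k, is what the
analysis pins down.  The procedure is deterministic — ties in distance
break by row order — and never touches observed cells.

Two diagnostics justify the completion: `correlation_fidelity` (mean
absolute difference between pairwise-complete raw correlations and
completed-data correlations, over pairs with ≥ 4 shared raw observations;
hotdeck beats column-mean imputation on this criterion and on RMSE in
simulation), and `psd_check` (the completed correlation matrix must be
positive semi-definite, with at most n positive eigenvalues when p > n;
tolerance 1e−8 × the largest eigenvalue).  Note the rank bound for n
centered rows is n − 1, so a complete 29 × 50 matrix shows at most 28
strictly positive eigenvalues; the test-count convention below nevertheless
uses 29 as the effective measure count, following the convention of the
motivating analysis.

## Reliability

For a measure observed over k occasions (years), Cronbach's α over the
unit × occasion panel quantifies the stability of *between-institution*
differences: α = k/(k−1)·(1 − Σ per-occasion variance / variance of
per-unit sums), variances over units with ddof = 1.  Units with any
missing occasion are dropped listwise (panels are built from the years
actually available).  α is reported unclipped — negative values are
diagnostic, flagged with a warning — and is bounded above by 1.
Unreliability attenuates correlations: measures with reliabilities a and b
can correlate at most √(a·b), which is why a measure with α = 0.47 can
hardly reach the screen's significance thresholds regardless of its true
associations.

The synthetic panel generator draws unit value = shared trait (variance
`icc`) + occasion noise (variance 1 − `icc`), for which the expected α is
the Spearman–Brown value k·icc/(1 + (k−1)·icc); parameter recovery against
this closed form is a standing test.

## Correlation screen and multiple testing

Pearson r for every pair; two-tailed p from the exact t transform
t = r·√((n−2)/(1−r²)) at n − 2 df (preferred over Fisher's z at these
sample sizes).  Two significance tiers: plain p < 0.05, and a
Tukey-adjusted level 0.05/√K — milder than Bonferroni's 0.05/K, appropriate
where zero correlations are not a credible prior for most pairs and tests
are far from independent.  Because at most min(n, p) dimensions are
informative, K defaults to C(min(n, p), 2): for 29 units this gives
K = 406 and a critical level of 0.0025 even though 1225 pairs are tabled.

`critical_r` inverts the transform (r = t/√(t² + n − 2)); at n = 29,
α = 0.05 this is 0.367.  A separate textbook power function is provided:
detecting a true ρ equal to the critical r has ≈ 50% power, and 80% power
at that n and α needs ρ ≈ 0.50.  The two notions are distinct and the
package does not conflate them.

Group comparisons use Welch's t with Satterthwaite df per measure.  The
family-level Tukey divisor defaults to the number of compared measures but
is exposed as a parameter, because published family sizes sometimes count
only the comparable measures.

Partial correlations residualize both variables on the control set by
least squares and test the residual correlation at df = n − 2 − c.  The
one-control case reduces to the textbook formula
(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)), which is a standing oracle test.

`null_calibration` simulates pure-noise matrices of a given shape and
verifies that the p < 0.05 tier captures ≈ 5% of pairs and the Tukey tier
≈ its own α — the screen's type-I behaviour is measured, not assumed.

## Bayesian model averaging

For a standardized response y and candidate set of size k, all 2^k linear
models are scored in closed form under the Zellner g-prior:

    log BF(M : null) = ((n − 1 − k_M)/2)·ln(1 + g) − ((n − 1)/2)·ln(1 + g·(1 − R²_M))

with a uniform prior over models (prior inclusion probability 1/2 per
candidate).  The implementation enumerates subsets grouped by size and
solves the batched systems β_S = R_S⁻¹ r_S on the correlation matrix, so
R² and the standardized coefficients come from the same solve; posterior
means shrink OLS coefficients by g/(1+g).  The enumeration is verified
against a naive model-by-model computation to 1e−10 and the single-model
Bayes factor against 2-D numerical quadrature of the g-prior integral.

**g defaults to n** (the unit information prior).  Where a "conventional
level of 1" is described for this prior in the literature of the cited
framework, it denotes the UIP — one observation's worth of information —
not a literal g = 1; a numeric override is accepted for sensitivity
analyses.

With prior inclusion odds of 1, a candidate's posterior inclusion
probability maps to a Bayes factor bf = pip/(1 − pip) (PIP 0.75 ↔ BF 3,
0.91 ↔ BF ≈ 10).  Evidence tiers: moderate [3, 10), strong10 [10, 30),
strong30 [30, 100), strong100 [100, ∞); null support: BF < 1/3 moderate,
< 1/10 strong.

**Rotation.**  When candidates outnumber what enumeration at small n can
sensibly carry, the eight causally closest candidates are enumerated
first; the five with the highest PIPs are retained and joined by the next
eight; rounds continue until all candidates have been evaluated, and the
final round's fit is reported.  Candidates evaluated but never retained
keep the PIP and coefficients from their last round — the only defensible
value, since they never appear in the final posterior.  "Causally closest"
means smallest causal-rank gap to the response, ties broken by registry
order; an ordering by prior significance would require peeking at fits
that have not happened yet.  Window 8 / retain 5 reflect the judgment that
more than five meaningful direct predictors per response is implausible at
these sample sizes.

**Small models.**  With three or fewer candidates, model enumeration is
uninformative and a weakly regularized linear model is used instead:
independent N(0, 2.5²) priors on standardized coefficients (ridge
shrinkage at the conventional weak scale), classical two-tailed inclusion
test at 0.05.  Its inclusions carry no Bayes factor; they are recorded at
the moderate tier.

## The path model

Following the nested-regression approach to path analysis on observed
variables, each measure in causal order (skipping the causally first) is
regressed on **all** causally prior measures via rotation-BMA (or the
small-model fit when ≤ 3 candidates).  Edges enter at BF ≥ 3, tiered at
10/30/100, sign = sign of the conditional posterior-mean standardized
coefficient; BF < 1/3 pairs are recorded as null-supported.  Every edge
runs from lower to higher causal rank, so the graph is acyclic by
construction.  For 29 measures, 406 ordered pairs are evaluated.

Path algebra: the indirect effect along a route is the product of its edge
betas; signs multiply (negative × positive × negative = positive);
parallel routes add.  Reduced models around a focal measure keep all
direct edges touching it and keep indirect edges only when they are strong
(BF ≥ 10) and lie on a chain of strong edges leading to or from the focal
measure; moderate indirect edges are pruned.

**Calibration.**  The procedure's error rates are measured by simulation.
Per response with 12 pure-noise candidates at n = 29, the mean number of
candidates reaching BF ≥ 3 is ≈ 0.3.  Over a full 29 × 29 all-noise
dataset (28 responses, 406 pairs) this compounds to a mean of ≈ 15
spurious edges (≈ 3.7% of evaluated pairs) — the BF ≥ 3 criterion at
n = 29 is liberal enough that a handful of noise edges per full model is
the expected cost, and substantive edge sets of several dozen should be
read with that base rate in mind.  On structured data the procedure is
sharp: on a seeded 6-node linear-Gaussian DAG with standardized paths
0.6–0.8 and n = 200, it recovers exactly the planted edge set with no
extras.

## Synthetic data: what it does and does not emulate

`generate_from_dag` simulates standardized measures from a linear-Gaussian
structural model: nodes in causal order, node = Σ β·parent + Gaussian
residual, residual SD solved so every node has unit variance (generation
errs if the structural variance alone exceeds 1 rather than silently
rescaling, keeping βs interpretable as standardized paths).  The implied
covariance is computed analytically and equals the path-tracing sum over
routes; Monte-Carlo agreement is a standing test.  `inject_missingness`
masks cells MCAR at a target rate (the study-like density is 11.1%) or as
an exact structural block (new institutions × historical measures).

What the generator does **not** emulate: non-Gaussian or nonlinear
structural relations, latent confounders, measurement unreliability
coupled to the structural model, informative (non-MCAR beyond block)
missingness, or the bounded/skewed scales of real percentage measures.
Passing recovery tests on this generator therefore shows the procedures
are correct and calibrated under their own assumptions; it does not show
that real institutional data satisfy those assumptions.

## Numerical choices and degenerate inputs

- Correlation p-values use `scipy.stats.t.sf`; |r| = 1 maps to p = 0.
- Model posteriors are normalized after subtracting the max log marginal
  (no overflow); PIPs are clipped to [0, 1] against accumulation error;
  PIP = 1 maps to BF = ∞, tier strong100.
- Singular candidate subsets (collinear columns) raise rather than being
  silently dropped.
- Constant columns are errors wherever a correlation or standardization is
  required, with the offending columns named.
- Hotdeck distance ties break by row order; the imputer uses no RNG.
- Matrices read empty cells and "NA" as missing and write missing as
  empty; unit ids are opaque strings (any merger/renaming of institutions
  is data preparation, not this package's concern).
- All simulation entry points take explicit seeds; the pipeline manifest
  records seed, config hash and package version, and identical configs
  produce byte-identical tables.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run entirely on printed inputs
and generated data: panels of 500 units for α recovery; n = 200 for DAG
structure recovery; 29 × 50 noise matrices (100–200 replicates) for screen
calibration; 29 × 29 noise datasets (20 in the script, 100 in the
acceptance suite) for path-procedure calibration; 40 × 15 matrices at
11.1% missingness for imputation quality.  These sizes give Monte-Carlo
error comfortably below the tolerances asserted while keeping a full run
in the minutes range on one CPU.

## Known limitations

- The rotation procedure is a heuristic screen; its selected set can
  differ from full enumeration when strong predictors are split across
  windows, and PIPs of never-retained candidates are conditional on their
  last evaluation round.
- Betas reported for edges are conditional on inclusion (the unconditional
  posterior means are also exposed); which convention a published model
  used is often unstated, and the two differ for middling PIPs.
- Small-model inclusions mix a frequentist 0.05 criterion into an
  otherwise Bayesian edge set; they are tagged by method in the pair
  table so the two kinds of evidence are never silently pooled.
- Aggregate-level associations do not license individual-level claims
  (the ecological inference caveat applies to every output of this
  package).
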