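# Methods

## The problem

A common two-stage workflow in biomarker studies clusters samples on
high-dimensional features (expression profiles, SNP panels, proteomics) and
then regresses a clinical outcome on the resulting class labels. The labels
are estimates, not observations: the clustering rule misassigns a
non-negligible fraction of samples. Treating them as true classes is
regression on a misclassified covariate, which attenuates effect estimates
and makes nominal 95% confidence intervals undercover — often severely, since
the bias does not shrink with sample size while the standard error does.

`misclasscal` implements two generally applicable corrections, an estimator
of the misclassification structure itself, and a Monte-Carlo engine that
quantifies bias and coverage of all methods under controlled conditions.

## Model and notation

Observations are i.i.d. triples (Y, Z, H): outcome, features, and a latent
class H in {1, ..., m}. The clustering produces an observed label H* whose
error law is the column-stochastic *misclassification matrix*

    Pi[i, j] = P(H* = i | H = j),

each column being the error distribution of one true class. (The R `simex`
package stores the transpose; conversion helpers are provided.) The outcome
model is a GLM or Cox proportional-hazards model with treatment contrasts:
class 1 is the reference, so the logistic model carries an intercept beta_1
plus class effects beta_2..beta_m, and the Cox model carries the m-1
log-hazard ratios. The *naive* estimator fits this model with H* in place of
H; its limit under misclassification is written beta(Pi).

### Regression calibration (RC)

Replace each class indicator by its conditional expectation given the data —
the posterior class probability P(H = h | Z = z) from a Gaussian mixture, or
a fuzzy c-means membership when the clustering is distance-based. The model
is then fitted unchanged on these soft indicators. RC costs nothing beyond
the naive fit. Wald intervals are reported without inflation for the
estimated posteriors (deliberately, matching common practice); when the
posteriors concentrate near 0/1, RC degenerates toward the naive fit, which
is its known weak spot.

### MCSIMEX

Simulation-extrapolation for categorical misclassification. Writing
G(lambda) = beta(Pi^(1+lambda)), the observed data sit at lambda = 0 and the
error-free target at lambda = -1. The algorithm:

1. for each lambda on a positive grid, draw B label sets with *extra* noise
   Pi^lambda applied to the observed labels (new label ~ Categorical of the
   column of Pi^lambda indexed by the current label);
2. refit the model on each noisy set and average the B estimates per lambda;
3. fit a parametric extrapolant through the naive estimate at lambda = 0 and
   the per-lambda means by least squares (default quadratic
   gamma_0 + gamma_1 lambda + gamma_2 lambda^2);
4. evaluate the extrapolant at lambda = -1.

Fractional powers use the spectral decomposition Pi^lambda =
E diag(Lambda^lambda) E^-1, which requires a real, strictly positive
spectrum; `check_existence` verifies this and scans a lambda grid for
negative entries. Entries in (-1e-10, 0) are treated as round-off, clipped,
and the columns renormalized; anything more negative raises. With Pi = I the
whole procedure collapses to the naive fit exactly (every refit sees the
original labels and the least-squares quadratic through constant points is
flat) — a structural fixed point the tests pin down.

### Variance

*Jackknife (default in the table reproductions):* at each lambda, the mean
model-based variance of the B refits minus the between-refit variance
estimates the sampling-variance component net of injected noise; these
components are extrapolated to lambda = -1 with the same functional form.
This estimator is known to be anticonservative — the simulation study shows
its coverage near 0.90 rather than 0.95 — and is tagged as such. A
non-positive extrapolated variance (rare, heavy noise) falls back to the
naive model variance with a warning.

*Full bootstrap:* resample the data, refit the clustering, re-estimate Pi
from the out-of-bag samples (confusion of in-bag-model predictions against
the reference labels on out-of-bag rows, column-normalized), run MCSIMEX on
the in-bag data, and take percentile intervals over the corrected estimates.
This propagates the uncertainty of Pi itself and is wider than the
jackknife. The point estimate is reported as the bootstrap median, alongside
the bootstrap mean and the plug-in fit at the element-wise average matrix
("average-MC" mode runs a single MCSIMEX at that average instead, trading
the Pi-uncertainty for a ~n_boot-fold cost reduction).

## Estimating Pi from a fitted clustering

Parametric Monte Carlo: for each class j, draw n_mc points (default 100 000)
from the fitted class-j Gaussian — mixture component for a GMM, per-cluster
empirical moments for k-means / fuzzy c-means — classify them with the
fitted rule (maximum posterior, or nearest center), and take column j as the
resulting assignment frequencies. Columns sum to one by construction. For
k-means the per-cluster moments are fitted to cluster *members*, which are
truncated at the cluster boundary; the resulting Pi therefore understates
the overlap when clusters are badly placed, which is exactly what happens in
the imbalanced scenario (see Limitations).

## The simulation engine

`Scenario` fixes the generating conditions of the benchmark study:

| parameter | default | meaning |
| --- | --- | --- |
| n | 1000 | samples per replicate (study grid: 200/500/1000) |
| prior_class1 | 0.5 | class-1 prior (0.5 balanced, 0.2 imbalanced) |
| component means | (-1, 0), (1, 0) | bivariate Gaussians, identity covariance |
| logistic truth | beta = (-1, 2) | intercept and class effect, log-odds |
| survival truth | log 2 | event time ~ Exp(rate = class), hazard ratio 2 |
| censor_rate | 0.5 | independent Exp censoring; ~2/3 and 4/5 events observed |
| replicates | 1000 | Monte-Carlo repetitions per cell |
| lambda grid / B | (0.5, 1, 1.5, 2) / 100 | simulation-extrapolation settings |
| n_mc | 100 000 | draws per class for the Pi estimate, fresh each replicate |

Each replicate derives six independent sub-streams (data, outcome,
clustering, fuzzy clustering, Pi estimate, noise injection) from
SeedSequence(master, replicate), so any component can be re-run in isolation
and results do not depend on execution order. Summaries are bias
(mean estimate minus truth) and coverage (fraction of Wald 95% CIs containing
the truth), each with Monte-Carlo standard errors.

**Reporting scale.** The published logistic benchmark grids print bias on
the log-odds scale; the survival grids print it on the *hazard-ratio* scale
(mean exponentiated estimate minus the true hazard ratio 2). This is visible
in the numbers themselves: at the clustering's ~0.16 error rate the
large-sample naive Cox coefficient bias is -0.24, and exp(log 2 - 0.24) - 2
= -0.42 is what the tables show. `summarize(..., hazard_ratio_scale=True)`
reproduces that convention; coverage is scale-invariant.

## Numerical choices

- **GMM fitting** uses EM with k-means++ starts, 10 restarts, up to 500
  iterations. The covariance structure is chosen by BIC among full, tied,
  diagonal and spherical — the standard model-based-clustering recipe. This
  matters: an unconstrained full-covariance fit at n=1000 misclassifies at
  ~0.184 against the 0.159 Bayes rate of the study scenario and visibly
  overshoots the attenuation, while the BIC choice (spherical here) sits at
  ~0.166. The EM stopping tolerance is 1e-4 on the per-sample mean lower
  bound and the covariance floor is 1e-6; a tighter floor invites degenerate
  spike components at n=200 that quasi-separate the downstream regression.
- **k-means** is Lloyd's with k-means++ and 10 restarts; empty clusters are
  re-seeded internally by scikit-learn. Fuzzy c-means uses fuzzifier 2
  (the conventional default), tolerance 1e-7 on memberships.
- **Label alignment** resolves cluster-identity switching by maximum
  agreement (optimal assignment on the confusion matrix), permuting labels,
  posterior columns and fitted components jointly. Posterior argmax ties
  break toward the lowest class index.
- **Cox fitting** is a vectorized Newton solver on the partial likelihood
  with Efron tie handling and step halving, validated against lifelines to
  1e-6 in coefficients, standard errors and log-likelihood. It exists
  because the extrapolation loop refits the model tens of thousands of
  times; per-fit overhead, not asymptotics, dominates a study run.
  Logistic fits use statsmodels Newton ML.
- **Failed refits** inside the noise loop (separation under heavy injected
  noise) are dropped with a warning and the divisor reduced; a failure rate
  above 20% at any lambda raises. Per-replicate method failures are recorded
  as missing cells rather than aborting the replicate.

## What the generator does and does not emulate

The synthetic data reproduce the benchmark's generating law exactly:
low-dimensional Gaussian classes, outcome depending on the true class only,
independent exponential censoring. Real applications differ in ways the
simulations do not probe: features are high-dimensional and non-Gaussian
(the clustering model is then misspecified in ways BIC cannot repair),
outcomes may depend on features beyond the class, censoring may be
informative, and classes may not be exchangeable with any Gaussian mixture
component. Passing tests therefore certify the estimators' behavior under a
correctly specified clustering model with a known error structure — not
performance on any particular omics data set.

## Known limitations

- With imbalanced classes, k-means drags cluster sizes toward equality; the
  per-cluster Pi estimate is then misspecified (truncated-member moments)
  and MCSIMEX cannot fully repair the naive bias. Our residual intercept
  bias (~0.97 from naive 1.08) is even larger than the published residual
  (~0.81), whose exact Pi-estimation intermediate is not recoverable from
  the description; the qualitative pathology — correction fails, use the
  GMM instead — is identical.
- Jackknife SEs undercover by construction (~0.90); prefer the bootstrap
  when the extra cost is affordable.
- RC reports model-based Wald intervals with no correction for posterior
  estimation error, and collapses toward the naive fit when posteriors are
  extreme.
- Only logistic and Cox outcome models are implemented; no continuous-
  covariate SIMEX, no validation-subsample designs for Pi.
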