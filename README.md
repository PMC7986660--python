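# misclasscal

Bias-corrected regression on class labels produced by unsupervised
clustering.

Clustering samples on molecular features and regressing a clinical outcome
on the resulting groups is everyday practice in biomarker research. The
cluster labels, however, are estimates: a fraction of samples is assigned to
the wrong class, and a regression that treats the labels as true classes is
*attenuated* — effect estimates shrink toward zero and confidence intervals
undercover, no matter how large the study. `misclasscal` treats this as a
covariate-misclassification problem and provides:

- **MCSIMEX** — misclassification simulation-extrapolation: inject extra
  label noise at levels `Pi^lambda`, refit the model, fit a curve in
  `lambda`, and extrapolate to `lambda = -1` (no noise). Works with logistic
  regression and Cox proportional hazards.
- **Regression calibration (RC)** — replace the class indicators with
  posterior class probabilities (GMM responsibilities or fuzzy c-means
  memberships) and fit the model unchanged.
- **Misclassification-matrix estimation** — the column-stochastic matrix
  `Pi[i, j] = P(observed class i | true class j)`, estimated either by Monte
  Carlo from a fitted clustering model or out-of-bag within a bootstrap.
- **A simulation engine** that measures bias and CI coverage of the naive,
  RC and MCSIMEX estimators under controlled two-class Gaussian scenarios,
  side by side with published reference values.

The model is a GLM / Cox model with treatment contrasts,
`g(E(Y | H=h)) = x_h' beta` with class 1 as reference; the MCSIMEX target is
`G(lambda) = beta(Pi^(1+lambda))` extrapolated to `G(-1)`. See
`docs/methods.md` for the full account.

## Worked example

Labels drawn as Bernoulli(0.5), flipped with probability 0.2 (so `Pi` is
known exactly), logistic outcome with true class effect 2 on the log-odds
scale:

```bash
$ misclasscal demo-extrapolation --seed 0 --outdir demo
naive class effect:      0.9570
corrected class effect:  1.4589
true class effect:       2.0000
curve data written to demo/
```

The naive fit on the corrupted labels recovers barely half of the true
effect. MCSIMEX refits the model at increasing noise levels
`lambda in (0.5, 1, 1.5, 2)` (100 refits each), fits a quadratic through the
mean estimates, and extrapolates back to the no-noise point: 1.46, roughly
halving the attenuation — the quadratic is an approximation to the true bias
trajectory, so some residual bias remains. `demo/` holds the per-refit
scatter, per-lambda means, fitted curve and corrected point as CSV for
plotting.

The same correction through the library API:

```python
import numpy as np
from misclasscal import MisclassMatrix, ModelSpec, SimexConfig, mcsimex

pi = MisclassMatrix(np.array([[0.8, 0.2], [0.2, 0.8]]))
result = mcsimex(y, labels, pi, ModelSpec("logistic", 2),
                 SimexConfig(seed=0), variance="jackknife")
result.naive_fit.coefficients   # attenuated
result.corrected                # extrapolated to no noise
result.ci_95                    # jackknife Wald intervals (anticonservative)
```

For data-driven pipelines, `fit_gmm` / `fit_kmeans` / `fit_fuzzy_cmeans`
cluster the features, `align_labels` fixes label switching against a
reference, `estimate_from_fitted_clustering` produces `Pi` from the fitted
model, `fit_rc` runs regression calibration, and `variance_bootstrap` wraps
the whole pipeline — clustering, out-of-bag `Pi`, MCSIMEX — in a bootstrap.

## The simulation study

```bash
misclasscal simulate --table 1 --replicates 1000 --seed 0          # full
misclasscal simulate --table 3 --replicates 200 --reduced --seed 0 # cheap
```

runs every cell of a benchmark grid (sample sizes 200/500/1000, GMM and
k-means clustering, balanced or imbalanced classes, logistic or survival
outcome) and writes a CSV comparing our bias/coverage with the published
reference values shipped in the package. Survival grids report bias on the
hazard-ratio scale, matching the published convention. Headline behavior at
n=1000, balanced classes, GMM clustering: naive class-effect bias about
-0.69 log-odds (coverage ~0), MCSIMEX about -0.12, RC about -0.03 — and the
imbalanced k-means grid reproduces the uniform-cluster-size pathology that
no downstream correction fully repairs.

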