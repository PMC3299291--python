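# Methods

## The models

Both models map the six molecular property descriptors
(OxidHL, P[BD], logBioHL, AlogP, ASol, MW — always in this canonical
order) to the clinical MRTD in mg/kg/day.

**Linear model.**  The published equation is an ordinary least-squares
fit on the 23 training compounds:

    MRTD = −34.3303 − 12.20·AlogP + 2.1249·ASol + 15.90·logBioHL
           + 0.2159·MW + 5.659·OxidHL + 46.5133·P[BD]

`published_mlr()` carries these printed coefficients verbatim.  Where the
published coefficient table and the published equation disagree in the
last digit (ASol 2.1239 vs 2.1249, AlogP −12.1995 vs −12.20), the
equation's values are used: they reproduce the published external-test
prediction column to four decimals for seven of the eight compounds,
the printed-table variant only to three.

`DescriptorLinearRegression.fit` re-estimates the model.  The solve is
delegated to statsmodels' QR-based OLS; the explicit normal-equations
solve exists only as an independent oracle in the test suite.  Inference
follows the classical conventions that reproduce the published table:
residual df = n − 7 (six slopes + intercept), RSD = √(SSE/(n−7)),
MCC = √R², ANOVA F = (R²/6)/((1−R²)/(n−7)), coefficient t-tests against
Student's t with df = n − 7.  Rank-deficient designs are rejected with
the collinear columns named; no variable selection, weighting or
regularization is performed (the source analysis fit all six descriptors
once).

**Neural network.**  The published 6-2-1 network is shipped as exact
constants taken from its printed SPSS-style scoring code: hidden unit 1
is *affine* (identity activation, post-scale 0.10899…), hidden unit 2 is
tanh-squashed (post-scale 1.44376…), and a third, constant unit
contributes −0.53525….  The hidden sum S is mapped to dose units by

    MRTD = ((S / 2) + 0.5) · 199.9625 + 0.0375

i.e. a min–max denormalization over the training-dose range
[0.0375, 200.0].  Two representation choices deserve note:

* The printed code adds a separate constant to each input product; these
  seven constants are folded into a single per-unit bias.  The fold is an
  arithmetic identity, but it is *proven*, not assumed: a tiny
  interpreter executes the printed code statement by statement and the
  test suite requires agreement with the folded evaluator to 1e−9 on all
  31 compounds and 1000 random descriptor vectors.
* Although the surrounding text describes two nonlinear hidden neurons,
  the printed code squashes only the second unit.  The code is taken as
  ground truth, which is why hidden units carry per-unit activation tags
  rather than a layer-wide activation.  Because unit 1 is unbounded,
  predictions can leave the denormalization range in both directions —
  no clipping is applied, consistent with the published negative and
  >200 mg/kg/day predictions (e.g. Ribavirin, 200.16).

**Trainer.**  `TanhNetworkRegressor` retrains the same representation
with stochastic (per-pattern) error backpropagation.  Choices, with
defaults:

* architecture 6-H-1 with H = 2 weighted tanh units (the published
  minimalistic structure); unit post-scales act as output weights and one
  trainable constant as the output bias; divisor = H.
* learning rate 0.7 (published value), no momentum.
* inputs standardized to training z-scores internally; the scaling is
  folded into the exported weights so saved models consume raw
  descriptors, exactly like the published code.
* targets min–max scaled from the training subset; a degenerate range is
  an error.
* initial weights uniform on [−0.5, 0.5]; per-epoch pattern order
  shuffled; both driven by one seeded `numpy` generator, so equal seeds
  give bit-identical fits.
* stopping: `max_epochs` (2000) or no best-RMSE improvement > 1e−6
  mg/kg/day for `patience` (200) epochs — a deterministic replacement for
  the source's wall-clock plateau rule.  The best-so-far weights are
  returned, so the recorded best-RMSE path is non-increasing by
  construction.  Non-finite loss raises a divergence error naming the
  epoch.

Backprop gradients are verified against central finite differences
(relative error ≤ 1e−5) in the tests.  Exact weight-level reproduction of
the published training run is not attempted — it depends on unstated
software internals — so the trainer is validated by properties:
recovering a known noiseless teacher network to < 1 % of the target range
and beating the null-model RMSE (the training-dose SD, 45.53) on the real
table.

## Validation statistics

* **RMSE** uses divisor n (the mean squared error), which is what
  reproduces both published test-set RMSEs from the published
  squared-error columns.
* **Kendall tau** is tau-a from inversion counting,
  τ = 1 − 4D/(n(n−1)).  For n ≤ 10 the two-sided p-value is exact:
  2·min(P(D ≤ d), P(D ≥ d)) under the Mahonian inversion-count
  distribution (computed by convolution; cross-checked in tests against
  full permutation enumeration and scipy's exact method).  Larger samples
  use z = 3τ√(n(n−1))/√(2(2n+5)).  Ties trigger a tau-b fallback with a
  warning.  The published tau values are reproduced exactly; the
  published p-values (0.019, 0.035) match neither exact enumeration
  (0.014, 0.031) nor the plain normal approximation and are therefore
  reported with a method tag rather than asserted.
* **Bland–Altman** differences are clinical − predicted, limits at
  bias ± 1.96·SD (sample SD).  This direction and multiplier reproduce
  both published limit pairs; the multiplier is exposed as an option but
  fixed at 1.96 by default to keep the reproduction bit-stable.
* **Goodness of fit** reports both R² definitions — 1 − SSE/SST and the
  squared Pearson correlation — because the published training-fit R²
  (0.992) is consistent with neither (both give ≈0.985 here) and the two
  differ in general for non-least-squares predictors.  Neither is
  asserted against 0.992.

## The bundled dataset

31 compounds, 23 training / 8 test, stored as plain CSV with P[BD] as a
0–1 fraction (the printed column head says "%", the printed values are
fractions).  A Unicode minus in input is normalized to ASCII.  Two
internal inconsistencies of the printed source table were found and
handled:

* **Tipranavir's training MRTD** is stored as 16.70, not the printed
  6.670.  With 16.70 — and only with it — every derived statistic
  published alongside the table reproduces to its printed precision: the
  training mean/SD/CV (28.54/45.53/159.52), all OLS refit statistics
  (R² 0.5970, MCC 0.7727, F 3.9507, RSD 33.89, every coefficient, SE and
  p-value), the network training fit (RMSE 5.53, MAX 13.64), and all six
  univariate correlations.  Tipranavir's label dose (500 mg twice daily
  ≈ 16.7 mg/kg/day at 60 kg) corroborates the dropped digit.
* **The training MW footer mean** (362.72) disagrees with its own rows
  (364.72) while the footer SD matches exactly; the rows are kept as
  printed and that single footer cell is treated as a misprint.

One residual rounding artifact remains: the published external-test
prediction for Efavirenz (−10.2863) cannot be reproduced from the
printed descriptor digits (which give −10.2876); the published
squared-error column confirms the original value, so the 0.0013 gap
stems from descriptor digits beyond the table's printed precision.  The
`reproduce` command allows 0.002 for that one cell and 0.001 for the
other seven.

## Synthetic data

The generator emulates the *distributional shape* of the training table,
not chemistry: lognormal marginals (moment-matched mean/SD) for OxidHL
(0.672/2.769), ASol (6.15/10.90) and MW (362.72/178.20); a beta law for
P[BD] (0.402/0.394 — U-shaped, like the real column); normal laws for
AlogP (0.939/2.809) and logBioHL (−2.5133/1.5738).  Descriptors are
independent by default (matching the reported lack of multicollinearity);
an equicorrelation knob couples them through a Gaussian copula for stress
tests.  Doses are truth-model predictions plus N(0, noise_sd²), with
noise_sd defaulting to 30 mg/kg/day (the order of the linear model's
residual SD on the real table), floored at 0.01 mg/kg/day so every record
satisfies the dose-positivity invariant.  The floor is a generator
artifact: it censors negative true-model predictions, so exact-recovery
tests use an intercept-shifted truth whose predictions stay positive.
Descriptors are drawn before the noise from a single seeded generator,
making datasets byte-identical under a fixed seed and the coefficient
error exactly proportional to noise_sd across a noise ladder.

Passing tests on this synthetic material demonstrates estimator
correctness (recovery, coverage, determinism) — not predictive validity
on real chemistry, which only the bundled clinical table speaks to, and
only at n = 31.

## Problem sizes and limitations

All reproduction computations run on the 31-compound table itself
(seconds on one CPU); property tests use n ≤ 1000 synthetic records, 200
replicates for CI coverage, and 1000 random vectors for evaluator
equivalence.  Known limitations: the dose models are specific to the
antiretroviral chemical space and descriptor set they were built on; the
network trainer implements plain online backprop (no momentum,
single hidden layer) by design; and descriptor computation from
structures is deliberately out of scope.
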