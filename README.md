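# mrtdpred

QSPR models for the **maximum recommended therapeutic dose** (MRTD,
mg/kg/day) of antiretroviral drugs.

The MRTD is the empirical human dose threshold above which dose-related
adverse effects appear.  For antiretrovirals — a chemically diverse class
that is often dosed near that threshold — being able to estimate the MRTD
directly from computed molecular properties is useful early in formulation
and delivery work, before clinical data exist.  `mrtdpred` implements a
published pair of such models, built on six descriptors per compound:

| descriptor | meaning | units |
|---|---|---|
| `oxid_hl` | oxidative (atmospheric) half-life | days |
| `p_bd` | probability of ready biodegradation | 0–1 |
| `log_bio_hl` | log₁₀ whole-body biotransformation half-life | log₁₀ days |
| `alogp` | octanol–water partition coefficient | – |
| `asol` | aqueous solubility | g/L |
| `mw` | molecular weight | Da |

The package is aimed at pharmaceutical / cheminformatics scientists who
want to reproduce, audit, or retrain these dose models.  Computing the
descriptors themselves from structures is out of scope; they come from
standard property-estimation software.

## What's inside

* **The published MLR equation**, evaluated verbatim:

  MRTD = −34.3303 − 12.20·AlogP + 2.1249·ASol + 15.90·logBioHL
  + 0.2159·MW + 5.659·OxidHL + 46.5133·P[BD]

* **The published 6-2-1 neural network** with its exact printed weights:
  two weighted hidden units (one affine, one tanh) plus a constant unit,
  with min–max output denormalization
  MRTD = ((S/2 + 0.5)·199.9625) + 0.0375,
  where S is the hidden-layer sum.  A statement-by-statement interpreter
  for the published SPSS-style `COMPUTE` scoring code serves as an
  independent oracle, and any network can be exported back into that
  dialect.

* **Refitting and retraining from scratch**:
  `DescriptorLinearRegression` (OLS with classical inference — coefficient
  SEs, t/p at df = n−7, R², MCC = √R², RSD, ANOVA F) and
  `TanhNetworkRegressor` (online error backpropagation, learning rate 0.7,
  seeded and bit-reproducible).  Both follow the scikit-learn estimator
  protocol (`fit`/`predict`/`get_params`).

* **Method-comparison statistics**: RMSE and squared-error tables,
  Kendall's tau-a with *exact* small-sample p-values from the
  inversion-count (Mahonian) distribution, Bland–Altman limits of
  agreement (bias ± 1.96·SD of clinical − predicted), and a two-model
  comparison report.

* **The 31-compound dataset** (23 training / 8 external-test compounds)
  bundled as a CSV fixture, plus a seeded synthetic-data generator with
  the same statistical shape and a known ground-truth model for testing.

## Worked example

```python
import mrtdpred as mp

ds = mp.load_arv_mrtd()                     # bundled 31-compound table
mlr = mp.published_mlr()                    # Eq.-style linear model
ann = mp.TanhNetworkRegressor.from_spec(mp.published_network())

comp = mp.compare_models(ds, mlr, ann, labels=("mlr", "tnn"), subset="test")
for rep in comp.reports:
    print(rep.label, round(rep.predictions.rmse, 2),
          round(rep.rank_correlation.tau, 3),
          round(rep.agreement.upper_loa, 1), round(rep.agreement.lower_loa, 1))
```

prints

```
mlr 27.28 0.714 58.3 -17.4
tnn 13.69 0.643 29.8 -27.3
```

i.e. on the 8 external-test compounds the network predicts the clinical
dose with half the RMSE of the regression (13.69 vs 27.28 mg/kg/day) and
clearly narrower limits of agreement, while the regression ranks the
compounds slightly better (tau 0.714 vs 0.643; exact two-sided p-values
0.014 and 0.031).  Per-compound prediction tables are in
`rep.predictions.table`.

The same workflow is available from the shell:

```sh
mrtdpred predict --model published-ann --subset test
mrtdpred fit-mlr --output mlr.json
mrtdpred train-ann --seed 7 --output ann.json
mrtdpred validate --plots figures/
mrtdpred generate-synthetic --n 100 --seed 1 --output synth.csv
mrtdpred reproduce        # checks every reference cell, non-zero exit on miss
```

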