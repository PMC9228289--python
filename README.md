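# qsarval

Fitting and validation statistics for descriptor-based QSAR models, built
around a reference dataset of 44 bicyclo((aryl)methyl)benzamide GlyT1
(glycine transporter type 1) inhibitors.

A QSAR (quantitative structure–activity relationship) model maps numeric
molecular descriptors to a biological activity. Here the response is
Log₁₀IC₅₀ from a locomotor activity assay and the descriptors are
polarizability (αe), surface tension (ɣ), torsion energy (TE), hydrogen-bond
donor count (HBD), stretch energy (SE) and topological diameter (TD). The
package fits the linear model

    Log₁₀IC₅₀ = b₀ + b₁·αe + b₂·ɣ + b₃·TE + b₄·HBD + b₅·SE + b₆·TD

by ordinary least squares, and a quadratic ("MNLR") variant on the design
augmented with squared descriptor columns (squares that are exactly collinear
with the linear design — HBD², since HBD takes only the values 1 and 2 — are
pruned automatically).

Fitting a model is the easy part; the point of the package is the validation
battery that decides whether the model should be trusted:

- coefficient inference (SE, t, p, 95% CI) and the regression ANOVA;
- leave-one-out cross-validation, Q²cv = 1 − PRESS/SStot;
- external validation on held-out test molecules (both the squared
  observed-vs-predicted correlation R²ext and the strict predictive form
  with the training mean in the denominator);
- Y-randomization: refitting after random permutation of the activities to
  estimate the chance-correlation null, summarized by
  cR²p = R·√(R² − (mean R_rand)²);
- leverage-based applicability domain with the Williams plot
  (warning leverage h\* = 3K/n, K = p + 1 parameters);
- the Golbraikh–Tropsha criteria battery (R² > 0.6, R²adj > 0.6,
  R²test > 0.6, Q²cv > 0.5, randomization averages below the model's own
  statistics, cR²p > 0.5).

A synthetic-data module generates descriptor tables with known ground truth
(linear or quadratic signal plus Gaussian noise, and a pure-noise null
variant) so every stage is testable without external data.

## Worked example

```python
import qsarval as qv

dataset = qv.load_glyt1()                    # 44 molecules, flags included
train, test = qv.split(dataset)              # 35 train / 7 test (2 outliers dropped)

model = qv.fit_ols(train.X, train.y)
print(qv.fit_metrics(model))
# {'R': 0.8299, 'R2': 0.6887, 'R2_adj': 0.6220, 'RMSE': 0.6572}

print(qv.q2_loo(train.X, train.y).q2)        # 0.5720  (internal predictivity)

rand = qv.y_randomization(train.X, train.y, n_runs=100, seed=1)
print(rand.avg_R2, rand.crp2)                # 0.164, 0.607 (chance-correlation null)

ad = qv.williams_analysis(dataset)
print(ad.h_star, ad.outlier_ids)             # 0.6, [1, 32]
```

The fit explains ~69% of the activity variance (F = 10.32 on 6 and 28 df),
holds up under leave-one-out (Q²cv = 0.57 > 0.5), beats all 100 permuted
refits (average randomized R² ≈ 0.17 vs 0.69; cR²p ≈ 0.60 > 0.5), and the
applicability-domain analysis flags exactly the two molecules (ids 1 and 32)
whose leverages exceed h\* = 0.6 — the same two an initial PCA screen marks as
poorly explained.

The same pipeline runs from the shell and exits non-zero if the
Golbraikh–Tropsha report rejects the model:

```sh
qsarval run --model both --yrand 100 --seed 42 --out report/
qsarval synth --n 35 --seed 1 --out synthetic.csv   # generated data + truth sidecar
```

`report/` then holds `coefficients.csv`, `anova.csv`, `predictions.csv`
(fitted, cross-validated and external predictions per molecule), `yrand.csv`,
`domain.csv`, `gt_report.json` and a Williams plot.

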