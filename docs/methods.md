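# Methods

## Data model

A dataset is a table of molecules with six descriptors (αe polarizability, ɣ
surface tension, TE torsion energy, HBD hydrogen-bond donor count, SE stretch
energy, TD topological diameter), an observed activity (Log₁₀IC₅₀), a
train/test flag, and an outlier flag. The bundled GlyT1-inhibitor table has
44 molecules: 35 training, 9 test, of which ids 1 and 32 are flagged
outliers. The outlier flags are stored in the fixture rather than re-derived,
because the PCA-based screening that first singles them out has no sharp
quantitative criterion; the leverage analysis below re-detects both
independently (h = 2.58 and 6.78 against h\* = 0.6), so the flag is
corroborated, not merely asserted. Numeric parsing accepts the Unicode minus
sign and comma decimal separators, both of which occur in typeset versions of
such tables.

## Models

**MLR.** Ordinary least squares with intercept of Log₁₀IC₅₀ on the six
descriptors. Fitting and coefficient inference (SE, t, two-sided p, 95% CI
from Student t with n−K df) are delegated to statsmodels; the package stores
the residuals, hat-matrix diagonal and residual scale that the validation
statistics need. RMSE is defined with the residual-degrees-of-freedom
denominator, √(SSE/(n−K)) — i.e. the square root of the ANOVA error mean
square — not √(SSE/n); on the reference fit this gives 0.657, consistent with
the error mean square 0.432 of the published ANOVA.

**MNLR.** The "non-linear" model is OLS on the quadratic design
Y = a₀ + Σ(aᵢXᵢ + bᵢXᵢ²). In auto mode each candidate squared column is
projected onto the span of the columns already in the design (intercept
included) and dropped when the relative residual norm is below √1e−10; on the
reference table this prunes HBD² (HBD ∈ {1, 2}, so HBD² = 3·HBD − 2 exactly)
and keeps the other five squares, an 11-term design. Predictions for new rows
reuse the training-derived term set rather than re-running the rank test, so
small query sets cannot silently change the design.

**Stepwise selection** (forward-backward on partial-F p-values,
p_enter = 0.05, p_remove = 0.10 by default, ties broken by column order) is
provided as a utility. On the reference table it stalls at {TE, TD}: the
other four descriptors are only significant jointly, not along the greedy
path. The six-descriptor reference model is therefore fitted directly on the
printed descriptor set — whose full-model partial p-values are all ≤ 0.045 —
rather than taken from a stepwise run.

## Validation statistics

**Leave-one-out Q²cv** = 1 − Σ(ŷ₍₋ᵢ₎ − yᵢ)² / Σ(yᵢ − ȳ)², where ȳ is the mean
of all n training activities (not the n−1 subset means; this reading
reproduces the published value 0.572045). The default implementation uses the
exact hat-matrix identity ŷ₍₋ᵢ₎ = yᵢ − eᵢ/(1 − hᵢᵢ); an explicit
refit-n-times route is kept alongside and the two are asserted equal to
1e−9 in the tests.

**External validation.** Two statistics are computed. `r2_external` is the
squared Pearson correlation between observed and predicted test activities —
the value read off an observed-vs-predicted scatter, and the form the
reference study's R²ext = 0.63 (MLR) / 0.68 (MNLR) corresponds to. `r2_test`
is the strict predictive form 1 − Σ(ŷ − y)²/Σ(y − ȳ_train)²; on the reference
test set it is −0.015, far below the correlation form, because the seven test
molecules cluster around the training mean while two of them are badly
over-predicted. Both are reported; the Golbraikh–Tropsha report uses the
correlation form for comparability with the reference study. Users doing
regulatory-grade validation should look at both numbers: a high correlation
with a negative predictive R² means rank order is right but calibration is
not.

**Y-randomization.** The activity vector is permuted uniformly at random
(without replacement), the same design refitted, and R, R² and LOO Q²
recorded per run; 100 runs by default, driven by a single seed through
numpy's Generator, so reruns are bit-reproducible. Q² inside each run uses
the same LOO procedure as the original model. The summary
cR²p = R·√(R² − (mean R_rand)²) uses the mean of the per-run R values (the
per-run R² mean is reported separately, as its own criterion). A radicand
within 1e−12 below zero is treated as zero; a genuinely negative radicand
raises an error — the model is then indistinguishable from chance and cR²p
is undefined. Under the permutation null E[R²] ≈ p/(n−1) = 6/34 ≈ 0.176 for
the reference design, which the 100-run average (≈ 0.16–0.18 depending on
seed) matches.

**Golbraikh–Tropsha report.** Seven criteria with strict inequalities:
R² > 0.6, R²adj > 0.6, R²test > 0.6, Q²cv > 0.5, mean randomized R² < R²,
mean randomized Q² < Q²cv, cR²p > 0.5. A value exactly at a threshold fails.
The report is exported as JSON and drives the CLI exit status.

## Applicability domain

Leverage h(x) = xᵀ(XᵀX)⁻¹x with the intercept entry included; warning
leverage h\* = 3K/n with K = p + 1 = 7 and n = 35 training molecules, giving
exactly 0.6. Standardized residuals are raw residuals divided by the training
RMSE (for test molecules too — standard external-AD practice), with ±3 as the
response-outlier band. Classification: leverage outlier iff h > h\*, response
outlier iff |standardized residual| > 3, both labels may co-occur.

The pipeline-level `williams_analysis` pools the 42 in-domain candidate
molecules (35 training + 7 non-outlier test) to form the hat-matrix basis and
scores the flagged outliers as external queries against it. This choice is
deliberate: in the training-only basis molecule 33's leverage is 0.621,
fractionally above h\*, while in the pooled basis it is 0.596, below — and the
pooled reading is the one under which the published classification (1 and 32
out, 33 in, everything else in domain) is internally consistent. The generic
`leverages(X_train, X_query)` primitive keeps the conventional training-only
basis for users who want it; the two disagree materially only for points
sitting on the boundary, as molecule 33 does.

## Synthetic data

The generator draws descriptors independently and uniformly within the ranges
the reference table spans (αe ∈ [38, 54], ɣ ∈ [38, 58], TE ∈ [5, 60],
HBD ∈ {1, 2}, SE ∈ [2.2, 5.2], TD ∈ {10…14}; counts as integers), and builds
the activity as a known linear (optionally quadratic) function plus Gaussian
noise, default σ = 0.66 — the residual scale of the reference fit. Bounded
uniform marginals preserve the leverage geometry the AD module assumes;
integer HBD ∈ {1, 2} makes HBD² exactly collinear by construction, so the
design-pruning path is always exercised. An outlier-injection option appends
points at 1.5× the ranges. The null variant keeps the descriptor geometry and
replaces the activity with independent standard normals.

What the generator does *not* emulate: the correlation structure among real
descriptors (real αe and TD are correlated; generated columns are
independent), the clustered, discrete character of real descriptor values,
and the heavier-than-uniform concentration of TE in the low range. One
consequence is quantitative: with independent uniform descriptors over the
full TE range the signal variance is much larger than in the real table, so a
generated dataset at σ = 0.66 fits with R² ≈ 0.97, not ≈ 0.69. Consistency
between the reference noise scale and the reference R² is therefore checked
by regenerating noise on the fixture's own descriptors, where the simulated
mean R² is ≈ 0.70. Passing tests on synthetic data demonstrate correctness of
the estimators and calibration of the inference under the stated model, not
robustness to real-data pathologies such as collinearity or non-Gaussian
noise.

## Numerical and design choices

- Rank checks use numpy's SVD-based matrix rank; rank-deficient designs raise
  an error naming the dependent column(s).
- Correlation filtering drops, from the most-correlated pair, the column with
  the larger mean |r| against the remaining pool (ties by column order);
  constant columns are removed first with a warning. The filter is
  deterministic and idempotent.
- PCA is eigendecomposition of the correlation matrix; each loading vector's
  sign is fixed so its largest-magnitude entry is positive, making score
  plots reproducible.
- The k-means splitting utility standardizes descriptors, uses
  k = ⌈n·(1 − train_fraction)⌉ clusters and takes the record nearest each
  centroid as a test member; deterministic for a fixed seed. The bundled
  table uses its printed flags, not this utility.
- All pipeline randomness (Y-randomization) flows from one seed; reruns with
  the same configuration produce byte-identical report files.

## Problem sizes

The reference analyses are small (35 training molecules, 7 parameters), so
everything runs in seconds: the full validation battery including a 100-run
Y-randomization with LOO inside each run takes well under a minute on one
CPU. Monte-Carlo checks in the test suite use 200–1000 replicates, enough to
pin the simulated means within the asserted tolerances.

## Known limitations

- No descriptor computation from structures: descriptor values are inputs.
- Inference assumes homoscedastic Gaussian errors; no robust covariance.
- The AD module implements only the leverage/Williams approach — no
  distance-to-model, kNN or density variants.
- External validation offers R²test and the correlation form only; Q²F2/Q²F3
  and the concordance correlation coefficient are out of scope.
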