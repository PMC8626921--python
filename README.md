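# foxcache

Behavioural classification of collar accelerometry and spatially
explicit prey-caching inference for a small, actively hunting
terrestrial predator.

## The problem

Small predators handle their prey too quickly to leave the GPS
location clusters that reveal kills of large carnivores. When a
foraging behaviour has a diagnostic acceleration signature, however,
the kill/cache record can be read directly off a collar accelerometer.
The canonical case is the arctic fox in a goose colony: food caching
involves a stereotyped head-down digging sequence, so classifying
tri-axial acceleration into *running*, *walking*, *digging* and
*motionless* turns a summer of collar data into a spatio-temporal map
of caching effort that can be confronted with prey (goose nest)
density.

`foxcache` implements that full analysis chain as a tested library:

1. **Synthetic campaign generator** — 30-s tri-axial bursts at 50 Hz
   every 4.5 min and a GPS fix every 4 min per fox, behaviour driven by
   a semi-Markov dwell-time process, movement by a correlated random
   walk, a patchy goose-density raster with dens, and per-burst digging
   events drawn from a complementary log-log model with known
   coefficients — so every downstream stage is testable by parameter
   recovery, without any field download.
2. **Training preparation** — BORIS-style annotation logs are shifted
   onto the accelerometry clock, raw ethogram names collapse onto the
   four categories, and 3-s windows wholly covered by one behaviour
   become the training set.
3. **Features** — 52 summary statistics per 3-s window: per-axis
   moments, extrema, percentiles, mean crossings and first differences;
   cross-axis correlations and covariances; ODBA, VeDBA and
   vector-magnitude summaries.
4. **Classification** — eight algorithms (3-NN, linear and RBF SVM,
   decision tree, random forest, Gaussian naive Bayes, LDA, neural
   network) under stratified 5-fold cross-validation with shared
   folds; out-of-fold predictions pool into one confusion matrix per
   algorithm, scored per behaviour by one-vs-rest

   ```
   accuracy  = (TP + TN) / (TP + TN + FP + FN)
   precision = TP / (TP + FP)
   recall    = TP / (TP + FN)
   ```

   with count-weighted averages across behaviours; model selection
   maximizes weighted precision (ties: digging precision, then
   weighted accuracy).
5. **Spatio-temporal fusion** — each burst takes the closest same-fox
   GPS fix within 30 s of the burst interval, then goose density
   (raster cell lookup), reproduction period (year-specific phenology
   dates), distance to the nearest den and fox covariates; an ordered
   exclusion cascade drops records within 2 days of capture, off-map,
   pre-season, or within 50 m of a den.
6. **Caching model** — a binomial GLMM with cloglog link
   `P(dig) = 1 − exp(−exp(η))`,
   `η = β0 + β1·z(density) + β2·brooding + β3·z·brooding + β4·female +
   β5·non-reproductive + β6·female·non-reproductive + u_fox + v_year`,
   crossed Gaussian random intercepts, fitted by penalized IRLS inside
   a Laplace-approximate likelihood maximized over the two variance
   parameters. Wald inference, population-level prediction curves.

The GLMM engine is written here (group-indexed `bincount`
crossproducts keep 55,000-burst fits at a few seconds); standard steps
(classifiers, GLM oracle, file formats) ride on scikit-learn,
statsmodels and pandas.

## Worked example

Score a pooled out-of-fold confusion matrix (rows = actual,
columns = predicted; order running/walking/digging/motionless):

```python
import numpy as np
from foxcache import ConfusionMatrix, compute_metrics

cm = ConfusionMatrix(np.array([
    [141,   4,  1,   0],
    [  5, 116,  2,   3],
    [  3,   5, 37,   4],
    [  3,   3,  0, 333],
]))
print(compute_metrics(cm).rounded())
```

```
                  accuracy  precision  recall
running              97.58      92.76   96.58
walking              96.67      90.63   92.06
digging              97.73      92.50   75.51
motionless           98.03      97.94   98.23
weighted_average     97.65      95.00   95.00
```

Digging is classified conservatively: precision 92.5% (only 7.5% of
windows called digging are wrong) at the cost of recall 75.5% (24.5%
of true digging windows are missed) — the right trade-off when false
caching events are the costly error.

Simulate a campaign-scale analysis table with known coefficients and
recover them:

```python
from foxcache import SimConfig, simulate_covariate_table, fit_glmm_cloglog

cfg = SimConfig(seed=1)            # true β1 = 0.16, σ_fox = 0.46, σ_year = 0.07
table, effects = simulate_covariate_table(
    cfg, seed=1, n_foxes=16, n_fox_years=23, bursts_per_fox_year=500)
fit = fit_glmm_cloglog(table)
print(fit.fixed.round(3)[["estimate", "se"]])
print(f"sigma_fox = {fit.sd_fox:.3f}, sigma_year = {fit.sd_year:.3f}")
```

```
                                   estimate     se
intercept                            -1.379  0.230
density_std                           0.147  0.023
period_brooding                       0.074  0.036
density_std:period_brooding          -0.112  0.034
sex_female                            0.713  0.322
status_nonreproductive               -0.008  0.307
sex_female:status_nonreproductive    -1.441  0.464
sigma_fox = 0.447, sigma_year = 0.016
```

The burst-level density slope (truth 0.16) is recovered within its
standard error; fox-level contrasts are noisier because only 16 foxes
inform them, exactly as in a real campaign.

The same chain is scriptable from the shell:

```bash
foxcache simulate --seed 1 --foxes 4 --hours 3 --out campaign/
foxcache run-all --input campaign/ --out artifacts/
foxcache report --out artifacts/
```

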