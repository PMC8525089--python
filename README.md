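# lakeddg — depth diversity gradients of submerged macrophytes

Lakes compress one of the steepest environmental gradients in nature —
light, temperature, and disturbance all change drastically over a few
metres of depth — yet the *depth diversity gradient* (DDG) of submerged
aquatic plants is rarely quantified. `lakeddg` is an analysis pipeline for
Water-Framework-Directive-style macrophyte monitoring data: per-lake
transect surveys recording species presence in four depth classes
(0–1, 1–2, 2–4, > 4 m), together with monthly physiochemistry and
water-level statistics. It is written for freshwater ecologists who want
to characterise DDG shape, its environmental drivers, and its change over
years — and for method developers, since a built-in synthetic lake
generator with closed-form expectations makes every stage testable
without external data.

## What it computes

For each *field campaign* (one lake mapped in one year):

- **Additive richness partition along depth.** At each depth-class
  midpoint *d* ∈ {−0.5, −1.5, −3.0, −5.0} m:
  α(d) = mean over transects of the per-transect species count,
  γ(d) = species count of the union over transects, and
  β(d) = γ(d) − α(d) ≥ 0 (additive turnover).
- **DDG peak measures.** D_max = depth of the richness maximum (tied
  classes average their midpoints) and R_max = the maximum itself; for α
  these are per-transect peaks averaged across transects. Curves are
  classified as *decreasing* (D_max > −1 m), *shallow hump*
  (−2 < D_max ≤ −1), *deep hump* (−4 < D_max ≤ −2) or *increasing*
  (D_max ≤ −4).
- **Depth statistics.** Simultaneous all-pairs (Tukey-type) contrasts of
  richness between depths that are robust to heteroscedasticity and
  unequal group sizes: a cell-means model with HC3 sandwich covariance
  and single-step max-|t| adjusted p-values (seeded Monte-Carlo from a
  multivariate t); Pearson correlations between components; a chi-square
  association of pattern types with components.
- **Environmental drivers.** Annual means of 12 monthly physiochemical
  variables (≥ 8 monthly values required; below-detection counted as 0),
  the stratification proxy Tempsd (SD of temperature across 0/−2/−4/−6 m),
  water-level fluctuation WLF = MHW − MLW, and lake area; log-transformed,
  standardized, PCA-reduced to the leading axes (> 80 % cumulative
  variance, each axis named by the variables with > 40 % of their variance
  on it); stepwise additive mixed models (penalized cubic splines + lake
  random intercept, REML) for each D_max / R_max response, with per-term
  drop contributions; a PERMANOVA representativeness check of the
  complete-data subset.
- **Temporal change.** Invariability coefficients IC = mean/sd over
  survey years and per-lake plus pooled linear year-trends with
  significance marks (*** / ** / * / . at .001/.01/.05/.1).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
12-lake system (4 transects per lake, 4 survey years, 60-species pool):

```bash
python analysis/01_simulate.py          # writes results/data/
python analysis/02_partition_richness.py
python analysis/03_ddg_patterns.py
python analysis/04_env_drivers.py
python analysis/05_temporal_trends.py
```

`02` prints the mean DDG curves and the richness range:

```
mean richness per depth (across campaigns):
  alpha  -5.0m  1.15  -3.0m  6.18  -1.5m  7.28  -0.5m  4.52
  beta   -5.0m  2.18  -3.0m  9.34  -1.5m 10.24  -0.5m  7.13
  gamma  -5.0m  3.33  -3.0m 15.52  -1.5m 17.52  -0.5m 11.65
total gamma per campaign: 22-34 (mean 27.40)
```

— a hump-shaped mean profile peaking at −1.5 m for all three components,
exactly what the generator's overlapping Gaussian depth niches should
produce. `03` classifies the per-campaign curves (all campaigns fall in
the two hump classes here) and finds all six alpha depth contrasts
significant at .05. `04` reduces the abiotic table and fits the driver
models:

```
environmental records: 48 campaigns, 36 complete
retained 6 axes (cumulative variance 85%):
  PC1 (25%): Chl & N_tot & Temp & Tempsd & Area
  PC2 (17%): Cond & WLF
  ...
PERMANOVA: pseudo-F = 0.60, p = 0.634 -> representative
  d_max_alpha: adjR2 = 0.34; retained: PC3 (p=0.00296, dc=37.0%)
  d_max_beta: adjR2 = 0.01; retained: none
```

Because the generator draws physiochemistry independently of the
communities, retained axes here reflect the selection's controlled
false-positive rate — the validation studies below quantify exactly that.
`05` prints the lakes × measures trend matrix (sign plus significance
mark) and the stability table; the depth of the beta/gamma peak comes out
as the least stable measure (mean IC ≈ 2.4–3.2 against ≈ 7–27 for the
others), as expected for argmax-type statistics of noisy profiles.

The same pipeline runs end-to-end on CSV inputs in the documented schemas
(`surveys.csv`, `lakes.csv`, `waterlevel.csv`, `monthly.csv`):

```bash
lakeddg all --input-dir my_data/ --seed 1 --out results/run1
```

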