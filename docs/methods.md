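# Methods

This note records the model conventions, parameter choices and numerical
decisions behind `lakeddg`, and what the synthetic validation does and
does not establish about real monitoring data.

## Data model and filtering

A survey row is one taxon in one depth class of one transect of one field
campaign (lake × year). Depth classes are fixed at 0–1, 1–2, 2–4 and
> 4 m and are converted at ingestion to signed midpoints −0.5, −1.5, −3.0
and −5.0 m (the open-ended class by convention); all downstream APIs use
midpoints. The five-step Kohler abundance is carried through but ignored
by every richness computation, which is presence/absence.

The selection gate keeps deep (max depth > 10 m), natural, dimictic lakes
with unregulated water level. Record-level rules drop emergent and
floating-leaved growth forms and records not determined to species rank.
Campaign-level rules drop campaigns mapped along a single transect and
lakes left without a repeat mapping (< 2 distinct survey years). The two
campaign-level rules are iterated to a fixed point, which makes the
filter idempotent — a reapplication removes nothing — at the price that a
lake can lose its repeat status when its only other campaign fell to the
single-transect rule. Removal counts per rule are logged as JSON lines.

## Richness partitioning

Every transect of a campaign contributes a count (possibly 0) to each of
the four depth classes: the survey protocol spans shoreline to the lowest
plant occurrence, so an empty class is an observed zero, and the mean
defining alpha is taken over all transects. Gamma is the union count per
class, beta = gamma − alpha. Alpha is kept at full precision; since it is
a mean of integers, alpha + beta = gamma holds exactly in floating point.
No multiplicative or pairwise dissimilarity (Sørensen/Jaccard) is
computed; the partition is strictly additive.

## Peak measures and pattern classes

A transect's peak is the maximising depth class; tied classes average
their midpoints, so peaks can fall between classes. For alpha, D_max and
R_max are the means over transects of the per-transect peak depth and
peak count — R_max is deliberately *not* the maximum of the mean profile
(a regression test pins the difference). Transects with no species at any
depth have no argmax and are excluded from the averages, with a count
reported. Beta and gamma peaks are taken on the campaign-level profile.

Pattern classes partition [−5, −0.5] by D_max: decreasing (> −1),
shallow hump (−2, −1], deep hump (−4, −2], increasing (≤ −4). Boundary
values, reachable only through tie averages, go to the deeper class — a
uniform "deeper wins" convention that is unobservable on pure midpoints.

## Robust simultaneous depth contrasts

Richness is compared across depths with all-pairs contrasts of a
cell-means model. Each group mean's variance is estimated by the HC3
(leave-one-out inflated) sandwich, so heteroscedasticity and unequal
group sizes are handled; contrast covariances share group terms. The
single-step adjusted p-value of contrast *j* is P(max_k |T_k| ≥ |t_j|)
under the joint null, approximated by seeded Monte-Carlo: correlated
normals from the contrasts' correlation matrix divided by a shared
χ²-based scale with the residual degrees of freedom — i.e. a multivariate
*t*. The t-scaling matters at the study's group sizes: with a plain
normal reference the familywise error sat at the top of its target band
in calibration runs, with the t reference it centres near 0.05 (measured
0.050/0.054 at 2,000 null datasets, 4 × 25 observations). With two groups
the adjusted p reduces analytically to the marginal two-sided t p-value.
Default 100,000 Monte-Carlo draws (4,000 in the calibration studies,
where only the 0.05 decision is needed). On an exactly homoscedastic
balanced fixture (one standardized residual vector repeated per group,
n = 100) the adjusted p-values agree with classical Tukey HSD within
0.006; the residual gap is the HC3 factor n/(n−1) on the variance scale.

## Environmental records

Annual means use surface samples only, require ≥ 8 monthly values, and
count below-detection values as zero. Tempsd is computed per month as the
SD across the 0/−2/−4/−6 m series and then averaged over complete months
(≥ 8 required): monthly-then-average preserves the seasonal
stratification signal that pooling would dilute. WLF = MHW − MLW; when
derived from a raw gauge series, MHW/MLW are the means of the annual
extremes (the standard hydrological summary). Log transforms are natural
logs; a column containing zeros is offset by half its smallest positive
value; pH is exempt (already a log scale). Negative inputs are errors.

The PCA is computed on standardized columns (correlation matrix — the
units are incommensurable), axes oriented so the largest-magnitude
loading is positive. The retained set is the minimal prefix of axes with
cumulative explained variance > 0.80. An axis is named by every variable
whose variance it carries to more than 40 %, i.e. squared variable–axis
correlation (loading² × eigenvalue) > 0.40. The representativeness of the
complete-data subset is tested by PERMANOVA (scikit-bio) on Euclidean
distances of the standardized peak measures, subset vs rest; p > .05 is
reported as "representative".

## Additive mixed models and stepwise selection

Each D_max / R_max response is modelled as intercept + one penalized
cubic-spline smooth per retained PCA axis + a lake random intercept.
Smooths use 8 cubic B-spline basis functions on equally spaced knots with
the exact curvature penalty ∫f″² (computed by two-point Gauss quadrature
per knot interval, which is exact for cubics); its null space is exactly
the linear functions, so infinite smoothing leaves a straight line and
the model degenerates to a linear mixed model (verified against GLS to
10⁻³). The sum-to-zero constraint is absorbed by a QR projection. The
random intercept is a ridge-penalized dummy block; its penalty λ_re
equals σ²/σ_b², so the reported random-effect variance is σ²/λ_re. All
penalties are selected jointly by restricted maximum likelihood (profiled
σ², L-BFGS-B on log₁₀ λ with a coarse restart); GCV is available as an
alternative.

Smooth-term significance is a Wald-type test on the function scale:
T = f̂ᵀ V_f⁻ f̂ with V_f the term's posterior covariance at the data
points, pseudo-inverted at rank ⌈edf⌉, referred to F(r, n − edf_total).
The ceil rank is deliberately conservative; coefficient-space truncation
was rejected because its leading-variance directions are exactly the
least-informed ones and discard the signal.

Backward elimination removes the least significant smooth until all
survivors are significant at 0.05. Because the procedure retains the
best-looking of the initial candidate axes, the stopping rule uses
Šidák-adjusted p-values, 1 − (1 − p)^m₀ with m₀ the initial candidate
count; this controls the probability of retaining any spurious axis at
the threshold (with unadjusted uniform p-values that probability is
1 − 0.95³ ≈ 14 % for three candidates, irreducible by better
calibration). Measured over 200 null responses (60 campaigns, 6 lakes,
3 axes): 93–95.5 % of runs end with the empty model; a genuine smooth
(sin with amplitude ≈ 3 × noise SD) is retained in 100 % of runs.

"Deviance explained" is computed on the smooth (fixed) part only,
relative to the empty intercept + random-intercept model, so that the
drop contribution — the percentage-point fall in deviance explained when
a term is refitted out of the retained model — equals the total deviance
explained when a single term is retained, exactly. Adjusted R² uses the
full fitted values (random effect included) with effective degrees of
freedom.

## Temporal trends

Trends are ordinary least squares of each measure on calendar year (not
year index, so uneven sampling intervals are honoured), per lake (≥ 3
survey years; shorter series are skipped and logged) and pooled. Two
flagging thresholds coexist deliberately: the per-lake tables mark
significance down to p < .1 (with ./*/**/*** classes), while pooled-trend
statements use .05; both are reported rather than reconciled. Because
depths are negative, a positive D_max slope means the richness peak
becomes shallower — a unit test pins this sign convention. Invariability
IC = mean/sd uses the sample SD and, for the (negative) depth measures,
the magnitude of the series; constant series are flagged as perfectly
stable rather than given an infinite coefficient silently.

## Synthetic lake systems

The generator emulates the structure of a state monitoring archive of
deep perialpine lakes: per-transect presence/absence in four depth
classes, lake metadata, gauge statistics, and monthly physiochemistry for
12 variables with temperature at four depths. Species have Gaussian depth
niches — presence probability p(d) = p_max · exp(−(d − opt)²/2τ²) scaled
by a per-lake affinity — drawn independently per transect × depth. This
is the simplest mechanism that produces hump-shaped alpha profiles by
geometric niche overlap and a known expectation
E[α](d) = Σ_s affinity_s · p_s(d), whose argmax is recorded as truth. It
is a stand-in, not a claim about macrophyte biology. Beta structure
arises from affinities and independent draws only; there is no spatial
autocorrelation, no light/temperature growth mechanism, and no
disturbance model. Physiochemistry is annual mean + seasonal sinusoid +
Gaussian noise with variable ranges matching deep-lake monitoring tables;
months go missing at 10 % (50 % in occasional sparse years, which pushes
campaigns below the 8-month rule and out of the complete-data tier), and
low values of the trace nutrients are flagged below-detection with the
value retained, so the zero-substitution rule is exercised. Environment
and communities are generated independently, so driver models fitted to
synthetic data estimate a true null — their retained terms measure the
selection's false-positive rate. Multi-year drifts shift niche optima
linearly (m/yr, positive = shallower) and grow or shrink the accessible
species pool; injected signs are recorded as truth.

Defaults are the study conditions: 28 lakes, 3 transects, 3 survey
years, a 75-species pool. Passing tests on this generator establishes
algorithmic correctness against known truth; it does not validate the
niche model against real macrophyte communities, nor the driver models
against real limnology.

## Validation studies and problem sizes

The acceptance harness regenerates everything from a seed: the
partitioning oracle (1,000 random toy campaigns vs brute-force set
enumeration, exact match required); alpha-peak recovery (200 lake systems
with expected peak at −3.0 m, |D̂ − truth| ≤ 0.75 m); max-t familywise
error (2,000 null datasets) and Tukey-HSD agreement; stepwise selection
(200 null responses, 60 signal responses, drop identity); trend-sign
recovery (200 replicates, drifts +0.5 m/yr and +2 species/yr) and
permuted-year null flagging (500 replicates of 2 lakes × 8 biennial
years — shorter or sparser series make richness counts too discrete for
the t reference). These sizes complete in ~90 s on one CPU.

## Known limitations

- The four-class depth resolution cannot localise peaks more finely than
  tie averages; no smooth reconstruction of the DDG curve is attempted.
- The lower depth limit of colonisation is not modelled; increasing
  patterns are truncated humps by construction.
- Smooth-term p-values are approximate (penalized Wald); they are tuned
  to be conservative for selection, not for effect-size inference.
- The PERMANOVA uses Euclidean distances on standardized measures only.
- GCV/REML smoothing selection can hit local optima; a coarse restart is
  used, not a global search.
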