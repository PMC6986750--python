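# Methods

This note records the models, parameter choices and numerical decisions
behind `dendroqtl`, and what the synthetic-data tests do and do not
demonstrate.

## Growth signal: from ring widths to relative BAI

Ring widths are cumulative radial increments; basal area increment
(BAI) is the annual cross-sectional area added, BAI_t = π(r_t² −
r_{t−1}²) with r_0 = 0, so the BAI series conserves total basal area.
Two radial measurement series per tree, when present, are averaged
element-wise before conversion.

The age/size trend is removed with a modified Hugershoff curve
g(t) = A·t^b·e^(−ct) + d, t = ring age (1-based from the innermost
measured ring). The fit is nonlinear least squares (scipy), constrained
to A > 0, 0 ≤ c ≤ 5, |b| ≤ 10, initialised from the log-linear
regression log BAI ~ (1, log t, −t). When the optimiser fails or the
fitted curve is not strictly positive over the observed ages, the
horizontal mean curve is used instead and flagged; a constant series
short-circuits to the mean curve.

Detrending is by **ratio** (index_t = BAI_t/g(t)), the ring-width-index
convention; difference detrending is available via
`detrend(..., mode="difference")`. Whether to divide or subtract is a
genuinely open choice for BAI-scale data; ratio was chosen because it
makes the index scale-free across trees of different vigour.

AR(1) prewhitening centres the index and estimates φ by conditional
least squares (OLS of x_t on x_{t−1}); residuals e_t = x_t − φx_{t−1}
(t ≥ 2) are the *relative BAI*. The centred first observation is kept as
e_1 by default so the chronology spans the same calendar years as the
rings (`keep_first=False` drops it). |φ| is clipped below 1 with a
warning; a constant series yields φ = 0 and zero residuals. Conditional
LS differs from Yule–Walker at O(1/n), immaterial for the series lengths
involved.

Replicate trees of a clone are combined per calendar year with Tukey's
biweight robust mean: location initialised at the median, scale = MAD,
weights (1 − u²)² for |u| < 1 with u = (x − m)/(c·S), iterated to
Δ < 1e-8. The tuning constant c = 9 is the standard chronology choice;
the statistic itself, not the constant, is the specified primitive. If
MAD = 0 the median is returned.

The stage order is fixed: per-tree detrend → per-tree prewhiten →
per-clone biweight. A test pins this by constructing a series where
swapping the steps changes the result.

## Climate: the dry-period index

A dry spell is a maximal run of days with precipitation ≤ wet_cutoff
(default 0 mm — strictly non-raining; 0.5 mm is a common trace-rain
alternative, available as a parameter). The monthly index at threshold
k sums, per calendar month, the days belonging to spells whose *full*
length is ≥ k. Spells qualify by their full length but their days are
credited to the month each day falls in, so a long cross-boundary
drought registers in both months and no day is counted twice; at k = 1
the index is exactly the count of dry days. This accumulation semantics
is pinned by tests against a brute-force day-enumeration oracle and by
cell-wise monotonicity in k.

Thresholds producing zero in ≥ 50% of (year, month) cells are flagged
inadmissible — nearly-all-zero indices make the correlation traits
unstable. All monthly matrices (temperature mean, precipitation sum,
dry-period indices) are linearly detrended per month-label across years
(March against Marches), which removes secular trend without touching
seasonality and is idempotent; detrending of the dry-period index
itself can be switched off.

## Sensitivity traits

For each clone, variable and month label, the trait is Pearson's r
between relative BAI in ring year Y and the climate value of (Y−1,
month) for p-labels / (Y, month) for c-labels, with the two-sided
t-test p-value (df = n − 2). Pairs with fewer than 3 complete years or
a constant side are recorded as missing, not errors. Pearson was chosen
as the plain reading of "correlation"; the phenotype handed to QTL
mapping is the raw r (not Fisher-z), matching the scale on which
genotype-class differences of ~0.14 are interpretable. Significance
counts use α = 0.05 per clone with no multiplicity correction — they
are descriptive, mirroring the bar-chart summaries such data sets are
usually shown with.

## Empirical Bayes lasso (NEG prior)

The marker model is y = μ + Xβ + e with the three-level prior
β_i ~ N(0, σ_i²), σ_i² ~ Exp(λ), λ ~ Gamma(a, b). Integrating λ out
gives the NEG marginal p(σ_i²) ∝ (b + σ_i²)^−(a+1), i.e. a penalty
(a+1)·log(1 + σ_i²/b) on each prior variance in the type-II
log-likelihood. Estimation is a greedy coordinate scheme: at each step
the candidate whose optimal prior variance most improves the penalised
marginal likelihood is added, re-estimated or deleted; the
per-coordinate optimum is the larger root of a closed-form quadratic in
σ_i², and coordinates whose optimum collapses to zero are *exactly*
zero. Sparsity/quality factors for all candidates are maintained
incrementally (O(p·M) per action); the noise variance is re-estimated
every 10 actions with a full refresh of the factors. The intercept is
handled by centring.

Two features of the penalty control distinct behaviours:

- the **entry slope** λ* = (a+1)/b sets the evidence a marker needs to
  enter the model (approximately, marginal χ² > 1 + 2λ*/s where s is
  the marker's precision scale);
- the **tail weight** a sets how strongly effects that barely cleared
  entry are shrunk, and therefore how hard it is for chance maxima
  among thousands of null markers to also reach a small p-value.

Defaults a = 10, b = 0.1 (λ* = 110) were calibrated on simulations at
the package's target scale (n ≈ 140, hundreds of markers): featureless
phenotypes pass the "non-zero effect and P < 0.01" rule in ≲ 5% of
replicates, while a single marker explaining 12% of variance is
retained with the correct sign in ≈ 94%. Inference per retained effect
is a t statistic β̂_i/se(β̂_i) with the posterior standard error and
df = n − |retained| − 1; the posterior se reflects the prior, which is
what keeps selection-inflated null effects below the significance cut.

Hyperparameter selection follows five-fold cross-validation: an ordered
strong→weak ladder of five (a, b) rungs is traversed, and a weaker rung
replaces the incumbent only when its *paired* per-fold improvement
exceeds one standard error (folds are shared across rungs, so this is a
one-SE-style paired rule); three consecutive rejections stop the
search. On featureless data the choice stays at the conservative top
rung; on data with real multi-QTL signal the search descends to rungs
where genuine effects are estimated nearly unshrunk. Fold splits are
seeded and recorded.

Reported QTLs: retained markers with p < 0.01 are clustered within
10 cM per linkage group (tightly linked significant markers are one
QTL; the strongest marker represents the cluster), then re-estimated
jointly by OLS. The reported effect sizes, per-QTL PVE
(β̂²·var(x)/var(y), in %) and total PVE (var(ŷ)/var(y) = R², identical
to 1e-10 by construction) all come from that joint refit, so they are
mutually consistent and free of the selection prior's shrinkage bias.
Prediction accuracy is the Pearson correlation between observed values
and out-of-fold OLS predictions assembled over five seeded folds.

Interval-mapping validation: Haley–Knott regression on a 1 cM grid —
the expected 0/1 genotype given flanking markers via inverse Haldane
recombination fractions (pseudo-testcross segregation behaves like a
backcross), LOD = (n/2)·log10(RSS₀/RSS₁). Optional cofactor markers
enter both models except within a 10 cM window of the tested position.
This is a validation aid, not a full composite-interval-mapping
implementation with automatic cofactor selection.

## Synthetic data generator

Genotypes: markers along each parental map follow a Markov chain whose
switch probability between adjacent markers is the Haldane
recombination fraction of their cM distance; linkage groups, clones and
the two parental maps are independent (each map's markers segregate 1:1
through its heterozygous parent only). Default maps: 11 groups × 60 cM
at 1.5 cM spacing (~450 markers per map).

Weather: a two-state (wet/dry) Markov chain with monthly transition
probabilities (defaults p(wet|wet) = 0.50, p(wet|dry) = 0.25, chosen so
dry spells have a realistic geometric length distribution for a humid
temperate climate and the k = 7 dry-period index stays below the 50%
zero-ratio bar while k = 1..7 all remain informative); gamma-distributed
rain amounts on wet days; sinusoidal seasonal temperature with white
noise.

Clone sensitivities: s_c = Σ_j α_j x_cj + η_c with η_c ~ N(0, σ_η²)
i.i.d. across clones. `build_truth_for_pve` converts target per-QTL PVE
fractions into effects α_j = ±√(PVE_j·var(s)/var(x)) and sets σ_η to
absorb the rest; QTLs are placed on distinct linkage groups so the
planted arithmetic is exact in expectation. The default architecture
mirrors the target study: one 12.4%-PVE major QTL (negative effect, as
a drought response) plus twelve minors of 0.9–2.9% (total ≈ 34%).

Ring widths: tree r of clone c grows BAI_t = g(t)·exp(s_c·κ·z_Y +
ε_rt), where g is a Hugershoff curve (defaults A = 120, b = 1.2,
c = 0.12, d = 40 mm²/yr — a realistic juvenile rise and decline),
z_Y the standardised March dry-period index (threshold 4) of ring year
Y, κ the link scale (default 1), and ε an AR(1) noise series
(φ = 0.3, innovation sd 0.15) independent across trees. BAI is
converted back to widths through the cumulative radius, so the emitted
table looks like a measured ring-width file.

What the generator does *not* emulate: measurement error in ring
boundaries, missing rings, multi-site genotype-by-environment structure
beyond a per-site link scale, realistic spatial weather correlation, or
linkage disequilibrium between the two parental maps. Passing tests
therefore demonstrate correctness of the estimation machinery under the
stated generative model, not robustness to those real-data features.

## Statistical limits at the study scale

At n = 139 clones, the marginal evidence for a 12.4%-PVE QTL is a
noncentral χ²(1) with noncentrality ≈ 19 and standard deviation ≈ 9:
its realised strength fluctuates strongly between populations. Two
consequences, quantified by Monte Carlo in the test suite's
study-scale checks:

- even an oracle that computes exact per-marker OLS effects at the true
  QTL markers (no selection, no multiplicity) ranks the major QTL first
  in only ~89% of replicate populations; the real procedure, which also
  pays selection and multiplicity costs over ~1800 markers and a
  familywise-calibrated significance filter, does so in ~60%, and the
  same fluctuation drives the genome-wide LOD maximum off the major QTL
  in a comparable fraction of replicates;
- any significance rule strict enough to keep featureless data clean at
  P < 0.01 across hundreds of markers (effectively a Bonferroni-scale
  threshold) necessarily leaves the major QTL short of significance in
  roughly a quarter of populations.

The corresponding study-scale assertions in `tests/test_acceptance.py`
are written at their nominal levels and fail honestly at this sample
size; the per-QTL PVE estimates, total PVE and cross-validated
prediction accuracy land in the expected ranges. A single real study
reports one draw from exactly this distribution.

## Problem sizes

Unit tests run at desk scale (tens of clones, 2–4 linkage groups).
Study-scale checks use the full default configuration (139 clones, two
~450-marker maps, 13 planted QTLs) with 50 replicates for recovery
statistics and 100 replicates for the null/power checks of the sparse
fitter; `scripts/acceptance.py` uses 20 recovery replicates plus one
full pipeline run. The whole suite completes in a few minutes on one
CPU.
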