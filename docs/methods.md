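# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `hrmclock`. Nothing here states an empirical result that
the tests or `scripts/acceptance.py` do not themselves compute.

## Melt-curve normalization and the Df value

A raw HRM curve is fluorescence F(T) on a strictly increasing temperature
grid. For each gene a pre-melt and a post-melt window (closed intervals in
°C) are configured where the signal sits on its linear plateau; the
defaults are the published assay settings for the two elephant loci,
67–68 / 82–83 °C for *RALYL* and 66–67 / 80–81 °C for *TET2*. Straight
lines L_pre and L_post are fitted by ordinary least squares to the raw
signal inside each window (at least two grid points required per window)
and the curve is mapped to a percent-helicity scale:

    N(T) = 100 · (F(T) − L_post(T)) / (L_pre(T) − L_post(T)).

This is invariant to any affine transform a·F + c (a > 0) of the raw
signal. The melt-shift threshold is fixed at zero — no temperature shift is
applied — because curve *shape* carries the methylation signal and shifting
would distort it. A non-positive denominator anywhere on the grid means the
baselines touch or cross (e.g. a flat curve) and is a hard error.

The difference curve is the sample's normalized curve minus the plate's
0 %-methylated standard, the baseline being the average of the baseline
replicates after normalization (replicates are normalized independently;
averaging before normalization would couple their baseline fits).
Interpolation between grids is linear and extrapolation is forbidden — the
difference is restricted to the overlapping temperature range. The Df value
is the maximum absolute difference over the grid, ties resolved to the
lowest temperature. Duplicate reactions are aggregated by the arithmetic
mean of their Df values; a configurable concordance limit (default 20 % of
Dfmax) flags — but does not reject — discordant duplicates.

A `difference_mode = derivative` switch computes the difference between
negative first derivatives (−dN/dT) instead of between normalized curves.
The default is the normalized-curve difference, the established
Gene-Scanning convention; on the synthetic designs both modes lead to the
same calibration behaviour because the derivative is a linear operator.

## PCR-bias calibration

Unmethylated template amplifies preferentially, so the measured Df is a
saturating function of the true methylation rate M (%). The standard-curve
model is

    a · M/(100 − M) = Df/(Dfmax − Df),

equivalently the forward map Df(M) = Dfmax · r/(1 + r) with
r = a·M/(100 − M). Dfmax is **pinned** to the measured (replicate-averaged)
Df of the 100 % standard — it is defined as that measurement, and freeing it
would change the model. The anchors at 0 and 100 % are reproduced by
construction and are excluded from the residual by default
(`include_anchors` reverses this). The single free parameter `a` is fitted
by least squares on Df over the interior standards (at least three
required), minimizing in log space with bounded scalar searches over three
overlapping intervals around a = 0.1, 1 and 10 (bounds 1e−6…1e6, x-tolerance
1e−12 in log a). Noise-free recovery is exact to well below 1e−6 (tested
over a ∈ {0.2, 0.5, 1, 2, 5}).

Inversion is closed-form: with R = Df/(Dfmax − Df), M = 100·R/(a + R);
Df ≤ 0 maps to 0 % and Df ≥ Dfmax to 100 %, with a clamp flag — clamping is
the contract, not an error, because instrument noise can push a sample
past the standards. The inversion is strictly increasing on (0, Dfmax) and
round-trips with the forward map to 1e−9. For a < 1 the map is steepest at
low methylation (|dM/dDf| at 5 % exceeds that at 70 %), which is why
low-methylation differences are the hardest to resolve on biased assays.

Calibration is per gene per plate (standards are run on every plate);
fits serialize to JSON.

## The melt simulator

Synthetic raw curves are a two-species mixture. Each species melts with a
logistic helicity profile h(T) = 1/(1 + exp((T − Tm)/s)) of width s
(default 0.8 °C); the methylated species melts ΔTm = 3 °C higher. The
logistic is *truncated*: affinely rescaled so it reaches exactly 1 at
Tm − 6s and exactly 0 at Tm + 6s, and held constant beyond. This keeps both
species perfectly flat inside the normalization windows, which makes the
measured Df exactly linear in the amplified methylated fraction q — the
identity the calibration oracle rests on. (A pure logistic leaks ~1e−3 of
its tails into the windows and would break that identity at the third
decimal; the truncation confines the approximation to a region the
pipeline never uses.) Default Tm placements keep both transitions strictly
between the windows and are validated against the assay.

PCR bias acts once on the final product: a true methylated fraction p
amplifies to

    q = p / (p + b·(1 − p)),   b ≥ 1,

so Df/(Dfmax − Df) = q/(1 − q) = p/(b(1 − p)) and the fitted coefficient
is analytically a = 1/b. This single-action choice trades per-cycle realism
for an exact algebraic oracle connecting the simulator to the calibration
model. Baselines are straight lines in arbitrary fluorescence units with
Gaussian noise (default sd 2, ≈0.4 % of the ~490-unit dynamic range) added
pointwise. The grid is 65–95 °C at 0.02 °C (1501 points) — far coarser than
the instrument's acquisition rate implies, chosen for tractability.

## The cohort generator

`CohortSpec` defaults emulate the reference study design: 25 individuals,
53 blood samples (each individual sampled once, the remaining 28 samples
assigned at random, giving 28 consecutive within-individual pairs), first
ages uniform on 0.2–65 years, resampling gaps uniform on 1–4 years,
3 males / 22 females, and 6 individuals flagged with estimated (rather than
recorded) birth years. Methylation of locus g in sample j of individual i is

    m_gij = α_g + β_g · age_ij + λ_g · u_i + ε_gij,   clipped to [0, 100],

with a *shared* standard-normal factor u_i per individual and independent
per-sample residuals ε. Defaults: RALYL-like α = 25 %, β = +0.35 %/y,
λ = 9.4 %, residual sd 5 %; TET2-like α = 35 %, β = −0.25 %/y, λ = 5.5 %,
residual sd 3 %. These were calibrated by Monte-Carlo against the
generator's own noise model so that the realized per-locus age correlations
centre near +0.52 and −0.60 at this design size.

The shared factor — a global per-individual methylation shift loading on
both loci with the same sign — is the structural choice that matters. It
models batch/cell-composition-like variation and is what a two-locus model
can cancel (the loci's age slopes have opposite signs, so the combination
orthogonal to the loadings removes u while adding signal). This is why the
combined model dramatically outperforms either single locus under grouped
cross-validation, while independent per-locus individual effects could not
reproduce that pattern. All randomness flows from one seed; identical seeds
give identical datasets.

What the generator does **not** emulate: non-uniform zoo age structure,
assay failure/dropout, bisulphite-conversion variability, per-CpG
heterogeneity within the amplicon, and any nonlinearity of the
methylation-age trend. Passing tests therefore demonstrate that the
pipeline recovers the structure this model encodes, not that real elephant
data has that structure.

## Age model

The clock is an epsilon-SVR with radial kernel on per-locus methylation
rates, z-scored with training-partition statistics only. Hyperparameters
are grid-searched — cost 2^−2…2^7 (log-2 steps), epsilon
{0.05, 0.1, 0.2, 0.5, 1}, gamma {0.5, 1}; all config-exposed because
printed results depend on them — scored by individual-grouped k-fold
(k = min(10, #individuals)) pooled mean absolute error, ties broken toward
the smallest cost, then epsilon, then gamma. Fold assignment (a seeded
shuffle of individuals) is the only stochastic element.

Cross-validation is leave-one-individual-out: every sample of one
individual forms the test fold and the model is tuned and fitted on the
rest. Tuning default is *per fold* (no information from the held-out
individual ever reaches model selection); `tune_once` tunes a single
parameter set on the full dataset first, which mirrors the common
single-global-`tune.svm` workflow and is what the multi-seed studies here
use (one tune per dataset, ~25× cheaper, and the workflow a single
published parameter table implies). R² is reported as the squared Pearson
correlation between predicted and chronological age (the
simple-linear-regression convention); a 1 − SSE/SST variant is available
and differs whenever predictions are biased.

## Validation battery

Age classes partition [0, ∞) as calf [0, 1), juvenile [1, 5), subadult
[5, 15), adult [15, ∞); the published ranges overlap at the boundaries, so
boundary ages go to the older class by default (a switch reverses this).
Predicted ages are floored at 0 before classification. Kappa is unweighted
Cohen's kappa with the large-sample standard-error CI and two-sided z-test
(via statsmodels); the ANOVA is a standard one-way F across true classes
with Tukey–Kramer pairwise contrasts, excluding classes with fewer than two
members (no within-class variance is estimable from one sample). The sex
test regresses Δage residuals (OLS residuals of predicted on chronological
age) on sex plus chronological age and reports the sex term; a single
stated covariate model is fitted, not a model-selection sweep. The
longitudinal assessment pairs each multi-sample individual's chronologically
consecutive samples (an `all_pairs` switch exists), counts a pair correct
only on strict predicted-age increase (ties are incorrect), and applies the
exact two-sided binomial test (sum of outcome probabilities ≤ P(X = k))
against 0.5. The cross-species accuracy rate is 100·(1 − error/lifespan).

## Problem sizes and determinism

The default test suite and the acceptance script use the study-sized cohort
(25/53) and run the multi-seed analyses over 20 seeds with `tune_once`
tuning; Monte-Carlo calibration checks use 200 seeds on a 0.05 °C grid.
These sizes were chosen so the whole analysis reruns in minutes on one
core. All seeds derive from the single `--seed` argument.

## Known limitations

- The a = 1/b identity holds for the single-action bias model; a per-cycle
  bias process would make `a` an effective, cycle-count-dependent quantity.
- With LOIOCV errors around 8 years and resampling gaps of 1–4 years, the
  within-individual ordering test has little power on synthetic cohorts —
  most consecutive pairs are closer in age than the model can resolve, so
  longitudinal binomial p-values near 1 are expected there and say nothing
  about cohorts with longer sampling gaps.
- Uniform ages leave the calf and juvenile classes sparsely populated, so
  synthetic age-class kappas run below what a cohort with a young-skewed
  design would give.
- The XLSX reader is a convenience for deposited-table layouts; proprietary
  instrument binaries are out of scope (text exports only).
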