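# hrmclock

Methylation-sensitive high-resolution melting (MS-HRM) quantification and
epigenetic age estimation, built for small-panel clocks in long-lived
mammals (the reference design: two blood-derived loci, *RALYL* and *TET2*,
in captive Asian elephants sampled repeatedly over years).

MS-HRM reads the methylation level of a PCR amplicon from the shape of its
melt curve: bisulphite conversion turns unmethylated cytosines into uracil,
so methylated templates keep a higher G/C content and melt at a higher
temperature. This package implements the full analysis chain downstream of
the instrument, plus synthetic-data generators that provide ground truth
for every stage:

1. **Melt processing** — normalize raw fluorescence between least-squares
   baseline lines fitted in pre-/post-melt windows (no temperature shift),
   subtract the 0 %-methylated standard to get a difference curve, and
   summarize it as the Df value (maximum absolute relative difference);
   duplicate reactions are averaged.
2. **PCR-bias calibration** — unmethylated templates amplify preferentially,
   so Df saturates in the true methylation rate M. A standard dilution
   series (0, 5, 10, 15, 25, 40, 50, 75, 100 %) calibrates

   `a · M / (100 − M) = Df / (Dfmax − Df)`

   where Dfmax is the Df of the 100 % standard and `a` is the bias
   coefficient, fitted by nonlinear least squares and inverted in closed
   form to quantify unknown samples.
3. **Age model** — an epsilon support vector regression (radial kernel,
   gamma ∈ {0.5, 1}, cost/epsilon grid-searched) on z-scored methylation
   rates, evaluated with leave-one-individual-out cross-validation
   (LOIOCV): all samples of one individual are held out together, so
   repeated sampling never leaks across the train/test split.
4. **Validation** — age-class agreement (calf < 1 y, juvenile 1–5 y,
   subadult 5–15 y, adult ≥ 15 y) via Cohen's kappa, one-way ANOVA with
   Tukey–Kramer pairwise class contrasts, a sex effect test on Δage
   residuals (residuals of predicted ~ chronological age, age-adjusted),
   and a within-individual longitudinal check (exact binomial test that
   later samples are predicted older).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each writes its tables under `results/`):

```sh
python analysis/01_simulate.py      # melt plates + 25-individual cohort
python analysis/02_quantify.py      # Df -> calibration -> methylation rates
python analysis/03_correlations.py  # methylation-age screening
python analysis/04_age_model.py     # SVR with LOIOCV, per-locus vs combined
python analysis/05_validation.py    # kappa, ANOVA, sex, longitudinal
```

Output of `02`–`04` (seed 0):

```
RALYL: fitted a = 0.724 (1/b = 0.667), Dfmax = 74.6; methylation error mean 1.31 / max 3.56 pct points
TET2:  fitted a = 0.340 (1/b = 0.333), Dfmax = 75.6; methylation error mean 2.31 / max 9.11 pct points

melt-quantified   : RALYL r = +0.507 (p = 0.00011), TET2 r = -0.686 (p = 1.5e-08)

model      refit MAE  refit R²  CV MAE  CV R²
RALYL          17.17      0.24   18.16   0.36
TET2            9.66      0.52   11.08   0.47
combined        4.63      0.86    8.05   0.72
```

Reading this: the generator simulated the TET2-like assay with a 3-fold
amplification advantage for unmethylated template (`b = 3`), and the fitted
standard-curve coefficient recovers its reciprocal (`a ≈ 1/3`); quantified
methylation tracks truth to a couple of percentage points. Each locus alone
is a weak clock, but combining them cancels the shared per-individual
methylation shift and brings the honest out-of-individual error down to
~8 years over a 0–65-year age range — while the train-on-everything refit
error (4.6 years) illustrates how much an un-grouped evaluation would
flatter the model.

## Library use

```python
from hrmclock import CohortSpec, simulate_cohort, tune_hyperparameters, loiocv

dataset, truth = simulate_cohort(CohortSpec(), seed=0)
params = tune_hyperparameters(dataset, seed=0)
pred = loiocv(dataset, params=params)
print(pred.mae(), pred.r_squared())
```

Real data enters through `read_melt_table` / `read_sample_metadata` (plate
exports and metadata CSVs) or `read_methylation_dataset` (a pre-quantified
per-sample table, CSV or XLSX, with a column-mapping option). A thin CLI
(`hrmclock simulate|quantify|correlate|model|validate|run`) wraps the same
functions.

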