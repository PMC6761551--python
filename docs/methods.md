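# Methods

## Setting and assumptions

The package analyzes longitudinal ECG and time-matched plasma-concentration
data from treatment studies without placebo arms.  Its core assumptions:

* the concentration-QTc relationship is linear and instantaneous (no
  hysteresis or effect compartment, no circadian structure — the sampling
  designs it targets are too sparse to support either);
* combination effects are additive in the analytes' individual effects;
  pairwise interaction products can be screened but are off by default;
* all time-dependent, concentration-independent drift is absorbed by free
  per-cell intercepts (cell = study x visit x time-postdose) and described
  afterwards by a parametric trend in treatment week.

## QT correction

`QTc = QT * (HR/60)^r`.  The population exponent `r` is the OLS slope of
log(QT) on log(RR) pooled over pretreatment points, one point per ECG
timepoint per subject, using triplicate-averaged QT and HR (averaging before
the log).  Natural logs; the slope is base-invariant.  No subject-level
weighting: subjects contribute the 1-5 pretreatment timepoints they have.
An individual-subject exponent is deliberately out of scope — with one or
two pretreatment ECGs per subject it is not estimable — and on-treatment
data never enter the exponent fit, to avoid biasing the response variable
toward the treatment effect.  `residual_hr_slope` (OLS of QTc on HR with a
95% CI) is the adequacy diagnostic; an adequate correction has a CI
containing zero.

## Exposure-response model

    dQTc_ijkt = Eo_jkt + eoI * (BQTc_i - median BQTc)
                + sum_a sl_a * C_a(ijkt) [+ r_ab * (sl_a C_a)(sl_b C_b) products]
                + eta_i + eps_ijkt,   eta ~ N(0, omega^2), eps ~ N(0, sigma^2)

Baselines are the unweighted mean of a subject's pretreatment
triplicate-averaged QTc values; `median BQTc` is the median over included
subjects, computed once and frozen into the fit.  A modeling row exists only
where the ECG is time-matched with a valid concentration for **every**
analyte in the subject's regimen (regimens are explicit per-cohort
configuration, not inferred); analytes outside the regimen enter as 0.
Below-quantification concentrations are expected to be encoded as 0
upstream — conservative for slope estimation — while empty/NA values are
invalid and fail the match.  Every exclusion carries a machine-readable
reason.

Estimation is maximum likelihood, not REML, so likelihood-ratio tests on
fixed effects between nested fits are valid; the retention rule is a forward
LRT at P < 0.001, main effects before interactions.  There is no global
intercept (the cell factors absorb it).  The random-intercept structure
gives each subject the marginal covariance `sigma^2 I + omega^2 J`, so the
likelihood is profiled over all fixed effects in closed form
(Sherman-Morrison per-subject rank-1 inverses) and optimized only over the
log-variance parameters with L-BFGS-B (relative log-likelihood tolerance
1e-6, iteration cap 500).  Options allow `omega` to differ by study and
`sigma` by singleton-vs-triplicate ECG; both default off (they were examined
and not needed in the motivating analysis).  Degenerate inputs: a
rank-deficient fixed-effect design raises an error naming the dependent
columns (drop or merge the cell); near-noise-free data pin the variances at
a floor instead of letting the optimizer chase an unbounded likelihood;
cells with fewer than 3 records are kept (free intercepts tolerate small
cells) but flagged.  Slope 90% CIs are Wald intervals, estimate +/- 1.645 SE.
The fitter is cross-checked in the test suite against statsmodels MixedLM
(ML) on the homogeneous default, and against OLS in the single-cell,
no-random-effect reduction.

## Secular trend

Second stage: the fitted cell intercepts (at median baseline QTc) are
regressed on week by nonlinear least squares, `E_w = Pmax (1 - e^(-lambda w))`,
weighted by the number of observations in the cell, ignoring the
intercepts' estimation SEs (a deliberate two-stage simplification).  `Pmax`
(ms) is the steady-state plateau; `log(2)/lambda` the half-life in weeks.

Scale convention: the size-weighting treats a cell of size n as having
residual variance `delta^2 / n`, so the reported `delta_sd` is on the
unit-weight (per-observation) scale; a cell of size n typically sits
`delta_sd / sqrt(n)` from the curve.  This is the convention under which a
weighted fit's plateau CI and its residual SD are mutually consistent, and
it is what the parameter CIs (asymptotic covariance scaled by the weighted
residual variance) assume.  Point estimates are invariant to rescaling all
weights; `delta_sd` rescales with them.

Start values are deterministic (plateau from the latest-week cells, a small
grid of rate scales) with restarts on failure.  Identifiability requires at
least 3 cells spanning 2 distinct weeks; in designs whose earliest visit is
already several half-lives in (e.g. week 2 at lambda ~ 2.3/wk), `lambda` is
weakly identified and its CI will say so, while `Pmax` remains well
determined.

## Predictions

ddQTc — the concentration-driven change, the analogue of the
placebo-corrected change in a thorough-QT study — is `sum_a sl_a * C_a` at
scenario concentrations (e.g. steady-state Cmax per dose; dose-to-
concentration translation is an input, not a feature).  Single drug:
analytic bounds `(sl +/- 1.645 se) * C`.  Combinations: slope vectors drawn
from the fitted multivariate normal (default 1,000 draws, seeded,
reproducible), empirical 5th/95th percentiles reported.  Total change:
dQTc = ddQTc + Pmax, with Pmax added as a constant — its estimation
uncertainty is deliberately not propagated.  Reports round to 1 decimal in
ms.

A reproduction note: for a bedaquiline-containing regimen the published
combination table lists an M2-alone mean contribution of 4.5 ms at 0.25
ug/ml, while the printed M2 slope gives 19.3 x 0.25 = 4.83 ms; the 4.5-ms
figure is evidently a simulation output rather than the point product, and
the exact concentration behind it is ambiguous.  Where the package's tests
reproduce that table's row sums they take the stated 4.5 ms as a given
input; the discrepancy is documented here, not resolved.

## Synthetic-data generator

The generator composes the model equations forward — it shares no code with
the fitters, so recovery tests are non-circular.  Per subject: a QTc scale
`A` (lognormal, median 405 ms, log-SD 0.04), a baseline heart rate
(lognormal, median 88.5 bpm, log-SD 0.11) that drops 7.5 bpm on treatment
(observed declines are 5-10 bpm), and 1/2/5 pretreatment ECGs for 20/76/4%
of subjects.  Pretreatment QT is `A * RR^0.42 * exp(noise)` (log-SD 0.02);
on-treatment dQTc is assembled from the secular trend (Pmax 3.99 ms, lambda
2.3/wk, residual on the unit-weight scale with SD 3.19), the baseline
covariate (-0.305), per-analyte lognormal concentrations (e.g. pretomanid
median 3 ug/ml, GSD 1.5; M2 0.25, GSD 1.5), slopes (pretomanid 1.61, M2
19.3, moxifloxacin 2.60, pyrazinamide/linezolid/bedaquiline-parent 0), a
subject effect (SD 9.58) and residual (SD 10.2) — then back-transformed to
replicate-level raw QT at the subject's current heart rate, with ~1-ms
within-triplicate jitter.  The default design is four studies (~800
subjects) spanning mono and combination regimens over weeks 2-26 with two
timepoints per visit.  Identical truth records (including the seed) produce
byte-identical tables.

What the generator does *not* emulate — and hence what passing recovery
tests do not demonstrate about real data: longitudinal PK (concentrations
are independent draws per visit, no accumulation or hysteresis), dropout and
missingness mechanisms, assay error structure, circadian QT variation,
study-level trend heterogeneity (real programs show intercept departures by
study), and any model misspecification (the generator is the fitted model
run forward).

## Problem sizes

The test suite runs the replicate studies at the sizes the estimators need
rather than the largest imaginable: 100 replicates of 500-subject studies
for slope bias/coverage and LRT size, 200 small-design replicates for LRT
null uniformity, 200 datasets for exponent-estimator bias, 200 replicates
for trend recovery, and 10^5-10^6 Monte-Carlo draws for the
analytic-vs-sampling cross-checks.  The acceptance script uses 2,000
pretreatment points (exponent) and one full-pipeline 500-subject study
(slope).

## Known limitations

* Two-stage trend estimation ignores the intercepts' estimation error; a
  one-stage joint fit is out of scope.
* The LRT's chi-squared reference is asymptotic; at very small cell or
  subject counts the screening threshold P < 0.001 is conservative but the
  p-values are approximate.
* Heterogeneous-variance options cover omega-by-study and
  sigma-by-replicate-class only.
* Covariate structure is limited to the baseline-QTc term; categorical
  intercept covariates (TB type, study) are not implemented — with free
  per-cell intercepts already absorbing study/visit/timepoint means, such
  covariates are largely confounded with the cells in the designs targeted
  here.
* Prediction CIs exclude Pmax uncertainty by design, mirroring the
  motivating analysis.
* The single shared exponent `r` assumes one QT-RR relationship for the
  whole population; subject-level correction is intentionally unsupported.
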