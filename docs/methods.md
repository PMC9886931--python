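# Methods

## The scientific problem

In patients on maintenance hemodialysis, routine monitoring produces long
time series for many biomarkers: blood chemistry drawn on twice-monthly,
monthly, or bi-monthly schedules, and blood pressure / pulse rate recorded
at every dialysis session (~three times a week).  The within-patient
*variability* of each biomarker — not its level — is treated as a readout
of how well the corresponding regulatory system is working: a poorly
regulated quantity fluctuates more.  Correlations among the variabilities
of different biomarkers then map which regulatory systems are coupled, and
latent-factor models summarize that map as a small number of "regulatory
domains" (metabolism, circulation, liver, salt, inflammation, protein)
whose dysfunction raises the variability of a specific indicator set.

`dysreg` implements that entire analysis chain — variability computation,
mixed-method correlation, weighted network description, exploratory and
confirmatory factor analysis, and multi-group measurement invariance —
together with a synthetic cohort generator so every stage is testable
without clinical data.

## The variability metric

For one patient, one biomarker, and one calendar window (month or year),

    M   = mean of the measurements,
    CV  = population SD / M        (SD with divisor n, not n - 1),
    LCV = log10(CV).

LCV is scale invariant (unit changes cancel) and approximately normal
across patients, which makes it suitable for product-moment correlation
and for linear latent-variable models.  Zero-variance windows have no
defined LCV and raise a degenerate-series error rather than producing
-inf; windows with fewer than two measurements are omitted with a logged
warning.  Eligibility filtering keeps patients with > 100 dialysis
sessions, > 21 of 24 scheduled blood tests, and >= 0.5 years of treatment
vintage at the window start.

## The generative model of the synthetic cohort

The latent model is placed directly on the LCV scale — the minimal
generative model consistent with the factor analyses it must support.
Patient i in group g carries a six-vector of domain states

    eta_i ~ MVN(alpha_g, Phi),      Phi: 6x6 correlation matrix,

and the patient's true variability for biomarker j is

    LCV_ij = nu_j + Lambda_j . eta_i + eps_ij,   eps_ij ~ N(0, theta_j).

Measurements are then drawn around a patient-level mean
M_ij ~ N(level_mean_j, level_sd_j^2) (resampled until positive) with
within-patient SD 10^LCV_ij * M_ij, Gaussian by default and resampled if
non-positive (the panel's CVs are <= ~0.2, so the truncation bias is
negligible); a lognormal option matching the same mean and SD exists
behind `noise="lognormal"`.  Blood pressure and pulse rate additionally
receive an additive cosine season, amplitude * cos(2*pi*(month - peak)/12)
with a February peak (defaults 3.9 / 2.4 / 0.2 native units for SBP /
DBP / PR, chosen to reproduce a winter-minus-summer SBP difference of
about 8 mmHg).

### Defaults and where they come from

* **Marginals.** Per-biomarker level means/SDs and LCV means/SDs default
  to reference values reported for a 22-biomarker maintenance-hemodialysis panel
  (e.g. SBP 150.8 ± 18.3 mmHg, SBP-LCV −0.99 ± 0.10).  The loading matrix
  is rescaled so the implied marginal LCV SD,
  sqrt((Lambda Phi Lambda' + Theta)_jj), matches its target exactly
  (communalities capped at 0.98 so every residual variance stays
  positive).
* **Loadings.** Standardized loadings follow the reference 6-factor
  solution for this panel.  The fifteen primary (>= 0.40) loadings define the domain
  structure used by every recovery test.  The remaining seven biomarkers
  (Hb, LDH, ALP, Ca, LDL, HDL, PR) carry their reported secondary loadings,
  whose factor assignment is this package's own modelling choice; they
  matter only for making the off-structure correlations realistically
  positive.
* **Inter-domain correlation.** Phi defaults to a uniform 0.4
  off-diagonal — a typical magnitude for positively correlated
  physiological-domain factors; the reference analyses report the factors as all
  positively correlated without a full inter-factor correlation matrix.
* **Schedules.** 24/yr (twice monthly: WBC, Hb, Plat, Alb, BUN, Cr, K,
  Ca, P), 12/yr (TP, UA, Na, Cl), 6/yr (AST, ALT, LDH, ALP, LDL, HDL),
  and per-session hemodynamics with per-patient yearly counts drawn from
  a discretized distribution with median 147 and IQR ~118–156 on a
  Mon/Wed/Fri session grid; the three hemodynamic markers share each
  patient's session dates.
* **Groups.** A diabetic fraction of 143/334 with domain-mean shifts
  equal to the reference diabetic contrasts (0.049, 0.009, 0.021, 0.034,
  0.005, −0.006).  Those contrasts are reported on the *marker-indicator*
  scale (the default identification of standard SEM software); the
  generator divides by the primary-marker loading to express them in
  unit-factor-variance latent units (metabolism: 0.049 / (0.82 * 0.14) ≈
  0.43 latent SD).  This reproduces the reference Wald statistics
  (z ≈ 3.5 for metabolism) almost exactly; taking 0.049 as a latent-SD
  shift instead would make the contrast statistically undetectable at
  n = 334, contradicting the reference contrasts.  Demographics (age, sex,
  vintage, BMI) are sampled independently of eta; group effects act only
  through factor means.

### What the generator does not emulate

* Within-patient serial correlation and dialysis-session dynamics: draws
  around M_ij are i.i.d.  Real LCVs computed from autocorrelated series
  would have somewhat different finite-series sampling noise.
* Finite-series attenuation is *inherited*, not modeled away: an LCV
  computed from k measurements estimates the true LCV with additional
  noise of roughly 1/(ln10 * sqrt(2(k-1))) log10 units and a small
  negative bias (~-0.09 for k = 6, negligible for k = 147).  Computed
  LCVs therefore show attenuated correlations relative to the latent
  truth.  Unstandardized CFA loadings and factor-mean contrasts remain
  unbiased (the extra noise is absorbed by the residual variances), which
  is why recovery tests on the full pipeline check unstandardized
  parameters; marginal-recovery tests use the latent truth tables.
* Non-normal LCVs: the generator's LCVs are Gaussian by construction, so
  the Kolmogorov-Smirnov screen typically rejects nothing (the reference
  cohort had one non-normal variability).  The correlation stage accepts
  a per-variable Spearman override for exactly that situation.
* No mortality/frailty outcomes, no missing windows, no GA monitoring.

## Correlation and network stage

Method selection per pair: any binary variable → point-biserial (a
product-moment correlation on 0/1 coding; Welch-t p-values for
factor-score contrasts), two normal continuous variables → Pearson,
otherwise Spearman; normality is tagged by a one-sample KS test against a
normal fit at alpha = 0.05.  P-values use the t approximation
t = r sqrt((n-2)/(1-r^2)) on n−2 df and are deliberately unadjusted for
multiplicity — with nearly all pairs truly correlated, multiplicity
control of single false positives is the wrong risk model.  At n = 334
the two-sided critical |r| is about 0.107.

The network is the complete weighted graph over the 22 LCVs with edge
weight r (sign preserved, no threshold).  Strength sums |r| over incident
edges; path-based centralities use edge length 1/|r| (the standard
weighted-network convention for correlation networks); closeness is the reciprocal of summed
shortest-path lengths, betweenness the usual shortest-path count share.
The Fruchterman–Reingold layout runs with attraction proportional to |r|
and a fixed default seed (42), recorded in the outputs.

## Exploratory factor analysis

ML extraction profiles the discrepancy over uniquenesses: for fixed Psi,
optimal loadings come from the leading eigenpairs of
Psi^{-1/2} S Psi^{-1/2}, leaving F(Psi) = sum_{i>m} (g_i − ln g_i − 1)
over the trailing eigenvalues.  Optimization is L-BFGS-B on log
uniquenesses with the analytic gradient
dF/d log psi_j = − sum_{i>m} (g_i − 1) v_ji^2, ten random restarts,
tolerance 1e-6, and a Heywood guard at uniqueness >= 0.005 (bounded and
flagged).  T = (n−1) F_min on df = [(p−m)^2 − (p+m)]/2.  The
implementation was cross-checked against R's `factanal` on a frozen
population matrix (agreement to ~1e-5 in uniquenesses and canonical
loadings).

Rotation is oblique gradient projection on the oblimin criterion
(gamma = 0, direct quartimin), with random-start restarts; communalities
are preserved to 1e-8, factors are reordered by descending explained
variance (sums of squared structure loadings, pattern · Phi, divided by
p) and sign-aligned so each pattern column sums >= 0.  Loadings below 0.1
in magnitude are suppressed only in printed tables, never in computation.

Factor-count guidance comes from Horn's parallel analysis.  The default
compares *common-factor* eigenvalues of the reduced correlation matrix
(squared multiple correlations on the diagonal) against the 95th
percentile from standard-normal data of the same shape — the convention
of the standard psychometrics tooling, and the variant that stays
sensitive to well-determined factors when one general dimension dominates
the raw spectrum (as it does here, with all domains positively
correlated); a `kind="pca"` variant uses raw eigenvalues.  The quantile
uses the conservative "higher" order statistic since plain interpolation
is anti-conservative at a few hundred replicates.

## Confirmatory factor analysis

The measurement model is x = nu + Lambda eta + eps with
Sigma = Lambda Phi Lambda' + Theta, mu = nu + Lambda alpha.  The default
specification has 6 correlated factors, 16 indicators, and 18 loadings:
metabolism {BUN, Cr, K, P, UA}, circulation {SBP, DBP}, liver {AST, ALT},
salt {Na, Cl}, inflammation {WBC, Plat, Hb}, protein {TP, Alb}, plus
Alb→metabolism and Hb→metabolism cross-loadings.  The reference degrees-of-freedom ladder (87/174/186/196/212) pins down
only the *counts* (16 indicators, 18 loadings); the choice of Hb as the sixteenth
indicator and of the two cross-loadings is a documented structural guess,
fully overridable by constructing a different `SemModelSpec`.  All
df-based checks depend only on the counts.

* **Identification** fixes every factor variance to 1 and every factor
  mean to 0 in unconstrained groups.  This (rather than marker-loading
  identification) reproduces the invariance-ladder df sequence exactly:
  metric constraining the 18 loadings frees the second group's 6 factor
  variances (net Δdf = 12), scalar constraining 16 intercepts frees 6
  factor means (Δdf = 10), strict constrains 16 residuals (Δdf = 16).
* **Estimation** minimizes the Wishart ML discrepancy
  F = ln|Sigma| − ln|S| + tr(S Sigma^{-1}) − p (+ mean term), weighted by
  (n_g − 1) per group, by L-BFGS-B with analytic gradients
  (dF/dLambda = 2 G Lambda Phi with
  G = Sigma^{-1}(Sigma − S − dd')Sigma^{-1}, etc.).  Residual variances
  are log-parameterized; factor correlations are bounded in (−0.99, 0.99)
  with an eigenvalue barrier against non-PD Phi.  Start values: loadings
  at half the marginal SD, residuals at half the variance, Phi = I.
  Convergence requires the per-observation gradient sup-norm < 1e-4;
  restarts perturb the start.  Factor signs are aligned after
  optimization (loading sums >= 0), which leaves Sigma and mu invariant.
* **T convention**: T = sum_g (n_g − 1) F_g (Wishart multiplier), and
  RMSEA uses df (n − 1); both reproduce the reference RMSEA values
  (147.6 on 87 df at n = 334 → 0.046; 178.8 on 114 → 0.041).
* **Fit indices**: CFI and TLI against the independence baseline
  (diagonal Sigma; baseline T is −(n−1) ln|R| per group), SRMR as the
  root mean square of standardized residuals including the diagonal,
  AIC/BIC from the Gaussian log-likelihood with k = number of free
  parameters.  A mean-scaled robust statistic (fourth-moment weight
  matrix, single-group raw data) is available behind `robust=True`; all
  structural arithmetic uses plain ML, since the degrees of freedom are estimator
  independent.
* **Standard errors** come from the inverse expected information
  ((n−1)/2 · J' (Sigma^{-1} ⊗ Sigma^{-1}) J for the covariance block,
  n · Jm' Sigma^{-1} Jm for means), Jacobians by central differences.
  Their calibration is checked empirically by the factor-mean CI coverage
  test (nominal 95%).
* **Factor scores** use the regression method,
  eta-hat = alpha + Phi Lambda' Sigma^{-1} (x − mu); regression scores are the default of the field's standard software.
* **Structural variants.**  A second-order variant replaces Phi by
  gamma gamma' + diag(1 − gamma^2) (second-order factor variance 1); a
  bifactor variant adds an orthogonal general factor.  Both converge and
  refit their own population moments to T ≈ 0; bifactor *parameters* are
  checked only through implied moments because two-indicator specifics
  make the bifactor decomposition non-unique — a known identification
  limit, not an implementation defect.

## Measurement invariance

The ladder fits configural → metric → scalar → strict with warm starts
from the previous level (newly shared parameters start at per-group
means).  Steps are judged by Δ fit indices: a step fails when
ΔCFI < −0.01, ΔTLI < −0.01, or ΔRMSEA > 0.015; the chi-square difference
is reported but never drives the decision (it is oversensitive at these
sample sizes).  Factor means are contrasted at the deepest achieved level
of at least scalar, by Wald z on the second group's alpha (reference
group fixed at 0); `scale="marker"` re-expresses estimates in the primary
indicator's LCV units (z and p are identification invariant).  Partial
invariance is available by exempting named parameters from a constraint
set.  Two-group ladders only: four-group analyses at this cohort size leave
too few patients per cell to converge reliably.

## Numerical choices and degenerate inputs

* Degenerate (zero-variance) series raise; downstream correlation cannot
  absorb −inf.
* Correlation pairs need >= 3 complete observations; zero-variance
  columns are rejected by name.
* Monthly windows are calendar months; the year is the configured
  data-collection year (default 2020).
* KS normality uses estimated parameters without a Lilliefors correction;
  this is conservative
  under the null, which the rejection-rate test verifies.
* The acceptance simulations use 50 replicate cohorts of 334 patients
  for recovery statistics and 10 for the acceptance script's quick
  recovery block — sizes chosen to make the Monte-Carlo error of the
  checked rates a few percentage points.

## Known limitations

* The reference cohort's data-dependent estimates (chi-square values,
  loadings, factor-score correlations) are not reproducible without its
  raw data; the package's claims about estimation quality rest on
  parameter recovery against the synthetic generator's known truth.
* The reference cohort's full 52-variable correlation table is not
  available; the significance census is validated against the generator's
  population-implied oracle instead.
* WLSMV/categorical estimation, FIML for missing data, Bayesian SEM, and
  >2-group ladders are out of scope.
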