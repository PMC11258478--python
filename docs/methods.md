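# Methods

This note documents the statistical machinery in `sleepbioage`: the
generative model behind the synthetic cohorts, the four predicted-age
metrics, the dose–response and mediation inference, the numerical
choices, and what the synthetic design can and cannot demonstrate.

## The synthetic cohorts

All analyses run on cohorts drawn by `sleepbioage.cohorts`. Two tables
are generated, sharing a ten-analyte blood-chemistry panel (albumin,
alkaline phosphatase, creatinine, log C-reactive protein, HbA1c, white
cell count, lymphocyte %, mean cell volume, red-cell distribution width,
glucose; albumin is the one analyte whose *low* values carry risk).

**Biomarkers.** Each analyte is linear in age plus Gaussian noise:
x_j = μ_j + β_j(age − 50) + s_j(ε_j + d_j·λ·B), where ε_j and the shared
physiological-burden factor B are independent standard normals, d_j is
the analyte's risk sign, and λ = 0.2 is the burden loading. The shared
factor induces the modest positive risk-direction correlation real blood
panels show (pairwise r ≈ 0.04) and is what lets the Mahalanobis-distance
metric see a coherent "risk axis" rather than ten independent columns.
Defaults for μ_j, β_j, s_j are typical adult clinical-chemistry values
with drifts small relative to cross-sectional spread (e.g. glucose
96 mg/dL, +0.15 mg/dL/yr, SD 12), so per-analyte age correlations are
weak (r ≈ 0.1–0.4), as in real panels.

**Mortality (reference cohort).** Death times follow a Gompertz hazard
log h(t) = α + γ(age + t) + w·Σ_j d_j z_j with shape γ = 0.085/yr
(mortality doubling ≈ 8 yr), log baseline rate α = −9.8 at age 0, and
w = 0.1 per risk-signed noise-SD of each analyte. Draws are by inverse
transform; administrative censoring at 27 years mirrors the linked
mortality span of the survey cohorts these metrics are classically
trained on. Ages are uniform on 38–73. At the defaults roughly half the
reference cohort dies in follow-up, giving the Gompertz fit plenty of
events.

**Sleep exposure (target cohort).** Durations sit on a 0.5-h grid
spanning 4–10 h, drawn per reporting category with probabilities
(≤5 h: 4.4%, 6 h: 17.9%, 7 h: 39.5%, 8 h: 30.4%, ≥9 h: 7.8%) shaped like
a large population questionnaire with its mode at 7 h. The sleep signal
is q = (hours − 7)²; every analyte is shifted by d_j·s_j·c·q with
curvature c = 0.05 noise-SD units per h². At that curvature a 5-h or 9-h
sleeper sits ≈ 0.2 SD higher per analyte than a 7-h sleeper — large
enough that a 5 000-person cohort has essentially certain power for the
1-df spline nonlinearity test at the Bonferroni threshold on the
age-scale metrics (the real phenomenon is detectable only at biobank
scale, so a desk-scale emulation must use a proportionally larger
effect). HD is the exception: because a distance responds second-order
to a mean shift, its nonlinearity power at these defaults is ≈ 0.8 at
the 0.01 gate — the metric ranking the four outcomes by
signal-to-noise, reported as measured rather than forced.

**Mediator routing.** Cystatin C and GGT are κ_c q and κ_g q plus noise
(κ_c = 0.05 mg/L/h², κ_g = 3 U/L/h²). Fractions m_c = 0.35 and
m_g = 0.07 of each analyte's total sleep shift are carried by the
mediator *deviations* (signal plus the mediator's own noise), the
remainder applied directly, so the linear mediation structural equations
hold exactly and the generative proportion mediated equals m_c (m_g) for
any linear functional of the biomarker vector. The default fractions
echo the ordering reported for kidney- and liver-marker mediation of
sleep–aging associations (CysC ≫ GGT). In the exact noiseless limit the
mediator and exposure become collinear and the regression decomposition
is unidentifiable; the identity is therefore asserted on the generative
construction (`generative_mediation_truth`), not on a degenerate fit.

**Genotypes.** Biallelic dosages Binomial(2, f_i) with f_i ~ U(0.05,
0.95), entries missing completely at random at rate 0.02, and positive
per-allele weights U(0.01, 0.1) — 112 SNPs by default, the size of the
habitual-sleep-duration GWAS instrument. No linkage disequilibrium,
stratification, or genotype–phenotype coupling is simulated: the PRS
exists to exercise the scoring arithmetic and the median-split
stratification, not to carry signal.

**Covariates** (BMI, smoking, drinking, physical activity, education,
Townsend deprivation, diet score, health rating, disease/family history,
medication, sleep disorder, depression, shift work, pregnancy, energy
intake) are drawn independently of exposure and outcome. Adjusting for
them therefore costs degrees of freedom without removing confounding —
there is none by construction. Passing tests show the machinery is
correct, not that the adjustment set would suffice in observational
data.

## The four metrics

**KDM.** Per-biomarker OLS of analyte on age gives (q_j, k_j, s_j); the
uncorrected estimator is the inverse-variance-weighted combination of
the per-biomarker age estimates, and the corrected estimator (default)
adds chronological age as a pseudo-biomarker weighted by 1/s²_BA. s²_BA
is the mean squared deviation of the uncorrected estimate from
chronological age minus (1 − r²_char)/r²_char · (age range)²/(12m),
with r_char the characteristic correlation Σr²_j/√(1−r²_j) ⁄
Σr_j/√(1−r²_j); if that expression is non-positive (near-perfect
biomarkers) the raw MSE is used. Biomarkers with |k_j| below a
configurable floor are excluded with a logged warning; an exactly
collinear biomarker (zero residual) is retained with its scale clamped
to 1e-12 rather than dropped, so exact textbook examples score exactly.

**PhenoAge.** The Gompertz partial likelihood is maximized by L-BFGS-B
with an analytic gradient; γ is optimized on the log scale and bounded
in [1e-4, 1] (unbounded line searches overflow exp(γt)). Biomarkers are
standardized internally and only their coefficients carry the
elastic-net penalty (default mix 0.5, strength 1e-3 per observation);
the L1 term uses the smooth approximation √(b² + 1e-8) so the objective
stays differentiable — at the default strength this differs from exact
soft-thresholding by far less than estimation error. Scoring converts
the linear predictor to 10-year mortality risk and inverts the age-only
Gompertz risk curve in closed form; risks are clamped to
[1e-10, 1 − 1e-10] with a logged count. Convergence failures raise with
the gradient norm.

**HD.** Analytes are standardized by the healthy subsample's mean/SD and
the Mahalanobis distance uses the Cholesky factor of their covariance.
"Healthy" defaults to the full reference cohort; a per-analyte
reference-interval filter is available and falls back (logged) to the
full cohort when it leaves fewer rows than analytes. A covariance
eigenvalue ≤ 1e-10 raises an error naming the most collinear analyte
pair. An optional log(1+HD) transform is off by default. Note HD
responds *second-order* to a mean shift away from the centroid: the
sleep effect on HD scales like q², so HD is always the least powered of
the four outcomes and its mediated-proportion estimate is unstable at
desk scale (the decomposition assumes a linear outcome model).

**AL.** Quartile cutoffs (75th percentile, 25th for albumin) are fitted
on the scoring cohort itself by default — the classical formulation
references the cohort's own distribution — with a flag to freeze
reference-cohort thresholds instead. AL is a count/10, hence always a
multiple of 0.1. AL is also a nonlinear (thresholded) functional, but
its sleep response is close enough to proportional for the mediation
recovery to hold in practice.

**Age acceleration.** OLS residuals of PhenoAge and KDM on chronological
age; exactly mean-zero and age-orthogonal by the normal equations.

## Dose–response and interaction inference

Categorical contrasts, trend tests, and splines are all OLS with the
declared covariate design (dummy coding against stated reference
levels); p-values and CIs use the large-sample normal/chi-square
reference with no small-sample F correction, appropriate for the n ≥
10³ regime the emulation targets. The trend test replaces each category
by its within-category median of observed hours — including the
open-ended extreme categories, where the median of what was actually
reported is the only defensible choice. The restricted cubic spline uses
the Harrell truncated-power natural-spline basis; with three knots
(10th/50th/90th percentiles of hours) it contributes exactly one linear
and one nonlinear column, so the overall Wald test always has 2 df and
the nonlinearity test 1 df. Quantile knots that collide on heavily tied
integer hours fall back deterministically to the nearest distinct
observed values (logged). Curves are anchored to 0 at 7 h (the
categorical reference) — the continuous analogue of the forest plot's
reference category — and changing the anchor shifts the curve by a
constant only. Stratified analyses test the joint Wald null on all
category × stratum products, dropping the stratifying variable from the
adjustment set to avoid self-collinearity.

## Mediation

Product-of-coefficients on standardized variables: mediator ~ exposure +
covariates and outcome ~ exposure + mediator + covariates, ACME = a·b,
ADE = c′, total = ACME + ADE (exact in this linear, no-interaction
setting), proportion mediated = ACME/total × 100. Intervals are
participant-level nonparametric bootstrap percentiles (default 1000
replicates, seeded per outcome × mediator from the run seed);
quasi-Bayesian draws would be asymptotically equivalent but need a
posterior machinery the linear case does not require. Mediators are
analysed one at a time. The default exposure contrast is the squared
deviation (hours − 7)² rather than per-hour linear: under a symmetric U
the per-hour total effect is driven only by the mild asymmetry of the
duration distribution and is statistically indistinguishable from zero
at desk scale, which makes the proportion (a ratio) numerically
meaningless; the squared-deviation contrast measures the same routing
fractions on the scale the effect actually lives on. Per-hour and
arbitrary-column contrasts remain available. A total effect within
1e-10 of zero reports the proportion as NaN with a warning rather than
crashing.

## Pipeline

A single seed fans out to per-stage seeds via SHA-256 of
`"{seed}:{stage}"` (mod 2³¹−1), so toggling one stage never perturbs
another's draws; reruns with the same configuration are byte-identical
in every numeric table (the manifest's wall-clock timings excepted).
Exclusions apply in flowchart order — missing sleep data, missing
biomarker/mediator data, pregnancy or implausible energy intake
(< 500 or > 6000 kcal/day), missing covariates — with a ledger of
per-criterion removals whose counts plus survivors equal the input rows.
Significance flags use 0.05/5 = 0.01 (four metric outcomes plus the
mediator model family); raw p-values are always reported alongside.

## Problem sizes and runtime

Defaults are 5 000 reference and 5 000 target participants, 112 SNPs,
1 000 bootstrap replicates; a full run takes ≈ 15 s on one CPU. The
operating-characteristic checks in the test suite use 500 replicates at
n = 1 000 for spline type-I error, 100 replicates at n = 2 000 for
spline power, 50 outer replicates at n = 5 000 with 500 bootstrap draws
for mediation recovery, and 50 seeded null pipeline runs — sizes chosen
so each Monte-Carlo tolerance is a 3σ binomial band around its nominal
rate.

## Known limitations

- All generative relations are linear/quadratic with Gaussian noise; no
  skewed analytes (beyond log-CRP by construction), floor/ceiling
  effects, or assay batch structure.
- Covariates are exposure-independent, so confounding control is
  exercised only mechanically.
- HD and AL are nonlinear functionals; their mediation decompositions
  are approximations (HD's badly so at desk scale — reported, with wide
  intervals, rather than hidden).
- The PRS carries no real genetic architecture (no LD, no effect on the
  phenotype), so genetic stratification is a null stratifier here.
- Reverse causation, selection, and measurement error in self-reported
  sleep — the substantive threats to the real-world finding — are out of
  scope by design.
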