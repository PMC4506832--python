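# Methods

## Tonotopic geometry

The geometry module converts per-subject CT measurements into a
characteristic neuron frequency (CNF) per electrode contact.

**Duct length.** Escudé's spiral model gives the arc length from the round
window to a point at angle θ (degrees) as `s(θ) = 2.62·A·ln(1 + θ/235)`,
with *A* the large diameter of the basal turn (mm). At the conventional
total coil of 2.75 turns (990°) the full cochlear duct length is
`CDL = 4.3259·A`.

**Contact positions.** The most apical contact (electrode 1) at insertion
angle θ_e1 sits at arc `s(θ_e1)`; contact *n* is `Y_n` mm more basal, where
`Y_n` comes from the array registry. Positions are stored as fractions of
CDL measured from the round window, so they decrease with electrode number;
they are flipped to Greenwood's from-apex convention only when evaluating
frequency. Deeper insertion therefore means lower frequency, as it must.

**Organ-of-Corti → spiral-ganglion map.** The spiral ganglion is shorter
than the organ of Corti, and the published closed-form fit of the
correspondence could not be reproduced: as transcribed,
`Z = 100·[1 + (23/x − x/0.0099 + 0.76)²]^{-1}` is non-monotone on (0, 1]
and essentially zero everywhere (≈0.017% at x = 1). The map is therefore a
pluggable monotone function: the `"printed"` variant ships for reference,
and the default is the identity, which keeps all downstream statistics
well-defined. This shifts the absolute frequency labels somewhat relative
to a true ganglion-compressed map but preserves ordering and
monotonicity — the properties the model actually uses.

**Greenwood function.** `F(z) = 165.4·(10^{2.1 z} − 0.88)` Hz with z the
fraction of spiral-ganglion length from the apex: 19.8 Hz at the apex,
20677 Hz at the base. The constant 0.88 is inside the parenthesis (the
standard form, `A(10^{ax} − k)`).

**Array registry.** Manufacturer inter-contact spacings are proprietary;
the packaged registry uses uniform spacing over nominal spans (PMA 13.0,
SA 13.5, SSA 14.0 mm for 22 contacts) and accepts a user YAML override.
The spans were chosen so that a fully inserted array fits inside even the
smallest simulated cochlea (CDL 26.38 mm) at realistic insertion angles
under the arc-length model above; longer nominal spans would make the
reported insertion-angle distributions geometrically infeasible for small
cochleae.

## Synthetic cohort generator

The generator is the testbed standing in for undeposited patient data. Per
subject it draws: cochlear duct length (normal 35.05 ± 4.68 mm clipped to
the observed range [26.38, 43.42]); array type by fixed composition
(27 : 2 : 2 perimodiolar : straight : slim-straight over 31 subjects,
rescaled by largest-remainder rounding for other cohort sizes); insertion
angle (normal per array type: 346 ± 22°, 312 ± 46°, 335 ± 35°) truncated
below at the smallest angle for which the whole contact span plus a 0.5 mm
basal margin fits in the drawn cochlea; whole-array scala-vestibuli
translocation with probability 0.3548 for perimodiolar arrays only;
etiology by fixed composition (11/8/4/4/3/1); and demographics. Per
electrode it draws impedance (8.71 kOhm + subject shift N(0, 2.05) +
contact noise N(0, 1.60), clipped to [2.86, 19.07]) and electrode–modiolus
distance (clipped normal, 0.4 ± 0.2 mm perimodiolar, 0.8 ± 0.3 mm
straight — an assumption, as distances are not reported numerically).

Ages are internally consistent by construction: age of profound deafness
and its duration follow the reported distributions, age at implantation is
their sum, and age at test adds a follow-up of 0.5 yr + Exp(mean 2 yr).
(The reported age summaries are mutually inconsistent — mean age 32.3 yr
but mean age at implantation 45.6 yr — so consistency, not all marginals,
was kept.)

The threshold is assembled exactly as the fitted model assumes:
intercept + spline profile s(CNF) + adjusted-coefficient effects
(impedance² −0.11, distance² +2.20, scala tympani −8.50, array and
etiology contrasts, age at test +0.29/yr, duration −0.17/yr) + subject
intercept b_i + residual, then rounded to integer current levels and
clipped to the device range [0, 255]. Quantisation noise folds into σ_ε.

**Frequency profile ("double bump").** The default mean profile is the
unique cubic spline on the model's own basis (knots 5000 and 10000 Hz)
satisfying six control conditions: s(500) = −7, s(2800) = +5 with zero
slope, s(10000) = +8 with zero slope (the dome peak), s(16000) = −1 C.L.
It rises monotonically from 500 to ~2800 Hz, drops through the 4–5 kHz
region, peaks at 10 kHz, and carries an overall base-over-apex elevation.
Amplitudes (≈15 C.L. peak-to-trough) were fixed once, before calibration.

**Calibration.** The covariates and the frequency profile already explain
part of the threshold spread, so the intercept and the two variance
components are back-solved rather than copied: one large noiseless cohort
(σ_b = σ_ε = 0, no quantisation) measures the explained within- and
between-subject SDs, the remainders to the targets (within 13.66, between
18.60 C.L.) are assigned in quadrature, and the intercept is shifted to
centre the grand mean at 169.68 C.L. The shipped defaults freeze one such
run (intercept 177.66, σ_b 13.75, σ_ε 13.16); `calibrate_config()` re-runs
it, and a test checks the frozen values are reproduced.

What the generator does **not** emulate: partial (within-array) scalar
translocation, spatial correlation of impedance along the array, current
spread between contacts, measurement error in the CT geometry, or any
dependence of thresholds on neural survival beyond the smooth frequency
profile. Passing recovery tests therefore show the estimator is correct
under the stated model, not that the model captures every feature of real
clinical data.

## Random-intercept REML

For grouped data the covariance of a subject's observations is
`σ_ε²(I + λJ)` with λ = σ_b²/σ_ε². The restricted likelihood is profiled
analytically over β (GLS, using the closed Woodbury inverse per group) and
over σ_ε², leaving a smooth scalar function of log λ maximised by bounded
Brent search on log λ ∈ [−30, 30] with tolerance 1e−8; the λ = 0 boundary
is checked explicitly and reported as σ_b² = 0 (falling back to exact OLS),
not treated as an error. Design columns are rescaled to unit RMS
internally — raw-Hz spline columns span ~12 orders of magnitude — and all
reported quantities are back-transformed; the log-likelihood is corrected
for the rescaling so it matches the standard REML convention (verified
against an independent dense-matrix implementation and statsmodels
MixedLM).

Standard errors are the plug-in GLS covariance `σ̂_ε²(X'V_λ⁻¹X)⁻¹`; Wald
tests use the large-sample normal reference (no Satterthwaite or
Kenward-Roger correction — with 31 subjects the random-intercept df are
ample for the contrasts of interest, and the reference analysis used the
same convention). BLUPs are the subject-mean marginal residuals shrunk by
`n_iσ_b²/(σ_ε² + n_iσ_b²)`.

**BIC.** `BIC = −2·ℓ + k·ln N`, k = fixed effects + 2 variance components,
smaller is better. ℓ is a separately profiled *maximum-likelihood*
log-likelihood, not the REML one: restricted likelihoods contain
`log|X'V⁻¹X|`, which changes by scale- and dimension-dependent constants
when the fixed-effect structure changes, making cross-structure comparison
meaningless (with raw-Hz polynomial columns the artifact reaches tens of
log-likelihood units and would always select the smallest model). Using ML
for information criteria while reporting REML estimates is the same
convention lme4 applies when comparing models. Both log-likelihoods are
exposed on the results object.

## Analysis pipeline

Univariate screens fit one covariate at a time (plus the random
intercept); the multivariate model fits the spline in CNF together with
impedance², distance², scalar placement, array type, etiology, age at test
and duration of deafness. Age at onset and age at implantation are
excluded from the adjusted model as collinear with age at test. Reference
levels: scala vestibuli, slim-straight array, progressive sensorineural
loss. P-values are raw two-tailed (α = 0.05); no multiplicity adjustment,
matching the reference analysis, and stated in the report output.

The frequency curve evaluates the fixed-effects prediction with a 95%
normal band over a log-spaced grid covering the observed CNF range only,
holding dummy covariates at their reference (0) and other numeric
covariates at the fitted-sample mean — the mean is the documented choice
for the adjustment level of the impedance and distance terms. The residue
profile bins conditional residuals into log-spaced CNF bins (default 10)
and flags bins with |mean| > 2 SE.

The recovery experiment regenerates cohorts (default 20 seeds) at the
study size 31 × 22, refits the multivariate model, and reports per
coefficient the truth, mean estimate, empirical SD, bias and 95% CI
coverage. With whole-array scalar placement the scala-tympani contrast is
a between-subject effect, so its single-replicate SE (~6 C.L.) is much
larger than a within-subject design would give; the mean over 20
replicates still recovers the truth within two empirical standard errors.

## Numerical and design choices

- Angles are degrees externally and are only used through `ln(1 + θ/235)`;
  natural logarithm throughout (the printed 4.3259 constant is consistent
  only with ln).
- The truncated-power basis is used as specified (it maps one-to-one onto
  "piecewise cubic with two knots"); equivalence of the spanned space with
  a B-spline basis is a property of the basis, and C² continuity at the
  knots is verified by finite differences in the tests.
- Rank deficiency is detected on the rescaled design and reported with the
  names of aliased columns; one-observation-per-group designs fall back to
  OLS with a warning (σ_b² is not separable).
- Problem sizes in the tests and the acceptance script — 500 subjects for
  generator-summary convergence, 2000 perimodiolar subjects for the
  translocation rate, 20 replicates of 31 × 22 for recovery, 200
  replicates for the Wald type-I-error check — were chosen to make the
  Monte-Carlo error small relative to each check's tolerance; the whole
  suite runs in well under a minute.

## Known limitations

- The identity organ-of-Corti→ganglion map compresses nothing; absolute
  CNF labels near the base are higher than a ganglion-referenced map would
  give. All qualitative conclusions (ordering, monotonicity, knot
  placement) are unaffected, but numeric frequencies should not be read as
  clinically exact.
- Placeholder uniform contact spacings; supply a manufacturer registry for
  real analyses.
- Random intercepts only — no random slopes or crossed effects; Wald
  inference is asymptotic.
- The generator's demographic correlation structure (ages, follow-up) is
  an assumption; only the reported marginals of deafness onset and
  duration are matched.
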