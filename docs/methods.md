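# Methods

## Problem and strategies compared

The package compares selective-screening strategies for gestational
diabetes mellitus (GDM) applied in the first trimester of pregnancy.

**Single-risk-factor reference method.** A woman is high-risk if at least
one rule fires: BMI > 30 kg/m², previous macrosomic infant, history of
GDM, first-degree family history of any diabetes, or ethnicity in a
configured non-western high-prevalence set. Two of the guideline's rule
items (polycystic ovary syndrome, unexplained fetal demise) are outside
the cohort schema and therefore outside the rule. The BMI comparison is
strict (`> 30`) by default but configurable (`bmi_strict=False` gives
`≥ 30`), since the two conventions circulate side by side. The ethnicity
mapping is a config choice (default `{asian, other}` of the schema's five
levels): guideline ethnicity lists do not map one-to-one onto coarse
cohort categories, so hard-coding a mapping would be wrong for most data
sets.

**Prognostic models.** Four published first-trimester logistic models
(Gabbay-Benziv 2014, Nanda 2011, Teede 2011, van Leeuwen 2010) are
represented declaratively: intercept plus terms
`coefficient × transform(predictor)`, transform ∈ {identity, natural log,
category indicator}. All four use ethnicity, BMI and history of GDM; age
is in all but van Leeuwen 2010; family history in Teede 2011 and
van Leeuwen 2010; parity in Nanda 2011 and van Leeuwen 2010; history of
macrosomia only in Nanda 2011; systolic blood pressure only in
Gabbay-Benziv 2014. A schema validator enforces these predictor sets for
the named models, so a mistranscribed config fails loudly. The shipped
coefficient file is a synthetic stand-in (see its header): magnitudes are
plausible placeholders, predictor sets and effect directions are correct.
Recalibration makes every downstream comparison depend on a model's risk
*ranking* rather than its absolute coefficients, which is exactly why
stand-in magnitudes are workable for pipeline development and testing —
and why results from the stand-in must not be read as statements about
the published models themselves.

## Model updating

Given a model's linear predictor `lp`, recalibration fits
`logit P(y=1) = a + b·lp` by maximum likelihood (statsmodels Newton,
tolerance 1e-10, max 100 iterations). Degenerate inputs are refused
rather than silently fitted: a single-class outcome, a constant `lp`, a
non-converged fit, or coefficient blow-up beyond 1e3 (the practical
signature of perfect separation) all raise a `FitError`.

Extension refits `logit P(y=1) = a + b·lp + g·ln(glucose)` jointly; the
log transform reflects the right-skew of random venous glucose. Added
value is the likelihood-ratio χ² on 1 df. Refitting an
already-recalibrated model returns slope 1 / intercept 0 up to
convergence tolerance (tested), and doubling all coefficients halves the
fitted slope — the reparameterisation identity that pins the procedure
down.

With multiply imputed data, recalibration and extension are fitted per
imputation and the coefficients pooled by Rubin's rules before any
scoring, so all downstream risks come from one pooled equation applied to
each completed data set. There is no generally agreed combination rule
for likelihood-ratio tests across imputations; rather than implement a
D1/D2-style pooled test and imply more precision than the procedure has,
the package reports the per-imputation statistics, their median, and the
fraction of imputations significant at 0.05, clearly labelled as such.

## Multiple imputation and pooling

Chained equations (fully conditional specification), m = 10 imputations
and 10 sweeps per chain by default. Each incomplete variable is drawn
from a conditional model given all other covariates *and the outcome*
(standard MI guidance; omitting the outcome biases associations toward
null). Draw types: continuous — proper Bayesian linear regression
(σ² from its scaled inverse-χ² posterior, β from N(β̂, σ²(XᵀX)⁻¹), then a
noisy prediction; glucose modelled on the log scale to stay positive);
binary — logistic fit with a coefficient draw; categorical — multinomial
logistic probability draw; counts — rounded linear draw clipped at zero.
Predictive-mean matching (5 donors) is available but off by default: the
plain draws are the transparent textbook scheme and are what the
calibration tests certify.

Two domain identities are enforced around the chained draws. BMI is never
a chained target: any single missing member of (height, weight, BMI) is
back-solved from BMI = weight/height(m)² beforehand, and BMI is
recomputed afterwards where it was missing, so the identity holds in
every completed table and observed cells are identical across
imputations. Histories of GDM/macrosomia force parity ≥ 1.

Designs are column-normalised and constant columns dropped per draw: with
rare categories (e.g. 0.8% African ethnicity) a bootstrap-scale cohort
can lack a level among the observed rows, which would otherwise make the
normal equations singular.

Pooling is untransformed Rubin: `q̄` = mean estimate, `W` = mean
within-imputation variance, `B` = between-imputation variance (ddof = 1),
`T = W + (1+1/m)·B`; intervals use Barnard–Rubin small-sample degrees of
freedom when a complete-data df is supplied, otherwise the classic
(m−1)/λ², with a normal reference as a flag. c-statistics are pooled on
the raw scale with Hanley–McNeil per-imputation variances (a bootstrap
would cost orders of magnitude more for a second-decimal refinement of an
interval the comparisons do not hinge on).

## Evaluation

*Discrimination*: c computed by midranks, identical to the all-pairs
definition with ties counting ½ (tested against brute force and an
independent library implementation). *Classification*: 2×2 counts with
Wilson score intervals — never degenerate at 0 or 1, unlike Wald; zero
denominators yield an explicit "undefined because …" rather than NaN.
*Calibration*: 10 equal-frequency bins by predicted risk (rank-stable, so
duplicated risks may straddle bins), plus a fixed-span moving local mean
(span 0.15 of the sample) — a named smoother would add a dependency and a
tuning story for a purely visual overlay. Calibration is computed on the
m imputations stacked as one large data set, which is the only coherent
way to show one plot per model.

*Decision curves*: net benefit `NB(pₜ) = TP/n − (FP/n)·pₜ/(1−pₜ)` on a
default grid 0.005–0.30 (step 0.005), computed per imputation and
averaged. The reference method has no risk scale, so its fixed flags are
carried across the grid (its NB still falls with pₜ through the
false-positive weight) — the only coherent way to place a binary rule on
a decision curve. Treat-all and treat-none close the family; treat-all
matches its closed form `prev − (1−prev)·pₜ/(1−pₜ)` to machine precision
(tested at 1e-12).

*Scenarios*: A fixes the flagged fraction (default: the reference
method's own), flagging by descending risk with stable row order until
the target count is met, so the attained fraction is within 1/n of the
target even with ties; B fixes sensitivity, taking the largest threshold
whose sensitivity reaches the target (minimal screening load). Both
report attained — not target — values, per-imputation spread, and the
8-cell reclassification cross-tabulation (outcome × reference × model),
averaged over imputations.

## Synthetic cohort generator

The generator emulates a general low-risk north-west-European obstetric
population, and its defaults are the study conditions of every
stochastic test:

| parameter | default | basis |
|---|---|---|
| age | N(30.8, 4.2) years | reported cohort mean (SD) |
| systolic BP | N(115, 12) mmHg | reported mean (SD) |
| BMI | log-normal, median 23.2, IQR 21.1–26.2 kg/m² | reported median (IQR), right-skewed |
| glucose | log-normal, median 4.7, IQR 4.4–5.1 mmol/l | reported median (IQR), right-skewed |
| height | N(168.7, 6.5) cm | adult-female anthropometry for the region |
| ethnicity / education / conception | category fractions from the reported counts | reported distribution |
| smoking, family history | 9.0%, 14.6% | reported rates |
| parity | P(0) = 44.5%, then 36/13/4.5/2.0% | reported nulliparity; remainder a plausible parity tail |
| history of GDM / macrosomia | 1.6% / 6.2% marginal, realised only among parous women | reported rates + logical constraint |
| copula correlation (age, BMI, glucose, SBP) | exchangeable 0.25 | no joint distribution is published; a modest positive dependence makes glucose partially redundant with adiposity, as in real cohorts |
| outcome mechanism | logistic in BMI, age, ethnicity, histories + 2.0·ln(glucose) | plausible directions; glucose effect set so the predictor genuinely adds signal |
| target prevalence | 4.86% (auto-tuned intercept, bisection) | reported outcome rate |

Log-normal parameters come from the median and IQR
(`σ = (ln q₃ − ln q₁)/(2·z₀.₇₅)`); weight is back-solved from height and
BMI so the BMI identity holds exactly. Missingness defaults are a few
percent MCAR on the staff-measured variables (glucose 5%, SBP 3%,
weight/BMI 2%): the source study's per-variable missing-data table is
supplementary material not transcribed here, so these rates are a free
parameter of the emulation, not a fidelity claim.

What the generator does **not** emulate: measurement error and digit
preference, gestational-age structure, within-practice clustering,
informative (MNAR) missingness, the partial-verification design in which
only screen-positive or symptomatic women receive the diagnostic test,
and the real joint distribution beyond one exchangeable copula. Passing
tests therefore certify the *machinery* — coverage, calibration,
identities, orderings under a known truth — not the published effect
sizes: absolute c-statistics on synthetic data are lower than published
ones mainly because the synthetic covariate space is cleaner and the
stand-in coefficients flatter than the real equations.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng`; chains use
  independently spawned `SeedSequence`s. Same config + seed ⇒
  byte-identical cohorts, imputations and reports (tested).
* The outcome-model intercept is tuned by 200 bisection steps on the
  mean inverse-logit — deterministic and exact to ~1e-58, i.e. to float
  precision.
* MAR missingness solves its intercept the same way, so the configured
  marginal rate is met while the logistic dependence on the driving
  covariate is exactly the declared weight (recoverable by refitting;
  tested).
* Risk ties in scenario A are broken by stable row order; this is the
  one place where two runs over permuted rows can differ at the margin,
  and it is documented behaviour rather than hidden nondeterminism.
* Logistic fits refuse to return under separation or non-convergence
  instead of emitting huge coefficients.
* The per-criterion simulation sizes (200 replicates at n = 5000 for
  recalibration coverage; 200 × n = 500, m = 10 for imputation coverage;
  n = 6000, m = 10 for the full comparison; n = 50 000 for generator
  marginals) were chosen so each Monte-Carlo standard error is small
  relative to the property being asserted while a full run stays in the
  tens of seconds.

## Limitations

* The shipped model coefficients are stand-ins; scoring the actual
  published equations requires transcribing them into the YAML config.
* LR-test pooling across imputations is reported descriptively (median,
  fraction significant), not as a single pooled p-value.
* The imputation engine covers the schema's variable types only; it is
  not a general-purpose mice replacement (no multilevel structure, no
  MNAR sensitivity analysis).
* Decision curves carry no confidence bands; scenario uncertainty is
  summarised as per-imputation spread only.
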