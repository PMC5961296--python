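# Methods

`heusurv` implements a pooled individual-participant survival analysis of
HIV-exposed uninfected (HEU) children followed from birth to 24 months:
shared-frailty Cox proportional-hazards models on counting-process data
with time-dependent covariates, and a counterfactual "adjusted
attributable fraction" (aAF) computed from predicted survival, with
bootstrap confidence intervals. Because the pooled data the analysis is
designed for are individual-level records from many trials that are not
publicly deposited, the package ships a synthetic-cohort generator with
known ground truth; every statistical component is validated against that
truth or against closed-form oracles.

## Data model and conventions

The analysis input is one row per child: study identifier, region, sex,
birth-weight group (≥2500 g / <2500 g / unknown), breastfeeding initiation
and weaning age, maternal antiretroviral category (none, single/dual ARVs
for PMTCT, 3-drug ART for PMTCT, ART for life), maternal antenatal CD4
group (≥350 / <350 / unknown), and the ages (days from birth) of maternal
death, child death and censoring. Time is child age in days; "24 months"
is operationalized as 730 days and "6 months" as 183 days (month-based
rules are given in the literature without a day convention; 183 was chosen
as ⌈365.25/2⌉ and is configurable).

Categorization rules, applied before modelling and idempotent:

- mothers with missing antiretroviral information are assigned to the
  single/dual-PMTCT category (study-protocol assumption);
- children with unknown breastfeeding status are excluded (logged, not
  silently dropped);
- missing birth weight, sex and CD4 become explicit `unknown` levels that
  enter the model as ordinary categories, so sample size is preserved;
- a breastfed child with unknown weaning date is treated as breastfed
  from birth until 183 days, study exit, or the mother's death, whichever
  comes first; unknown 3-drug-ART stop dates are imputed as
  min(weaning, 183 days) (delivery for formula-fed children);
- follow-up is truncated at 730 days; deaths recorded later count as
  censorings at the cap. A death exactly at 730 days counts as an event.

Counting-process expansion turns each child into contiguous half-open
episodes `(start, stop]` beginning at 0, cut at every change-point of the
time-dependent indicators — maternal death, weaning (breastfeeding also
ceases at maternal death), ART start/stop — that falls strictly inside
follow-up. Events sit at the `stop` of the last episode. A covariate
change on the same day as a death does not open a new episode, so deaths
are attributed to the pre-change covariate value; a change-point at age 0
makes the post-change value apply from birth. Total episode time equals
min(outcome age, 730) exactly, and this identity is asserted in tests.
Three expansion schemes exist: maternal vital status only (the main
model), plus breastfeeding cessation (weaning as a time-dependent
exposure among breastfed children), and the four-level joint
breastfed × mother-on-3-drug-ART classification (A = neither, the
reference; B = ART only; C = breastfed only; D = both).

## Shared gamma-frailty Cox model

Child *i* in study *s* has hazard

    h_is(t) = u_s · h0(t) · exp(x_is(t)'β),

with study frailties u_s i.i.d. Gamma(mean 1, variance θ). The gamma
family is chosen for its closed-form posterior frailty means and
closed-form marginal survival; θ = 0 recovers the ordinary Cox model.

Estimation combines the classical EM for gamma frailty with a profile
search for θ:

- **Inner EM (θ fixed).** E-step: û_s = (1/θ + D_s)/(1/θ + A_s), where
  D_s is the cluster's event count and A_s its cumulative risk-weighted
  baseline hazard. M-step: β maximizes the Breslow partial likelihood
  with log û_s as offsets (one guarded quasi-Newton step per iteration;
  the Hessian is refreshed periodically or when a step fails to improve
  the likelihood), and H0 is the Breslow step estimator under the same
  offsets. The linearly-convergent frailty sequence is Aitken-accelerated
  every eighth iteration (guarded elementwise). Convergence: max|Δβ| <
  1e-6 (frailty values get a 100× looser band, matching the precision at
  which they are reported) within 200 iterations.
- **Profile for θ.** The gamma marginal log-likelihood has cluster terms
  log Γ(1/θ + D_s) − log Γ(1/θ) + (1/θ)log(1/θ) − (1/θ + D_s)log(1/θ + A_s)
  added to the event terms Σ log dH0(t) + x'β. θ̂ maximizes this profile
  via a coarse log-grid bracket followed by bounded Brent refinement,
  warm-starting each inner EM at the previous solution; θ = 0 is compared
  explicitly as a boundary candidate. Refits of nearly-identical data
  (bootstrap resamples) may restrict the search to a bracket around a
  known point estimate and warm-start at it.

Ties are handled by Breslow's method throughout (day-rounded ages create
many ties; the generator can also emit continuous times). Standard errors
come from the observed information of the offset partial likelihood at
convergence; Wald tests give p-values, and a covariate's levels are
tested jointly by a block Wald chi-square. Design columns with no
contrast are dropped with a warning; levels with essentially no event
information are reported with large standard errors rather than failing
(quasi-separation), with β clamped at ±20.

Validation: at θ = 0 the fit agrees with lifelines'
`CoxTimeVaryingFitter` to < 1e-6 in β; at any fixed θ it agrees with R
`survival::coxph(..., frailty(study, "gamma", theta=...), ties="breslow")`
to ~1e-5. θ̂ itself is validated by consistency (200 clusters, true
θ = 0.25 → θ̂ ≈ 0.24) because the EM-based θ search in `coxph` proved
unreliable as an oracle on the same fixture: the profile criterion is
flat and its history-based search can stop far from the optimum (it
returned 0.60 there).

Variable selection mirrors the stepwise-descending procedure: univariate
screens (one single-covariate frailty fit each), candidates entering at
block p < 0.1, iterated removal of the least significant covariate until
all remaining have block p < 0.05. Maternal ARV category is always kept
regardless of significance, and region and CD4 group are treated as
forced adjusters — the published description leaves partially open
whether these entered selection; forcing both is the design choice here.
Covariates enter and leave as whole blocks, so `unknown` levels can never
be dropped separately from their parent covariate.

## Prediction and attributable fractions

Individual survival predictions marginalize over the frailty
analytically: with H_i(t) = ∫ exp(x_i(s)'β) dH0(s) accumulated over the
child's covariate path,

    S_i(t) = (1 + θ·H_i(t))^(−1/θ),

computed as exp(−log1p(θH)/θ) for numerical stability and as exp(−H_i)
when θ < 1e-8. Predictions conditional on the estimated study frailty
(exp(−û_s H_i)) are available as an option; the marginal form is the
default because the attributable-fraction procedure treats the population
as a mixture over studies. H0 is flat beyond the last event time; a
prediction beyond the fitted follow-up support warns.

Expected deaths by age t are D(t) = N − Σ_i S_i(t), with every child's
covariate path extended to the horizon past any censoring by holding the
last observed category — D(t) is a full-population expectation, not a
censored count. "Nonexposure" to a factor reassigns all children to a
protective level while other covariates keep their observed values:
birth weight → ≥2500 g, breastfeeding → ever breastfed (with a
birth-to-183-days breastfeeding path imputed where a time-dependent
breastfeeding model requires one), maternal ARV → **ART for life** (the
protective extreme, deliberately not the model's "no ARVs" reference),
and maternal vital status → mother stays alive. Then

    aAF(t) = (D(t) − D_cf(t)) / D(t),

attributable deaths = D − D_cf, and the combined aAF applies all four
reassignments simultaneously. Confidence intervals resample children
with replacement within study strata (study sizes preserved), re-running
episode expansion, model fit and prediction per resample, and take
percentile 2.5/97.5 bounds; the default is B = 500 (tests and the
reproduction script use smaller B, reported alongside the results).
Resampling studies instead was rejected: with ~20 clusters the percentile
distribution would rest on ~20 exchangeable units. Resamples with zero
events are skipped and counted; more than 20% skips aborts.

## Synthetic cohorts and ground truth

The generator emulates the pooled multi-study population: 20 study
clusters (16 African, 4 Asian) of 960 children each by default; gamma
frailty variance 0.25; a piecewise-constant baseline hazard on age breaks
{28, 91, 183, 365} days with rates (3.0, 1.6, 0.8, 0.4, 0.2)×10⁻⁴/day
chosen so that the reference profile accumulates ~4% two-year mortality
and the covariate mix brings the population to ~5%, with roughly half of
deaths before age 3 months; covariate prevalences at the pooled values
(low birth weight 12.1%, unknown 1.3%; never breastfed 30.2%; ARV mix
22.9/61.4/11.7/4.0%; CD4 ≥350 57.9%); maternal death as a constant
2.2×10⁻⁵/day hazard (~1.6% of mothers by 24 months); weaning lognormal
with median 181 days and log-sd 0.79 (matching a 126–365 day IQR),
truncated at maternal death; ART windows implied by the ARV category
(PMTCT: birth to min(weaning, 183); for life: throughout); per-study
planned follow-up between 210 and 730 days plus exponential loss to
follow-up (rate 1.5×10⁻⁴/day), capped at 730. True log hazard ratios
default to the adjusted estimates the analysis is designed to recover
(LBW 2.92, never-breastfed 2.48, maternal death 11.08, ARV categories
0.78/0.66/0.51, Asia 0.05, CD4 <350 1.43); an alternative flavor drives
the hazard by the joint breastfeeding × ART categories (B 0.63, C 0.08,
D 0.04). Small fractions of records are masked as missing (weaning date
7.7% of breastfed children, ARV category 0.23%, feeding status 2.3%) so
the categorization and sensitivity-analysis machinery operates on
realistic inputs. Death times are drawn by piecewise-exponential
inversion on the refinement of baseline breaks and the child's own
change-points, so the generating hazard is exactly the model's. Ages are
rounded to whole days (deaths/censorings up, so day-0 events land on day
1); continuous times are available for oracle fixtures that need
tie-free data.

What the generator does *not* emulate: study-specific enrollment
calendars and protocols, covariate prevalences varying by study (only
region does), informative censoring, competing risks, or correlation
between covariates (e.g. CD4 and ARV category are drawn independently,
unlike reality). Passing recovery tests therefore demonstrates that the
estimators are correct and calibrated under the model's own assumptions
at realistic sizes and prevalences — not that the published estimates are
reproduced from the real data, which are not available.

`true_attributable_fraction` evaluates the generating model's own AF
exactly: each child's cumulative hazard is integrated in closed form over
its piecewise-constant pieces, the frailty is marginalized analytically,
and the counterfactual reassignments are applied in the generating model
(recomputing downstream change-points such as ART windows). A coupled
Monte-Carlo simulator provides an independent brute-force check.

## Validation experiments and their problem sizes

The acceptance suite runs at sizes chosen to keep the full test run
comfortably on one CPU while preserving statistical meaning; each scaled
experiment states its own binomial tolerance band:

- hazard-ratio CI coverage: 40 replicate cohorts of 20×960 children,
  accepted band 34–40 of 40 covered per parameter (the nominal-95%
  analogue of an 88–99/100 band at this replicate count);
- aAF recovery: one 32 000-child cohort with complete 730-day follow-up
  (administrative censoring only), each factor's estimate within 3
  bootstrap SEs (B = 30) of the analytic truth. Complete follow-up is
  used here because under early exit the factual covariate paths cannot
  see post-exit maternal deaths; that information limit shifts the
  maternal-death aAF by about −0.007 at the default censoring mix — a
  property of the prediction procedure under incomplete follow-up, not an
  estimation error, and it is excluded from this experiment by design;
- bootstrap CI coverage: 50 replicates at n = 1500 with B = 60 (accepted
  band 42–50 of 50), a scaled version of a 100×B = 200 experiment;
- exact identities (person-time conservation, KM = 1 − ECDF without
  censoring, log-rank p = 1 on duplicated groups, aAF = 0 under zero
  prevalence or a null effect) are asserted at machine precision.

## Known limitations

- Standard errors ignore the uncertainty in θ̂ and in the estimated
  frailties (the usual penalized-likelihood approximation); the coverage
  experiment shows this is adequate at ~20 clusters and ~900 events.
- The aAF under incomplete follow-up inherits the path-extension
  convention (hold the last observed category); see above.
- No left truncation, recurrent events, competing risks,
  proportional-hazards diagnostics, or parametric baselines.
- The stepwise procedure is the published one; it inherits the known
  inferential caveats of stepwise selection (post-selection p-values are
  not corrected).
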