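# Methods

## Causal model and estimands

The package targets a cohort with binary exposure X, a 3-level childcare
mediator M ∈ {parental, non_centre, centre}, pre-exposure confounders C
(common causes of X, M and Y), post-exposure confounders L (common causes of
M and Y, possibly caused by X), and continuous outcomes Y. Three estimands
are estimated, all as design-weighted population contrasts:

* **ATE of the mediator** — E[Y(M=m)] − E[Y(M=parental)] with X, C, L at
  their natural values. Identified by stabilized mediator weights
  P(M=m)/P(M=m | X, C, L); the exposure sits in the denominator's
  conditioning set because it confounds the mediator–outcome relation.
* **Total effect of the exposure** — E[Y(X=1)] − E[Y(X=0)] through all
  pathways. Only C is adjusted (stabilized weights P(X=x)/P(X=x | C));
  adjusting L or M would block part of the effect being estimated.
* **Controlled direct effect** — CDE(m) = E[Y(x=1, M=m)] − E[Y(x=0, M=m)].
  Identified by the product of the exposure factor P(X=x)/P(X=x|C) and the
  mediator factor P(M=m|X)/P(M=m|X,C,L), feeding a weighted marginal
  structural model Y ~ X + M + X:M. Because the MSM has one parameter per
  (x, m) cell it is saturated in the joint intervention, and
  CDE(m) = β_X + β_{X:m}. The X→L→Y path remains open: differences in L
  *caused by* X contribute to the CDE, while confounding by L is removed.
  Scenario 1 evaluates CDE(centre), scenario 2 CDE(parental).

Identification assumes no unmeasured confounding of X→Y, M→Y (given X, C, L)
and X→M, consistency, and positivity of all weight denominators.

## Propensity models

Defaults are main-effects logistic (binary X) and multinomial-logistic
(3-level M, reference = parental) models; the right-hand side is overridable
per model (`ModelOptions.formula`), and `ModelOptions.saturated=True`
estimates conditional probabilities by weighted cell proportions — the exact
multinomial MLE for discrete predictors, used by the population-table oracle
tests. Binary models are fitted with statsmodels GLM using the design weight
as a frequency weight; multinomial models with scikit-learn's unpenalized
multinomial logistic regression and design-weight sample weights
(statsmodels' multinomial fitter does not accept weights). Fitted
probabilities at 0/1 raise an error naming the remedy; an optional ridge
penalty (`ridge`) and probability clipping (`clip`) are both off by default.
Weight truncation (winsorizing at configurable percentiles) is available but
off by default. Design weights multiply into every analysis weight and into
the balance computations.

ATE stabilization uses the marginal mediator distribution by default; the
X-conditional numerator is available (`stabilizer="marginal_given_x"`).
Balance is summarized by standardized mean differences: weighted group-mean
difference over the *unweighted* pooled SD (so before/after values share a
denominator), for each confounder and pairwise treatment contrast, overall
and within exposure strata; 0.1 is the conventional reporting threshold.
Constant covariates report SMD 0 with a flag.

## Outcome models and variance

Outcomes are analysed by weighted least squares; effects are linear contrasts
of coefficients. Outcomes can first be standardized to design-weighted unit
SD (centering on by default; a ×100 display factor is available via
`scale_factor`). Variances are stratified cluster sandwiches: score
contributions are summed within primary sampling units, centered within
stratum, and combined with the WLS bread; no small-sample factor is applied,
so with one-person clusters and one stratum the estimator equals HC0 exactly
(a Stata-style n_h/(n_h−1) factor is available via `ddof="cluster"`).
Design degrees of freedom are clusters − strata. Single-dataset confidence
intervals use point ± 1.96·se. Weights are treated as known in the variance
(standard MSM practice); a stratified cluster bootstrap (resampling PSUs
within strata, weights held fixed) is provided as a cross-check and agrees
with the linearized SEs within a few percent at the default design. The
plug-in variance is mildly conservative for stabilized-IPW ATEs — empirical
coverage of nominal 95% intervals runs between roughly 93% and 99% per
estimand in the recovery study, ~95–97% pooled.

## Multiple imputation

Chained equations with m = 25 datasets by default and 10 cycles per chain
(the cycle count is a convergence choice; halving it changes results
negligibly at 5% missingness). Conditional models by type: Bayesian logistic
draws (coefficients drawn from the asymptotic normal) for binary columns;
a multinomial logistic draw for the mediator (coefficient uncertainty is not
propagated for the multinomial — a known small-m understatement that the
pooling's between-variance dominates at m = 25); predictive mean matching
(type 1, 5 donors) for continuous columns, with a plain Bayesian normal draw
available. Every conditional model uses all other analysis variables plus
the design weight as predictors — the weight enters as a predictor, not as a
fitting weight — and, because the substantive model is an interaction MSM,
the exposure-by-mediator product is included among the predictors
(congeniality; `xm_interaction=True`). Observed cells are never modified;
chains are independent and seeded from a root generator, so runs are
reproducible. Columns more than 95% missing are rejected.

Weights and outcome models are re-estimated within each completed dataset
and pooled by Rubin's rules: point = mean, T = W + (1+1/m)B, degrees of
freedom by Barnard–Rubin using the design df as the complete-data df, CI from
the t quantile. Imputing before weighting is the package's resolution of the
MI-vs-IPW ordering question; the reverse order is not supported.

## Synthetic cohort generator

The generator emulates the structure of a stratified, clustered national
birth cohort:

* C: two binaries (prevalences 0.15 and ~0.30 — the second is the "area
  disadvantage" variable, see design below) and one standard-normal
  continuous confounder. This compact set exercises every estimator code
  path; a longer confounder list adds nothing structurally.
* X | C logistic; the intercept is solved at run time (fixed-seed 400k
  calibration population, Brent root-finding) so the population prevalence
  equals 0.54 — the low-parental-education share of the motivating cohort.
* L | X, C: one binary (logistic) and one Gaussian post-exposure confounder.
* M | X, C, L multinomial-logistic with reference "parental"; the two
  intercepts are solved so population marginals equal 39.6 / 33.0 / 27.4%
  (parental / non-centre / centre), the childcare distribution of the
  motivating cohort.
* Y = β₀ + β_X·X + β_M[m] + β_{XM}[m]·X + γ_C·C + γ_L·L + ε, ε ~ N(0, 0.9²),
  plus a cluster-level intercept. Coefficients are small relative to the
  noise, so outcomes have SD ≈ 1 and structural coefficients read directly
  as SD-unit effects. The default externalising-symptom analogue solves β_X
  so that the true CDE(parental) = 0.15 SD and sets the centre interaction so
  CDE(centre) = 0.02 SD — a strong inequality nearly erased under universal
  centre care; the vocabulary analogue has a non-centre benefit of +0.10 SD
  and no interaction.
* Survey design: 2 strata (advantaged/disadvantaged areas), 50 clusters per
  stratum, disadvantaged stratum oversampled 2:1; the disadvantage
  confounder's prevalence differs by stratum (0.18 vs 0.42), so unweighted
  analyses are design-biased and weighting genuinely matters. Cluster random
  intercepts have SD 0.05 (ICC ≈ 0.3%, a modest geographic clustering).
  Design weights are inverse sampling rates scaled to mean 1.
* Attrition: a single follow-up response indicator, logistic in X and
  disadvantage (response ≈ 0.89); nonrespondents are dropped and the true
  inverse response probability is folded into the design weight, mirroring a
  cohort that supplies attrition weights rather than documenting their
  construction.
* Missingness: MAR masking of confounders, mediator and outcomes at 5% per
  column by default; the missingness propensity depends only on the
  always-observed exposure and stratum, with the intercept solved so the
  expected masked fraction equals the target. Exposure and design columns
  are never masked.

True estimands come from the structural equations: exact enumeration over
the full covariate support for discrete-only configurations (the oracle used
in exact-agreement tests, tolerance 1e-10), otherwise a coupled Monte Carlo
evaluation at n = 10⁶ with a fixed internal seed (shared uniform/normal
draws across the x = 0, 1 arms; L-path terms computed analytically), keeping
Monte Carlo error well below 0.005 SD.

What the generator does *not* emulate: real instrument scoring and
measurement error, the ~30-variable confounder battery of a real cohort,
informative (MNAR) missingness, non-response patterns beyond a single
indicator, and effect heterogeneity beyond the single X×M interaction.
Passing tests therefore demonstrate correctness of the estimation machinery
under a data-generating process that satisfies the identification
assumptions — not robustness to their violation in real data.

## Numerical choices and study sizes

Saturated-model probabilities are computed by group-by proportions (exact);
WLS solves the normal equations directly. The recovery study uses 200
replicates at n = 20,000 (replicate SEs ≈ 0.0014–0.002 SD on the bias, an
order below the 0.01 SD acceptance band); balance is assessed at n = 50,000;
the MI comparison uses one n = 20,000 cohort with m = 25; the bootstrap
cross-check uses 500 resamples. The calibration check runs at n = 14,376,
the motivating cohort's analysed sample size. Degenerate inputs fail loudly:
zero-SD outcomes, empty exposure–mediator cells (named), absent mediator
levels (named), nonpositive or non-finite weights, strata with fewer than
two clusters, and missing values reaching a weighting stage all raise typed
errors.

## Known limitations

The CDE variance ignores propensity-estimation uncertainty (conservative);
the multinomial imputation draw ignores coefficient uncertainty; no
finite-population corrections; no natural direct/indirect effect
decomposition, no doubly-robust or TMLE estimators, and no MNAR sensitivity
analysis. Sensitivity variants (reduced post-exposure adjustment set,
alternative mediator-window column) are configuration re-runs labelled in
the manifest, not separate code paths.
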