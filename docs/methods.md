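# Methods

## The model

The unit of analysis is the country-year. For outcome deaths `Y_it` with
denominator `N_it` (population, or live births for under-five outcomes) the
retrospective model is a log-link quasi-Poisson rate regression with country
fixed effects:

```
E[Y_it] = exp( α_i + Σ_k β_k 1[band_it = k] + γ' x_it + δ_t ) · N_it / 1000
```

* `band_it` — the funding-exposure band of per-capita disbursement
  (total disbursement / population), categorised at cut points estimated as
  quartiles of the low-income-country distribution. The defaults are
  $1.97 / $3.97 / $7.10, with half-open bands `[0,c1)` baseline, `[c1,c2)`
  low, `[c2,c3)` intermediate, `[c3,∞)` high, so a value exactly at a cut
  belongs to the upper band. Quartiles use linear interpolation between
  order statistics, recorded in the scheme metadata so alternative
  percentile definitions can be compared.
* `x_it` — covariates dichotomised at their pooled median over the study
  window (strict `value > median`; ties map to 0). The default covariate set
  is Gini index, primary education, education expenditure, piped water,
  adequate sanitation, nurses per 1000, hospital beds per 1000, health
  expenditure and military expenditure; GDP per capita, literacy and
  fertility are carried in the panel for stratification and sensitivity use.
* `δ_t` — time controls. Three variants are configurable: indicator dummies
  for crisis periods 2008–09 / 2013–14 / 2015–16 / 2020–21 (the default), an
  alternative single-year set (2007–08, 2015, 2020, 2021), or a full set of
  year dummies (two-way fixed effects).

Age-standardised rates are accepted as pseudo-counts
(`deaths = rate · N / 1000`, possibly non-integer): the Poisson score
equations are well-defined for real-valued outcomes and all inference rests
on the sandwich variance — a quasi-likelihood contract, not a claim that
standardised rates are Poisson counts.

### Estimation

The likelihood is maximised either by profiling the country intercepts out
analytically (`method="absorb"`, the default; exact for the Poisson, scalar
Newton steps per country for the negative binomial) or by explicit dummy
columns (`method="dummies"`). The two parameterisations are mathematically
identical and the suite asserts their agreement to 1e-6, plus agreement with
an independent GLM implementation. Convergence is declared at a relative
log-likelihood change below 1e-8 (max 100 iterations); failure raises with
the iteration trace. Perfect collinearity after the within transformation is
detected by pivoted QR and reported with the aliased column names. Countries
whose outcome is zero in every year contribute nothing to the fixed-effects
likelihood and are dropped with a logged count.

Robust variance defaults to clustering by country: outcomes are serially
correlated within country, so observation-level HC errors would be
anti-conservative. The estimator is `A⁻¹ B A⁻¹` with `B` the outer product
of within-cluster summed scores and a `G/(G−1)` small-sample factor; the
slope block is computed on the within-residualised regressors, which equals
the corresponding block of the full-parameterisation sandwich. The
observation-level HC variant is available for comparison. Population
weighting enters as analytic weights on the score contributions.

The negative-binomial variant (NB2) alternates coefficient fits at fixed
dispersion with a Pearson moment root-solve for the dispersion; a dispersion
pinned at its lower bound (1e-8) means the data show no overdispersion
beyond Poisson.

### Attribution

The counterfactual forces every record into the baseline band while keeping
all covariates and intercepts at their fitted values; since only the
exposure indicators change, `μ_cf = μ_obs · exp(−x_exp'β_exp)` exactly, so
unexposed records are untouched by construction. Deaths averted are
`Σ(μ_cf − μ_obs)`; the prevented fraction for the population is
`1 − Σμ_obs / Σμ_cf`. Intervals are percentile intervals over multivariate
normal draws of the coefficient vector on the log-rate-ratio scale
(100 000 draws by default), deterministic given the seed. Two propagation
modes exist: the full coefficient vector (default) or exposure coefficients
only. Percent averted uses `averted / (observed + averted)` by default —
algebraically the prevented fraction — with `averted / observed` selectable.

Because the draws propagate coefficient uncertainty only (the standard
procedure for this design), coverage of an external all-sources truth runs
slightly below nominal: on replicate synthetic panels whose truth also
embeds the secular trend the default model omits, the 95% interval covers
the analytic averted total ~87% of the time. The test-suite documents this
rather than hiding it.

### Forecast

Stage one builds the synthetic cohort 2024–2030: per country, each covariate
and denominator is extrapolated by an OLS line on a transformed scale (logit
for shares — which automatically clips projections to the admissible range —
log for positive quantities) over the most recent ten observed years;
dichotomisation reuses the frozen retrospective medians and the frozen
exposure cut points; reference funding is the last observed per-capita
value. Countries lacking three usable look-back points are excluded with a
logged reason. Horizon years that are already observed are copied through
and tagged `observed`.

Stage two predicts deaths per country-year from the retrospective fit under
each scenario. Scenarios are per-year multipliers on reference funding:
business-as-usual (`m_t = 1`) and defunding (`m_2025 = 0.17`, `m_t = 0` from
2026). Coefficient draws are shared across scenarios within each Monte-Carlo
cycle (1000 by default), so excess-death uncertainty reflects the scenario
contrast, not independent sampling noise. Country intercepts and fitted time
terms are carried forward unchanged (in year-dummy mode the last fitted
year's dummy persists); future years lie outside every shock period, so
shock terms are zero. Reporting covers 2025–2030; the cumulative row is the
per-draw sum of annual excess, so cumulative = Σ annual holds exactly within
every draw. Mortality rate ratios divide scenario deaths year by year
(denominators are shared, so death and rate ratios coincide).

### Triangulation

Treatment for the matched analysis is "medium/high funding coverage": a
country's period-mean per-capita funding at or above the low/intermediate
cut. The propensity model is a logistic regression of treatment on
baseline-year covariates (perfect separation is reported with the offending
covariate); matching is greedy 1:1 nearest-neighbour on the logit score
without replacement, treated units processed in descending score order, ties
broken by country id, caliper 0.2 SD of the logit score. The DiD contrasts
log rates between the baseline and end years across matched pairs — directly
comparable to a log rate ratio — with the SE from the pair-level double
differences; pairs with a zero rate in any cell are dropped with a logged
count. The negative-control harness refits the primary model on injury
mortality and reports PASS when every exposure-band 95% CI covers 1. Note
PASS is a joint statement over three intervals, so its null rate is about
0.95³ ≈ 0.86, not 0.95; the per-band coverage is the cleaner null property
and both are tested.

## The synthetic-data generator

The generator emulates the study conditions: 133 countries observed
2001–2021 (2793 country-years) split 20/40/40 across low / lower-middle /
upper-middle income; log-rates built from country intercepts (log-normal
heterogeneity, sd 0.25), linear secular decline (calibrated so all-age falls
~13% and under-five ~49% over two decades, partly through improving
covariates), +3% crisis-period bumps, dichotomised covariate effects (taken
from the published adjusted estimates), and true band rate ratios defaulting
to 0.94/0.91/0.85 (all-age), 0.86/0.80/0.68 (under-five), 0.75/0.55/0.35
(HIV/AIDS) and 1/1/1 (injuries, the negative control). Deaths are Poisson
(or NB2 with configurable size) around `rate · denominator / 1000`.

Covariate paths are linear drifts on logit/log scales (calibrated to the
published 2001→2021 descriptive means) plus AR(1) noise. Covariate effects
act through the same pooled-median indicators the estimator constructs
(two-pass generation), so the default fitted model is correctly specified up
to the secular trend — which makes parameter recovery a clean oracle.

Per-capita funding is drawn from a zero-inflated law whose quantile function
passes exactly through the configured low-income quartiles ($1.97/$3.97/
$7.10) — piecewise log-linear between the quartile anchors, with a
lognormal-style upper tail whose width (1.3) puts the top-band mean near
$20 — driven by a persistent country-level uniform rank plus AR(1) wiggle.
A pure two-parameter lognormal cannot pass through all three printed cut
points, hence the anchored quantile construction. The rank drift defaults to
zero so exposure is orthogonal to time in expectation; a nonzero drift (and
a confounding knob tying country intercepts to funding rank) are available
for robustness experiments and are used by the triangulation tests.

What the generator does not emulate: real country identities or magnitudes,
spatial correlation between countries, measurement error in covariates,
exposure misclassification, or funding shocks correlated with crises.
Passing tests therefore demonstrate internal validity of the estimators
under the assumed model class, not external validity on real extracts.

## Problem sizes and numerical choices

* Parameter-recovery acceptance runs 200 study-geometry replicates (a few
  seconds per hundred on one CPU) and asserts the seed-averaged high-band
  rate ratios within ±0.08 of truth with 95% CI coverage inside [90%, 99%].
  The recovery fits use the two-way fixed-effects variant, under which the
  estimator's model class matches the generator's linear secular decline;
  with the shock-dummy default the same points are recovered but coverage
  measures a few points lower (~89–91%) because the omitted trend biases the
  high-band coefficient by ~0.3 SE — a deliberate illustration of why the
  time-control choice matters.
* Monte-Carlo sizes in tests are scaled to the property being checked
  (hundreds to thousands of draws for identities and determinism; 100 000
  draws only where Monte-Carlo stability itself is asserted).
* Tolerances: likelihood convergence 1e-8 relative; formulation-equivalence
  1e-6; exact identities (prevented-fraction algebra, per-draw cumulative
  sums, baseline invariance of the counterfactual) asserted to near machine
  precision because they are implemented as identities, not recomputations.
* Degenerate inputs: constant funding distributions raise a
  degenerate-distribution error; covariates constant after dichotomisation
  warn; zero-rate DiD cells drop the pair; zero baseline deaths make the
  forecast rate ratio an error for that year.

## Known limitations

* The attribution interval understates total uncertainty when the model is
  misspecified (see above); intercept uncertainty is not propagated (it is
  negligible at national death counts but would not be for rare outcomes).
* Synthetic counts at national scale make sandwich CIs extremely tight;
  real age-standardised extracts carry estimation error the quasi-likelihood
  contract absorbs into the robust variance but the generator does not
  emulate.
* The matched DiD identifies an effect only insofar as funding coverage
  changes between the baseline and end years; with the generator's
  stationary default funding law the DiD is close to null by design.
* Covariate extrapolation is a linear trend per transformed series; no
  uncertainty is attached to the extrapolation itself.
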