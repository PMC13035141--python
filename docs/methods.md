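# Methods

## Estimator

The package estimates the price elasticity of quantity demanded for a
good observed only through household expenditures and quantities, using
the spatial variation of unit values across survey clusters. The
identifying assumptions are the standard ones for this class of
estimator:

1. **Common within-cluster price.** Households in one primary sampling
   unit (ward) face the same market price in a given wave; prices vary
   across wards. With panel data, year fixed effects in both first-stage
   equations remove common temporal price trends, so the cluster price
   can be treated as static once year effects are controlled; waves are
   then pooled within cluster to enlarge the cluster samples.
2. **Quality shading is an expenditure phenomenon.** Conditional on
   price, unit values respond to household resources (elasticity `beta1`)
   and demographics, not to unobserved cluster taste shocks that also
   drive budget shares.
3. **Weak separability of quality.** The quality response to price is
   tied to the quality response to expenditure through Deaton's
   `zeta = beta1 / (beta0 + wbar (1 - beta1))`, which lets `psi` (price
   elasticity of the unit value) and `theta` (price slope of the budget
   share) be recovered from the single second-stage slope `phi`.
4. **Stable preferences over the panel window.** Shifts in demand across
   waves load onto year effects; household-level persistence of the
   errors is treated as a nuisance (see below), not modelled
   structurally.

### First stage

Both equations are estimated by OLS with absorbed cluster effects
(within-cluster demeaning, numerically identical to cluster dummies; the
equivalence is tested against an explicit dummy-variable fit). The
unit-value equation runs on consuming records only; the budget-share
equation runs on the full sample with zeros, so its coefficients carry
the participation margin as well as the intensity margin — consistent
with using the unconditional mean share `wbar` in the recovery formulas.
Cluster-constant regressors (e.g. an urban indicator defined at ward
level) are absorbed and dropped from the coefficient table. Coefficient
standard errors are household-clustered, allowing arbitrary serial
correlation within a household across waves. A `year_only` mode estimates
the unit-value equation without cluster absorbers for comparison; its
residual moments are then measured from within-cluster deviations so the
error variance never includes the spatial price signal.

### Error moments and the second stage

The corrections in

`phi = [cov(y1c, y0c) - s10/n~] / [var(y1c) - s11/n~+]`

must estimate the contribution of averaged idiosyncratic error to the
cluster-level moments. With serially correlated errors, the relevant
per-observation moment is `K/T = sigma * (3 + 4 rho + 2 rho^2) / 3` for
three waves of an AR(1), not `sigma` itself; the estimators therefore sum
residuals within household across waves before forming products
(`temporal_clustering`, on by default). Two degrees-of-freedom subtleties
matter and are easy to get wrong:

* Demeaning within G absorbed clusters shrinks household sums by
  `(H - G)/H` in expectation (H = households), so the household-summed
  moments are divided by `T_bar (H - G) - k` rather than `n - k - G`.
* The `s10` correction divides by the full cluster size summary `n~`
  (the budget-share average runs over all `n_c` records while only
  consuming records carry the cross-equation error), whereas the `s11`
  correction divides by the consumer-based `n~+`. Cluster-size summaries
  default to harmonic means, since the error contribution of each
  cluster scales with its inverse size; an arithmetic option exists.

Clusters with no consuming household in any wave contribute to the
budget-share equation but carry no unit-value signal and are excluded
from the second stage (their count is recorded). A non-positive corrected
denominator aborts estimation with a diagnostic rather than returning a
sign-flipped slope.

### Recovering psi: three formula variants

The second-stage slope estimates `theta/psi`. Combining this with the
separability link gives the exact inversion used by default
(`psi_formula="separability_exact"`):

`theta = phi / (1 + (wbar - phi) zeta)`,  `psi = theta / phi = 1 / (1 + (wbar - phi) zeta)`.

Two other arrangements circulate in the applied literature and are
implemented and reported alongside: `deaton_1997`,
`psi = 1 + zeta (theta - wbar)`, the first-order expansion of the exact
form; and `as_printed`, `psi = 1 - beta1 (wbar - theta) / (beta1 + wbar)`.
For broad commodity groups (shares 10–30%, `zeta` below ~1) the three
agree to a few thousandths. For a small-share good like cigarettes
(`wbar` below 1%, `zeta` near 90) they disagree by 0.1–0.4 in `psi`, and
only the exact inversion recovers the generating `psi` of an internally
consistent simulated survey — the recovery suite demonstrates this, and
the discrepancy of the other variants is asserted in the tests rather
than hidden. All variants satisfy the structural limits `psi = 1` when
`theta = wbar` and when `beta1 = 0`. The `as_printed` arrangement is kept
selectable because published cigarette estimates for South Asia are
numerically consistent with it; use it when replicating such studies.

### Inference

Wards are resampled with replacement (all waves of a ward move together),
and the full pipeline — first stage, error moments, aggregation,
corrected slope, recovery — is re-run per replicate; this preserves
within-cluster dependence and the price-commonality structure, and
propagates every estimation step into the interval. Intervals are 2.5/97.5
percentile intervals (the replicate distribution of `eps_p` is visibly
asymmetric), the standard error is the replicate standard deviation.
Replicates whose corrected denominator is non-positive are dropped and
counted; more than 20% dropped raises an error instead of quietly
reporting an interval. Consumption quintiles are taken from the original
sample rather than re-ranked per replicate: the thresholds are population
quantities, and re-ranking would add spurious between-replicate variation.

## Synthetic survey

The generator draws a balanced three-wave ward-sample panel from the
structural model above with every parameter known, so the pipeline can be
validated by parameter recovery. Defaults describe a low-income South
Asian cigarette market: 400 wards x 15 households x 3 waves; 15.5% of
households consuming (a persistent household trait, drawn independently
of price and expenditure); conditional budget share ~5.1% (unconditional
~0.8%); quality elasticity 0.78; unit-value noise SD 0.5 on the log scale
with cross-equation error correlation 0.5 and AR(1) persistence 0.3;
ward log-price SD 0.40 (unit values in such markets spread over a factor
of five between the 10th and 90th percentile); weekly household
consumption ~NPR 3,550 in 2017 prices.

Two parametrisation choices deserve emphasis:

* **Unconditional coefficients.** `beta0`, `theta`, `gamma0` are the
  slopes of the unconditional budget-share equation — the regression the
  pipeline actually runs. Consuming households receive conditional mean
  `linear index / participation_rate`; non-consumers are exactly zero.
  The estimated coefficients therefore converge to the labelled
  parameters, and implied elasticities computed from the truth with the
  unconditional `wbar` line up with the pipeline.
* **Internal consistency.** The default `psi` (0.7518) sits on the
  separability locus `psi = (1 + zeta theta)/(1 + zeta wbar)` at the
  calibrated mean share. Without this restriction no recovery based on
  the quality-correction algebra could return the generating values —
  `psi` remains a free field precisely so misspecification can be
  studied.

A strictly positive linear share model cannot carry the full covariate
dispersion observed in real data: with the conditional mean scaled by
1/participation, Table-magnitude slopes push a nontrivial share of
consumers below zero. The generator therefore (i) halves the
budget-share covariate slopes, (ii) keeps expenditure dispersion moderate
(log-consumption SD ~0.28 rather than the ~0.6 of real surveys), and
(iii) floors the conditional systematic share at 0.005 (Engel curves for
a habit good flatten near zero rather than turning negative). Residual
violations are clipped into (0,1); if they would exceed 1% of consuming
records the generator refuses with an error rather than distorting the
data. Consequently the synthetic data are *cleaner* than a real survey:
shares are near-Gaussian around their conditional means instead of
heavily right-skewed, expenditure is less dispersed, there is no
attrition, misreporting is symmetric, and participation is exogenous.
Passing recovery tests therefore demonstrate that the estimator and its
corrections are implemented correctly and are consistent under the
model's own assumptions — not that the assumptions hold in any particular
real survey.

## Tunable parameters that matter

| Parameter | Default | Why |
| --- | --- | --- |
| `recall_divisor` | 365/7 ≈ 52.14 | converts annual recall to true weekly equivalents; 52 selectable |
| `base_year` / `cpi_series` | 2017 | all currency in base-year prices; deflation is flagged and idempotent |
| `fe_mode_eq1` | `cluster_and_year` | cluster absorbers keep the spatial price signal out of `s11`; `year_only` provided for comparison |
| `psi_formula` | `separability_exact` | only variant consistent with the second-stage slope at small shares |
| `wbar_mode` | `unconditional` | matches the unconditional `beta0`; conditional mean available |
| `sigma10_divisor` | `all` (n_c) | derived from which records enter each cluster average |
| `cluster_size_summary` | `harmonic` | corrections average inverse cluster sizes |
| `temporal_clustering` | on | household-summed moments price in serial correlation |
| `bootstrap_reps` | 1000 | replicate SD stabilises around several hundred replicates |
| weighting | descriptives weighted, regressions unweighted | design weights belong in population summaries; both modes exposed for regressions |

## Numerical choices

Fixed effects are absorbed by exact within-group demeaning and solved by
dense least squares on the demeaned design; rank deficiency is detected
from the QR diagonal and reported with the offending column names.
Group-constant columns are dropped (absorbed) rather than treated as
errors. Education enters as log(1 + years) so zero-schooling households
remain in the sample. Quintiles are pooled per-capita expenditure
quantiles with first-occurrence rank tie-breaks. Unit values are stored
as missing — never zero — for non-consumers, and positive expenditure
with zero quantity is a hard data error. Deflation is tracked via a frame
attribute, making it idempotent. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`.

Test problem sizes: parameter recovery runs 200 study-scale replicates
(|mean bias| < 0.05 for both elasticities); bootstrap coverage uses 100
outer surveys of 300 wards x 15 households with 200 replicates each —
the ward count, not the ward size, is reduced, because the corrected
denominator `var(y1) - s11/n~+` needs realistic cluster sizes to stay
away from zero. That fragility is a genuine property of the method:
designs with few or small clusters produce heavy-tailed slope estimates,
and the dropped-replicate accounting plus the denominator guard make the
failure loud.

## Limitations

* Participation (smoking prevalence) is treated as exogenous; there is no
  two-part or selection model, matching the estimator's own assumptions.
* The method identifies one elasticity for the pooled population;
  subgroup elasticities would require far more consuming households per
  cluster than these designs provide.
* `theta` and `psi` are identified only through the separability
  restriction; if quality shading responds to price differently than the
  restriction implies, `eps_p` inherits that misspecification, and the
  formula-variant spread (reported in `psi_variants`) is a useful
  sensitivity range.
* Cluster prices are assumed static across the three waves once year
  effects are removed; a `price_wave_sd` option simulates violations but
  the estimator does not model them.
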