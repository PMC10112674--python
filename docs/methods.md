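# Methods

## Latent model and data-generating assumptions

Respondent *i*'s willingness to pay for an increase in essential equine
care costs is modeled as a latent fraction of their current monthly
cost,

    WTP_i = x_i'β + ε_i,   ε_i ~ iid N(0, σ²),

where x_i collects an intercept, 0/1 indicators (equid-count bins,
board/lease tier, disciplines, COVID financial-stability categories,
sell/stop-lease intent, South region, household income > $75k, age
< 35) and the current monthly cost in raw dollars. The dependent
variable is dimensionless (a proportion of current cost): all
coefficients are in proportion units, and the cost coefficient is
proportion per dollar. WTP is never observed directly; the double-bounded
design brackets it in a censored interval (closed lower, open upper
bound; the Gaussian likelihood is insensitive to boundary openness).
A double-no respondent's lower bound is −∞, not 0 — negative latent WTP
is meaningful (a respondent who would pay *less* than today) and
standard left censoring handles it; `floor_zero` truncates at 0 as a
sensitivity switch. Note the source text's prose describes the double-no
upper bound inconsistently with its own mapping table; the mapping table
is authoritative here (`c2n` is the double-no upper bound).

### Bid design

Every respondent first sees a 10% increase (the dollar amount shown is
rounded half-up to cents; the analysis fraction is exactly 0.10). The
follow-up is a discrete-uniform integer percent, 11–20 inclusive after a
yes and 1–9 inclusive after a no, mirroring the survey platform's
uniform randomization. Whether the original instrument drew integer or
continuous percents is not documented; integer percents are assumed.
Ties (latent WTP exactly at a bid) count as yes throughout, fixing the
simulator's determinism at a measure-zero boundary.

## Estimation

Each observation contributes
ln[Φ((u−μ)/σ) − Φ((l−μ)/σ)], μ = x'β, with one-sided forms for censored
rows. Numerics that matter:

- **Tail stability.** The interval probability is evaluated in log space
  via `log_ndtr`, reflecting the pair into the lower tail and combining
  with `log1p(−exp(Δ))`, so intervals 30+ SDs from the mean return
  finite log-probabilities instead of underflowing to −∞.
- **Parameterization.** The scale is optimized as ln σ, so σ > 0 on
  every iterate.
- **Conditioning.** Design columns are internally standardized to unit
  root-mean-square (the cost column is O(100) while indicators are O(1));
  estimates and covariances are transformed back afterwards.
- **Initialization.** OLS of pseudo-midpoints on X — interval rows use
  (l+u)/2, right-censored rows l + 0.05, left-censored rows u − 0.05 —
  with ln σ from the midpoint residual SD (floored at σ = 0.01).
- **Optimizer.** BFGS with the analytic score, then Newton polishing
  with a finite-difference Hessian of that score, declaring convergence
  at total-gradient inf-norm ≤ 1e-8 (in the standardized space), max 200
  iterations; all tolerances live in `FitOptions`. Non-convergence
  returns `converged=False` with a warning; rank deficiency and fully
  unbounded data raise errors naming the problem.

### Inference

Robust covariance is the sandwich A⁻¹BA⁻¹ with A the observed
information (negative finite-difference Hessian of the total
log-likelihood at the optimum) and B = Σᵢ sᵢsᵢ' the outer product of
per-observation analytic scores. No small-sample degrees-of-freedom
scaling is applied by default; `dof_scale` enables n/(n−k) for
cross-checking against implementations that do. The Wald statistic is
b'V_b⁻¹b over all slope coefficients (intercept and ln σ excluded),
referred to χ²(#slopes). Mean WTP is x̄'β̂ at the estimation-sample
covariate means with delta-method SE √(x̄'Vx̄); means are treated as
fixed constants by default (`include_mean_variance` adds their sampling
variance as a sensitivity). Significance stars implement ≤ at each
boundary: p ≤ 0.10 *, ≤ 0.05 **, ≤ 0.01 ***.

## Survey-data conventions

- Skip-logic classification is the fixed priority leaser > boarder >
  owner (smallest expected population first); boarding is checked before
  at-home ownership. Records with no equids reported are excluded and
  logged.
- Equid-count bins 5–9/10–19/20+ collapse to a single "5+" indicator in
  models; the finer bins stay on the raw record.
- Free-text "other" lease/board descriptions are binned by a
  configurable keyword rule table; unresolvable text keeps type "other"
  and contributes 0 to both the Partial and Full indicators.
- Missing model covariates are handled by listwise deletion per model
  (no imputation), with per-field drop counts logged.
- Summary SD uses the n−1 denominator and is labeled SD; n = 1 reports
  SD 0 with a warning. Mean comparisons use the pooled-variance Student
  t-test; zero pooled variance returns (t = 0, p = 1) when means are
  equal and is an error otherwise.
- Covariates with no variation in an estimation sample (possible at
  desk-scale group sizes) can be omitted per model via
  `drop_degenerate_columns`, with the omission logged — the standard
  behavior of interval-regression software.
- Respondent sex is carried on the record but never enters models (too
  little variability in the motivating population).

## Synthetic generator

The generator emulates the structure the analysis assumes: independent
Bernoulli indicators at the published frequencies (South 0.73, income
> $75k 0.55, age < 35 0.32, ...), categorical draws for mutually
exclusive blocks, and log-normal costs with a point mass at $0 for free
arrangements. The log-normal respects non-negativity and the heavy right
tail (owner cost SD exceeds the mean); its parameters are solved in
closed form so the *overall* mean/SD hit the published targets
(owner $406.37/$606.40, boarder $391.42/$285.45, leaser $190.22/$211.19).
Item missingness of 6.5% each on income and age brackets reproduces the
observed drop from group sizes to model sizes under listwise deletion.

The `table1-like` preset sets per-group (β, σ) so the simulated
response-sequence mix resembles the published one — owners mostly
yes-yes, boarders mostly no-no, leasers in between. Two calibration
facts worth knowing:

- The published boarder coefficient table and the published boarder
  response mix are mutually inconsistent under this model (a mean WTP
  fraction of ~0.14 with σ ≈ 0.11 cannot produce 66% double-no), so the
  preset follows the response mix; preset coefficients are package
  presets, not published estimates.
- **Identification is bounded by the bid ladder.** Bids only span 1–20%
  of cost, so a subgroup whose latent mean sits far above 0.20 answers
  yes-yes almost surely and its coefficient exhibits quasi-complete
  separation (the likelihood is monotone in it; no estimator recovers
  it). Preset effects are therefore kept small enough that every
  subgroup's latent mean stays within the informative range. The very
  large leaser effects printed in the motivating study's small sample
  (n = 44) are of exactly the kind this limit flags.

What the generator does **not** emulate: covariate correlations (none
are published to calibrate to; an independence draw is used),
cost-by-covariate relationships, protest zeros, nonresponse mechanisms,
and free-text answers. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions, not robustness to real-survey misspecification.

## Test and verification design

Problem sizes were chosen so the full suite runs comfortably on one CPU:
exhaustive enumeration for the interval mapping (all 38 legal
sequence × follow-up combinations); 1000 random triples against a plain
normal-CDF oracle for the likelihood (1e-10 agreement); brute-force
(β₀, ln σ) grid search as the optimizer oracle on n = 30 fixtures
(agreement within one grid step); 200 replicates × n = 5000 per group
for parameter recovery (bias within 3 Monte-Carlo SEs, pooled 95%
robust-CI coverage in [93%, 97%], σ within 10%); 500 replicates at
n = 2000 for the Wald test's size under the null (99% binomial band
around 0.05); and chi-square goodness of fit of simulated sequence
frequencies against the closed-form distribution at α = 0.01 over 20
random parameter settings, where a setting only fails if an independent
re-simulation also rejects (a real mismatch rejects on every stream; a
1%-level fluctuation does not recur).

## Known limitations

- The interval regression is fully parametric; there is no
  nonparametric (Turnbull-type) cross-check.
- Delta-method CIs only; no Krinsky–Robb simulation.
- The sandwich uses a finite-difference Hessian of the analytic score;
  an analytic Hessian would be marginally faster and tighter.
- Single-bid respondents (missing second response) are dropped rather
  than contributing one-sided information.
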