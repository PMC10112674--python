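# equiwtp

Double-bounded dichotomous-choice willingness-to-pay (WTP) estimation
for equine-care surveys: randomized bid design, interval-censored
Gaussian maximum likelihood with robust inference, mean-WTP prediction,
and a calibrated synthetic survey generator.

## The problem

When the cost of essential equine care (feed, water, daily care) rises,
how much more are horse owners, boarders, and leasers willing to pay
before cutting back? A contingent-valuation survey elicits this with two
sequential yes/no questions: first a bid equal to a **10%** increase
over the respondent's current monthly cost, then a follow-up bid of
**11–20%** after a yes or **1–9%** after a no (integer percents, drawn
uniformly at random). The two answers bracket the respondent's latent
WTP — expressed as a *fraction of current cost* — in a censored
interval:

| response sequence | interval for WTP |
|---|---|
| yes, yes | [c2y, +∞) |
| yes, no  | [0.10, c2y) |
| no, yes  | [c2n, 0.10) |
| no, no   | (−∞, c2n) |

## The model

Latent WTP is linear-normal in respondent characteristics,

    WTP_i = x_i'β + ε_i,   ε_i ~ iid N(0, σ²),

and each respondent contributes the interval-censored log-likelihood

    ℓ_i(β, ln σ) = ln[ Φ((u_i − x_i'β)/σ) − Φ((l_i − x_i'β)/σ) ],

with the one-sided forms for left/right censoring. `equiwtp.fit`
maximizes Σᵢ ℓ_i over (β, ln σ) with the analytic score (BFGS plus
Newton polishing), reports heteroskedasticity-robust sandwich standard
errors H⁻¹(Σᵢ sᵢsᵢ')H⁻¹, a Wald χ² test that all slopes are zero, and
the mean WTP as the linear prediction x̄'β̂ at the estimation-sample
covariate means with a delta-method standard error √(x̄'Vx̄).

Separate models are fit for the three survey groups, assigned by
skip-logic priority (leaser > boarder > owner). Since no respondent-level
data were ever deposited for the motivating study, the package ships a
synthetic generator whose covariate frequencies and cost distributions
track the published summary tables, so the whole pipeline is testable
end to end against known truth.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on the
default study-shaped population (seed 20200701):

```sh
python analysis/01_simulate.py      # 292 owners, 282 boarders, 79 leasers
python analysis/02_descriptives.py
python analysis/03_fit_models.py
python analysis/04_report.py
```

`02_descriptives.py` prints per-group cost summaries and the
response-sequence mix, e.g.

```
owner    n= 292 cost $ 473.84 +-  688.28 [0, 5967]  sequences yes_yes=0.66 yes_no=0.12 no_yes=0.07 no_no=0.15
boarder  n= 282 cost $ 406.56 +-  300.24 [0, 2598]  sequences yes_yes=0.12 yes_no=0.10 no_yes=0.14 no_no=0.64
```

— most owners accept both bids while most boarders reject both, the
qualitative pattern the generator is calibrated to. `03_fit_models.py`
fits the three interval regressions (listwise-deleting records missing a
model covariate) and prints the headline quantity, the mean WTP at
covariate means:

```
owner    n= 251 ... loglik= -210.748 Wald chi2(13)= 41.03
         mean WTP = 0.225 of current cost (robust SE 0.017) = $110.77/month at the mean cost $492.07
boarder  n= 255 ... loglik= -217.236 Wald chi2(15)= 54.29
         mean WTP = 0.012 of current cost (robust SE 0.010) = $4.97/month at the mean cost $406.01
```

The owner estimate says: at this population's covariate mix, owners
would tolerate a ~22.5% increase in monthly care costs on average
(about $111/month at the sample-mean cost), and the Wald test rejects
the hypothesis that no covariate matters. `04_report.py` renders the
three fits side by side (coefficient, robust SE, significance stars at
p ≤ 0.10 / 0.05 / 0.01) into `results/wtp_table.tsv`.

The same stages are available as a CLI
(`equiwtp simulate|summarize|fit|report`); every run writes a
`*.manifest.json` with the seed and options, and identical seeds give
byte-identical outputs.

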