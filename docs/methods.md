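# Methods

This note documents the model implemented by `psmcea`, the conventions
chosen where the source analysis is silent, and what the synthetic-data
generator does and does not emulate. It is the package's own account; the
original analysis was built in TreeAge from BEATcc trial data, and only its
printed inputs and results are available for reconstruction.

## Partitioned survival model

Three mutually exclusive states: progression-free (PF), progressed disease
(PD), dead. Occupancy is read directly off the two survival curves rather
than from transition rates:

    PF(t)   = S_PFS(t)
    dead(t) = 1 − S_OS(t)
    PD(t)   = max(0, S_OS(t) − S_PFS(t))

- **Cycle grid.** 21-day cycles; months are days/30.4375, years are
  days/365.25. A 10-year horizon gives ⌊10·365.25/21⌋ = 173 cycles. Exact
  day arithmetic avoids cumulative drift on the grid.
- **Clipping.** Fitted PFS/OS curves can cross in the far tail; PD occupancy
  is clipped at zero (standard partitioned-survival practice) and any
  violation beyond 1e-9 raises a structural warning carrying the maximum
  gap. The published base-case curves do not cross within the horizon.
- **Half-cycle correction** (default on): continuous accruals (life-years,
  QALYs) use the mean of the state occupancy at each cycle's start and end,
  which is exactly trapezoidal integration of the occupancy curves on the
  cycle grid. The engine is tested against adaptive-quadrature integrals of
  the continuous curves: agreement within 1% at 21-day cycles and
  convergence as the cycle length shrinks.
- **Point costs at cycle start.** Drug administrations, monitoring visits
  and per-cycle event costs are charged at the start of each cycle to the
  patients then occupying the relevant state, discounted at the cycle-start
  time. This mirrors how a cohort model administers day-1 drugs and is the
  natural partner of the half-cycle-corrected accruals.
- **Discounting.** (1 + r)^(−t) with r = 0.05/yr (range 0.04–0.06) at
  continuous cycle time in years, not integer-year steps.

## Survival curves

The published curves are log-logistic in the *rate* form
S(t) = 1/(1 + λt^γ), t in months:

| arm, endpoint        | γ    | λ       | implied median (mo) | trial median (mo) |
|----------------------|------|---------|---------------------|-------------------|
| intervention PFS     | 1.74 | 0.0079  | 16.15               | 13.7              |
| control PFS          | 2.18 | 0.0052  | 11.16               | 10.4              |
| intervention OS      | 2.02 | 0.00099 | 30.71               | 32.1              |
| control OS           | 2.16 | 0.0011  | 23.43               | 22.8              |

The implied medians bracket the trial medians only when t is in months; that
consistency check is a unit test and pins the time unit. Conversions to the
scale form 1/(1 + (t/α)^β) used by lifelines and `scipy.stats.fisk`
(λ = α^(−β), γ = β) are provided and tested in both directions.

The fitting stage supports the full six-family candidate set (exponential,
Weibull, Gompertz, log-normal, log-logistic, gamma) by right-censored
maximum likelihood, likelihood Π f(t_i)^{δ_i} S(t_i)^{1−δ_i}, with AIC/BIC
model selection and a deterministic tie-break in family enum order. Because
individual patient data are not available, fitting operates on *pseudo-IPD*
(simulated records, or records reconstructed elsewhere from digitized
curves); least-squares refitting of digitized (t, S) coordinates is also
provided. Numerical choices: parameters are optimized on the log scale
(Gompertz shape unconstrained, so decreasing hazards are representable),
Nelder-Mead with three fixed moment-informed starting points per family,
best converged likelihood kept; log-sum-exp forms keep the log-logistic
density stable for large λt^γ. Non-convergence returns a diagnostic report,
never a silent fallback.

## Costing

Per-cycle regimen cost is Σ weight × dose(rule, patient) × price/mg over the
components active that cycle. Dosing rules: flat mg; mg/kg (weight 60 kg);
mg/m² (body surface area 1.64 m², range 1.23–2.05); Calvert formula
dose = AUC × (CrCl + 25) with CrCl 70 mL/min — so 1200 mg atezolizumab,
900 mg bevacizumab, 287 mg paclitaxel, 82 mg cisplatin, 475 mg carboplatin.
Cisplatin/carboplatin are mix-weighted 50/50. Platinum + paclitaxel run for
six induction cycles; bevacizumab (both arms) and atezolizumab (intervention
arm) are maintenance drugs.

Where the source analysis is under-specified, the package takes a position
and exposes the alternative as a toggle:

- **Maintenance stopping rule** (`treatment_duration`, default
  `response_cap`): maintenance drugs continue while progression-free, at
  most the arm's median duration of response from the trial (13.6 months
  intervention, 8.6 control) — the source text states trial treatment
  duration was the model's basis. The alternative `until_progression`
  (treat while PF over the whole horizon) multiplies intervention-arm drug
  cost by roughly 2× and is irreconcilable with the published totals: the
  discounted PF time of the intervention arm alone is ≈ 32.9 cycles, worth
  ≈ $200k of atezolizumab + bevacizumab at list prices.
- **SAE cost timing** (`sae_timing`, default `per_cycle`): the published
  cost table labels adverse-event management costs "per cycle", so the
  expected cost Σ incidence × unit cost is charged per on-treatment cycle.
  `once` instead charges it a single time at model entry.
- **Monitoring scope** (`monitoring_scope`, default `alive`): follow-up,
  laboratory work and CT are charged every cycle a patient is alive;
  the alternative restricts labs + CT to on-treatment cycles.
- **Supportive-care split** (`bsc_scope`, default `all_pd`): best supportive
  care accrues for all progressed occupancy, and second-line therapy cost
  additionally for the 54% / 58% of progressors who receive it (supportive
  care co-occurs with, and follows, second-line treatment). The alternative
  `split` charges BSC only to the (1 − proportion) complement.

No vial wastage is modelled (prices are per mg, no vial sizes published).
Itemized totals (drug, SAE, monitoring, subsequent therapy, supportive
care) are each non-negative and sum exactly to the arm total; totals are
monotone in every unit price, and rescaling all unit costs by a constant
rescales costs and the ICER by that constant while leaving QALYs unchanged
(all tested).

## QALY accrual — the reproduction convention

The textbook partitioned accrual (available as
`qaly_accrual="partitioned"`, discounted) is

    QALY = Σ_k [PF_k·u_PF + PD_k·u_PD] · Δt · d_k − AE decrement.

Under it, the intervention arm's QALY total is bounded above by
u_PF × restricted life expectancy = 0.85 × 3.37 ≈ 2.86 — *below* the
published 3.52, for any discounting and any utility set within the published
table. The published totals are therefore not producible by the textbook
accrual; they are, however, reproduced almost exactly by an accrual in which
every **alive** patient accrues u_PD and progression-free patients accrue
u_PF on top of it, with QALYs undiscounted (costs stay discounted):

    QALY = Σ_k [PF_k·u_PF + (PF_k + PD_k)·u_PD] · Δt − AE decrement.

This yields 3.519 / 2.458 QALYs against the published 3.52 / 2.35. The
effective PF weight u_PF + u_PD = 1.37 exceeds 1 — a mis-specification by
usual standards, but evidently the source model's computation (it is an easy
construction in a TreeAge payoff table, with discounting configured per
payoff). The package defaults to this reproduction convention
(`qaly_accrual="alive_weighted"`, `discount_qalys=False`) so that the
pipeline regenerates the published results, and keeps the textbook accrual
one flag away; analysts studying the decision problem rather than the
reproduction should prefer `partitioned` with discounting.

Adverse-event disutilities are one-off decrements: incidence × disutility ×
one cycle length, applied at model entry (duration is unpublished; one
cycle per affected patient is the package's choice). Death utility is 0.

## Incremental analysis

ΔC, ΔE, ICER = ΔC/ΔE (undefined at ΔE = 0 or under dominance, with a
dominance flag), NMB = WTP·ΔE − ΔC at WTP $39,855.79/QALY. The ICER is
computed from unrounded totals; the published table's ICER differs from the
ratio of its own rounded increments only by that rounding.

## One-way sensitivity analysis and price threshold

Every parameter with a published range uses those exact bounds; parameters
without one (SAE incidences, subsequent-therapy proportions, platinum mix)
use ±25% of base. Survival parameters carry no published ranges and are
held fixed. Each parameter is moved alone (clamped to its domain and
flagged if a bound leaves it), the ICER recomputed, and bars sorted by
spread — fully deterministic and stable under re-run. The price-threshold
search verifies the ICER is monotone in the drug price numerically, then
bisects (Brent) on [0, list price] to within $1/QALY of the target WTP;
targets outside the attainable range are reported as unreachable rather
than extrapolated.

## Probabilistic sensitivity analysis

10,000 Monte-Carlo iterations; per iteration one independent joint draw of
all varied parameters, full model rerun, (ΔC, ΔE) recorded; the CEAC is the
fraction of iterations with positive NMB on a WTP grid of $0–200,000 by
$1,000 plus the three reference thresholds exactly. Distribution
assignment: gamma for costs, beta for probabilities and utilities, both by
method of moments with the standard error read from each parameter's range
as a 95% interval, se = (max − min)/(2·1.96); body surface area and the
discount rate (published with beta tags but non-unit supports) use a
four-parameter beta scaled onto their published ranges. The published
acceptability percentages cannot identify the original dispersion
convention uniquely, so an `se_scale` multiplier is exposed; the default
(1.0) is the plain 95%-interval reading. Survival parameters stay fixed, as
in the one-way analysis — consequently ΔE varies only through utilities and
the acceptability curve is tighter around the deterministic ICER than the
published curve appears to be. Invalid draws would be rejected and redrawn
(counted, > 1% aborts); with the base inputs none occur. Runs are
bit-reproducible by seed (`numpy.random.default_rng`).

## Synthetic data generator

`synthetic_data` makes the pipeline self-contained:

- **Pseudo-IPD**: inverse-CDF log-logistic draws t = ((1/u − 1)/λ)^{1/γ}
  with independent Uniform(0, c) administrative censoring, c calibrated
  numerically so the expected censored fraction matches the request. This
  emulates the *statistical* situation of curve fitting (right-censored
  records from the published curves); it does not emulate digitization bias,
  number-at-risk reconstruction, covariates, or informative censoring.
- **Digitized curves**: (t, S(t) + ε) coordinate files with clamped Gaussian
  noise, standing in for graph-digitizer output.
- **Base-case config**: the complete published input table as a validated
  object, YAML round-trippable, with a 34-row manifest test guaranteeing
  each table row appears exactly once.

Passing recovery tests on these fixtures shows the estimators are correct
on data from the assumed model; it says nothing about fit adequacy to the
real trial curves, which only the published parameters represent here.

## Problem sizes and tolerances

Cycle engine: 173 cycles (all analyses). Parameter-recovery tests: n = 5,000
records (shape within ±5%, rate within ±15%, fixed seeds; tolerances set
from the sampling spread of the estimator at that n). MLE cross-checked
against lifelines on log-logistic fits (≤ 0.1% parameter discrepancy).
Engine-vs-quadrature life-years: 1% at 21-day cycles. S(median) = 0.5 to
1e-9. Occupancy conservation to 1e-12. PSA: 10,000 iterations (Monte-Carlo
s.e. ≈ 0.5 percentage points on the CEAC).

## Known limitations

- The reproduction QALY convention is deliberately non-standard (above);
  conclusions about *incremental* effectiveness under the textbook accrual
  are roughly half as large, which proportionally raises the ICER.
- The control-arm total cost reproduces less closely than the intervention
  arm's under any single consistent reading of the costing rules; the two
  arms' published totals appear to embody slightly different treatment-
  duration assumptions, which a single-rule model cannot satisfy at once.
- Survival uncertainty is excluded from both sensitivity analyses (no
  published ranges), so decision uncertainty is understated.
- No vial wastage, administration fees, premedication, or indirect costs;
  second-line therapy is a single blended cost; grade 1–2 adverse events
  are excluded.
- A 10-year horizon truncates the log-logistic tails; restricted means are
  used throughout.
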