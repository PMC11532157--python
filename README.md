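# psmcea

Partitioned survival cost-effectiveness analysis of first-line
**atezolizumab + bevacizumab + platinum chemotherapy** versus
**bevacizumab + platinum chemotherapy** for metastatic cervical cancer,
from the Chinese healthcare-system perspective.

The package is a faithful, fully scripted reimplementation of a published
TreeAge analysis built on the BEATcc phase-III trial. It is aimed at health
economists and methodologists who want to reproduce, audit, or perturb that
analysis: every input is the published table value, every structural
assumption is an explicit, documented toggle, and every stage (survival
fitting, cycle engine, costing, sensitivity analyses) is a tested library
function with a thin CLI on top.

## The model

A three-state partitioned survival model (progression-free → progressed →
dead) on a 21-day cycle over a 10-year horizon. State occupancy is read
directly off log-logistic survival curves in the rate form

    S(t) = 1 / (1 + λ t^γ),   t in months

with published (γ, λ) per arm and endpoint: occupancy at cycle time *t* is
`PF = S_PFS(t)`, `dead = 1 − S_OS(t)`, `PD = max(0, S_OS − S_PFS)`.

Costs (USD, discounted 5%/yr) cover drug acquisition under body-size dosing
rules (flat 1200 mg atezolizumab, 15 mg/kg bevacizumab, 175 mg/m²
paclitaxel, 50 mg/m² cisplatin or Calvert-formula carboplatin at AUC 5,
50/50 platinum mix), grade ≥ 3 adverse-event management, routine monitoring,
second-line therapy and best supportive care after progression. Utility
weights (u_PF = 0.85, u_PD = 0.52, minus adverse-event decrements) turn
occupancy into QALYs. The two arms are paired into ΔC, ΔE, the incremental
cost-effectiveness ratio ICER = ΔC/ΔE and net monetary benefit at the
willingness-to-pay threshold of $39,855.79/QALY (3× 2023 Chinese GDP per
capita).

Uncertainty is handled twice: a deterministic one-way (tornado) analysis
over every published parameter range (±25% where no range is printed), and
a 10,000-iteration probabilistic sensitivity analysis (gamma for costs,
beta for probabilities and utilities) summarized as a cost-effectiveness
acceptability curve.

Structural choices the source analysis leaves unstated — the maintenance
stopping rule, SAE cost timing, monitoring scope, supportive-care split,
QALY accrual convention — are configuration toggles whose defaults
reproduce the published totals; `docs/methods.md` discusses each and what
the textbook alternative yields.

## Worked example

```sh
$ psmcea run-base-case -o results/
atezolizumab: cost=121611.47 qaly=3.5187
chemotherapy: cost=37120.66 qaly=2.4580
dC=84490.81 dE=1.0608 ICER=79650.29 USD/QALY (WTP 39855.79; not cost-effective)
```

Adding atezolizumab buys 1.06 QALYs at an extra cost of $84,491, i.e.
roughly $79,650 per QALY gained — about twice the Chinese willingness-to-pay
threshold, so the combination is not cost-effective at list price (the
published analysis reports $128,179.56 vs $42,065.89, 3.52 vs 2.35 QALYs,
ICER $73,601.43 — the same conclusion).

```sh
$ psmcea run-dsa -o results/
tornado written (33 parameters; top drivers: price_atezolizumab, utility_progression_free, utility_progressive)
break-even price_atezolizumab = 1.6768 USD/mg (ICER 39855.79, reachable=True)
```

The atezolizumab price dominates the tornado; no one-way perturbation pulls
the ICER below the threshold. Bisection finds the drug becomes
cost-effective at ≈ $1.68/mg (≈ 43% of the $3.88/mg list price).

```sh
$ psmcea run-psa -o results/ --seed 1 --iterations 10000
10000 iterations (seed 1): mean dC=84582.58 mean dE=1.0612; P(cost-effective at 39855.79) = 0.00%
```

The same library calls are available in Python:

```python
from psmcea import base_case_config, evaluate
res = evaluate(base_case_config())
print(res.icer, res.nmb, res.cost_effective)
```

Other commands: `psmcea make-fixtures` (base-case YAML plus synthetic
pseudo-IPD and digitized-curve CSVs) and `psmcea fit-survival <ipd.csv>`
(censored MLE across six candidate families, ranked by AIC/BIC).

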