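# survgwas

Cox versus logistic regression for genetic association studies of **cohort**
and **case-cohort** design: a simulation laboratory, from-scratch estimators,
and a two-step (logistic filter → Cox refit) association scan.

## The problem

Prospective cohorts and case-cohort studies observe *time to disease*, so the
natural association model for a SNP is the Cox proportional-hazards model,
with the per-allele hazard ratio (HR) as the effect measure. In practice GWAS
of such studies are usually run with logistic regression on end-of-follow-up
case status — it is far cheaper computationally and universally supported —
which estimates an odds ratio (OR) instead. The two measures diverge as
cumulative incidence, follow-up length and effect size grow, and the two
approaches differ in power. This package quantifies those trade-offs by
simulation and implements the practical compromise: screen every SNP with
logistic regression at a liberal threshold, then refit only the survivors
with (appropriately weighted) Cox regression.

## The model

Event times are Weibull with proportional hazards,

    h(t | A, G) = λ v t^(v-1) · exp(β_A·A + β_G·G),

with age A ~ Normal(56, 6²) years, genotype G ~ Binomial(2, RAF), and inverse-CDF
sampling T = [−log U / (λ e^{β_A A + β_G G})]^{1/v}. Censoring is administrative at
20 years ("complete"), at one of four surveys {5, 10, 15, 20} years
("survey"), or Uniform(0, 20) ("random"); a subject is a case iff T < C, and
time in study is min(T, C). The shape v is calibrated by root-finding so the
expected case fraction matches a target cumulative incidence (5–15%).

Estimators, all written here from first principles and verified against
brute-force likelihood maximisation and reference libraries in the tests:

* **Cox** — partial likelihood on the time-on-study scale, Newton–Raphson,
  Efron (default) or Breslow ties, inverse-information SEs;
* **Prentice-weighted Cox** — the Prentice (1986) case-cohort
  pseudo-likelihood (subcohort members at risk throughout; outside cases enter
  only at their own failure) with dfbeta sandwich robust SEs;
* **logistic** — IRLS/Newton maximum likelihood on case status (cases +
  subcohort non-cases in the case-cohort design), model-based SEs.

Inference throughout is the two-sided Wald test, p = 2Φ(−|β̂/SE|).

## Worked example

```python
import numpy as np
from survgwas import (Scenario, calibrate_params, simulate_cohort, sample_case_cohort,
                      cox_fit, logistic_fit, prentice_cox_fit)

scenario = Scenario(design="cohort", n_cohort=20_000, raf=0.25, hr=1.5,
                    incidence=0.15, censoring="complete")
rng = np.random.default_rng(2)
cohort = simulate_cohort(scenario, calibrate_params(scenario), rng)
print(cox_fit(cohort).estimates["genotype"], logistic_fit(cohort).estimates["genotype"])
```

Running `python examples/02_fit_models.py` (which is exactly this, plus a 10%
case-cohort subsample) prints:

```
true log(HR) per allele = 0.4055

cohort Cox        beta_G = 0.3836  SE = 0.0278  p = 3.05e-43
cohort logistic   beta_G = 0.4258  SE = 0.0314  p = 5.40e-42
case-cohort Prentice Cox beta_G = 0.3459  SE = 0.0493  p = 2.23e-12
case-cohort logistic     beta_G = 0.3889  SE = 0.0503  p = 1.07e-14
```

Both Cox estimates scatter around the generating log(HR) = 0.405 (the Cox
model is unbiased for it), while the logistic log(OR)s sit systematically
higher — at 15% incidence with complete follow-up the odds ratio genuinely
exceeds the hazard ratio. The case-cohort SEs are larger because only ~12% of
the cohort is analysed, and the Prentice fit's SE is a robust sandwich that
accounts for the subcohort sampling.

The other example scripts cover cohort simulation and calibration
(`01_simulate_cohort.py`), a small power/bias grid (`03_power_grid.py`), and
the two-step scan on a 50-SNP panel (`04_two_step_scan.py`). The same
machinery is exposed as thin CLIs: `simulate-grid --config grid.yaml --out DIR`
and `two-step-scan --genotypes dosages.tsv --phenotypes pheno.tsv
--design case-cohort --filter-p 1e-4 --out scan.tsv` (genotypes as a
SNP-by-subject dosage matrix or a VCF).

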