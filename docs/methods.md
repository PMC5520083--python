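# Methods

## Data-generating process

Each simulated subject carries a baseline age A ~ Normal(56, 6²) years
(untruncated) and a genotype G ~ Binomial(2, RAF) — Hardy–Weinberg
proportions for a biallelic SNP under a multiplicative allelic model. Event
times are Weibull under proportional hazards,

    h(t | A, G) = λ v t^{v−1} exp(β_A A + β_G G),

sampled by the inverse-CDF transform T = [−log U / (λ e^{β_A A + β_G G})]^{1/v}
with U ~ Uniform(0, 1). Censoring C is independent of T and follows one of
three regimes over a 20-year horizon: **complete** (C = 20 exactly), **survey**
(C uniform on {5, 10, 15, 20}), **random** (C ~ Uniform(0, 20)). A subject is
a case iff T < C (strict; exact float ties are treated as censored, an event
of probability zero under continuous generation) and time in study is
min(T, C).

### Parameters and calibration

| parameter | meaning | default | why |
|---|---|---|---|
| `raf` | risk allele frequency | scenario | grid value, 0.05–0.95 |
| `hr` = e^{β_G} | per-allele hazard ratio | scenario | grid value, 1–2 |
| `incidence` | target P(T < C) | scenario | grid value, 0.05–0.15 |
| `beta_age` (β_A) | log HR per year of age | 0.08 | a typical age log-HR for coronary disease; nuisance once incidence is calibrated |
| `lam` (λ) | baseline Weibull scale | 5×10⁻⁵ /yr^v | puts a 56-year-old's 20-year baseline risk in a plausible range |
| `v` | Weibull shape | calibrated | see below |
| `max_follow_up` | administrative horizon | 20 y | study design |
| `alpha` | per-test type-I error | 0.05 | Wald test level |

λ and β_A are stand-ins: the quantity that drives power, bias and precision
in every comparison is the number of cases, and that is pinned by calibrating
the shape v so that the expected case fraction equals the target incidence.
Calibration computes P(T < C) by deterministic quadrature — 64-node
Gauss–Hermite over the age mixture, the exact 3-point genotype pmf, the exact
4-point survey mixture and 64-node Gauss–Legendre for the uniform censoring
density — and solves for v with Brent's method on the bracket [0.1, 10]
(incidence is monotone in v for horizons beyond one year). The root is found
to ~1e-12 in v; the nominal acceptance tolerance on achieved incidence is
±0.002. An unattainable target inside the bracket raises a calibration error
reporting the incidences achieved at both bracket ends.

**Primary vs secondary mode.** Primary calibration targets the incidence
*under the scenario's own censoring regime* (the case count is held fixed
across regimes, as when model choice is driven by the attained number of
cases). Secondary mode calibrates under complete follow-up and then applies
the survey/random censoring to those event times, holding the event-time
distribution fixed instead; realized case fractions are then below the
nominal target. Under complete follow-up the two modes coincide exactly
(deterministic quadrature, no Monte-Carlo estimator involved).

### Case-cohort sampling

The subcohort is a simple random sample without replacement of
round(fraction × n) subjects drawn without regard to case status; the
analysis set is the union of all cases and the subcohort. Rounding is to the
nearest integer (the grid fractions used here make it exact).

## Estimators

All three models are fitted by damped Newton–Raphson on the exact
log-(pseudo-)likelihood: full step, halved until the objective does not
decrease (so the log-likelihood is non-decreasing across iterations);
convergence when max|score| < 1e-8 or the relative log-likelihood change is
< 1e-10, with at most 50 iterations. Covariates are centred internally for
numerical stability (the reported estimates are invariant to this; the
logistic intercept is transformed back). A monotone likelihood — perfect
separation in the outcome or in the risk sets — is detected by a
scale-invariant runaway check (|β_j|·SD(x_j) > 20) and reported as
non-convergence rather than raised; a singular information matrix raises an
error naming the offending covariate.

**Cox (cohort).** Partial likelihood on the time-on-study scale. Risk-set
sums are suffix cumulative sums over the time-sorted data, so one Newton
iteration is O(n p²) after an O(n log n) sort. Tied event times use Efron's
correction by default (Breslow selectable); the two coincide on the tie-free
continuous data generated here. Standard errors come from the inverse
observed information; an optional sandwich variant aggregates per-subject
score residuals.

**Prentice-weighted Cox (case-cohort).** The Prentice (1986)
pseudo-likelihood: subcohort members contribute to risk sets over their whole
observed time (including their own failure); cases outside the subcohort
enter only the risk set of their own failure. The denominator at each failure
is therefore a suffix sum over the subcohort plus, for an outside case, its
own hazard term. Ties are handled Breslow-style within this pseudo-likelihood
(they have probability zero here). Reported standard errors are the robust
dfbeta sandwich I⁻¹(Σᵢ UᵢUᵢᵀ)I⁻¹ built from per-subject score residuals under
the pseudo-likelihood risk sets — for a subcohort member the usual
martingale-integral residual over (0, observed time]; for an outside case the
single-point residual (xᵢ − x̄(tᵢ))(1 − wᵢ/S₀(tᵢ)). When the subcohort is the
whole cohort the fit degenerates exactly to the unweighted Cox fit with the
full-cohort sandwich SE. Alternative case-cohort variance estimators
(Self–Prentice, Barlow) share the same point estimates and differ from the
dfbeta sandwich at O(1/n); the tests check agreement with a delete-one
jackknife.

**Logistic.** Maximum likelihood on case status, Newton/IRLS, intercept plus
covariates, follow-up time ignored. In case-cohort data the fitting set is
exactly the union of cases and subcohort non-cases (equivalently cases ∪
subcohort, each subject once). Standard errors are model-based: this
sampling design needs no robust correction for the logistic model.

Wald inference throughout: p = 2Φ(−|β̂/SE|).

## Experiment layer

For each scenario, every replicate simulates a fresh dataset and fits both
the Cox-type model and logistic regression to identical data. Summaries over
replicates: mean bias of the genotype coefficient against log(HR), mean of
the estimated SEs, power as the rejection fraction at α (the empirical type-I
error when HR = 1), and the Cox − logistic power difference. Replicates in
which either model fails to converge are dropped for both models, so the
comparison is always paired; the converged count is reported. Mean follow-up
and the achieved case fraction are computed over the full cohort of every
replicate.

Reproducibility: each scenario holds one master seed; per-replicate
generators are spawned from it (`SeedSequence.spawn`), so any single
replicate can be reproduced in isolation, and grid runs assign per-scenario
seeds up front so results are independent of the worker count. A grid run
writes formatted 4-decimal tables (one per design, rows grouped by censoring
regime and incidence), a full-precision machine CSV, a JSON manifest (config
echo, seeds, version, convergence diagnostics) and a plain-text log.

### Problem sizes

Replicate counts are configurable; the bundled acceptance script and
acceptance tests use 1,000 replicates per scenario (2,000 under the null)
rather than the 5,000 of a full study, with check tolerances widened
accordingly (3 binomial / Monte-Carlo standard errors at the reduced count).
Mean-SE and mean-bias summaries are far less noisy than power at these
counts; power differences are the noisiest quantity, which the widened
tolerances reflect.

## Two-step scan

Stage 1 fits logistic regression to every SNP (on the analysis set); stage 2
refits only SNPs with stage-1 p below the filter threshold using the
(Prentice-weighted) Cox model. The filter never modifies stage 2: a passing
SNP's Cox fit is identical to a direct single-SNP Cox fit on the same data,
and a threshold of 1 reproduces an exhaustive Cox scan. Subjects with missing
dosage are dropped per SNP; monomorphic SNPs are skipped with a warning;
fractional dosages in [0, 2] (imputed data) are accepted; extra covariates
pass through to both stages; no multiple-testing correction is applied inside
the scan — thresholds are caller policy. A filtered SNP whose Cox fit fails
to converge is reported with missing stage-2 fields and a flag.
`filter_sensitivity` estimates by simulation the rate at which SNPs an
exhaustive Cox scan would call at the overall threshold (e.g. 5×10⁻⁸) fail a
liberal logistic filter (e.g. 10⁻⁴); because the two Wald statistics are
computed from the same data and track each other closely, this miss rate is
essentially zero at conventional thresholds.

Genotype input is a delimited SNP-by-subject dosage matrix or a VCF (DS
FORMAT field when present, else the ALT-allele count from GT; missing
genotypes become NaN).

## What the generator does and does not emulate

It reproduces the statistical structure that drives the Cox/logistic
comparison: a common-disease incidence over a 20-year horizon, an age-graded
baseline hazard, Hardy–Weinberg genotypes with multiplicative allelic
effects, and independent censoring of three qualitatively different shapes.
It does **not** simulate confounding, gene–environment interaction,
non-proportional hazards, competing risks, linkage disequilibrium between
SNPs, population structure, genotyping error or missingness mechanisms —
passing tests therefore speak to model behaviour under a clean
proportional-hazards world, not to robustness against those features of real
data. Real-cohort nuisance values of λ and β_A would shift the age
composition of cases slightly but are absorbed, to first order, by the
incidence calibration.

## Known limitations

* Only Prentice weighting is implemented for case-cohort Cox fits (no
  Barlow or Self–Prentice weighting options); only the dfbeta sandwich
  variance is offered.
* The survey censoring times scale with `max_follow_up` as quarters of the
  horizon; arbitrary survey schedules are not configurable.
* The scan loops over SNPs in Python; it is intended for panels up to ~10⁴
  SNPs, not genome-wide matrices.
* `filter_sensitivity` treats additional SNPs as independent null markers;
  it does not model correlated panels.
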