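"""Replicate simulations over a scenario grid and the bias/precision/power summaries.

Each replicate simulates one dataset and analyses it with both a Cox-type model
(unweighted Cox for cohorts, Prentice-weighted Cox with robust SEs for
case-cohorts) and logistic regression, on identical data. A scenario summary
aggregates the genotype coefficient across replicates:

* mean bias  = mean(beta_hat) - log(HR)
* mean SE    = mean of the estimated standard errors
* power      = fraction of replicates with two-sided Wald p < alpha
               (the empirical type-I error when HR = 1)
* power diff = power(Cox) - power(logistic)

Replicates where either model fails to converge are dropped for both models, so
the power comparison is always on identical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cohort import (
    CohortColumns,
    Scenario,
    WeibullParams,
    calibrate_params,
    sample_case_cohort,
    simulate_cohort,
)
from .estimators import FitResult, cox_fit, logistic_fit, prentice_cox_fit

__all__ = [
    "ReplicateResult",
    "ScenarioSummary",
    "run_grid",
    "run_replicate",
    "run_scenario",
    "summaries_to_frame",
    "summarize",
]

GENOTYPE = CohortColumns.GENOTYPE
COVARIATES = (CohortColumns.GENOTYPE, CohortColumns.AGE)


@dataclass
class ReplicateResult:
    """Both model fits for one simulated dataset, plus full-cohort diagnostics."""

    cox: FitResult
    logistic: FitResult
    mean_follow_up: float
    case_fraction: float

    @property
    def converged(self) -> bool:
        return self.cox.converged and self.logistic.converged


def run_replicate(
    scenario: Scenario, params: WeibullParams, replicate_seed
) -> ReplicateResult:
    """Simulate one dataset under the scenario and fit both models to it."""
    rng = np.random.default_rng(replicate_seed)
    cohort = simulate_cohort(scenario, params, rng)
    if scenario.design == "case_cohort":
        data = sample_case_cohort(cohort, scenario.sampling_fraction, rng)
        cox_res = prentice_cox_fit(data, covariates=COVARIATES)
    else:
        data = cohort
        cox_res = cox_fit(cohort, covariates=COVARIATES)
    log_res = logistic_fit(data, covariates=COVARIATES)
    return ReplicateResult(
        cox=cox_res,
        logistic=log_res,
        mean_follow_up=float(cohort[CohortColumns.OBSERVED_TIME].mean()),
        case_fraction=float(cohort[CohortColumns.IS_CASE].mean()),
    )


@dataclass
class ScenarioSummary:
    """Aggregate of one scenario's replicates — one row of the results tables."""

    scenario: Scenario
    cox_mean_bias: float
    cox_mean_se: float
    cox_power: float
    logistic_mean_bias: float
    logistic_mean_se: float
    logistic_power: float
    power_diff: float
    n_converged: int
    n_replicates: int
    mean_follow_up: float
    achieved_incidence: float

    def to_row(self) -> dict:
        s = self.scenario
        return {
            "design": s.design,
            "censoring": s.censoring,
            "n_cohort": s.n_cohort,
            "sampling_fraction": s.sampling_fraction,
            "raf": s.raf,
            "incidence": s.incidence,
            "true_hr": s.hr,
            "cox_mean_bias": self.cox_mean_bias,
            "cox_mean_se": self.cox_mean_se,
            "cox_power": self.cox_power,
            "logistic_mean_bias": self.logistic_mean_bias,
            "logistic_mean_se": self.logistic_mean_se,
            "logistic_power": self.logistic_power,
            "power_diff": self.power_diff,
            "n_converged": self.n_converged,
            "n_replicates": self.n_replicates,
            "mean_follow_up": self.mean_follow_up,
            "achieved_incidence": self.achieved_incidence,
        }


def summarize(scenario: Scenario, results: Sequence[ReplicateResult]) -> ScenarioSummary:
    """Aggregate replicate fits; drops replicates (pairwise) that did not converge."""
    kept = [r for r in results if r.converged]
    if not kept:
        raise ValueError("no converged replicates to summarize")
    log_hr = float(np.log(scenario.hr))
    cox_beta = np.array([r.cox.estimates[GENOTYPE] for r in kept])
    cox_se = np.array([r.cox.se[GENOTYPE] for r in kept])
    cox_p = np.array([r.cox.p_value[GENOTYPE] for r in kept])
    log_beta = np.array([r.logistic.estimates[GENOTYPE] for r in kept])
    log_se = np.array([r.logistic.se[GENOTYPE] for r in kept])
    log_p = np.array([r.logistic.p_value[GENOTYPE] for r in kept])
    cox_power = float(np.mean(cox_p < scenario.alpha))
    log_power = float(np.mean(log_p < scenario.alpha))
    return ScenarioSummary(
        scenario=scenario,
        cox_mean_bias=float(cox_beta.mean() - log_hr),
        cox_mean_se=float(cox_se.mean()),
        cox_power=cox_power,
        logistic_mean_bias=float(log_beta.mean() - log_hr),
        logistic_mean_se=float(log_se.mean()),
        logistic_power=log_power,
        power_diff=cox_power - log_power,
        n_converged=len(kept),
        n_replicates=len(results),
        mean_follow_up=float(np.mean([r.mean_follow_up for r in results])),
        achieved_incidence=float(np.mean([r.case_fraction for r in results])),
    )


def replicate_seeds(scenario: Scenario) -> list[np.random.SeedSequence]:
    """Deterministic per-replicate seeds spawned from the scenario master seed."""
    return np.random.SeedSequence(scenario.seed).spawn(scenario.n_replicates)


def run_scenario(
    scenario: Scenario,
    lam: float | None = None,
    beta_age: float | None = None,
    return_replicates: bool = False,
):
    """Calibrate, run all replicates of one scenario, and summarize.

    Any replicate is reproducible in isolation: replicate ``i`` uses the i-th
    seed spawned from ``SeedSequence(scenario.seed)``.
    """
    kwargs = {}
    if lam is not None:
        kwargs["lam"] = lam
    if beta_age is not None:
        kwargs["beta_age"] = beta_age
    params = calibrate_params(scenario, **kwargs)
    results = [run_replicate(scenario, params, s) for s in replicate_seeds(scenario)]
    summary = summarize(scenario, results)
    if return_replicates:
        return summary, results
    return summary


def summaries_to_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


def run_grid(config, out_dir=None, n_jobs: int = 1):
    """Expand a grid config into scenarios and run each one.

    Per-scenario seeds are assigned up front from the master seed, so results
    are bit-identical regardless of the worker count. Calibration failures are
    reported per scenario and the grid continues. If ``out_dir`` is given,
    tables, a manifest and a log are written there.
    """
    from .config import GridConfig, expand_grid
    from .report import write_outputs

    if not isinstance(config, GridConfig):
        raise TypeError("config must be a GridConfig (see survgwas.config.load_config)")
    scenarios = expand_grid(config)

    def one(scn: Scenario):
        try:
            return run_scenario(scn, lam=config.lam, beta_age=config.beta_age), None
        except Exception as exc:  # calibration or degenerate-fit failure
            return None, f"{scn.design}/{scn.censoring} hr={scn.hr} incidence={scn.incidence}: {exc}"

    outputs = Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in scenarios)
    summaries = [s for s, _ in outputs if s is not None]
    failures = [msg for _, msg in outputs if msg is not None]
    frame = summaries_to_frame(summaries) if summaries else pd.DataFrame()
    if out_dir is not None:
        write_outputs(config, scenarios, summaries, failures, out_dir)
    return frame, failures
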