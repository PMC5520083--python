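"""Two-step association scan: logistic screen, Cox refit of sub-threshold SNPs.

Fitting every SNP with (weighted) Cox regression is far more expensive than
with logistic regression, so the scan first screens all SNPs by logistic
regression at a liberal threshold (e.g. 1e-4 when the overall genome-wide
threshold is 5e-8) and then refits only the survivors with Cox regression
(Prentice-weighted in case-cohort data) to obtain unbiased log hazard ratios
and final p-values. The filter never alters the stage-2 computation: a passing
SNP's Cox fit is identical to a direct single-SNP Cox fit on the same data.

``filter_sensitivity`` quantifies by simulation the rate at which SNPs that an
exhaustive Cox scan would call at the overall threshold are lost to the
logistic filter (the two-step miss rate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    CohortColumns,
    Scenario,
    calibrate_params,
    sample_case_cohort,
    simulate_cohort,
)
from .estimators import cox_fit, logistic_fit, prentice_cox_fit

__all__ = [
    "FilterSensitivity",
    "filter_sensitivity",
    "read_dosage_matrix",
    "read_vcf_dosages",
    "two_step_scan",
]

log = logging.getLogger("survgwas")

GENOTYPE = CohortColumns.GENOTYPE

_SCAN_COLUMNS = [
    "snp_id",
    "n_used",
    "beta_logistic",
    "se_logistic",
    "p_logistic",
    "passed_filter",
    "beta_cox",
    "se_cox",
    "p_cox",
    "cox_converged",
]


def read_dosage_matrix(path, sep: str | None = None) -> pd.DataFrame:
    """Read a SNPs-by-subjects dosage matrix from delimited text.

    First column: SNP identifier; header row: subject IDs. Dosages may be hard
    calls {0,1,2} or fractional in [0,2]; empty/NA cells are missing.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python" if sep is None else "c")
    df.columns = df.columns.astype(str)
    return df.astype(float)


def read_vcf_dosages(path) -> pd.DataFrame:
    """Read per-sample dosages from a VCF: the DS FORMAT field when present,
    otherwise the count of ALT alleles in GT. Missing genotypes become NaN."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = [str(s) for s in vcf.samples]
    rows, ids = [], []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, float).reshape(-1)
            dose = np.where(dose < 0, np.nan, dose)
        else:
            dose = np.empty(len(samples))
            for i, gt in enumerate(var.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                dose[i] = np.nan if not alleles else float(sum(1 for a in alleles if a > 0))
        rows.append(dose)
        ids.append(snp_id)
    return pd.DataFrame(rows, index=ids, columns=samples)


def _stage2_fit(data, design, covariates):
    if design == "case_cohort":
        return prentice_cox_fit(data, covariates=covariates)
    return cox_fit(data, covariates=covariates)


def two_step_scan(
    genotypes: pd.DataFrame,
    phenotype: pd.DataFrame,
    design: str = "cohort",
    filter_threshold: float = 1e-4,
    covariates: tuple[str, ...] = (CohortColumns.AGE,),
) -> pd.DataFrame:
    """Screen every SNP with logistic regression; refit the survivors with Cox.

    Parameters
    ----------
    genotypes : DataFrame
        SNPs x subjects dosage matrix; columns must match ``phenotype`` IDs.
    phenotype : DataFrame
        One row per subject with the cohort schema (observed_time, is_case,
        subcohort flags for case-cohort data, and any extra covariates); the
        ``id`` column, or the index, keys the genotype columns.
    design : {"cohort", "case_cohort"}
        Chooses unweighted vs Prentice-weighted Cox for stage 2. Logistic fits
        always use the analysis set (cases + subcohort non-cases for
        case-cohort data; everyone for cohorts).
    filter_threshold : float
        Stage-1 p-value threshold; SNPs with logistic p below it are refitted.

    Returns a per-SNP frame with both stages' estimates, SEs and p-values;
    ``beta_cox``/``se_cox``/``p_cox`` are NaN for SNPs that did not pass the
    filter, and ``p_cox`` is the final p-value for those that did. Subjects
    with missing dosage are dropped per SNP; monomorphic SNPs are skipped with
    a warning.
    """
    if design not in ("cohort", "case_cohort"):
        raise ValueError(f"design must be 'cohort' or 'case_cohort', got {design!r}")
    if not 0 <= filter_threshold <= 1:
        raise ValueError("filter_threshold must lie in [0, 1]")
    pheno = phenotype.copy()
    if CohortColumns.ID in pheno.columns:
        pheno = pheno.set_index(CohortColumns.ID)
    pheno.index = pheno.index.astype(str)
    geno = genotypes.copy()
    geno.columns = geno.columns.astype(str)
    if set(geno.columns) != set(pheno.index) or geno.shape[1] != len(pheno):
        raise ValueError("genotype columns do not match phenotype subject IDs")
    geno = geno.loc[:, pheno.index]
    fit_covariates = (GENOTYPE, *covariates)

    records = []
    for snp_id, dose in geno.iterrows():
        d = dose.to_numpy(float)
        valid = ~np.isnan(d)
        if valid.sum() == 0 or np.nanmax(d) == np.nanmin(d):
            msg = f"SNP {snp_id} is monomorphic or all-missing; skipped"
            warnings.warn(msg, stacklevel=2)
            log.warning(msg)
            continue
        data = pheno.loc[valid].copy()
        data[GENOTYPE] = d[valid]
        log_fit = logistic_fit(data, covariates=fit_covariates)
        p_log = float(log_fit.p_value[GENOTYPE])
        passed = bool(log_fit.converged and p_log < filter_threshold)
        rec = {
            "snp_id": snp_id,
            "n_used": int(valid.sum()),
            "beta_logistic": float(log_fit.estimates[GENOTYPE]),
            "se_logistic": float(log_fit.se[GENOTYPE]),
            "p_logistic": p_log,
            "passed_filter": passed,
            "beta_cox": np.nan,
            "se_cox": np.nan,
            "p_cox": np.nan,
            "cox_converged": pd.NA,
        }
        if passed:
            cox_res = _stage2_fit(data, design, fit_covariates)
            rec["cox_converged"] = bool(cox_res.converged)
            if cox_res.converged:
                rec["beta_cox"] = float(cox_res.estimates[GENOTYPE])
                rec["se_cox"] = float(cox_res.se[GENOTYPE])
                rec["p_cox"] = float(cox_res.p_value[GENOTYPE])
            else:
                log.warning("SNP %s passed the filter but the Cox fit did not converge", snp_id)
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=_SCAN_COLUMNS)


@dataclass
class FilterSensitivity:
    """Simulation estimate of the two-step miss rate.

    ``miss_rate`` is the fraction of SNP-replicate pairs significant under an
    exhaustive Cox scan at the overall threshold whose logistic p-value failed
    the filter; 0.0 (with ``n_cox_hits == 0``) when there were no Cox hits.
    """

    miss_rate: float
    n_cox_hits: int
    n_missed: int
    n_snp_replicates: int


def filter_sensitivity(
    n_snps: int,
    scenario: Scenario,
    filter_threshold: float,
    overall_threshold: float,
    n_reps: int,
    rng: np.random.Generator,
) -> FilterSensitivity:
    """Estimate how often the logistic filter loses an exhaustive-Cox hit.

    Each replicate simulates a dataset whose phenotype is driven by the
    scenario's (single) SNP; when ``n_snps > 1`` the remaining SNPs are
    independent null markers at the same allele frequency. Every SNP is fitted
    with both models and hits are counted at the overall Cox threshold.
    """
    if not filter_threshold > overall_threshold:
        raise ValueError("filter_threshold must exceed overall_threshold")
    if n_snps < 1 or n_reps < 1:
        raise ValueError("n_snps and n_reps must be >= 1")
    params = calibrate_params(scenario)
    covars = (GENOTYPE, CohortColumns.AGE)
    n_hits = n_missed = n_pairs = 0
    for _ in range(n_reps):
        cohort = simulate_cohort(scenario, params, rng)
        data = (
            sample_case_cohort(cohort, scenario.sampling_fraction, rng)
            if scenario.design == "case_cohort"
            else cohort
        )
        for s in range(n_snps):
            if s > 0:  # null marker: replace the genotype with an independent draw
                data = data.assign(
                    **{GENOTYPE: rng.binomial(2, scenario.raf, size=len(data))}
                )
            if data[GENOTYPE].nunique() < 2:
                continue
            cox_res = _stage2_fit(data, scenario.design, covars)
            log_res = logistic_fit(data, covariates=covars)
            if not (cox_res.converged and log_res.converged):
                continue
            n_pairs += 1
            if cox_res.p_value[GENOTYPE] < overall_threshold:
                n_hits += 1
                if log_res.p_value[GENOTYPE] >= filter_threshold:
                    n_missed += 1
    miss_rate = n_missed / n_hits if n_hits else 0.0
    return FilterSensitivity(
        miss_rate=miss_rate,
        n_cox_hits=n_hits,
        n_missed=n_missed,
        n_snp_replicates=n_pairs,
    )
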