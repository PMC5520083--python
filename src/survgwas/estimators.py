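"""Maximum-(partial-)likelihood estimators for the cohort / case-cohort comparison.

Three models, all fitted from scratch by Newton-Raphson with step-halving:

* ``cox_fit`` — Cox proportional-hazards partial likelihood on the
  time-on-study scale, Efron (default) or Breslow tie handling, model-based
  standard errors from the inverse observed information.
* ``prentice_cox_fit`` — the Prentice (1986) pseudo-likelihood for case-cohort
  data: subcohort members are at risk over their whole observed time; cases
  outside the subcohort enter the risk set only at (just before) their own
  failure. Standard errors are robust sandwich estimates built from per-subject
  score residuals (dfbeta aggregation), accounting for subcohort sampling.
* ``logistic_fit`` — maximum-likelihood logistic regression of case status on
  the covariates, model-based standard errors, follow-up time ignored. On
  case-cohort data the fitting set is the union of cases and subcohort
  non-cases.

Convergence: max |score| < 1e-8 or relative log-likelihood change < 1e-10,
at most 50 iterations. A monotone (separated) likelihood is reported as
non-convergence, not raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortColumns, read_cohort

__all__ = [
    "FitResult",
    "SingularInformationError",
    "cox_fit",
    "logistic_fit",
    "prentice_cox_fit",
    "wald_test",
]

MAX_ITER = 50
SCORE_TOL = 1e-8
LOGLIK_TOL = 1e-10


class SingularInformationError(np.linalg.LinAlgError):
    """Raised when the information matrix is singular (e.g. collinear covariates)."""


@dataclass
class FitResult:
    """One fitted model: estimates, uncertainties and Wald inference.

    ``se`` is model-based (inverse information) for ``cox`` and ``logistic``,
    and the robust sandwich for ``prentice_cox``. ``covariance`` is on the same
    scale as ``se``.
    """

    model: str
    estimates: pd.Series
    se: pd.Series
    wald_z: pd.Series = field(init=False)
    p_value: pd.Series = field(init=False)
    converged: bool = True
    n_iterations: int = 0
    loglik: float = np.nan
    n_obs: int = 0
    n_events: int = 0
    covariance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        with np.errstate(divide="ignore", invalid="ignore"):
            self.wald_z = self.estimates / self.se
        self.p_value = pd.Series(
            2.0 * stats.norm.sf(np.abs(self.wald_z.to_numpy())), index=self.estimates.index
        )


def wald_test(fit: FitResult, covariate: str) -> float:
    """Two-sided Wald p-value for one coefficient, p = 2*Phi(-|beta/SE|)."""
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    se = float(fit.se[covariate])
    if not se > 0:
        raise ValueError(f"standard error for {covariate!r} is not positive: {se}")
    z = float(fit.estimates[covariate]) / se
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Newton machinery


def _newton(
    fun: Callable[[np.ndarray], tuple[float, np.ndarray, np.ndarray]],
    beta0: np.ndarray,
    names: Sequence[str],
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, float, np.ndarray, int, bool]:
    """Maximise a concave objective; ``fun`` returns (loglik, score, information).

    Step-halving guarantees the log-likelihood is non-decreasing across
    iterations. Returns (beta, loglik, information, n_iter, converged).
    """
    beta = np.asarray(beta0, dtype=float).copy()
    ll, score, info = fun(beta)
    converged = bool(np.max(np.abs(score)) < SCORE_TOL)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if converged:
            n_iter -= 1
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            bad = _most_collinear(info, names)
            raise SingularInformationError(
                f"information matrix is singular; check covariate {bad!r}"
            ) from None
        new_beta = beta + step
        new_ll, new_score, new_info = fun(new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 40:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_score, new_info = fun(new_beta)
            halvings += 1
        rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score)) < SCORE_TOL or rel_change < LOGLIK_TOL:
            converged = True
            break
    return beta, ll, info, n_iter, converged


def _most_collinear(info: np.ndarray, names: Sequence[str]) -> str:
    diag = np.abs(np.diag(info))
    return str(names[int(np.argmin(diag))])


def _diverged(beta: np.ndarray, X: np.ndarray) -> bool:
    """Monotone-likelihood heuristic: a coefficient spanning >20 units of linear
    predictor across one covariate SD means the likelihood has no interior
    maximum (perfect separation in the risk sets / outcome)."""
    sd = X.std(axis=0)
    return bool(np.any(np.abs(beta[-len(sd):]) * sd > 20.0))


def _suffix_cumsums(w: np.ndarray, X: np.ndarray):
    """Sums over {j : j >= k} of w, w*x and w*x x^T, indexed by array position."""
    c0 = np.cumsum(w[::-1])[::-1]
    c1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    xx = X[:, :, None] * X[:, None, :]
    c2 = np.cumsum((w[:, None, None] * xx)[::-1], axis=0)[::-1]
    return c0, c1, c2


# ---------------------------------------------------------------------------
# Cox partial likelihood (full cohort)


def _prepare_frame(data, covariates) -> pd.DataFrame:
    if isinstance(data, (str, Path)):
        data = read_cohort(data)
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValueError(f"covariates not found in data: {missing}")
    return data


def _check_nonconstant(X: np.ndarray, names: Sequence[str]) -> None:
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"covariate {name!r} is constant in the analysis set")


def cox_fit(
    data,
    covariates: Sequence[str] = ("genotype", "age"),
    ties: str = "efron",
    robust: bool = False,
) -> FitResult:
    """Fit the Cox model on the time-on-study scale to a full cohort.

    Parameters
    ----------
    data : DataFrame or path
        Needs ``observed_time`` and ``is_case`` columns plus the covariates.
    ties : {"efron", "breslow"}
        Tie-handling in the partial likelihood; identical on tie-free data.
    robust : bool
        If True, report sandwich standard errors built from score residuals
        instead of the inverse observed information.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    data = _prepare_frame(data, covariates)
    covariates = list(covariates)
    time = data[CohortColumns.OBSERVED_TIME].to_numpy(float)
    event = data[CohortColumns.IS_CASE].to_numpy(bool)
    X = data.loc[:, covariates].to_numpy(float)
    if event.sum() < 1:
        raise ValueError("Cox fit requires at least one case")
    _check_nonconstant(X[_at_risk_any(time, event)], covariates)

    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    Xc = X - X.mean(axis=0)
    Xs = Xc[order]
    n, p = Xs.shape

    e_pos = np.flatnonzero(d)
    te = t[e_pos]
    Xe = Xs[e_pos]
    uniq, first_e, inv, counts = np.unique(te, return_index=True, return_inverse=True, return_counts=True)
    m = counts[inv].astype(float)
    rank_in_tie = np.arange(len(te)) - first_e[inv]
    frac = rank_in_tie / m if ties == "efron" else np.zeros_like(m)
    has_ties = bool(np.any(counts > 1))
    start = np.searchsorted(t, uniq, side="left")[inv]  # first index at risk per event

    def fun(beta: np.ndarray):
        eta = Xs @ beta
        shift = eta.max()
        w = np.exp(eta - shift)
        c0, c1, c2 = _suffix_cumsums(w, Xs)
        S0 = c0[start]
        S1 = c1[start]
        S2 = c2[start]
        if has_ties and ties == "efron":
            we = w[e_pos]
            T0 = np.add.reduceat(we, first_e)[inv]
            T1 = np.add.reduceat(we[:, None] * Xe, first_e, axis=0)[inv]
            T2 = np.add.reduceat(
                we[:, None, None] * (Xe[:, :, None] * Xe[:, None, :]), first_e, axis=0
            )[inv]
            S0 = S0 - frac * T0
            S1 = S1 - frac[:, None] * T1
            S2 = S2 - frac[:, None, None] * T2
        ll = float((eta[e_pos] - shift).sum() - np.log(S0).sum())
        xbar = S1 / S0[:, None]
        score = (Xe - xbar).sum(axis=0)
        info = (S2 / S0[:, None, None]).sum(axis=0) - xbar.T @ xbar
        return ll, score, info

    beta, ll, info, n_iter, converged = _newton(fun, np.zeros(p), covariates)
    converged = converged and not _diverged(beta, Xs)
    cov = _safe_inverse(info, covariates)
    if robust:
        resid = _cox_score_residuals(beta, t, d, Xs)
        cov = cov @ (resid.T @ resid) @ cov
    se = np.sqrt(np.diag(cov))
    idx = pd.Index(covariates)
    return FitResult(
        model="cox",
        estimates=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        converged=converged,
        n_iterations=n_iter,
        loglik=ll,
        n_obs=n,
        n_events=int(d.sum()),
        covariance=pd.DataFrame(cov, index=idx, columns=idx),
    )


def _at_risk_any(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    # Subjects at risk at the first event time (used only for the constancy check).
    if not event.any():
        return np.ones_like(event)
    return time >= time[event].min()


def _safe_inverse(info: np.ndarray, names: Sequence[str]) -> np.ndarray:
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise SingularInformationError(
            f"information matrix is singular; check covariate {_most_collinear(info, names)!r}"
        ) from None


def _cox_score_residuals(beta, t, d, Xs) -> np.ndarray:
    """Per-subject score residuals of the full-cohort Cox fit (Breslow hazard).

    Inputs are sorted ascending by time; returns residuals in that order.
    """
    eta = Xs @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    c0, c1, _ = _suffix_cumsums(w, Xs)
    e_pos = np.flatnonzero(d)
    te = t[e_pos]
    uniq, first_e, inv, counts = np.unique(
        te, return_index=True, return_inverse=True, return_counts=True
    )
    start_u = np.searchsorted(t, uniq, side="left")
    S0u = c0[start_u]
    S1u = c1[start_u]
    xbar_u = S1u / S0u[:, None]
    dL_u = counts / S0u  # Breslow hazard increments (scaled by e^shift, cancels below)
    cumA = np.concatenate([[0.0], np.cumsum(dL_u)])
    cumB = np.concatenate([[np.zeros(Xs.shape[1])], np.cumsum(dL_u[:, None] * xbar_u, axis=0)])
    k = np.searchsorted(uniq, t, side="right")
    resid = -w[:, None] * (Xs * cumA[k][:, None] - cumB[k])
    resid[e_pos] += Xs[e_pos] - xbar_u[inv]
    return resid


# ---------------------------------------------------------------------------
# Prentice pseudo-likelihood (case-cohort)


def prentice_cox_fit(
    data, covariates: Sequence[str] = ("genotype", "age")
) -> FitResult:
    """Fit the Prentice-weighted Cox model to a case-cohort dataset.

    Risk sets follow Prentice (1986): a subcohort member is at risk over
    (0, observed_time]; a case outside the subcohort is at risk only at its own
    failure time. Ties are handled Breslow-style (simulated times are
    continuous, so ties have probability zero). Reported standard errors are
    the dfbeta sandwich, robust to the subcohort sampling process.
    """
    data = _prepare_frame(data, covariates)
    covariates = list(covariates)
    for col in (CohortColumns.IN_SUBCOHORT, CohortColumns.IN_ANALYSIS):
        if col not in data.columns:
            raise ValueError(f"case-cohort fit requires the {col!r} column")
    df = data.loc[data[CohortColumns.IN_ANALYSIS].to_numpy(bool)]
    time = df[CohortColumns.OBSERVED_TIME].to_numpy(float)
    event = df[CohortColumns.IS_CASE].to_numpy(bool)
    insc = df[CohortColumns.IN_SUBCOHORT].to_numpy(bool)
    X = df.loc[:, covariates].to_numpy(float)
    if event.sum() < 1:
        raise ValueError("case-cohort fit requires at least one case")
    _check_nonconstant(X, covariates)

    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    sc = insc[order]
    Xs = (X - X.mean(axis=0))[order]
    n, p = Xs.shape

    sc_pos = np.flatnonzero(sc)
    t_sc = t[sc_pos]
    X_sc = Xs[sc_pos]
    e_pos = np.flatnonzero(d)
    te = t[e_pos]
    Xe = Xs[e_pos]
    ext = ~sc[e_pos]  # event by a case outside the subcohort
    # first subcohort index at risk for each event (t_sc is sorted)
    pos = np.searchsorted(t_sc, te, side="left")

    def parts(beta: np.ndarray):
        eta = Xs @ beta
        shift = eta.max()
        w = np.exp(eta - shift)
        w_sc = w[sc_pos]
        c0 = np.concatenate([np.cumsum(w_sc[::-1])[::-1], [0.0]])
        c1 = np.vstack(
            [np.cumsum((w_sc[:, None] * X_sc)[::-1], axis=0)[::-1], np.zeros(p)]
        )
        xx = X_sc[:, :, None] * X_sc[:, None, :]
        c2 = np.concatenate(
            [np.cumsum((w_sc[:, None, None] * xx)[::-1], axis=0)[::-1], np.zeros((1, p, p))]
        )
        we = w[e_pos]
        S0 = c0[pos] + ext * we
        S1 = c1[pos] + (ext * we)[:, None] * Xe
        S2 = c2[pos] + (ext * we)[:, None, None] * (Xe[:, :, None] * Xe[:, None, :])
        return eta, shift, w, we, S0, S1, S2

    def fun(beta: np.ndarray):
        eta, shift, _, _, S0, S1, S2 = parts(beta)
        ll = float((eta[e_pos] - shift).sum() - np.log(S0).sum())
        xbar = S1 / S0[:, None]
        score = (Xe - xbar).sum(axis=0)
        info = (S2 / S0[:, None, None]).sum(axis=0) - xbar.T @ xbar
        return ll, score, info

    beta, ll, info, n_iter, converged = _newton(fun, np.zeros(p), covariates)
    converged = converged and not _diverged(beta, Xs)

    # dfbeta sandwich: score residuals under the pseudo-likelihood risk sets
    _, _, w, we, S0, S1, _ = parts(beta)
    xbar_e = S1 / S0[:, None]
    dL = 1.0 / S0  # pseudo-hazard increments (e^shift scaling cancels against w)
    cumA = np.concatenate([[0.0], np.cumsum(dL)])
    cumB = np.vstack([np.zeros(p), np.cumsum(dL[:, None] * xbar_e, axis=0)])
    k = np.searchsorted(te, t, side="right")
    resid = np.zeros((n, p))
    # subcohort members: at risk over (0, observed_time]
    resid[sc_pos] = -w[sc_pos, None] * (
        Xs[sc_pos] * cumA[k[sc_pos]][:, None] - cumB[k[sc_pos]]
    )
    resid[e_pos] += (Xe - xbar_e) * np.where(ext, (1.0 - we / S0), 1.0)[:, None]
    info_inv = _safe_inverse(info, covariates)
    cov = info_inv @ (resid.T @ resid) @ info_inv
    se = np.sqrt(np.diag(cov))
    idx = pd.Index(covariates)
    return FitResult(
        model="prentice_cox",
        estimates=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        converged=converged,
        n_iterations=n_iter,
        loglik=ll,
        n_obs=n,
        n_events=int(d.sum()),
        covariance=pd.DataFrame(cov, index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# Logistic regression


def logistic_fit(
    data, covariates: Sequence[str] = ("genotype", "age")
) -> FitResult:
    """Maximum-likelihood logistic regression of case status on the covariates.

    Follow-up time is ignored. If the frame carries an ``in_analysis`` flag
    (case-cohort data) the fitting set is restricted to it — i.e. the union of
    all cases and the subcohort, which is exactly {cases} U {subcohort
    non-cases}. Standard errors are model-based (no robust correction is
    needed for this design).
    """
    data = _prepare_frame(data, covariates)
    covariates = list(covariates)
    if CohortColumns.IN_ANALYSIS in data.columns:
        data = data.loc[data[CohortColumns.IN_ANALYSIS].to_numpy(bool)]
    y = data[CohortColumns.IS_CASE].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("logistic fit requires both cases and non-cases")
    X = data.loc[:, covariates].to_numpy(float)
    _check_nonconstant(X, covariates)
    means = X.mean(axis=0)
    design = np.column_stack([np.ones(len(y)), X - means])
    names = ["intercept", *covariates]
    n, p = design.shape

    def fun(beta: np.ndarray):
        eta = design @ beta
        # log-likelihood via log1p for numerical stability at large |eta|
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = design.T @ (y - mu)
        wdiag = mu * (1.0 - mu)
        info = (design * wdiag[:, None]).T @ design
        return ll, score, info

    beta0 = np.zeros(p)
    ybar = y.mean()
    beta0[0] = np.log(ybar / (1.0 - ybar))
    beta, ll, info, n_iter, converged = _newton(fun, beta0, names)
    converged = converged and not _diverged(beta, design[:, 1:])
    cov = _safe_inverse(info, names)
    # undo the centering: only the intercept changes
    beta_out = beta.copy()
    beta_out[0] = beta[0] - means @ beta[1:]
    A = np.eye(p)
    A[0, 1:] = -means
    cov_out = A @ cov @ A.T
    se = np.sqrt(np.diag(cov_out))
    idx = pd.Index(names)
    return FitResult(
        model="logistic",
        estimates=pd.Series(beta_out, index=idx),
        se=pd.Series(se, index=idx),
        converged=converged,
        n_iterations=n_iter,
        loglik=ll,
        n_obs=n,
        n_events=int(y.sum()),
        covariance=pd.DataFrame(cov_out, index=idx, columns=idx),
    )
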