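"""Provider-profiling reliability: signal-to-noise for each indicator.

Reliability asks how confidently one provider's indicator value can be
distinguished from another's.  The *noise* is the sampling variance of a
proportion, p(1-p)/n_j, at each provider's caseload n_j; the *signal* is
the between-provider variance of true performance, estimated as the
random-intercept variance tau^2 of a hierarchical logistic model with the
patient-level indicator value as outcome, case-mix covariates (age class,
sex, stage, Charlson class) as first-level predictors, and provider as
the grouping level.

tau^2 lives on the log-odds scale while the noise is on the probability
scale; by default the signal is converted with the delta method,
tau_p^2 = tau^2 * [p(1-p)]^2, making the ratio dimensionally coherent.
The naive unconverted ratio is available as ``scale='logit'``.
Reliability is reported in percent; 70% is the conventional adequacy
cut-off.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from lungqi.errors import ConvergenceError

RELIABILITY_CUTOFF_PCT = 70.0
CASEMIX_COVARIATES = ("age_stratum", "sex", "stage_group", "charlson_class")


def _design_matrix(df: pd.DataFrame, covariates: Iterable[str]) -> np.ndarray:
    cols = [c for c in covariates if c in df.columns]
    if not cols:
        return np.ones((len(df), 1))
    dummies = pd.get_dummies(
        df[cols].astype(object).where(df[cols].notna(), "missing"),
        drop_first=True,
        dtype=float,
    )
    return np.column_stack([np.ones(len(df)), dummies.to_numpy()])


def fit_hierarchical(
    outcomes: pd.DataFrame,
    covariates: Iterable[str] = CASEMIX_COVARIATES,
    n_quadrature: int = 25,
    maxiter: int = 500,
) -> dict:
    """Random-intercept logistic regression by Gauss-Hermite quadrature ML.

    ``outcomes`` needs columns ``outcome`` (binary), ``provider`` and any
    case-mix covariate columns.  The marginal likelihood integrates the
    provider intercepts out with ``n_quadrature`` Hermite nodes and is
    maximised over the fixed effects and log of the random-intercept SD.

    Returns ``{'tau2', 'beta', 'sigma', 'converged', 'trace', 'loglik'}``;
    tau^2 is floored at zero by the parametrisation.  Raises on fewer than
    two providers or on optimiser failure (with the iteration trace).
    """
    df = outcomes.dropna(subset=["outcome", "provider"]).reset_index(drop=True)
    providers = df["provider"].astype(str)
    if providers.nunique() < 2:
        raise ValueError("hierarchical model needs at least two providers")
    y = df["outcome"].to_numpy(dtype=float)
    X = _design_matrix(df, covariates)
    group_codes, _ = pd.factorize(providers, sort=True)
    n_groups = group_codes.max() + 1

    nodes, weights = np.polynomial.hermite.hermgauss(n_quadrature)
    log_w = np.log(weights / np.sqrt(np.pi))
    trace: list = []

    def nll(params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        eta = X @ beta
        # observations x nodes linear predictor with the scaled intercepts
        lp = eta[:, None] + np.sqrt(2.0) * sigma * nodes[None, :]
        ll_obs = y[:, None] * lp - np.log1p(np.exp(lp))
        ll_group = np.zeros((n_groups, n_quadrature))
        np.add.at(ll_group, group_codes, ll_obs)
        total = float(logsumexp(ll_group + log_w[None, :], axis=1).sum())
        trace.append((params.copy(), -total))
        return -total

    x0 = np.concatenate([np.zeros(X.shape[1]), [np.log(0.5)]])
    # crude intercept start from the pooled proportion
    p0 = min(max(y.mean(), 1e-4), 1 - 1e-4)
    x0[0] = np.log(p0 / (1 - p0))
    bounds = [(None, None)] * X.shape[1] + [(-10.0, 3.0)]
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter})
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise ConvergenceError(f"hierarchical fit failed: {res.message}", trace=trace)
    sigma = float(np.exp(res.x[-1]))
    return {
        "tau2": sigma**2,
        "sigma": sigma,
        "beta": res.x[:-1],
        "converged": bool(res.success),
        "loglik": -float(res.fun),
        "trace": trace,
        "n_groups": int(n_groups),
        "n_obs": int(len(y)),
    }


def provider_reliability(
    tau2: float,
    p_hat: float,
    n_j,
    scale: str = "probability",
):
    """Reliability (percent) for providers with ``n_j`` evaluated patients.

    noise_j = p(1-p)/n_j with ``p_hat`` the overall indicator proportion;
    the signal tau^2 is delta-method converted to the probability scale
    (``scale='probability'``, default) or used raw (``scale='logit'``).
    Undefined (NaN) when the overall proportion is degenerate at 0 or 1.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    n = np.asarray(n_j, dtype=float)
    if np.any(n < 1):
        raise ValueError("n_j must be at least 1")
    pq = p_hat * (1.0 - p_hat)
    if pq == 0:
        out = np.full(n.shape, np.nan)
        return float(out) if out.ndim == 0 else out
    noise = pq / n
    signal = tau2 * pq**2 if scale == "probability" else tau2
    with np.errstate(invalid="ignore"):
        rel = np.where(signal + noise > 0, 100.0 * signal / (signal + noise), 0.0)
    return float(rel) if rel.ndim == 0 else rel


def summarize_reliability(
    reliabilities,
    cutoff_pct: float = RELIABILITY_CUTOFF_PCT,
    provider_ids: Optional[Iterable[str]] = None,
) -> dict:
    """Count and share of providers at or above the reliability cut-off."""
    rel = np.asarray(list(reliabilities), dtype=float)
    ok = rel >= cutoff_pct
    providers = list(provider_ids) if provider_ids is not None else list(range(len(rel)))
    return {
        "n_providers": int(len(rel)),
        "n_reliable": int(np.nansum(ok)),
        "pct_reliable": float(100.0 * np.nansum(ok) / len(rel)) if len(rel) else float("nan"),
        "reliable_providers": [p for p, good in zip(providers, ok) if good],
    }


def indicator_reliability(
    patient_outcomes: pd.DataFrame,
    covariates: Iterable[str] = CASEMIX_COVARIATES,
    cutoff_pct: float = RELIABILITY_CUTOFF_PCT,
    scale: str = "probability",
) -> dict:
    """Full reliability analysis of one indicator from patient-level data.

    Fits the hierarchical model, computes per-provider reliability at the
    overall proportion, and summarises against the cut-off.  Providers
    with a single evaluated patient are kept but flagged low-information.
    """
    df = patient_outcomes.dropna(subset=["provider"])
    fit = fit_hierarchical(df, covariates=covariates)
    per = (
        df.groupby("provider")["outcome"]
        .agg(n="size", k="sum")
        .reset_index()
        .sort_values("provider")
        .reset_index(drop=True)
    )
    p_hat = float(df["outcome"].mean())
    per["p"] = 100.0 * per["k"] / per["n"]
    per["reliability"] = provider_reliability(fit["tau2"], p_hat, per["n"].to_numpy(), scale=scale)
    per["low_information"] = per["n"] < 2
    summary = summarize_reliability(per["reliability"], cutoff_pct, per["provider"])
    return {"fit": fit, "per_provider": per, "p_hat": p_hat, "summary": summary}
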