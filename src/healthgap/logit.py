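"""Survey-weighted logistic regression and odds-ratio tables.

The fitter maximises the weight-multiplied Bernoulli log-likelihood

    l(b) = sum_i w_i [ y_i log mu_i + (1 - y_i) log(1 - mu_i) ],
    mu_i = expit(x_i' b)

by iteratively reweighted least squares (Newton scoring). Weights enter both
the score and the information, i.e. frequency-style weighting, which gives
survey-weighted point estimates; by default weights are normalised to mean 1
over the fitted subset so reported variances are on the sample-size scale.
Odds ratios are exp(b) with symmetric Wald confidence intervals on the
log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data_model import AnalysisDataset, Covariate, CovariateSchema, DataError, encode_design_matrix

SCORE_TOL = 1e-8
PARAM_TOL = 1e-10
MAX_ITER = 100
SEPARATION_BOUND = 15.0


class RankDeficiencyError(DataError):
    """The design matrix is rank deficient (collinear columns)."""


class SeparationError(DataError):
    """Quasi-separation: the likelihood is maximised at infinite coefficients."""


class NotConvergedError(DataError):
    """The IRLS iteration did not converge."""


@dataclass
class LogitFit:
    """A fitted weighted logistic model."""

    params: np.ndarray
    cov_params: np.ndarray
    column_labels: list[str]
    converged: bool
    n_iter: int
    log_likelihood: float
    n_obs: int
    weight_sum: float
    group_tag: str | None = None

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.params)

    def coef_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.column_labels)


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    """Name the offending columns when the design is collinear."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [labels[j] for j in np.flatnonzero(diag <= tol)]
    if bad:
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def fit_logit_irls(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    labels: list[str] | None = None,
    *,
    normalize_weights: bool = True,
    max_iter: int = MAX_ITER,
    score_tol: float = SCORE_TOL,
    param_tol: float = PARAM_TOL,
    group_tag: str | None = None,
    check_rank: bool = True,
) -> LogitFit:
    """IRLS maximum likelihood for a weighted logit on a raw design matrix.

    Convergence requires max|score| < ``score_tol`` or max coefficient change
    < ``param_tol`` within ``max_iter`` iterations. A coefficient drifting
    beyond +-15 on the log-odds scale while the score has not converged is
    diagnosed as quasi-separation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    labels = labels if labels is not None else [f"x{j}" for j in range(p)]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise DataError("weights must be positive")
    weight_sum = float(w.sum())
    if normalize_weights:
        w = w * (n / weight_sum)
    if check_rank:
        _check_rank(X, labels)

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (w * (y - mu))
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        wls = w * mu * (1.0 - mu)
        # guard against exactly-saturated probabilities
        wls = np.maximum(wls, 1e-12)
        H = (X * wls[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(f"singular information matrix: {exc}") from exc
        # step-halving keeps the likelihood finite for extreme starts
        new = beta + step
        for _ in range(20):
            if np.all(np.isfinite(new)) and abs(new).max() < 1e3:
                break
            step /= 2.0
            new = beta + step
        delta = np.max(np.abs(new - beta))
        beta = new
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                "quasi-separation detected: coefficients diverging beyond "
                f"{SEPARATION_BOUND} on the logit scale"
            )
        if delta < param_tol:
            converged = True
            break
    if not converged:
        raise NotConvergedError(f"IRLS did not converge in {max_iter} iterations")

    mu = expit(X @ beta)
    wls = np.maximum(w * mu * (1.0 - mu), 1e-12)
    H = (X * wls[:, None]).T @ X
    cov = np.linalg.inv(H)
    cov = (cov + cov.T) / 2.0
    eps = 1e-12
    llf = float(np.sum(w * (y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))))
    return LogitFit(
        params=beta, cov_params=cov, column_labels=list(labels),
        converged=converged, n_iter=it, log_likelihood=llf,
        n_obs=n, weight_sum=weight_sum, group_tag=group_tag,
    )


def fit_weighted_logit(
    ds: AnalysisDataset,
    covariates: list[str] | None = None,
    subset: str | None = None,
    **kwargs,
) -> LogitFit:
    """Weighted logit of the outcome on dummy-encoded covariates.

    ``subset`` restricts the fit to one group level (e.g. ``"rural"``); the
    design layout always spans the full schema so group-specific fits share
    column labels.
    """
    X, labels = encode_design_matrix(ds, covariates=covariates)
    y, w = ds.outcome, ds.weights
    if subset is not None:
        m = ds.group_mask(subset)
        X, y, w = X[m], y[m], w[m]
        kwargs.setdefault("group_tag", subset)
    return fit_logit_irls(X, y, w, labels, **kwargs)


# ---------------------------------------------------------------------------
# Odds-ratio tables
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""


def odds_ratio_table(
    fit: LogitFit,
    schema: CovariateSchema,
    alpha: float = 0.05,
    include_constant: bool = False,
) -> pd.DataFrame:
    """OR = exp(beta) with Wald CIs and two-sided p-values, reference rows first.

    Rows carry ``(covariate, level, OR, CI_low, CI_high, p_value,
    is_reference, stars)``; reference rows print OR 1 with an empty CI.
    """
    if not fit.converged:
        raise NotConvergedError("odds ratios require a converged fit")
    z = stats.norm.ppf(1 - alpha / 2)
    by_label = {l: j for j, l in enumerate(fit.column_labels)}

    def lookup(name: str) -> Covariate:
        if name == schema.group_variable:
            return Covariate(name, schema.group_levels, schema.group_levels[0])
        return schema.covariate(name)

    names_in_fit: list[str] = []
    for l in fit.column_labels:
        if l == "constant":
            continue
        name = l.split("=", 1)[0]
        if name not in names_in_fit:
            names_in_fit.append(name)

    rows = []
    for name in names_in_fit:
        cov = lookup(name)
        rows.append((name, cov.reference, 1.0, np.nan, np.nan, np.nan, True, ""))
        for level in cov.levels:
            if level == cov.reference:
                continue
            j = by_label[f"{name}={level}"]
            b, se = fit.params[j], fit.bse[j]
            p = 2 * stats.norm.sf(abs(b) / se) if se > 0 else 0.0
            rows.append((
                name, level, float(np.exp(b)),
                float(np.exp(b - z * se)), float(np.exp(b + z * se)),
                float(p), False, _stars(p),
            ))
    if include_constant and "constant" in by_label:
        j = by_label["constant"]
        b, se = fit.params[j], fit.bse[j]
        p = 2 * stats.norm.sf(abs(b) / se)
        rows.append(("constant", "", float(np.exp(b)),
                     float(np.exp(b - z * se)), float(np.exp(b + z * se)),
                     float(p), False, _stars(p)))
    return pd.DataFrame(rows, columns=[
        "covariate", "level", "OR", "CI_low", "CI_high",
        "p_value", "is_reference", "stars",
    ])


def unadjusted_or_sweep(
    ds: AnalysisDataset,
    alpha: float = 0.05,
    include_group: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """One single-covariate weighted logit per schema entry, tables stacked.

    ``include_group`` adds the group variable itself as a predictor (its
    first level as reference), mirroring residence in an unadjusted sweep.
    """
    schema = ds.schema
    frames = []
    names = list(schema.covariate_names)
    if include_group:
        names.append(schema.group_variable)
    for name in names:
        if name == schema.group_variable:
            gcov = Covariate(name, schema.group_levels, schema.group_levels[0])
            ind = (ds.data[name].to_numpy() == schema.group_levels[1]).astype(float)
            X = np.column_stack([np.ones(len(ds.data)), ind])
            labels = ["constant", f"{name}={schema.group_levels[1]}"]
            fit = fit_logit_irls(X, ds.outcome, ds.weights, labels, **fit_kwargs)
        else:
            fit = fit_weighted_logit(ds, covariates=[name], **fit_kwargs)
        frames.append(odds_ratio_table(fit, schema, alpha=alpha))
    return pd.concat(frames, ignore_index=True)


def adjusted_or_table(
    ds: AnalysisDataset,
    alpha: float = 0.05,
    include_group: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """One weighted logit on all covariates (optionally plus the group)."""
    schema = ds.schema
    X, labels = encode_design_matrix(ds)
    if include_group:
        ind = (ds.data[schema.group_variable].to_numpy()
               == schema.group_levels[1]).astype(float)
        X = np.column_stack([X, ind])
        labels = labels + [f"{schema.group_variable}={schema.group_levels[1]}"]
    fit = fit_logit_irls(X, ds.outcome, ds.weights, labels, **fit_kwargs)
    return odds_ratio_table(fit, schema, alpha=alpha)


def render_or_table(df: pd.DataFrame, decimals: int = 2) -> str:
    """Plain-text OR table; reference rows print as "1"."""
    out = []
    for _, r in df.iterrows():
        if r.is_reference:
            out.append((r.covariate, r.level, "1", ""))
        else:
            out.append((
                r.covariate, r.level,
                f"{r.OR:.{decimals}f} ({r.CI_low:.{decimals}f}-{r.CI_high:.{decimals}f})",
                r.stars,
            ))
    return pd.DataFrame(out, columns=["covariate", "level", "OR (95% CI)", ""]
                        ).to_string(index=False)
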