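"""OLS contrasts with diagnostics and the mixed-type association screen.

The regression layer produces adjusted mean-difference tables (stunting
category versus the overall and per-domain ASQ-3 scores) from first
principles (normal equations, classical standard errors, Breusch-Pagan
homoskedasticity test). The association layer computes the pairwise
mixed-type matrix (Spearman r / Cramer's V / sqrt R^2 of a one-way ANOVA)
that gates which variable blocks may become latent constructs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OlsFit:
    """Ordinary least squares fit with classical inference and diagnostics."""

    params: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    residuals: np.ndarray
    r2: float
    n: int
    bp_stat: float
    bp_p: float
    max_std_resid: float
    max_cooks: float


def _design_matrix(design: pd.DataFrame, add_intercept: bool) -> tuple[np.ndarray, list[str]]:
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + names
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns involved in the deficiency via the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in range(X.shape[1]) if diag[j] < tol] or names
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def ols_fit(
    response: pd.Series, design: pd.DataFrame, add_intercept: bool = True
) -> OlsFit:
    """OLS by normal equations with t-based 95% CIs and a Breusch-Pagan test.

    Rows with any missing value in response or design are dropped (listwise
    deletion); the retained n is reported. The Breusch-Pagan statistic is
    n * R^2 of the auxiliary regression of squared residuals on the design,
    referred to chi-square with (#regressors) degrees of freedom.
    """
    df = pd.concat([response.rename("__y__"), design], axis=1).dropna()
    y = df["__y__"].to_numpy(dtype=float)
    X, names = _design_matrix(df[design.columns], add_intercept)
    n, p = X.shape
    _check_rank(X, names)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = resid @ resid / dof if dof > 0 else 0.0
    XtX_inv = np.linalg.inv(XtX)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tvals), dof) if dof > 0 else np.full(p, np.nan)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / ss_tot if ss_tot > 0 else 1.0

    # Breusch-Pagan: auxiliary regression of e^2 on the same design
    e2 = resid**2
    gamma = np.linalg.solve(XtX, X.T @ e2)
    aux_resid = e2 - X @ gamma
    ss_e2 = np.sum((e2 - e2.mean()) ** 2)
    r2_aux = 1.0 - (aux_resid @ aux_resid) / ss_e2 if ss_e2 > 0 else 0.0
    k = p - 1 if add_intercept else p
    bp_stat = n * r2_aux
    bp_p = stats.chi2.sf(bp_stat, k) if k > 0 else np.nan

    # influence diagnostics as numeric summaries
    H = X @ XtX_inv @ X.T
    lev = np.diag(H)
    denom = np.sqrt(np.maximum(sigma2 * (1 - lev), 1e-300))
    std_resid = resid / denom
    cooks = std_resid**2 * lev / (np.maximum(1 - lev, 1e-300) * p)

    idx = pd.Index(names)
    return OlsFit(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        ci_low=pd.Series(beta - tcrit * se, index=idx),
        ci_high=pd.Series(beta + tcrit * se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        residuals=resid,
        r2=float(r2),
        n=int(n),
        bp_stat=float(bp_stat),
        bp_p=float(bp_p),
        max_std_resid=float(np.max(np.abs(std_resid))) if n else np.nan,
        max_cooks=float(np.max(cooks)) if n else np.nan,
    )


def adjusted_contrast(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: list[str] | tuple[str, ...] = (),
    exposure: str = "stunting_category",
    order: tuple[str, ...] = ("normal", "moderate", "severe"),
) -> pd.DataFrame:
    """Adjusted mean differences of an outcome across stunting categories.

    Dummy-codes ``exposure`` with the first category of ``order`` as the
    reference and fits a single OLS including the covariates. Returns one row
    per non-reference category with the mean difference, 95% CI, p-value and
    the retained n.
    """
    cols = [outcome, exposure, *covariates]
    df = cohort[cols].dropna()
    for cat in order:
        if (df[exposure] == cat).sum() == 0:
            raise ValueError(f"category {cat!r} empty after listwise deletion")
    design = pd.DataFrame(index=df.index)
    for cat in order[1:]:
        design[cat] = (df[exposure] == cat).astype(float)
    for cov in covariates:
        design[cov] = pd.to_numeric(df[cov])
    fit = ols_fit(df[outcome], design)
    rows = []
    for cat in order[1:]:
        rows.append(
            {
                "category": cat,
                "mean_difference": fit.params[cat],
                "ci_low": fit.ci_low[cat],
                "ci_high": fit.ci_high[cat],
                "p": fit.pvalues[cat],
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def pair_association(x: pd.Series, y: pd.Series, types: tuple[str, str]) -> float:
    """Mixed-type pairwise association.

    Spearman's r for two continuous variables (in [-1, 1]); bias-uncorrected
    Cramer's V for two categoricals (in [0, 1]); the square root of the R^2
    of a one-way ANOVA (continuous response on categorical groups) for mixed
    pairs (in [0, 1]). Constant variables yield NaN.
    """
    tx, ty = types
    for t in (tx, ty):
        if t not in ("continuous", "categorical"):
            raise ValueError(f"unknown type {t!r}")
    mask = x.notna() & y.notna()
    xv, yv = x[mask], y[mask]
    if xv.nunique() < 2 or yv.nunique() < 2:
        return np.nan
    if tx == ty == "continuous":
        return float(stats.spearmanr(xv, yv).statistic)
    if tx == ty == "categorical":
        table = pd.crosstab(xv, yv).to_numpy()
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        n = table.sum()
        r, c = table.shape
        return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))
    cont, cat = (xv, yv) if tx == "continuous" else (yv, xv)
    vals = cont.to_numpy(dtype=float)
    grand = vals.mean()
    ss_tot = np.sum((vals - grand) ** 2)
    if ss_tot == 0:
        return np.nan
    ss_between = sum(
        len(g) * (g.mean() - grand) ** 2 for _, g in cont.groupby(cat, observed=True)
    )
    return float(np.sqrt(ss_between / ss_tot))


def association_matrix(block: pd.DataFrame, types: dict[str, str]) -> pd.DataFrame:
    """Symmetric pairwise association matrix over a variable block (diagonal 1)."""
    cols = list(block.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            v = pair_association(block[a], block[b], (types[a], types[b]))
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def screen_block(
    block: pd.DataFrame, types: dict[str, str], threshold: float = 0.2
) -> tuple[bool, pd.DataFrame]:
    """Latent-construct eligibility of a variable block.

    A block is eligible if it has at least 4 indicator variables and the
    median absolute off-diagonal association is at least ``threshold``
    (default 0.2). Returns (eligible, association matrix).
    """
    if block.shape[1] < 2:
        raise ValueError("block needs at least 2 variables")
    mat = association_matrix(block, types)
    vals = mat.to_numpy()
    off = np.abs(vals[~np.eye(len(vals), dtype=bool)])
    off = off[~np.isnan(off)]
    if len(off) == 0:
        raise ValueError("all pairwise associations undefined (constant block?)")
    eligible = block.shape[1] >= 4 and float(np.median(off)) >= threshold
    return eligible, mat
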