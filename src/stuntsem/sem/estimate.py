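"""Maximum-likelihood estimation, standard errors and standardized solutions.

Estimation minimizes F_ML with an analytic gradient from deterministic
starting values (free loadings at 1, paths at 0, variances at half the
observed variances, covariances at 0) using BFGS. Standard errors come from
the numerically differentiated Hessian of F_ML at the optimum via
acov = (2/(n-1)) H^-1; the standardized solution rescales every coefficient
by model-implied standard deviations of all variables (latent included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from stuntsem.sem.model import SemModelSpec
from stuntsem.sem.ram import Ram, build_ram, fml_and_grad, full_covariance, implied_sigma


@dataclass
class SemFit:
    """A fitted structural equation model."""

    spec: SemModelSpec
    ram: Ram
    theta: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    std: pd.Series
    acov: np.ndarray
    fmin: float
    n: int
    S: pd.DataFrame
    converged: bool
    n_iter: int
    grad_norm: float
    heywood: bool
    df: int = field(init=False)

    def __post_init__(self) -> None:
        self.df = self.ram.df

    @property
    def chi_square(self) -> float:
        return (self.n - 1) * self.fmin

    def parameter_table(self) -> pd.DataFrame:
        """Long-form table of estimates, SEs, z, p and standardized values."""
        return pd.DataFrame(
            {
                "estimate": self.theta,
                "se": self.se,
                "z": self.z,
                "p": self.p,
                "std": self.std,
            }
        )


def _start_values(ram: Ram, S: np.ndarray) -> np.ndarray:
    obs_pos = {v: k for k, v in enumerate(ram.observed)}
    anchor: dict[str, str] = {
        lat: inds[0] for lat, inds in ram.spec.measurement.items()
    }
    theta0 = np.empty(ram.n_free)
    for k, fp in enumerate(ram.free):
        if fp.kind == "loading":
            theta0[k] = 1.0
        elif fp.kind == "path":
            theta0[k] = 0.0
        elif fp.kind == "cov":
            theta0[k] = 0.0
        else:  # resid | var
            var = ram.variables[fp.i]
            if var in obs_pos:
                theta0[k] = 0.5 * S[obs_pos[var], obs_pos[var]]
            else:  # latent: half the variance of its anchor indicator
                a = anchor[var]
                theta0[k] = 0.5 * S[obs_pos[a], obs_pos[a]]
    return theta0


def _numerical_hessian(fun_grad, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        step = h * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += step
        tm = theta.copy()
        tm[j] -= step
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[:, j] = (gp - gm) / (2 * step)
    return (H + H.T) / 2


def _standardized(ram: Ram, theta: np.ndarray) -> np.ndarray:
    C = full_covariance(ram, theta)
    sd = np.sqrt(np.clip(np.diag(C), 1e-300, None))
    std = np.empty(ram.n_free)
    for k, fp in enumerate(ram.free):
        if fp.matrix == "A":
            std[k] = theta[k] * sd[fp.j] / sd[fp.i]
        elif fp.i == fp.j:
            std[k] = theta[k] / C[fp.i, fp.i] if C[fp.i, fp.i] > 0 else np.nan
        else:
            std[k] = theta[k] / (sd[fp.i] * sd[fp.j])
    return std


def _rescaling_factors(ram: Ram, sd: np.ndarray) -> np.ndarray:
    """Per-parameter factor mapping a standardized-data solution to raw units.

    Each variable carries a scale: its own SD if observed, its anchor
    indicator's SD if latent (the fixed-to-1 loading ties the latent's scale
    to that indicator). Directed-edge parameters rescale by scale(target) /
    scale(source); (co)variance parameters by scale(i) * scale(j).
    """
    obs_pos = {v: k for k, v in enumerate(ram.observed)}
    anchor = {lat: inds[0] for lat, inds in ram.spec.measurement.items()}

    def scale(var: str) -> float:
        return sd[obs_pos[var]] if var in obs_pos else sd[obs_pos[anchor[var]]]

    factors = np.empty(ram.n_free)
    for k, fp in enumerate(ram.free):
        vi, vj = ram.variables[fp.i], ram.variables[fp.j]
        if fp.matrix == "A":
            factors[k] = scale(vi) / scale(vj)
        else:
            factors[k] = scale(vi) * scale(vj)
    return factors


def estimate(
    spec: SemModelSpec,
    data: pd.DataFrame,
    max_iter: int = 500,
    gtol: float = 1e-8,
) -> SemFit:
    """Fit a model to a data table by maximum likelihood.

    Uses listwise deletion over the observed variables of the spec, requires
    the sample covariance (n-1 denominator) to be positive definite and the
    retained n to exceed the number of free parameters. Estimation is
    deterministic: BFGS from fixed starting values, no randomness.

    Optimization runs on standardized data for scale-invariant convergence
    (F_ML and chi-square are invariant under this rescaling); the solution is
    mapped back to raw units exactly. Models with fixed (co)variance values
    are fitted directly on the raw scale, where those constants live.
    """
    ram = build_ram(spec)
    cols = list(spec.observed)
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks model variables: {missing_cols}")
    df = data[cols].apply(pd.to_numeric).dropna()
    n = len(df)
    if n <= ram.n_free:
        raise ValueError(f"n after listwise deletion ({n}) must exceed #free ({ram.n_free})")
    X = df.to_numpy(dtype=float)
    S_raw = np.cov(X, rowvar=False, ddof=1)
    S_raw = (S_raw + S_raw.T) / 2
    try:
        np.linalg.cholesky(S_raw)
    except np.linalg.LinAlgError as err:
        raise ValueError("sample covariance is not positive definite") from err

    standardize_scale = len(spec.fixed) == 0
    if standardize_scale:
        sd = np.sqrt(np.diag(S_raw))
        S = S_raw / np.outer(sd, sd)
        factors = _rescaling_factors(ram, sd)
    else:
        S = S_raw
        factors = np.ones(ram.n_free)

    def fun_grad(t: np.ndarray) -> tuple[float, np.ndarray]:
        return fml_and_grad(ram, t, S)

    theta0 = _start_values(ram, S)
    res = optimize.minimize(
        fun_grad,
        theta0,
        jac=True,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    theta = res.x
    fmin, grad = fun_grad(theta)
    grad_norm = float(np.max(np.abs(grad))) if len(grad) else 0.0
    for _ in range(2):  # polish while the gradient is not yet tight
        if np.isfinite(fmin) and grad_norm < 1e-6:
            break
        res = optimize.minimize(
            fun_grad,
            theta,
            jac=True,
            method="BFGS",
            options={"maxiter": 2 * max_iter, "gtol": gtol / 10},
        )
        theta = res.x
        fmin, grad = fun_grad(theta)
        grad_norm = float(np.max(np.abs(grad))) if len(grad) else 0.0
    converged = bool(np.isfinite(fmin)) and grad_norm < 1e-5

    H = _numerical_hessian(fun_grad, theta)
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Hinv = np.linalg.pinv(H)
    acov = (2.0 / (n - 1)) * Hinv
    se = np.sqrt(np.clip(np.diag(acov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, theta / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))

    # map the standardized-scale solution back to the raw units of the data
    theta_raw = factors * theta
    se_raw = factors * se
    acov_raw = np.outer(factors, factors) * acov

    heywood = any(
        fp.kind == "resid" and theta_raw[k] < 0 for k, fp in enumerate(ram.free)
    )
    names = pd.Index(ram.param_names(), name="parameter")
    return SemFit(
        spec=spec,
        ram=ram,
        theta=pd.Series(theta_raw, index=names, name="estimate"),
        se=pd.Series(se_raw, index=names, name="se"),
        z=pd.Series(z, index=names, name="z"),
        p=pd.Series(p, index=names, name="p"),
        std=pd.Series(_standardized(ram, theta_raw), index=names, name="std"),
        acov=acov_raw,
        fmin=float(fmin),
        n=n,
        S=pd.DataFrame(S_raw, index=cols, columns=cols),
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        heywood=heywood,
    )


def cfa(spec: SemModelSpec, data: pd.DataFrame, **kwargs):
    """Confirmatory factor analysis: a measurement-only model, fitted + indexed.

    Returns (SemFit, FitStatistics). Raises if the spec has structural edges.
    """
    from stuntsem.sem.fitstats import fit_statistics

    if spec.structural:
        raise ValueError("a CFA spec must not contain structural edges")
    fit = estimate(spec, data, **kwargs)
    return fit, fit_statistics(fit)


def path_analysis(spec: SemModelSpec, data: pd.DataFrame, **kwargs):
    """Path analysis: an observed-variables-only model, fitted + indexed.

    Returns (SemFit, FitStatistics). Raises if the spec declares latents.
    """
    from stuntsem.sem.fitstats import fit_statistics

    if spec.measurement:
        raise ValueError("a path-analysis spec must not contain latent variables")
    fit = estimate(spec, data, **kwargs)
    return fit, fit_statistics(fit)


def simulate_data(
    spec: SemModelSpec,
    theta: dict[str, float],
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw observed data from the multivariate normal implied by (spec, theta).

    ``theta`` maps free-parameter labels (as produced by the RAM index, e.g.
    ``'Neuro=~ps'``, ``'haz~SES'``, ``'haz~~haz'``) to generating values;
    unlisted parameters default to their start-value convention (loadings 1,
    paths 0, variances 1, covariances 0).
    """
    ram = build_ram(spec)
    vec = np.empty(ram.n_free)
    for k, fp in enumerate(ram.free):
        if fp.name in theta:
            vec[k] = theta[fp.name]
        elif fp.kind == "loading":
            vec[k] = 1.0
        elif fp.kind in ("path", "cov"):
            vec[k] = 0.0
        else:
            vec[k] = 1.0
    Sigma = implied_sigma(ram, vec)
    X = rng.multivariate_normal(np.zeros(len(Sigma)), Sigma, size=n, method="cholesky")
    return pd.DataFrame(X, columns=list(spec.observed))
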