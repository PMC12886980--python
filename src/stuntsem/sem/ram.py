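"""RAM representation and the maximum-likelihood discrepancy function.

``build_ram`` lowers a :class:`~stuntsem.sem.model.SemModelSpec` into the
matrices (A, Omega, F): A collects directed-edge coefficients (factor
loadings and structural paths) over the joint observed+latent vector, Omega
collects exogenous (co)variances and residual variances, and F selects the
observed rows. By default every endogenous variable gets a free residual
variance, every exogenous variable a free variance, and every pair of
exogenous variables a free covariance (the usual convention for recursive
models with correlated exogenous inputs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from stuntsem.sem.model import SemModelSpec


@dataclass(frozen=True)
class FreeParam:
    """One free parameter: its label, target matrix ('A' or 'O'), and cell."""

    name: str
    matrix: str
    i: int
    j: int
    kind: str  # loading | path | resid | var | cov


@dataclass(frozen=True)
class Ram:
    """RAM matrices with a free-parameter index for a given model spec."""

    spec: SemModelSpec
    variables: tuple[str, ...]
    observed: tuple[str, ...]
    A0: np.ndarray
    Omega0: np.ndarray
    free: tuple[FreeParam, ...]
    obs_idx: np.ndarray

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def df(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free

    def param_names(self) -> list[str]:
        return [fp.name for fp in self.free]

    def fill(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Materialize (A, Omega) at a parameter vector."""
        A = self.A0.copy()
        Om = self.Omega0.copy()
        for fp, val in zip(self.free, theta):
            if fp.matrix == "A":
                A[fp.i, fp.j] = val
            else:
                Om[fp.i, fp.j] = val
                Om[fp.j, fp.i] = val
        return A, Om


def build_ram(spec: SemModelSpec) -> Ram:
    """Lower a model spec to RAM matrices plus a free-parameter index."""
    variables = spec.variables
    idx = {v: k for k, v in enumerate(variables)}
    m = len(variables)
    A0 = np.zeros((m, m))
    Om0 = np.zeros((m, m))
    free: list[FreeParam] = []
    seen_edges: set[tuple[int, int]] = set()

    def add_edge(i: int, j: int, name: str, kind: str, fixed_value: float | None) -> None:
        if (i, j) in seen_edges:
            raise ValueError(f"duplicate edge {name!r}")
        seen_edges.add((i, j))
        if fixed_value is not None:
            A0[i, j] = fixed_value
        else:
            free.append(FreeParam(name, "A", i, j, kind))

    for lat, inds in spec.measurement.items():
        for k, ind in enumerate(inds):
            add_edge(
                idx[ind],
                idx[lat],
                f"{lat}=~{ind}",
                "loading",
                1.0 if k == 0 else None,
            )
    for out, pred in spec.structural:
        add_edge(idx[out], idx[pred], f"{out}~{pred}", "path", None)

    fixed_pairs = {frozenset((a, b)): v for (a, b), v in spec.fixed.items()}

    def omega_entry(a: str, b: str, kind: str) -> None:
        i, j = idx[a], idx[b]
        key = frozenset((a, b))
        if key in fixed_pairs:
            Om0[i, j] = Om0[j, i] = fixed_pairs.pop(key)
            return
        name = f"{a}~~{b}"
        free.append(FreeParam(name, "O", i, j, kind))

    endo = spec.endogenous()
    exo = spec.exogenous()
    for v in variables:
        omega_entry(v, v, "resid" if v in endo else "var")
    for a_i in range(len(exo)):
        for b_i in range(a_i + 1, len(exo)):
            omega_entry(exo[a_i], exo[b_i], "cov")
    for a, b in spec.covariances:
        if a in exo and b in exo:
            continue  # already free by the exogenous default
        omega_entry(a, b, "cov")
    for key, val in fixed_pairs.items():  # fixed pairs not covered above
        a, b = tuple(key) if len(key) == 2 else (next(iter(key)),) * 2
        Om0[idx[a], idx[b]] = Om0[idx[b], idx[a]] = val

    obs_idx = np.array([idx[v] for v in spec.observed], dtype=int)
    return Ram(
        spec=spec,
        variables=variables,
        observed=spec.observed,
        A0=A0,
        Omega0=Om0,
        free=tuple(free),
        obs_idx=obs_idx,
    )


def full_covariance(ram: Ram, theta: np.ndarray) -> np.ndarray:
    """Implied covariance over all variables (latent included): B Omega B^T."""
    A, Om = ram.fill(np.asarray(theta, dtype=float))
    m = A.shape[0]
    B = np.linalg.solve(np.eye(m) - A, np.eye(m))
    return B @ Om @ B.T


def implied_sigma(ram: Ram, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance of the observed variables, Sigma(theta)."""
    C = full_covariance(ram, theta)
    S = C[np.ix_(ram.obs_idx, ram.obs_idx)]
    return (S + S.T) / 2


def _logdet_spd(M: np.ndarray) -> float:
    c, low = cho_factor(M, check_finite=False)
    return 2.0 * float(np.sum(np.log(np.diag(c))))


def fml(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Maximum-likelihood discrepancy ln|Sigma| + tr(S Sigma^-1) - ln|S| - p.

    Non-negative, zero iff Sigma equals S. Raises on non-SPD input.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape:
        raise ValueError("S and Sigma must have the same shape")
    p = S.shape[0]
    try:
        ld_sigma = _logdet_spd(Sigma)
        c = cho_factor(Sigma, check_finite=False)
        tr = float(np.trace(cho_solve(c, S, check_finite=False)))
        ld_s = _logdet_spd(S)
    except np.linalg.LinAlgError as err:
        raise ValueError("S and Sigma must be symmetric positive definite") from err
    return ld_sigma + tr - ld_s - p


def fml_and_grad(ram: Ram, theta: np.ndarray, S: np.ndarray) -> tuple[float, np.ndarray]:
    """F_ML and its analytic gradient at theta.

    Uses dF = tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma] with the RAM
    derivatives of Sigma. Returns (inf, zeros) when Sigma(theta) is not
    positive definite, so a line search backs off.
    """
    theta = np.asarray(theta, dtype=float)
    A, Om = ram.fill(theta)
    m = A.shape[0]
    obs = ram.obs_idx
    B = np.linalg.solve(np.eye(m) - A, np.eye(m))
    C = B @ Om @ B.T
    Sigma = C[np.ix_(obs, obs)]
    Sigma = (Sigma + Sigma.T) / 2
    try:
        c = cho_factor(Sigma, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(ram.n_free)
    ld_sigma = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    Sigma_inv = cho_solve(c, np.eye(len(obs)), check_finite=False)
    p = len(obs)
    ld_s = _logdet_spd(S)
    F = ld_sigma + float(np.sum(Sigma_inv * S)) - ld_s - p

    W = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    Mfull = np.zeros((m, m))
    Mfull[np.ix_(obs, obs)] = W
    P = C @ Mfull @ B  # for A-parameters: dF/da_ij = 2 P[j, i]
    Q = B.T @ Mfull @ B  # for Omega-parameters

    grad = np.empty(ram.n_free)
    for k, fp in enumerate(ram.free):
        if fp.matrix == "A":
            grad[k] = 2.0 * P[fp.j, fp.i]
        elif fp.i == fp.j:
            grad[k] = Q[fp.i, fp.i]
        else:
            grad[k] = 2.0 * Q[fp.i, fp.j]
    return F, grad
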