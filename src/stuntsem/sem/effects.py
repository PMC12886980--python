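"""Direct / indirect / total effect decomposition with delta-method inference.

For a recursive model with directed-edge matrix A, the matrix of total
effects is (I - A)^-1 - I; the direct effect of a source on an outcome is
the corresponding entry of A, and the indirect effect (the sum over all
mediated routes of products of path coefficients) is total minus direct.
Standard errors use the delta method with a numerical Jacobian of the three
effects against the estimated parameter covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from stuntsem.sem.estimate import SemFit


@dataclass(frozen=True)
class EffectDecomposition:
    source: str
    outcome: str
    direct: float
    indirect: float
    total: float
    se_direct: float
    se_indirect: float
    se_total: float
    z_direct: float
    z_indirect: float
    z_total: float
    p_direct: float
    p_indirect: float
    p_total: float


def _effect_triplet(fit: SemFit, theta: np.ndarray, i: int, j: int) -> np.ndarray:
    A, _ = fit.ram.fill(theta)
    m = A.shape[0]
    total_mat = np.linalg.solve(np.eye(m) - A, np.eye(m)) - np.eye(m)
    direct = A[i, j]
    total = total_mat[i, j]
    return np.array([direct, total - direct, total])


def effects(fit: SemFit, source: str, outcome: str) -> EffectDecomposition:
    """Decompose the effect of ``source`` on ``outcome`` in a fitted model."""
    if source == outcome:
        raise ValueError("source and outcome must differ")
    variables = fit.ram.variables
    for v in (source, outcome):
        if v not in variables:
            raise ValueError(f"{v!r} is not a model variable")
    idx = {v: k for k, v in enumerate(variables)}
    i, j = idx[outcome], idx[source]
    theta = fit.theta.to_numpy()
    vals = _effect_triplet(fit, theta, i, j)

    # delta method: numerical Jacobian of (direct, indirect, total) wrt theta
    k = len(theta)
    J = np.zeros((3, k))
    for q in range(k):
        h = 1e-6 * max(1.0, abs(theta[q]))
        tp = theta.copy()
        tp[q] += h
        tm = theta.copy()
        tm[q] -= h
        J[:, q] = (_effect_triplet(fit, tp, i, j) - _effect_triplet(fit, tm, i, j)) / (2 * h)
    var = np.clip(np.diag(J @ fit.acov @ J.T), 0.0, None)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, vals / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    return EffectDecomposition(
        source=source,
        outcome=outcome,
        direct=float(vals[0]),
        indirect=float(vals[1]),
        total=float(vals[2]),
        se_direct=float(se[0]),
        se_indirect=float(se[1]),
        se_total=float(se[2]),
        z_direct=float(z[0]),
        z_indirect=float(z[1]),
        z_total=float(z[2]),
        p_direct=float(p[0]),
        p_indirect=float(p[1]),
        p_total=float(p[2]),
    )
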