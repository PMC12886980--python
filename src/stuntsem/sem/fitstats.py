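"""Global fit statistics: chi-square, CFI, TLI, RMSEA, SRMR.

The chi-square uses the Wishart convention (n-1) * F_min with the sample
covariance computed on the n-1 denominator; the baseline (independence)
model frees only the observed variances, for which F_B has the closed form
-ln|R| with R the sample correlation matrix. SRMR averages squared
standardized residuals over all unique cells including the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from stuntsem.sem.estimate import SemFit
from stuntsem.sem.ram import implied_sigma


@dataclass(frozen=True)
class FitStatistics:
    chi_square: float
    df: int
    p: float
    baseline_chi_square: float
    baseline_df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p": self.p,
            "baseline_chi_square": self.baseline_chi_square,
            "baseline_df": self.baseline_df,
            "cfi": self.cfi,
            "tli": self.tli,
            "rmsea": self.rmsea,
            "srmr": self.srmr,
        }


def indices_from_chi_square(
    chi_m: float, df_m: int, chi_b: float, df_b: int, n: int
) -> tuple[float, float, float]:
    """CFI, TLI and RMSEA from model and baseline chi-squares.

    CFI = 1 - max(chi_m - df_m, 0) / max(chi_m - df_m, chi_b - df_b, 0);
    TLI = ((chi_b/df_b) - (chi_m/df_m)) / ((chi_b/df_b) - 1);
    RMSEA = sqrt(max(chi_m - df_m, 0) / (df_m (n-1))).
    A zero-df model gets CFI = TLI = 1 and RMSEA = 0 by convention.
    """
    if df_m == 0:
        return 1.0, 1.0, 0.0
    num = max(chi_m - df_m, 0.0)
    den = max(chi_m - df_m, chi_b - df_b, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    ratio_b = chi_b / df_b
    ratio_m = chi_m / df_m
    tli = (ratio_b - ratio_m) / (ratio_b - 1.0) if ratio_b != 1.0 else 1.0
    rmsea = float(np.sqrt(max(chi_m - df_m, 0.0) / (df_m * (n - 1))))
    return float(cfi), float(tli), rmsea


def srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Standardized root mean square residual, diagonal cells included."""
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    resid = (S - Sigma) / d
    iu = np.triu_indices_from(resid)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def fit_statistics(fit: SemFit) -> FitStatistics:
    """Compute the full fit-index panel for a converged fit."""
    if not fit.converged:
        raise ValueError(
            f"fit did not converge (gradient norm {fit.grad_norm:.2e}); "
            "fit statistics would be unreliable"
        )
    S = fit.S.to_numpy()
    p_star = S.shape[0]
    chi_m = fit.chi_square
    df_m = fit.df
    # independence baseline: F_B = -ln|R|
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    chi_b = -(fit.n - 1) * logdet
    df_b = p_star * (p_star - 1) // 2
    cfi, tli, rmsea = indices_from_chi_square(chi_m, df_m, chi_b, df_b, fit.n)
    p_val = stats.chi2.sf(chi_m, df_m) if df_m > 0 else 1.0
    Sigma = implied_sigma(fit.ram, fit.theta.to_numpy())
    return FitStatistics(
        chi_square=float(chi_m),
        df=int(df_m),
        p=float(p_val),
        baseline_chi_square=float(chi_b),
        baseline_df=int(df_b),
        cfi=cfi,
        tli=tli,
        rmsea=rmsea,
        srmr=srmr(S, Sigma),
    )
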