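"""Overidentified per-variant MR: Wald ratios, IVW pooling, Cochran's Q.

Probes the exclusion restriction: when every variant affects the outcome
only through the disease, the per-variant Wald ratios (outcome association
divided by exposure association) scatter around a common causal effect and
Cochran's Q is chi-squared with n_snps - 1 degrees of freedom.  Horizontal
pleiotropy on a subset of variants inflates Q.

Ratios use first-order delta-method SEs, ``se_outcome / |beta_exposure|``,
ignoring first-stage uncertainty — the standard two-sample convention.
Pooling is fixed-effect inverse-variance weighting.  An MR-Egger
intercept regression is available behind ``egger_regression`` for users
who want a directional-pleiotropy check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, DosageMatrix

__all__ = ["SnpEstimate", "IVWResult", "per_snp_estimates", "ivw_pool",
           "egger_regression"]

_BETA_TOL = 1e-12


@dataclass(frozen=True)
class SnpEstimate:
    """Per-variant exposure and outcome associations and their ratio."""

    variant: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float

    @property
    def wald_ratio(self) -> float:
        return self.beta_outcome / self.beta_exposure

    @property
    def se_ratio(self) -> float:
        return self.se_outcome / abs(self.beta_exposure)


@dataclass(frozen=True)
class IVWResult:
    beta_pooled: float
    se_pooled: float
    q_statistic: float
    q_df: int
    q_pvalue: float
    n_snps: int


def _residualise(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the covariate block C."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def per_snp_estimates(cohort: Cohort, dosages: DosageMatrix,
                      covariates: np.ndarray | None = None,
                      outcome: str = "annual_cost",
                      exposure: str = "cancer") -> list[SnpEstimate]:
    """Variant-by-variant regressions of exposure and outcome on dosage.

    For each variant, the exposure (and separately the outcome) is
    regressed on that variant's dosage plus covariates; by
    Frisch-Waugh-Lovell both slopes are computed on covariate-residualised
    data, which lets all variants be handled in one vectorised pass.
    Complete cases only.  Variants whose exposure association is numerically
    zero cannot yield a ratio and are excluded with a warning.
    """
    if len(dosages.variant_ids) < 2:
        raise ValueError("per-SNP MR requires at least 2 variants")
    y = cohort.df[outcome].to_numpy(float)
    keep = np.isfinite(y)
    y = y[keep]
    x = cohort.df[exposure].to_numpy(float)[keep]
    G = dosages.values[keep]
    n = y.size
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = np.column_stack([np.ones(n), C[keep] if C.shape[0] != n else C])

    Gt = _residualise(G, C)
    xt = _residualise(x[:, None], C)[:, 0]
    yt = _residualise(y[:, None], C)[:, 0]

    gg = np.einsum("ij,ij->j", Gt, Gt)
    degenerate = gg <= _BETA_TOL  # constant dosage column: no association
    gg = np.where(degenerate, 1.0, gg)
    bx = np.where(degenerate, 0.0, (Gt.T @ xt) / gg)
    by = (Gt.T @ yt) / gg
    # residual dof: covariates (incl. intercept) + the dosage column
    dof = max(n - C.shape[1] - 1, 1)
    sx = np.sqrt(np.maximum(
        np.sum(xt[:, None] ** 2 - 2 * xt[:, None] * Gt * bx
               + (Gt * bx) ** 2, axis=0), 0.0) / dof / gg)
    sy = np.sqrt(np.maximum(
        np.sum(yt[:, None] ** 2 - 2 * yt[:, None] * Gt * by
               + (Gt * by) ** 2, axis=0), 0.0) / dof / gg)

    out: list[SnpEstimate] = []
    for j, vid in enumerate(dosages.variant_ids):
        if abs(bx[j]) < _BETA_TOL:
            warnings.warn(f"variant {vid}: exposure association below "
                          f"tolerance; excluded from per-SNP MR",
                          UserWarning)
            continue
        out.append(SnpEstimate(vid, float(bx[j]), float(sx[j]),
                               float(by[j]), float(sy[j])))
    return out


def ivw_pool(estimates: list[SnpEstimate]) -> IVWResult:
    """Fixed-effect inverse-variance-weighted pooling of Wald ratios.

    ``beta = sum(w r) / sum(w)`` with ``w = 1/se_ratio^2``;
    ``Q = sum w (r - beta)^2`` referred to chi-squared on n-1 df.
    """
    if len(estimates) < 2:
        raise ValueError("IVW pooling requires at least 2 usable estimates")
    r = np.array([e.wald_ratio for e in estimates])
    w = np.array([1.0 / e.se_ratio ** 2 for e in estimates])
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - beta) ** 2))
    df = len(estimates) - 1
    return IVWResult(beta, se, q, df, float(stats.chi2.sf(q, df)),
                     len(estimates))


def egger_regression(estimates: list[SnpEstimate]
                     ) -> tuple[float, float, float, float]:
    """MR-Egger: weighted regression of outcome on exposure associations
    with a free intercept (directional-pleiotropy check).

    Returns ``(slope, se_slope, intercept, se_intercept)``.  Weights are
    ``1/se_outcome^2``; associations are oriented so exposure betas are
    positive.
    """
    if len(estimates) < 3:
        raise ValueError("Egger regression requires at least 3 variants")
    bx = np.array([e.beta_exposure for e in estimates])
    by = np.array([e.beta_outcome for e in estimates])
    sy = np.array([e.se_outcome for e in estimates])
    sgn = np.sign(bx)
    bx, by = bx * sgn, by * sgn
    W = np.diag(1.0 / sy ** 2)
    X = np.column_stack([np.ones_like(bx), bx])
    XtWX = X.T @ W @ X
    coef = np.linalg.solve(XtWX, X.T @ W @ by)
    resid = by - X @ coef
    s2 = float(resid @ W @ resid) / max(len(estimates) - 2, 1)
    cov = np.linalg.inv(XtWX) * max(s2, 1.0)  # overdispersed Egger variant
    return (float(coef[1]), float(np.sqrt(cov[1, 1])),
            float(coef[0]), float(np.sqrt(cov[0, 0])))


def estimates_to_frame(estimates: list[SnpEstimate]) -> pd.DataFrame:
    """Forest-plot-ready long format of per-variant estimates."""
    return pd.DataFrame([{
        "variant": e.variant, "beta_exposure": e.beta_exposure,
        "se_exposure": e.se_exposure, "beta_outcome": e.beta_outcome,
        "se_outcome": e.se_outcome, "wald_ratio": e.wald_ratio,
        "se_ratio": e.se_ratio} for e in estimates])
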