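"""Instrumented and multivariable estimation of disease effects on outcomes.

The central estimator is just-identified two-stage least squares with a
polygenic risk score as the single instrument for a binary disease
exposure.  Stage 1 regresses the exposure on the instrument and covariates;
stage 2 regresses the outcome on the fitted exposure and the same
covariates.  The coefficient is computed via the instrumental-variable
closed form ``(Z'X)^-1 Z'y`` (algebraically identical for a just-identified
model), and its standard error is a heteroskedasticity-robust (HC1) IV
sandwich built from residuals that use the *observed* exposure, as required
for correct IV inference.  Under the additive structural mean model the
coefficient is the average change in the outcome caused by having versus
not having the disease.

Estimation is exposed statsmodels-style: ``TwoStageLeastSquares(...)`` /
``LinearModel(...)`` are model objects whose ``fit()`` returns an
``MRResults`` carrying the estimate, robust uncertainty, diagnostics and a
``summary()`` table.  ``fit_2sls`` / ``fit_ols`` are convenience wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, DosageMatrix
from .prs import PRSVector, build_prs

__all__ = [
    "MREstimate", "MRResults", "HausmanResult", "StratumSpec",
    "TwoStageLeastSquares", "LinearModel",
    "fit_2sls", "fit_ols", "hausman_test", "stratified_mr",
    "negative_control", "impute_and_pool", "scale_qaly",
]

Z95 = 1.96  # normal critical value used for all reported 95% intervals


@dataclass(frozen=True)
class MREstimate:
    """Tidy record of one exposure-outcome effect estimate."""

    beta: float
    se: float
    ci95: tuple[float, float]
    first_stage_f: float | None
    n: int
    outcome_label: str
    exposure_label: str
    method: str  # '2sls' or 'ols'

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.method == "2sls" and self.first_stage_f is None:
            raise ValueError("2SLS estimates must carry a first-stage F")
        if self.method == "ols" and self.first_stage_f is not None:
            raise ValueError("OLS estimates carry no first-stage F")


class MRResults:
    """Fit results: point estimate, robust covariance and diagnostics.

    Attributes mirror :class:`MREstimate` (``beta``, ``se``, ``ci95``,
    ``first_stage_f``, ``n``, ...) and additionally expose the full
    coefficient vector ``params``, robust ``cov_params``, ``resid`` and
    ``summary()``.
    """

    def __init__(self, params: np.ndarray, cov: np.ndarray, resid: np.ndarray,
                 n: int, method: str, first_stage_f: float | None,
                 outcome_label: str, exposure_label: str,
                 param_names: list[str]):
        self.params = params
        self.cov_params = cov
        self.resid = resid
        self.n = n
        self.method = method
        self.first_stage_f = first_stage_f
        self.outcome_label = outcome_label
        self.exposure_label = exposure_label
        self.param_names = param_names
        self._j = param_names.index("exposure")

    @property
    def beta(self) -> float:
        return float(self.params[self._j])

    @property
    def se(self) -> float:
        return float(np.sqrt(self.cov_params[self._j, self._j]))

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)

    @property
    def pvalue(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))

    @property
    def estimate(self) -> MREstimate:
        return MREstimate(self.beta, self.se, self.ci95, self.first_stage_f,
                          self.n, self.outcome_label, self.exposure_label,
                          self.method)

    def summary(self) -> pd.DataFrame:
        rows = {"method": self.method, "outcome": self.outcome_label,
                "exposure": self.exposure_label, "n": self.n,
                "beta": self.beta, "se": self.se,
                "ci95_low": self.ci95[0], "ci95_high": self.ci95[1],
                "p": self.pvalue}
        if self.first_stage_f is not None:
            rows["first_stage_f"] = self.first_stage_f
        return pd.DataFrame([rows])

    def __repr__(self) -> str:
        f = (f", F1={self.first_stage_f:.1f}"
             if self.first_stage_f is not None else "")
        return (f"<MRResults {self.method} {self.exposure_label}->"
                f"{self.outcome_label}: beta={self.beta:.4g} "
                f"(se {self.se:.4g}){f}, n={self.n}>")


def _as_design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise ValueError("covariate rows do not match outcome length")
    return c


def _check_full_rank(mat: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise np.linalg.LinAlgError(f"{what} design matrix is rank deficient")


def _hc1_sandwich(A_inv: np.ndarray, Z: np.ndarray, e: np.ndarray,
                  k: int) -> np.ndarray:
    n = Z.shape[0]
    meat = (Z * e[:, None] ** 2).T @ Z
    return A_inv @ meat @ A_inv.T * (n / max(n - k, 1))


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                np.ndarray]:
    """OLS coefficients, residuals and HC1 covariance."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    A_inv = np.linalg.inv(X.T @ X)
    return beta, e, _hc1_sandwich(A_inv, X, e, X.shape[1])


class TwoStageLeastSquares:
    """Just-identified 2SLS of an outcome on an instrumented exposure.

    Parameters
    ----------
    outcome, exposure : arrays of length n
    instrument : array or PRSVector, the single excluded instrument
    covariates : optional (n, p) matrix of included exogenous regressors
        (an intercept is always added internally)
    """

    def __init__(self, outcome, exposure, instrument,
                 covariates=None, outcome_label: str = "outcome",
                 exposure_label: str = "exposure"):
        y = np.asarray(outcome, dtype=float)
        x = np.asarray(exposure, dtype=float)
        z = np.asarray(instrument, dtype=float)
        if not (y.shape == x.shape == z.shape):
            raise ValueError("outcome, exposure and instrument lengths differ")
        if not np.all(np.isfinite(y)):
            raise ValueError("outcome contains non-finite values; drop or "
                             "impute missing data before fitting")
        if np.var(z) == 0.0:
            raise ValueError("instrument has zero variance")
        n = y.size
        C = _as_design(covariates, n)
        ones = np.ones((n, 1))
        self.y = y
        self.X = np.column_stack([ones, x, C])
        self.Z = np.column_stack([ones, z, C])
        self.param_names = (["const", "exposure"]
                            + [f"x{i}" for i in range(C.shape[1])])
        self._x, self._z, self._C = x, z, C
        self.outcome_label = outcome_label
        self.exposure_label = exposure_label

    def _first_stage_f(self) -> float:
        """Robust F for excluding the instrument from stage 1 (single
        instrument: the squared HC1 t-ratio)."""
        beta, e, V = _ols(self._x, self.Z)
        t = beta[1] / np.sqrt(V[1, 1])
        return float(t * t)

    def fit(self) -> MRResults:
        _check_full_rank(self.X, "second-stage")
        _check_full_rank(self.Z, "instrument")
        ZtX = self.Z.T @ self.X
        if abs(np.linalg.det(ZtX)) < 1e-300:
            raise np.linalg.LinAlgError("Z'X is singular: instrument does "
                                        "not identify the exposure")
        A_inv = np.linalg.inv(ZtX)
        params = A_inv @ (self.Z.T @ self.y)
        resid = self.y - self.X @ params  # observed-exposure residuals
        cov = _hc1_sandwich(A_inv, self.Z, resid, self.X.shape[1])
        return MRResults(params, cov, resid, self.y.size, "2sls",
                         self._first_stage_f(), self.outcome_label,
                         self.exposure_label, self.param_names)


class LinearModel:
    """Multivariable linear regression with HC1 robust standard errors."""

    def __init__(self, outcome, exposure, covariates=None,
                 outcome_label: str = "outcome",
                 exposure_label: str = "exposure"):
        y = np.asarray(outcome, dtype=float)
        x = np.asarray(exposure, dtype=float)
        if y.shape != x.shape:
            raise ValueError("outcome and exposure lengths differ")
        if not np.all(np.isfinite(y)):
            raise ValueError("outcome contains non-finite values")
        n = y.size
        C = _as_design(covariates, n)
        self.y = y
        self.X = np.column_stack([np.ones((n, 1)), x, C])
        self.param_names = (["const", "exposure"]
                            + [f"x{i}" for i in range(C.shape[1])])
        self.outcome_label = outcome_label
        self.exposure_label = exposure_label

    def fit(self) -> MRResults:
        _check_full_rank(self.X, "regression")
        params, resid, cov = _ols(self.y, self.X)
        return MRResults(params, cov, resid, self.y.size, "ols", None,
                         self.outcome_label, self.exposure_label,
                         self.param_names)


def fit_2sls(outcome, exposure, instrument, covariates=None,
             outcome_label="outcome", exposure_label="exposure") -> MRResults:
    return TwoStageLeastSquares(outcome, exposure, instrument, covariates,
                                outcome_label, exposure_label).fit()


def fit_ols(outcome, exposure, covariates=None,
            outcome_label="outcome", exposure_label="exposure") -> MRResults:
    return LinearModel(outcome, exposure, covariates,
                       outcome_label, exposure_label).fit()


@dataclass(frozen=True)
class HausmanResult:
    """Endogeneity test contrasting the IV and OLS coefficients."""

    statistic: float
    df: int
    p_value: float


def hausman_test(iv: MRResults | MREstimate,
                 ols: MRResults | MREstimate) -> HausmanResult:
    """Hausman test: ``(b_iv - b_ols)^2 / (se_iv^2 - se_ols^2) ~ chi2(1)``.

    A small p-value is evidence the instrumented and multivariable
    estimates differ, i.e. that the exposure is endogenous.  The variance
    difference is not guaranteed positive in finite samples; a
    non-positive difference is clamped to statistic 0, p 1, with a warning.
    """
    if iv.method != "2sls" or ols.method != "ols":
        raise ValueError("hausman_test expects (2sls, ols) results")
    if (iv.outcome_label != ols.outcome_label
            or iv.exposure_label != ols.exposure_label or iv.n != ols.n):
        raise ValueError("IV and OLS results refer to different fits "
                         f"({iv.outcome_label}/{iv.exposure_label}/n={iv.n} "
                         f"vs {ols.outcome_label}/{ols.exposure_label}/"
                         f"n={ols.n})")
    var_diff = iv.se ** 2 - ols.se ** 2
    diff = iv.beta - ols.beta
    if var_diff <= 0.0:
        if diff != 0.0:
            warnings.warn("Hausman variance difference non-positive; "
                          "statistic clamped to 0", UserWarning)
        return HausmanResult(0.0, 1, 1.0)
    stat = diff ** 2 / var_diff
    return HausmanResult(float(stat), 1, float(stats.chi2.sf(stat, 1)))


@dataclass
class StratumSpec:
    """Partition of the cohort for stratified analyses.

    ``variable`` is ``'sex'``, ``'age_band'`` or the name of a cohort
    column; ``age_bands`` are half-open ``[lo, hi)`` intervals used only
    for ``'age_band'``.
    """

    variable: str
    age_bands: Sequence[tuple[float, float]] = (
        (0, 50), (50, 60), (60, np.inf))

    def labels(self, cohort: Cohort) -> pd.Series:
        if self.variable == "sex":
            return cohort.df["sex"].astype(str)
        if self.variable == "age_band":
            age = cohort.df["age"]
            lab = pd.Series(["?"] * len(cohort), index=cohort.df.index)
            for lo, hi in self.age_bands:
                name = (f"{lo:g}-{hi:g}" if np.isfinite(hi) else f"{lo:g}+")
                lab[(age >= lo) & (age < hi)] = name
            return lab
        if self.variable in cohort.df.columns:
            return cohort.df[self.variable].astype(str)
        raise ValueError(f"unknown stratification variable: "
                         f"{self.variable!r}")


@dataclass
class StratumResult:
    level: str
    result: MRResults | None
    skipped: str | None = None


def _complete_case(cohort: Cohort, outcome: str):
    y = cohort.df[outcome].to_numpy(float)
    return np.isfinite(y)


def stratified_mr(cohort: Cohort, dosages: DosageMatrix,
                  weights: pd.DataFrame, spec: StratumSpec,
                  outcome: str = "annual_cost", scheme: str = "beta",
                  ) -> list[StratumResult]:
    """Per-stratum 2SLS fits with stratum-appropriate covariates.

    Sex is dropped from the adjustment set inside sex strata (it is
    constant there).  Strata violating preconditions (a single exposure
    class, or too few rows) are reported as skipped rather than silently
    dropped.
    """
    prs = build_prs(dosages, weights, scheme)
    labels = spec.labels(cohort)
    out: list[StratumResult] = []
    for level in sorted(labels.unique()):
        mask = (labels == level).to_numpy()
        sub = cohort.subset(mask)
        scores = prs.scores[mask]
        keep = _complete_case(sub, outcome)
        sub_cc = sub.subset(keep)
        scores = scores[keep]
        cancer = sub_cc.df["cancer"].to_numpy(float)
        if len(sub_cc) < 10:
            out.append(StratumResult(level, None, "fewer than 10 complete "
                                                  "cases"))
            continue
        if cancer.min() == cancer.max():
            out.append(StratumResult(level, None,
                                     "single exposure class in stratum"))
            continue
        include_sex = (spec.variable != "sex"
                       and sub_cc.df["sex"].nunique() > 1)
        covs = sub_cc.covariate_matrix(include_sex=include_sex)
        res = fit_2sls(sub_cc.df[outcome].to_numpy(float), cancer, scores,
                       covs, outcome_label=outcome, exposure_label="cancer")
        out.append(StratumResult(level, res))
    return out


def negative_control(cohort: Cohort, prs: PRSVector | np.ndarray,
                     control_sex: str,
                     outcomes: Sequence[str] = ("annual_cost",
                                                "annual_qaly"),
                     ) -> dict[str, MRResults]:
    """Association of a sex-specific cancer's PRS with outcomes in the
    sex that cannot express the cancer.

    Under a valid instrument and generator the expectation is the null.
    Fits OLS of each outcome on the PRS plus covariates (sex dropped, the
    stratum is single-sex).
    """
    if control_sex not in ("male", "female"):
        raise ValueError("control_sex must be 'male' or 'female'")
    scores = np.asarray(prs, dtype=float)
    if scores.size != len(cohort):
        raise ValueError("PRS length does not match cohort")
    mask = (cohort.df["sex"] == control_sex).to_numpy()
    if not mask.any():
        raise ValueError(f"no {control_sex} individuals in cohort; "
                         "negative control undefined")
    sub = cohort.subset(mask)
    scores = scores[mask]
    results: dict[str, MRResults] = {}
    for outcome in outcomes:
        keep = _complete_case(sub, outcome)
        covs = sub.subset(keep).covariate_matrix(include_sex=False)
        results[outcome] = fit_ols(
            sub.df.loc[keep, outcome].to_numpy(float), scores[keep], covs,
            outcome_label=outcome, exposure_label="prs_negative_control")
    return results


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination over multiply imputed data sets."""

    beta: float
    se: float
    ci95: tuple[float, float]
    m: int
    within_variance: float
    between_variance: float
    n: int
    outcome_label: str
    exposure_label: str
    method: str


def impute_and_pool(cohort: Cohort, m: int,
                    fit: Callable[[np.ndarray, Cohort], MRResults],
                    seed: int = 0) -> MRResults | PooledEstimate:
    """Regression imputation of missing costs with Rubin's-rules pooling.

    Each of ``m`` imputations replaces missing annual costs by the
    prediction of a linear model (covariates + disease status) fitted to
    the observed costs, plus a residual resampled with replacement from the
    observed-data residuals.  ``fit(cost, cohort)`` is applied to each
    completed set; the pooled coefficient is the mean of the per-imputation
    coefficients and the pooled variance is ``W + (1 + 1/m) B``.

    With no missing data the single-fit result is returned unchanged.
    """
    if m < 2:
        raise ValueError("at least 2 imputations are required")
    cost = cohort.df["annual_cost"].to_numpy(float)
    miss = ~np.isfinite(cost)
    if not miss.any():
        return fit(cost, cohort)
    if miss.all():
        raise ValueError("no observed costs available to fit the "
                         "imputation model")

    covs = cohort.covariate_matrix()
    design = np.column_stack([np.ones(len(cohort)),
                              cohort.df["cancer"].to_numpy(float), covs])
    obs = ~miss
    coef, *_ = np.linalg.lstsq(design[obs], cost[obs], rcond=None)
    fitted_obs = design[obs] @ coef
    residuals = cost[obs] - fitted_obs
    pred_miss = design[miss] @ coef

    rng = np.random.default_rng(seed)
    betas, variances = [], []
    template = None
    for _ in range(m):
        completed = cost.copy()
        completed[miss] = pred_miss + rng.choice(residuals, miss.sum(),
                                                 replace=True)
        res = fit(completed, cohort)
        template = res
        betas.append(res.beta)
        variances.append(res.se ** 2)
    betas = np.asarray(betas)
    W = float(np.mean(variances))
    B = float(np.var(betas, ddof=1))
    total = W + (1.0 + 1.0 / m) * B
    beta = float(np.mean(betas))
    se = float(np.sqrt(total))
    return PooledEstimate(beta, se, (beta - Z95 * se, beta + Z95 * se), m,
                          W, B, template.n, template.outcome_label,
                          template.exposure_label, template.method)


def scale_qaly(values: np.ndarray | float) -> np.ndarray | float:
    """QALY fractions -> percentage points of a QALY per year (x100)."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("QALY values must be finite")
    out = arr * 100.0
    return float(out) if np.isscalar(values) else out
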