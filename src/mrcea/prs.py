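"""Polygenic risk scores from GWAS weight tables and genotype dosages.

A PRS is the weighted allele count ``score_i = sum_j w_j d_ij`` where the
default weight is the GWAS log-odds ratio itself (scheme ``beta``).  The
alternative scheme ``precision`` weights each log-OR by its inverse
squared SE, for users who read "weighted by the precision with which it
was estimated" literally.  Scores are left unstandardised: just-identified
two-stage least squares point estimates are invariant to affine rescaling
of the instrument, so standardisation would change nothing downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import STRAND_AMBIGUOUS, DosageMatrix

__all__ = ["PRSVector", "build_prs", "pseudo_r2", "write_prs", "read_prs"]

logger = logging.getLogger(__name__)


@dataclass
class PRSVector:
    """Per-individual polygenic score with construction metadata."""

    scores: np.ndarray
    scheme: str
    n_variants: int
    flipped_variants: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PRS contains non-finite values")

    def __len__(self) -> int:
        return self.scores.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.scores, dtype=dtype)


def build_prs(dosages: DosageMatrix, weights: pd.DataFrame,
              scheme: str = "beta") -> PRSVector:
    """Weighted allele-count score, harmonising allele orientation.

    A weight row whose effect allele is the dosage's counted allele uses the
    dosage as-is; the opposite orientation (effect allele equals the other
    allele) recodes d -> 2 - d.  Strand-ambiguous (A/T, C/G) variants are
    accepted unchanged but logged, as strand cannot be resolved from the
    table alone.
    """
    if scheme not in ("beta", "precision"):
        raise ValueError(f"unknown PRS scheme: {scheme!r}")
    missing = [v for v in weights["variant"] if v not in dosages.variant_ids]
    if missing:
        raise ValueError(f"variants in weight table absent from dosages: "
                         f"{missing}")

    w = weights["beta"].to_numpy(float)
    if scheme == "precision":
        w = w / weights["se"].to_numpy(float) ** 2

    scores = np.zeros(dosages.n_individuals)
    flipped: list[str] = []
    counted = dict(zip(dosages.variant_ids, dosages.counted_allele))
    for wj, (_, row) in zip(w, weights.iterrows()):
        vid = row["variant"]
        d = dosages.column(vid)
        pair = frozenset((row["effect_allele"], row["other_allele"]))
        if pair in STRAND_AMBIGUOUS:
            logger.warning("strand-ambiguous variant %s (%s/%s) accepted "
                           "unchanged", vid, row["effect_allele"],
                           row["other_allele"])
        if counted[vid] == row["effect_allele"]:
            scores += wj * d
        elif counted[vid] == row["other_allele"]:
            flipped.append(vid)
            scores += wj * (2.0 - d)
        else:
            raise ValueError(
                f"variant {vid}: counted allele {counted[vid]!r} matches "
                f"neither effect ({row['effect_allele']!r}) nor other "
                f"({row['other_allele']!r}) allele")

    if scores.size > 1 and np.var(scores) == 0.0:
        warnings.warn("PRS has zero variance; downstream first-stage "
                      "F-statistics will be undefined", UserWarning)
    return PRSVector(scores, scheme, len(weights), flipped)


def _logistic_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # stable log-likelihood: sum y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def pseudo_r2(cancer: np.ndarray, prs: PRSVector | np.ndarray,
              tol: float = 1e-8, max_iter: int = 100) -> float:
    """McFadden pseudo-R^2 of a logistic regression of disease on the PRS.

    Fits ``logit P(y=1) = a + b*score`` by iteratively reweighted least
    squares and returns ``1 - l_full / l_null``.  Raises on non-convergence
    or (quasi-)complete separation, which sends coefficients to infinity.
    """
    y = np.asarray(cancer, dtype=float)
    s = np.asarray(prs, dtype=float)
    if y.shape != s.shape:
        raise ValueError("cancer and PRS lengths differ")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both disease classes must be present")

    X = np.column_stack([np.ones_like(s), s])
    beta = np.zeros(2)
    ll_old = _logistic_loglik(y, X @ beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.max(w) < 1e-10 or np.max(np.abs(beta)) > 1e3:
            raise FloatingPointError(
                "logistic fit diverged: complete or quasi-complete "
                "separation between PRS and disease status")
        # IRLS step: weighted least squares on the working response
        Xw = X * w[:, None]
        try:
            step = np.linalg.solve(X.T @ Xw, X.T @ (y - mu))
        except np.linalg.LinAlgError as e:
            raise FloatingPointError(f"IRLS normal equations singular: {e}")
        beta = beta + step
        ll = _logistic_loglik(y, X @ beta)
        if abs(ll - ll_old) < tol * (abs(ll_old) + tol):
            p_bar = y.mean()
            ll_null = _logistic_loglik(y, np.full_like(y, np.log(
                p_bar / (1.0 - p_bar))))
            r2 = 1.0 - ll / ll_null
            return float(min(max(r2, 0.0), 1.0 - 1e-12))
        ll_old = ll
    raise FloatingPointError(f"logistic IRLS did not converge in "
                             f"{max_iter} iterations")


def write_prs(prs: PRSVector, ids: np.ndarray, path) -> None:
    pd.DataFrame({"id": ids, "score": prs.scores}).to_csv(path, index=False)


def read_prs(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if not {"id", "score"} <= set(df.columns):
        raise ValueError("PRS file must have columns id, score")
    return df
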