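"""Synthetic cohort generation under a liability-threshold disease model.

Produces cohorts with the statistical structure that PRS-instrumented
Mendelian randomization assumes: independent biallelic variants whose
dosages raise a latent disease liability, a shared latent confounder that
jointly shifts liability, annual health care costs and annual QALYs,
right-skewed costs, QALYs bounded in [0, 1], and centre-driven
missing-at-random cost data.  Every true parameter is recorded so that
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorParams",
    "Cohort",
    "DosageMatrix",
    "TruthRecord",
    "generate_cohort",
    "inject_pleiotropy",
    "read_weight_table",
    "write_weight_table",
]

_BASES = np.array(list("ACGT"))
# base pairs on opposite strands read identically; flagged downstream
STRAND_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}


@dataclass
class GeneratorParams:
    """Ground-truth parameters of the synthetic data-generating process.

    The liability model is::

        L_i = sum_j G_ij * b_j + c_L * U_i + e_i,   e_i ~ Logistic(0, 1)

    with ``U_i ~ N(0,1)`` a latent confounder, so each ``b_j`` is a genuine
    per-allele log-odds ratio.  Disease status is ``L_i`` above the empirical
    within-sample quantile matching ``prevalence``.  Annual cost is a linear
    age/sex baseline plus ``beta_cost`` for cases, the confounder's cost
    loading, and strictly positive lognormal noise (right-skewed), truncated
    at zero.  Annual QALYs are a linear baseline minus ``|beta_qaly|`` for
    cases plus Gaussian noise, clamped to [0, 1].
    """

    n_individuals: int
    allele_freqs: np.ndarray
    true_log_or: np.ndarray
    prevalence: float = 0.043
    beta_cost: float = 800.0
    beta_qaly: float = -0.05
    confounder_effects: tuple[float, float, float] = (0.5, 400.0, -0.04)
    cost_noise_sd: float = 1200.0
    qaly_noise_sd: float = 0.15
    age_range: tuple[int, int] = (40, 70)
    sex_ratio: float = 0.463  # probability of male
    n_centres: int = 8
    n_pcs: int = 10
    missing_rate: float = 0.0
    sex_specific: str | None = None  # 'male'/'female': other sex never a case
    gwas_se_range: tuple[float, float] = (0.01, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        self.true_log_or = np.asarray(self.true_log_or, dtype=float)
        self.validate()

    @property
    def n_variants(self) -> int:
        return self.allele_freqs.size

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.allele_freqs.size != self.true_log_or.size:
            raise ValueError(
                "allele_freqs and true_log_or must have equal length "
                f"({self.allele_freqs.size} != {self.true_log_or.size})"
            )
        if not np.all((self.allele_freqs > 0) & (self.allele_freqs < 1)):
            raise ValueError("allele_freqs must lie strictly inside (0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.sex_specific not in (None, "male", "female"):
            raise ValueError("sex_specific must be None, 'male' or 'female'")
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must lie in (0, 1)")

    @classmethod
    def realistic(cls, n_individuals: int = 20_000, n_variants: int = 20,
                  seed: int = 0, **overrides) -> "GeneratorParams":
        """Default study conditions: a prostate-cancer-like scenario.

        20 independent common variants (frequencies 0.1-0.5, per-allele
        log-OR ~0.15) explaining roughly 5% of liability variance, 4.3%
        prevalence, and true annual effects of +£800 on costs and -0.05
        QALYs for cases.
        """
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(0.1, 0.5, n_variants)
        betas = rng.uniform(0.10, 0.20, n_variants)
        return cls(n_individuals=n_individuals, allele_freqs=freqs,
                   true_log_or=betas, seed=seed, **overrides)

    def replace(self, **changes) -> "GeneratorParams":
        return dataclasses.replace(self, **changes)


@dataclass
class DosageMatrix:
    """Individuals x variants matrix of allele dosages in [0, 2].

    ``counted_allele`` records which allele each column counts, so that a
    weight table with the opposite orientation can be harmonised by the
    recoding d -> 2 - d.
    """

    values: np.ndarray
    variant_ids: list[str]
    counted_allele: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("dosage values must be 2-D")
        if self.values.shape[1] != len(self.variant_ids):
            raise ValueError("variant_ids length must match column count")
        if np.any((self.values < 0) | (self.values > 2)):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id: {variant_id!r}") from None
        return self.values[:, j]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.variant_ids)
        header = ",".join(f"{v}:{a}" for v, a in
                          zip(self.variant_ids, self.counted_allele))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#counted_alleles={header}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DosageMatrix":
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
            if not first.startswith("#counted_alleles="):
                raise ValueError(f"{path}: missing counted_alleles header")
            pairs = [p.split(":") for p in
                     first.strip().split("=", 1)[1].split(",")]
            df = pd.read_csv(fh, sep="\t")
        return cls(values=df.to_numpy(float),
                   variant_ids=[p[0] for p in pairs],
                   counted_allele=[p[1] for p in pairs])


@dataclass
class Cohort:
    """Per-individual covariates, disease status and annual outcomes.

    Backed by a DataFrame with columns ``id, age, sex, centre,
    pc0..pc{k-1}, cancer, annual_cost, annual_qaly, followup,
    cost_missing``.  Missing costs are NaN with ``cost_missing == 1``.
    """

    df: pd.DataFrame
    n_pcs: int

    REQUIRED = ("id", "age", "sex", "centre", "cancer", "annual_cost",
                "annual_qaly", "followup", "cost_missing")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        q = self.df["annual_qaly"]
        if ((q < 0) | (q > 1)).any():
            raise ValueError("annual_qaly must lie in [0, 1]")
        if (self.df["followup"] <= 0).any():
            raise ValueError("followup must be positive")
        if not self.df["cancer"].isin([0, 1]).all():
            raise ValueError("cancer status must be binary")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pc_columns(self) -> list[str]:
        return [f"pc{i}" for i in range(self.n_pcs)]

    def covariate_matrix(self, include_sex: bool = True,
                         n_pcs: int | None = None) -> np.ndarray:
        """Default adjustment set: age, sex, PCs, centre indicators.

        Centre enters one-hot with the first level dropped; no intercept
        column (model classes add their own).
        """
        k = self.n_pcs if n_pcs is None else min(n_pcs, self.n_pcs)
        cols = [self.df["age"].to_numpy(float)]
        if include_sex:
            cols.append((self.df["sex"] == "male").to_numpy(float))
        for c in self.pc_columns[:k]:
            cols.append(self.df[c].to_numpy(float))
        centres = np.sort(self.df["centre"].unique())
        for c in centres[1:]:
            cols.append((self.df["centre"] == c).to_numpy(float))
        return np.column_stack(cols)

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.df.loc[np.asarray(mask)].reset_index(drop=True),
                      self.n_pcs)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), self.n_pcs)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        df = pd.read_csv(path, comment="#")
        n_pcs = sum(c.startswith("pc") and c[2:].isdigit() for c in df.columns)
        return cls(df, n_pcs)


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort, for parameter-recovery checks."""

    params: GeneratorParams
    realised_prevalence: float
    liability_threshold: float
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self.params)
        d["allele_freqs"] = self.params.allele_freqs.tolist()
        d["true_log_or"] = self.params.true_log_or.tolist()
        payload = {"params": d,
                   "realised_prevalence": self.realised_prevalence,
                   "liability_threshold": self.liability_threshold,
                   "notes": self.notes}
        Path(path).write_text(json.dumps(payload, indent=2))


def _draw_alleles(rng: np.random.Generator, m: int) -> tuple[list[str], list[str]]:
    # avoid complementary (strand-ambiguous) pairs: A/T and C/G variants
    # are routinely excluded when building scores from external weights
    complement = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G
    eff = rng.choice(4, m)
    oth = np.empty(m, dtype=int)
    for i, e in enumerate(eff):
        choices = [b for b in range(4) if b not in (e, complement[e])]
        oth[i] = rng.choice(choices)
    return list(_BASES[eff]), list(_BASES[oth])


def generate_cohort(params: GeneratorParams
                    ) -> tuple[Cohort, DosageMatrix, pd.DataFrame, TruthRecord]:
    """Draw a full synthetic cohort.

    Returns the cohort table, the dosage matrix, a GWAS-style weight table
    (true log-ORs observed with sampling noise at the tabulated SEs) and the
    ground-truth record.  Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, m = params.n_individuals, params.n_variants

    dosages = rng.binomial(2, params.allele_freqs, size=(n, m)).astype(float)
    confounder = rng.standard_normal(n)

    age = rng.integers(params.age_range[0], params.age_range[1] + 1, n)
    sex = np.where(rng.random(n) < params.sex_ratio, "male", "female")
    centre = rng.integers(0, params.n_centres, n)
    pcs = rng.standard_normal((n, params.n_pcs))

    c_liab, c_cost, c_qaly = params.confounder_effects
    liability = (dosages @ params.true_log_or + c_liab * confounder
                 + rng.logistic(0.0, 1.0, n))

    if params.sex_specific is None:
        eligible = np.ones(n, dtype=bool)
    else:
        eligible = sex == params.sex_specific
        if not eligible.any():
            raise ValueError(
                "sex_specific: no individuals of the eligible sex present")
    # empirical quantile within the eligible subset keeps the realised
    # prevalence (among those at risk) close to target even at small n
    threshold = np.quantile(liability[eligible], 1.0 - params.prevalence)
    cancer = (eligible & (liability > threshold)).astype(int)
    n_cases = int(cancer.sum())
    if n_cases == 0 or n_cases == eligible.sum():
        raise ValueError(
            f"prevalence={params.prevalence} produced a degenerate cohort "
            f"({n_cases} cases of {int(eligible.sum())} eligible); "
            "adjust prevalence or n_individuals")

    base_cost = 50.0 + 3.0 * (age - 40) + 30.0 * (sex == "male")
    # lognormal(mu, 1) has sd exp(mu)*sqrt(e*(e-1)); solve mu for target sd
    scale = params.cost_noise_sd / np.sqrt(np.e * (np.e - 1.0))
    cost_noise = rng.lognormal(np.log(scale), 1.0, n)
    annual_cost = np.maximum(
        base_cost + params.beta_cost * cancer + c_cost * confounder
        + cost_noise, 0.0)

    base_q = 0.85 - 0.004 * (age - 40)
    annual_qaly = np.clip(
        base_q - abs(params.beta_qaly) * cancer + c_qaly * confounder
        + rng.normal(0.0, params.qaly_noise_sd, n), 0.0, 1.0)

    followup = np.maximum(rng.normal(8.1, 0.8, n), 0.5)

    # centre-driven MAR: per-centre rates span [0.5, 1.5] x missing_rate
    if params.missing_rate > 0:
        spread = np.linspace(0.5, 1.5, params.n_centres)
        p_centre = np.clip(params.missing_rate * spread, 0.0, 0.97)
        miss = rng.random(n) < p_centre[centre]
    else:
        miss = np.zeros(n, dtype=bool)
    annual_cost = annual_cost.copy()
    annual_cost[miss] = np.nan

    df = pd.DataFrame({"id": np.arange(n), "age": age, "sex": sex,
                       "centre": centre})
    for i in range(params.n_pcs):
        df[f"pc{i}"] = pcs[:, i]
    df["cancer"] = cancer
    df["annual_cost"] = annual_cost
    df["annual_qaly"] = annual_qaly
    df["followup"] = followup
    df["cost_missing"] = miss.astype(int)

    variant_ids = [f"rs{1000 + j}" for j in range(m)]
    eff, oth = _draw_alleles(rng, m)
    se = rng.uniform(*params.gwas_se_range, m)
    beta_obs = params.true_log_or + rng.normal(0.0, se)
    weights = pd.DataFrame({"variant": variant_ids, "effect_allele": eff,
                            "other_allele": oth, "beta": beta_obs, "se": se})

    cohort = Cohort(df, params.n_pcs)
    dmat = DosageMatrix(dosages, variant_ids, list(eff))
    truth = TruthRecord(params, n_cases / float(eligible.sum()),
                        float(threshold))
    return cohort, dmat, weights, truth


def inject_pleiotropy(dosages: DosageMatrix, cohort: Cohort,
                      variant_subset: list[str], direct_effect: float,
                      truth: TruthRecord | None = None) -> Cohort:
    """Add a direct (exclusion-restriction-violating) dosage effect on cost.

    Each listed variant contributes ``direct_effect`` GBP/year per counted
    allele to annual cost, bypassing disease status.  Returns a modified
    copy; the original cohort is untouched.
    """
    unknown = [v for v in variant_subset if v not in dosages.variant_ids]
    if unknown:
        raise KeyError(f"unknown variant ids: {unknown}")
    out = cohort.copy()
    if variant_subset and direct_effect != 0.0:
        extra = np.zeros(dosages.n_individuals)
        for v in variant_subset:
            extra += direct_effect * dosages.column(v)
        out.df["annual_cost"] = out.df["annual_cost"].to_numpy() + extra
    if truth is not None:
        truth.notes.append(
            f"pleiotropy injected: direct_effect={direct_effect} GBP/year "
            f"per allele on {len(variant_subset)} variant(s)")
    return out


def write_weight_table(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, sep="\t", index=False)


def read_weight_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"variant", "effect_allele", "other_allele", "beta", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if (df["se"] <= 0).any():
        raise ValueError("weight table SEs must be positive")
    if df["variant"].duplicated().any():
        dup = df.loc[df["variant"].duplicated(), "variant"].tolist()
        raise ValueError(f"duplicate variant ids in weight table: {dup}")
    return df
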