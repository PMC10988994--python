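"""Monte-Carlo cost-effectiveness of a preventative intervention.

Evaluates a population-wide drug that lowers disease odds by a given
odds ratio against a do-nothing comparator.  Three quantities feed the
simulation, each with uncertainty: (1) the baseline proportion of the
population diagnosed (binomial SE), (2) the risk difference implied by
applying the odds ratio to those counts, and (3) the causal effect of the
disease on annual costs and on QALYs (point estimate with 95% CI, e.g.
from the instrumented regressions).  Per draw, the per-person annual cost
change is the drug price plus risk difference times cost effect, the QALY
change is risk difference times QALY effect (in percentage points), and
net monetary benefit is ``threshold x dQALY - dCost``.  Medians and
2.5/97.5 percentiles over draws are reported, together with the annual
drug price at which the median NMB crosses zero.

Odds-ratio uncertainty is drawn on the log scale by default (keeps draws
positive); natural-scale drawing is available via ``or_scale='natural'``.
Cost- and QALY-effect draws are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StratumCounts", "InterventionSpec", "EffectInput", "CEAResult",
    "InterventionModel", "proportion_se", "or_to_risk_difference",
    "run_intervention_sim", "nmb", "annualise_drug_cost",
]

Z95 = 1.96


@dataclass(frozen=True)
class StratumCounts:
    """Cases and totals for one scenario (overall or an age band)."""

    n_cases: int
    n_total: int
    label: str = "all"

    def __post_init__(self):
        if not 0 < self.n_cases < self.n_total:
            raise ValueError(
                f"require 0 < n_cases < n_total, got {self.n_cases}/"
                f"{self.n_total}")


@dataclass(frozen=True)
class InterventionSpec:
    """The hypothetical drug: its odds ratio on disease, price and the
    willingness-to-pay threshold."""

    or_point: float
    or_ci95: tuple[float, float]
    drug_cost_annual: float
    wtp_threshold: float = 20_000.0
    n_draws: int = 10_000
    seed: int = 0
    or_scale: str = "log"  # 'log' or 'natural' draw scale for the OR

    def __post_init__(self):
        if self.or_point <= 0:
            raise ValueError("odds ratio must be positive")
        lo, hi = self.or_ci95
        if not 0 < lo <= hi:
            raise ValueError("OR CI bounds must be positive and ordered")
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        if self.or_scale not in ("log", "natural"):
            raise ValueError("or_scale must be 'log' or 'natural'")


@dataclass(frozen=True)
class EffectInput:
    """Causal effect of the disease on annual cost (GBP/year) and QALYs
    (percentage points of a QALY per year, i.e. the x100 scale)."""

    cost_effect: float
    cost_ci95: tuple[float, float]
    qaly_effect: float
    qaly_ci95: tuple[float, float]
    source: str = "mendelian_randomization"

    def __post_init__(self):
        if self.cost_ci95[0] > self.cost_ci95[1]:
            raise ValueError("cost CI bounds must be ordered")
        if self.qaly_ci95[0] > self.qaly_ci95[1]:
            raise ValueError("QALY CI bounds must be ordered")


def _se_from_ci(lo: float, hi: float) -> float:
    return (hi - lo) / (2.0 * Z95)


@dataclass
class Percentiles:
    median: float
    lo: float
    hi: float

    def __iter__(self):
        yield from (self.median, self.lo, self.hi)


@dataclass
class CEAResult:
    """Per-scenario simulation summary; draw arrays retained for
    diagnostics and plotting."""

    label: str
    source: str
    delta_cost: Percentiles
    delta_qaly: Percentiles
    nmb: Percentiles
    breakeven_price: float
    breakeven_verified: bool
    n_draws: int
    draws: dict = field(default_factory=dict, repr=False)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, p, unit in [
                ("annual_total_cost", self.delta_cost, "GBP/person/year"),
                ("qalys_per_year", self.delta_qaly, "% of a QALY/year"),
                ("net_monetary_benefit", self.nmb, "GBP/person/year")]:
            rows.append({"scenario": self.label, "source": self.source,
                         "outcome": name, "median": p.median,
                         "ci95_low": p.lo, "ci95_high": p.hi, "unit": unit})
        rows.append({"scenario": self.label, "source": self.source,
                     "outcome": "breakeven_annual_price",
                     "median": self.breakeven_price, "ci95_low": np.nan,
                     "ci95_high": np.nan, "unit": "GBP/person/year"})
        return pd.DataFrame(rows)

    def plot_nmb(self, ax=None):
        """Histogram of NMB draws with the median and zero marked."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.draws["nmb"], bins=60, color="#4878a8")
        ax.axvline(self.nmb.median, color="k", lw=1.5, label="median")
        ax.axvline(0.0, color="r", lw=1.0, ls="--", label="NMB = 0")
        ax.set_xlabel("net monetary benefit (GBP/person/year)")
        ax.set_ylabel("draws")
        ax.set_title(f"{self.label} ({self.source})")
        ax.legend()
        return ax


def proportion_se(counts: StratumCounts) -> tuple[float, float]:
    """Proportion of cases and its binomial standard error
    ``sqrt(p(1-p)/N)``."""
    p = counts.n_cases / counts.n_total
    return p, math.sqrt(p * (1.0 - p) / counts.n_total)


def or_to_risk_difference(counts: StratumCounts, odds_ratio: float) -> float:
    """Risk difference implied by applying an odds ratio to baseline counts.

    ``RD = n*OR / (N - n + n*OR) - n/N``: the baseline proportion is moved
    to the odds scale, multiplied by the OR, back-transformed, and the
    baseline subtracted.  Negative for a protective (OR < 1) intervention.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    n, N = counts.n_cases, counts.n_total
    return n * odds_ratio / (N - n + n * odds_ratio) - n / N


def nmb(delta_cost: float, delta_qaly: float, threshold: float) -> float:
    """Net monetary benefit: ``threshold x dQALY - dCost`` (dQALY in QALY
    units, not percentage points)."""
    return threshold * delta_qaly - delta_cost


def annualise_drug_cost(monthly_price: float, months: int = 12) -> float:
    """Annual drug cost from a monthly tariff price (carried unrounded;
    round only for display)."""
    if monthly_price < 0:
        raise ValueError("price must be non-negative")
    return monthly_price * months


class InterventionModel:
    """Monte-Carlo model of the intervention for one scenario.

    ``run()`` (alias ``fit()``) propagates uncertainty in the odds ratio,
    the baseline proportion and both effect estimates through
    ``spec.n_draws`` draws and returns a :class:`CEAResult`.
    """

    def __init__(self, spec: InterventionSpec, effects: EffectInput,
                 counts: StratumCounts):
        self.spec = spec
        self.effects = effects
        self.counts = counts

    def _draws(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        spec, eff, counts = self.spec, self.effects, self.counts
        M = spec.n_draws
        if spec.or_scale == "log":
            se_lor = _se_from_ci(math.log(spec.or_ci95[0]),
                                 math.log(spec.or_ci95[1]))
            or_draws = np.exp(rng.normal(math.log(spec.or_point), se_lor, M))
        else:
            se_or = _se_from_ci(*spec.or_ci95)
            or_draws = np.maximum(rng.normal(spec.or_point, se_or, M), 1e-12)
        p, se_p = proportion_se(counts)
        p_draws = np.clip(rng.normal(p, se_p, M), 1e-12, 1.0 - 1e-12)
        # rescale drawn proportions to counts so the RD formula applies
        n_draws_cases = p_draws * counts.n_total
        N = counts.n_total
        rd = (n_draws_cases * or_draws
              / (N - n_draws_cases + n_draws_cases * or_draws)) - p_draws
        cost = rng.normal(eff.cost_effect, _se_from_ci(*eff.cost_ci95), M)
        qaly = rng.normal(eff.qaly_effect, _se_from_ci(*eff.qaly_ci95), M)
        return {"or": or_draws, "p": p_draws, "rd": rd, "cost_effect": cost,
                "qaly_effect": qaly}

    def run(self, drug_cost_annual: float | None = None) -> CEAResult:
        spec = self.spec
        price = (spec.drug_cost_annual if drug_cost_annual is None
                 else drug_cost_annual)
        rng = np.random.default_rng(spec.seed)
        d = self._draws(rng)
        delta_cost = price + d["rd"] * d["cost_effect"]
        delta_qaly = d["rd"] * d["qaly_effect"]  # percentage points
        nmb_draws = (delta_qaly / 100.0) * spec.wtp_threshold - delta_cost
        d.update(delta_cost=delta_cost, delta_qaly=delta_qaly, nmb=nmb_draws)

        def pct(a: np.ndarray) -> Percentiles:
            return Percentiles(float(np.median(a)),
                               float(np.percentile(a, 2.5)),
                               float(np.percentile(a, 97.5)))

        med_nmb = float(np.median(nmb_draws))
        # NMB draws translate one-for-one with price, so the median NMB
        # crosses zero at price + median NMB; verified by re-running there
        breakeven = price + med_nmb
        verified = abs(float(np.median(
            (delta_qaly / 100.0) * spec.wtp_threshold
            - (breakeven + d["rd"] * d["cost_effect"])))) <= 1.0
        return CEAResult(self.counts.label, self.effects.source,
                         pct(delta_cost), pct(delta_qaly), pct(nmb_draws),
                         breakeven, verified, spec.n_draws, d)

    fit = run


def run_intervention_sim(spec: InterventionSpec, effects: EffectInput,
                         counts: StratumCounts) -> CEAResult:
    return InterventionModel(spec, effects, counts).run()
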