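"""Stage orchestration: simulate -> prs -> mr -> sensitivity -> cea.

Each stage reads its inputs from the artefact directory (or explicit
``paths`` overrides), writes CSV/TSV outputs carrying a header comment
with package version, seed and config hash, and is individually
re-runnable.  A single global seed spawns named per-stage substreams so a
stage rerun in isolation reproduces its output byte-for-byte.  Partial
outputs of a failing stage are removed.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import (CEAResult, EffectInput, InterventionModel,
                  InterventionSpec, StratumCounts, annualise_drug_cost)
from .cohort import (Cohort, DosageMatrix, GeneratorParams, generate_cohort,
                     read_weight_table, write_weight_table)
from .config import ConfigError, PipelineConfig
from .mr import (StratumSpec, fit_2sls, fit_ols, hausman_test,
                 impute_and_pool, scale_qaly, stratified_mr)
from .prs import build_prs, write_prs
from .sensitivity import estimates_to_frame, ivw_pool, per_snp_estimates

__all__ = ["run_pipeline", "STAGES", "stage_seed"]

STAGES = ("simulate", "prs", "mr", "sensitivity", "cea")


def stage_seed(global_seed: int, stage: str) -> int:
    """Named substream: stable per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(global_seed),
                                 zlib.crc32(stage.encode()) & 0x7FFFFFFF])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _header(config: PipelineConfig, stage: str) -> str:
    return (f"# mrcea {__version__} stage={stage} seed={config.seed} "
            f"config_hash={config.config_hash()}\n")


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               stage: str, sep: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header(config, stage))
        df.to_csv(fh, index=False, sep=sep)


def _require(path: Path | None, field_name: str) -> Path:
    if path is None or not Path(path).exists():
        raise ConfigError(f"{field_name}: required input file not found "
                          f"({path})")
    return Path(path)


def _resolve(config: PipelineConfig, outdir: Path, attr: str,
             default_name: str, field_name: str) -> Path:
    override = getattr(config.paths, attr)
    if override is not None:
        return _require(Path(override), field_name)
    return _require(outdir / default_name, field_name)


def _stage_simulate(config: PipelineConfig, outdir: Path) -> list[Path]:
    g = config.generator
    params = GeneratorParams.realistic(
        n_individuals=g.n_individuals, n_variants=g.n_variants,
        seed=stage_seed(config.seed, "simulate"),
        prevalence=g.prevalence, beta_cost=g.beta_cost,
        beta_qaly=g.beta_qaly, confounder_effects=g.confounder_effects,
        cost_noise_sd=g.cost_noise_sd, qaly_noise_sd=g.qaly_noise_sd,
        sex_ratio=g.sex_ratio, n_centres=g.n_centres, n_pcs=g.n_pcs,
        missing_rate=g.missing_rate, sex_specific=g.sex_specific)
    cohort, dosages, weights, truth = generate_cohort(params)
    paths = [outdir / "cohort.csv", outdir / "dosages.tsv",
             outdir / "weights.tsv", outdir / "truth.json"]
    with open(paths[0], "w", encoding="utf-8", newline="") as fh:
        fh.write(_header(config, "simulate"))
        cohort.df.to_csv(fh, index=False)
    dosages.to_tsv(paths[1])
    write_weight_table(weights, paths[2])
    truth.to_json(paths[3])
    return paths


def _stage_prs(config: PipelineConfig, outdir: Path) -> list[Path]:
    dosages = DosageMatrix.from_tsv(
        _resolve(config, outdir, "dosages", "dosages.tsv", "paths.dosages"))
    weights = read_weight_table(
        _resolve(config, outdir, "weights", "weights.tsv", "paths.weights"))
    prs = build_prs(dosages, weights, config.analysis.scheme)
    out = outdir / "prs.csv"
    with open(out, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header(config, "prs"))
        fh.write(f"# scheme={prs.scheme} n_variants={prs.n_variants}\n")
        pd.DataFrame({"id": np.arange(len(prs)),
                      "score": prs.scores}).to_csv(fh, index=False)
    return [out]


def _analysis_frames(config: PipelineConfig, outdir: Path):
    cohort = Cohort.from_csv(
        _resolve(config, outdir, "cohort", "cohort.csv", "paths.cohort"))
    prs_df = pd.read_csv(
        _resolve(config, outdir, "prs", "prs.csv", "paths.prs"), comment="#")
    if len(prs_df) != len(cohort):
        raise ConfigError("paths.prs: PRS length does not match cohort")
    return cohort, prs_df["score"].to_numpy(float)


def _outcome_vector(cohort: Cohort, outcome: str) -> np.ndarray:
    y = cohort.df[outcome].to_numpy(float)
    return scale_qaly(y) if outcome == "annual_qaly" else y


def _stage_mr(config: PipelineConfig, outdir: Path) -> list[Path]:
    cohort, scores = _analysis_frames(config, outdir)
    covs = cohort.covariate_matrix(n_pcs=config.analysis.n_pcs)
    cancer = cohort.df["cancer"].to_numpy(float)
    rows = []
    for outcome in config.analysis.outcomes:
        y = _outcome_vector(cohort, outcome)
        keep = np.isfinite(y)
        if not keep.all() and config.analysis.m_imputations >= 2:
            if outcome == "annual_cost":
                pooled = impute_and_pool(
                    cohort, config.analysis.m_imputations,
                    lambda c, co: fit_2sls(c, cancer, scores, covs,
                                           outcome_label=outcome,
                                           exposure_label="cancer"),
                    seed=stage_seed(config.seed, "mr-impute"))
                rows.append({"outcome": outcome, "exposure": "cancer",
                             "method": "2sls_pooled", "stratum": "all",
                             "beta": pooled.beta, "se": pooled.se,
                             "ci95_low": pooled.ci95[0],
                             "ci95_high": pooled.ci95[1],
                             "first_stage_f": np.nan, "n": pooled.n,
                             "note": f"m={config.analysis.m_imputations}"})
        iv = fit_2sls(y[keep], cancer[keep], scores[keep], covs[keep],
                      outcome_label=outcome, exposure_label="cancer")
        ols = fit_ols(y[keep], cancer[keep], covs[keep],
                      outcome_label=outcome, exposure_label="cancer")
        h = hausman_test(iv, ols)
        for res, method in [(iv, "2sls"), (ols, "ols")]:
            rows.append({"outcome": outcome, "exposure": "cancer",
                         "method": method, "stratum": "all",
                         "beta": res.beta, "se": res.se,
                         "ci95_low": res.ci95[0], "ci95_high": res.ci95[1],
                         "first_stage_f": res.first_stage_f
                         if method == "2sls" else np.nan,
                         "n": res.n,
                         "note": f"hausman_p={h.p_value:.4g}"})
    # stratified sensitivity fits reuse the raw genetic inputs
    if config.analysis.strata:
        dosages = DosageMatrix.from_tsv(
            _resolve(config, outdir, "dosages", "dosages.tsv",
                     "paths.dosages"))
        weights = read_weight_table(
            _resolve(config, outdir, "weights", "weights.tsv",
                     "paths.weights"))
        for var in config.analysis.strata:
            for sr in stratified_mr(cohort, dosages, weights,
                                    StratumSpec(var),
                                    scheme=config.analysis.scheme):
                if sr.result is None:
                    rows.append({"outcome": "annual_cost",
                                 "exposure": "cancer", "method": "2sls",
                                 "stratum": f"{var}={sr.level}",
                                 "beta": np.nan, "se": np.nan,
                                 "ci95_low": np.nan, "ci95_high": np.nan,
                                 "first_stage_f": np.nan, "n": 0,
                                 "note": f"skipped: {sr.skipped}"})
                else:
                    r = sr.result
                    rows.append({"outcome": "annual_cost",
                                 "exposure": "cancer", "method": "2sls",
                                 "stratum": f"{var}={sr.level}",
                                 "beta": r.beta, "se": r.se,
                                 "ci95_low": r.ci95[0],
                                 "ci95_high": r.ci95[1],
                                 "first_stage_f": r.first_stage_f,
                                 "n": r.n, "note": ""})
    out = outdir / "mr_results.csv"
    _write_csv(pd.DataFrame(rows), out, config, "mr")
    return [out]


def _stage_sensitivity(config: PipelineConfig, outdir: Path) -> list[Path]:
    cohort, _ = _analysis_frames(config, outdir)
    dosages = DosageMatrix.from_tsv(
        _resolve(config, outdir, "dosages", "dosages.tsv", "paths.dosages"))
    covs = cohort.covariate_matrix(n_pcs=config.analysis.n_pcs)
    frames, pooled_rows = [], []
    for outcome in config.analysis.outcomes:
        y = _outcome_vector(cohort, outcome)
        sub = cohort.copy()
        sub.df[outcome] = y
        ests = per_snp_estimates(sub, dosages, covs, outcome=outcome)
        frame = estimates_to_frame(ests)
        frame.insert(0, "outcome", outcome)
        frames.append(frame)
        ivw = ivw_pool(ests)
        pooled_rows.append({"outcome": outcome,
                            "beta_pooled": ivw.beta_pooled,
                            "se_pooled": ivw.se_pooled,
                            "q_statistic": ivw.q_statistic,
                            "q_df": ivw.q_df, "q_pvalue": ivw.q_pvalue,
                            "n_snps": ivw.n_snps})
    p1 = outdir / "per_snp_estimates.csv"
    p2 = outdir / "ivw_results.csv"
    _write_csv(pd.concat(frames, ignore_index=True), p1, config,
               "sensitivity")
    _write_csv(pd.DataFrame(pooled_rows), p2, config, "sensitivity")
    return [p1, p2]


def _effects_from_results(path: Path) -> EffectInput:
    df = pd.read_csv(path, comment="#")
    iv = df[(df["method"] == "2sls") & (df["stratum"] == "all")]
    cost = iv[iv["outcome"] == "annual_cost"].iloc[0]
    qaly = iv[iv["outcome"] == "annual_qaly"].iloc[0]
    return EffectInput(float(cost["beta"]),
                       (float(cost["ci95_low"]), float(cost["ci95_high"])),
                       float(qaly["beta"]),
                       (float(qaly["ci95_low"]), float(qaly["ci95_high"])),
                       source="mendelian_randomization")


def _stage_cea(config: PipelineConfig, outdir: Path) -> list[Path]:
    ic = config.intervention
    if ic is None:
        raise ConfigError("intervention: section required for the cea stage")
    counts = StratumCounts(ic.counts.n_cases, ic.counts.n_total,
                           ic.counts.label)
    if ic.effects is not None:
        eff = EffectInput(ic.effects.cost_effect, ic.effects.cost_ci95,
                          ic.effects.qaly_effect, ic.effects.qaly_ci95,
                          ic.effects.source)
    else:
        eff = _effects_from_results(
            _resolve(config, outdir, "mr_results", "mr_results.csv",
                     "paths.mr_results"))
    spec = InterventionSpec(
        ic.or_point, ic.or_ci95,
        annualise_drug_cost(ic.drug_cost_monthly, ic.months_per_year),
        ic.wtp_threshold, ic.n_draws, stage_seed(config.seed, "cea"),
        ic.or_scale)
    result = InterventionModel(spec, eff, counts).run()
    out = outdir / "cea_results.csv"
    _write_csv(result.summary(), out, config, "cea")
    return [out]


_STAGE_FNS = {"simulate": _stage_simulate, "prs": _stage_prs,
              "mr": _stage_mr, "sensitivity": _stage_sensitivity,
              "cea": _stage_cea}


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 stages: tuple[str, ...] = STAGES) -> list[Path]:
    """Run the requested stages in order; returns all written paths.

    On a stage failure its partial outputs are deleted and the error is
    re-raised (the CLI converts this to a nonzero exit status).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in _STAGE_FNS]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    written: list[Path] = []
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            written.extend(_STAGE_FNS[stage](config, outdir))
        except Exception:
            # remove partial outputs of the failing stage only
            for p in _expected_outputs(stage, outdir):
                if p.exists() and p not in written:
                    p.unlink()
            raise
    return written


def _expected_outputs(stage: str, outdir: Path) -> list[Path]:
    names = {"simulate": ["cohort.csv", "dosages.tsv", "weights.tsv",
                          "truth.json"],
             "prs": ["prs.csv"], "mr": ["mr_results.csv"],
             "sensitivity": ["per_snp_estimates.csv", "ivw_results.csv"],
             "cea": ["cea_results.csv"]}
    return [outdir / n for n in names[stage]]
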