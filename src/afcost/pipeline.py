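"""End-to-end orchestration: simulate → clean → cohort → cost → fit → report.

A run is fully described by a :class:`PipelineConfig` (loadable from YAML);
rerunning with the same configuration and seed is bit-identical.  Every stage
writes its artefacts under the run directory together with the resolved
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import (
    build_panel,
    clean_episodes,
    derive_covariates_from_records,
    identify_incident_af,
)
from .costing import aggregate_to_panel
from .design import DesignSpec
from .reporting import cohort_summary, plot_stratified_costs, stratified_cost_table
from .synthetic import (
    default_dgp_params,
    generate_linked_records,
    generate_population,
    inject_data_errors,
    write_streams,
)
from .twopart import bootstrap_ci, fit_sensitivity, fit_two_part, mean_annual_cost

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one analysis run."""

    n_patients: int = 2000
    seed: int = 0
    followup_years: int = 5
    lookback_years: int = 5
    dup_rate: float = 0.02
    transfer_tolerance_days: int = 0
    bootstrap_B: int = 0  # 0 disables the bootstrap
    sector_split: tuple = (0.79, 0.08, 0.07, 0.06)
    gamma_shape: float = 1.2
    include_mortality: bool = True
    age_comorbidity_interaction: bool = True
    mortality_simd_interaction: bool = True
    sensitivity: bool = True
    diagnose: bool = True
    write_figures: bool = True
    outdir: str = "afcost_run"
    #: free-text provenance of the unit costs (recorded, not interpreted)
    tariff_provenance: str = "synthetic amount-coded tariffs"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        if not 0 <= cfg.dup_rate < 1:
            raise ConfigError("dup_rate must be in [0, 1)")
        if cfg.bootstrap_B and cfg.bootstrap_B < 100:
            raise ConfigError("bootstrap_B must be 0 or at least 100")
        split = tuple(cfg.sector_split)
        if len(split) != 4 or abs(sum(split) - 1) > 1e-12 or min(split) < 0:
            raise ConfigError("sector_split must be 4 non-negative proportions summing to 1")
        cfg.sector_split = split
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sector_split"] = list(self.sector_split)
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artefacts under the run dir.

    Stages: generate linked records (with injected duplicates) → clean →
    incident cohort and covariates → patient-year panel → sector costing →
    two-part fit (with AIC comparison and diagnostics) → stratified tables,
    sensitivity refits and optional bootstrap CI.

    Returns a dict with the costed panel, the fit, the summary tables and the
    headline mean annual cost.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    params = default_dgp_params(
        seed=config.seed,
        sector_split=config.sector_split,
        gamma_shape=config.gamma_shape,
    )
    population = generate_population(config.n_patients, params)
    bundle = generate_linked_records(population, params, config.followup_years)
    bundle = inject_data_errors(bundle, config.dup_rate, seed=config.seed + 1)
    write_streams(bundle, outdir / "streams")

    episodes = clean_episodes(bundle.episodes)
    flow = dict(episodes.attrs["cleaning_log"])

    index_events = identify_incident_af(episodes, config.lookback_years)
    flow["cohort_n"] = len(index_events)

    covariates = derive_covariates_from_records(episodes, index_events, population)
    skeleton = build_panel(index_events, covariates, bundle.deaths, config.followup_years)
    flow["excluded_death_before_index"] = skeleton.attrs["excluded_death_before_index"]
    flow["panel_rows"] = len(skeleton)

    from dataclasses import replace as _replace

    costed = aggregate_to_panel(
        skeleton,
        _replace(bundle, episodes=episodes),
        bundle.tariffs,
        config.transfer_tolerance_days,
    )
    costed.to_csv(outdir / "panel.csv", index=False)

    spec = DesignSpec(
        include_mortality=config.include_mortality,
        age_comorbidity_interaction=config.age_comorbidity_interaction,
        mortality_simd_interaction=config.mortality_simd_interaction,
        year_center=int(costed["admission_year"].min()),
    )
    fit = fit_two_part(costed, spec, compare=True, diagnose=config.diagnose)
    mean_cost = mean_annual_cost(costed, fit)

    import numpy as np

    with np.errstate(invalid="ignore"):
        coef_table = pd.DataFrame(
            {
                "probit_coef": fit.probit.params,
                "probit_se": pd.Series(
                    (fit.probit.cov.to_numpy().diagonal()) ** 0.5, index=fit.columns
                ),
                "cost_coef": fit.gamma.params,
                "cost_se": pd.Series(
                    (fit.gamma.cov.to_numpy().diagonal()) ** 0.5, index=fit.columns
                ),
            }
        )
    ci_p = fit.probit.conf_int()
    ci_g = fit.gamma.conf_int()
    coef_table["probit_lo"], coef_table["probit_hi"] = ci_p["lower"], ci_p["upper"]
    coef_table["cost_lo"], coef_table["cost_hi"] = ci_g["lower"], ci_g["upper"]
    coef_table.to_csv(outdir / "coefficients.csv")

    summary = cohort_summary(covariates.merge(
        costed.drop_duplicates("patient_id")[["patient_id", "died_within_5y"]],
        on="patient_id", how="left",
    ))
    tables = {}
    for by in ("sex", "age_group", "comorbidity", "died_within_5y"):
        t = stratified_cost_table(costed, by)
        t.to_csv(outdir / f"costs_by_{by}.csv", index=False)
        tables[by] = t
        if config.write_figures:
            plot_stratified_costs(t, outdir / f"costs_by_{by}.png")

    result = {
        "config": config,
        "panel": costed,
        "fit": fit,
        "mean_annual_cost": mean_cost,
        "cohort_summary": summary,
        "tables": tables,
        "cohort_flow": flow,
        "aic": {
            "gamma_glm": fit.gamma.aic,
            "ols": fit.comparators.ols,
            "log_ols_jacobian": fit.comparators.log_ols_jacobian,
            "best": fit.comparators.best(),
        },
    }

    if config.sensitivity:
        sens = {}
        for status in ("alive", "dead"):
            try:
                _, m = fit_sensitivity(costed, status, spec)
                sens[status] = m
            except ValueError as e:
                sens[status] = None
                logger.warning("sensitivity %s skipped: %s", status, e)
        result["sensitivity_means"] = sens

    if config.bootstrap_B:
        result["bootstrap"] = bootstrap_ci(
            costed, spec, B=config.bootstrap_B, seed=config.seed + 2
        )

    report = {
        "mean_annual_cost": mean_cost,
        "cohort_flow": flow,
        "aic": result["aic"],
        "sensitivity_means": result.get("sensitivity_means"),
        "bootstrap": result.get("bootstrap"),
        "diagnostics": fit.diagnostics.summary() if fit.diagnostics else None,
        "tariff_provenance": config.tariff_provenance,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return result
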