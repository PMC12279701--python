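"""End-to-end orchestration of the workforce model.

Two entry modes exist because the survey microdata are not public while the
published summary tables are:

* ``reference`` mode runs the desk-scale arithmetic from the published
  inputs: regional staffing tables, national and global need estimates.  It
  reproduces the reference-country extrapolation, the global workforce
  scaling, the sensitivity analysis and the prescriber extrapolation.
* ``synthetic`` mode runs the full statistical pipeline on a generated world
  with known truth: simulate surveys, estimate surveyed-country needs with
  binomial CIs, screen and fit the fourth-root mixed model, predict
  prevalence for unsurveyed countries, aggregate to global needs and scale
  the workforce.

All randomness flows from the single root seed, split deterministically per
stage.  Identical configuration and seed give an identical results JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import refdata
from .domains import DOMAINS
from .global_scaling import (
    GlobalNeeds,
    NeedBand,
    WorkforceRequirement,
    aggregate_global_needs,
    required_prescribers,
    required_workforce,
    subset_need_band,
)
from .io import (
    global_needs_frame,
    national_estimate_frame,
    needs_frame,
    requirement_frame,
)
from .prevalence_model import (
    PrevalenceModelFit,
    TransformedObservation,
    fit_mcmc,
    predict_prevalence,
    transform_prevalence,
)
from .survey_needs import NeedsEstimate, prevalence_from_counts, survey_to_needs
from .synthetic_world import SyntheticWorld, SyntheticWorldConfig, generate_synthetic_world, write_fixtures
from .workforce import NationalWorkforceEstimate, extrapolate_national

logger = logging.getLogger("atworkforce")


@dataclass
class MCMCSettings:
    n_iter: int = 13_000
    burn_in: int = 3_000
    n_walkers: int = 40
    convergence_cutoff: float = 1.05


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    mode: str = "reference"  # "reference" | "synthetic"
    synthetic: SyntheticWorldConfig | None = None
    seed: int = 0
    ci_method: str = "clopper-pearson"
    cooks_threshold: float = 0.5
    cooks_max_flagged: int = 2
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    include_residual: bool = True
    aggregation: str = "bound_sum"  # "bound_sum" | "monte_carlo"
    sensitivity_factors: tuple[float, float] = (0.5, 1.5)
    use_true_prevalence: bool = False
    n_prescribers_reference: float | None = None
    prescriber_domains: tuple[str, ...] = ("cognition_communication", "mobility_selfcare")
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("reference", "synthetic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.synthetic is None:
            self.synthetic = SyntheticWorldConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            synth = dict(raw["synthetic"])
            for key in ("true_slopes", "true_workforce_ftepm"):
                if key in synth:
                    synth[key] = {d: tuple(v) for d, v in synth[key].items()}
            for key in ("child_factor_range",):
                if key in synth:
                    synth[key] = tuple(synth[key])
            raw["synthetic"] = SyntheticWorldConfig(**synth)
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            raw["mcmc"] = MCMCSettings(**raw["mcmc"])
        if "sensitivity_factors" in raw:
            raw["sensitivity_factors"] = tuple(raw["sensitivity_factors"])
        if "prescriber_domains" in raw:
            raw["prescriber_domains"] = tuple(raw["prescriber_domains"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    """All artifacts of one pipeline run."""

    config: RunConfig
    workforce_reference: NationalWorkforceEstimate
    reference_needs: list[NeedsEstimate]
    country_needs: list[NeedsEstimate]
    global_needs: GlobalNeeds
    requirement: WorkforceRequirement
    fit: PrevalenceModelFit | None
    world: SyntheticWorld | None
    results: dict[str, Any]
    log: dict[str, Any]


def _stage_seeds(root: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(root)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _requirement_results(req: WorkforceRequirement) -> dict[str, Any]:
    def row(r):
        return {
            "total_mfte": r.w_total / 1e6,
            "total_ci_mfte": [r.w_total_ci[0] / 1e6, r.w_total_ci[1] / 1e6],
            "clinical_mfte": r.w_clinical / 1e6,
            "clinical_ci_mfte": [r.w_clinical_ci[0] / 1e6, r.w_clinical_ci[1] / 1e6],
            "total_ftepm": r.ftepm_total,
            "clinical_ftepm": r.ftepm_clinical,
            "sensitivity_total_mfte": list(v / 1e6 for v in r.sensitivity_total),
            "sensitivity_clinical_mfte": list(v / 1e6 for v in r.sensitivity_clinical),
        }

    out = {d: row(r) for d, r in req.by_domain.items()}
    out["all_domains"] = row(req.all_domains)
    return out


def _config_provenance(config: RunConfig) -> dict[str, Any]:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    return clean(config)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline for the configured mode."""
    log: dict[str, Any] = {"mode": config.mode, "seed": config.seed, "stages": []}
    fit: PrevalenceModelFit | None = None
    world: SyntheticWorld | None = None

    if config.mode == "reference":
        workforce_ref = extrapolate_national(
            refdata.regional_workforce(), refdata.SWEDEN_POPULATION
        )
        reference_needs = refdata.sweden_needs()
        global_rows = refdata.global_needs()
        country_needs = list(reference_needs)
        global_needs = GlobalNeeds(
            by_domain={
                ne.domain: NeedBand(ne.n_need, ne.ci_low, ne.ci_high) for ne in global_rows
            },
            n_countries_surveyed=28,
            n_countries_modeled=161,
        )
        global_population = refdata.GLOBAL_POPULATION
        n_prescribers = (
            refdata.PRESCRIBERS_NATIONAL
            if config.n_prescribers_reference is None
            else config.n_prescribers_reference
        )
        log["stages"].append({"stage": "reference_inputs", "n_domains": len(DOMAINS)})
    else:
        synth_seed, mcmc_seed, predict_seed, agg_seed = _stage_seeds(config.seed)
        synth_config = dataclasses.replace(config.synthetic, seed=synth_seed)
        world = generate_synthetic_world(synth_config)
        ref = world.reference_country
        workforce_ref = extrapolate_national(world.regional_tables, ref.population_total)
        log["stages"].append(
            {
                "stage": "synthetic_world",
                "n_countries": len(world.countries),
                "n_surveyed": sum(c.surveyed for c in world.countries),
            }
        )

        country_needs = []
        if config.use_true_prevalence:
            # oracle passthrough: zero-width intervals around the truth
            for c in world.countries:
                for d in DOMAINS:
                    n = world.true_need(c.country_id, d)
                    country_needs.append(
                        NeedsEstimate(
                            country_id=c.country_id,
                            domain=d,
                            n_need=n,
                            ci_low=n,
                            ci_high=n,
                            source="surveyed" if c.surveyed else "modeled",
                        )
                    )
            log["stages"].append({"stage": "true_prevalence_passthrough"})
        else:
            countries_by_id = {c.country_id: c for c in world.countries}
            observations = []
            for cid, survey in world.surveys.items():
                country = countries_by_id[cid]
                country_needs.extend(survey_to_needs(survey, country, method=config.ci_method))
                for d in DOMAINS:
                    p_hat = prevalence_from_counts(
                        survey.weighted_need_count[d],
                        survey.weighted_total[d],
                        method=config.ci_method,
                    ).p_hat
                    observations.append(
                        TransformedObservation(
                            country_id=cid,
                            domain=d,
                            y=transform_prevalence(p_hat),
                            median_age=country.median_age,
                            hdi=country.hdi,
                        )
                    )
            from .prevalence_model import screen_outliers

            kept, flagged = screen_outliers(
                observations,
                threshold=config.cooks_threshold,
                max_flagged=config.cooks_max_flagged,
            )
            log["stages"].append(
                {
                    "stage": "outlier_screen",
                    "n_observations": len(observations),
                    "n_flagged": len(flagged),
                    "flagged": [
                        {"country_id": o.country_id, "domain": o.domain, "cooks_d": o.influence}
                        for o in flagged
                    ],
                }
            )
            fit = fit_mcmc(
                kept,
                n_iter=config.mcmc.n_iter,
                burn_in=config.mcmc.burn_in,
                seed=mcmc_seed,
                n_walkers=config.mcmc.n_walkers,
                convergence_cutoff=config.mcmc.convergence_cutoff,
            )
            log["stages"].append(
                {
                    "stage": "mcmc_fit",
                    "n_draws": fit.n_draws,
                    "max_rhat": max(fit.rhat.values()),
                    "converged": fit.converged,
                    "warnings": fit.warnings,
                }
            )
            if fit.warnings:
                for w in fit.warnings:
                    logger.warning(w)
            unsurveyed = [c for c in world.countries if not c.surveyed]
            result = predict_prevalence(
                fit, unsurveyed, include_residual=config.include_residual, seed=predict_seed
            )
            log["stages"].append(
                {
                    "stage": "prediction",
                    "n_countries": len(unsurveyed),
                    "n_truncated_negative": result.n_truncated_negative,
                    "n_clipped_above_one": result.n_clipped_above_one,
                }
            )
            for p in result.predictions:
                pop = countries_by_id[p.country_id].population_total
                country_needs.append(
                    NeedsEstimate(
                        country_id=p.country_id,
                        domain=p.domain,
                        n_need=p.p_hat * pop,
                        ci_low=p.ci_low * pop,
                        ci_high=p.ci_high * pop,
                        source="modeled",
                    )
                )

        reference_needs = [ne for ne in country_needs if ne.country_id == ref.country_id]
        global_needs = aggregate_global_needs(
            country_needs, method=config.aggregation, seed=agg_seed
        )
        global_population = sum(c.population_total for c in world.countries)
        n_prescribers = config.n_prescribers_reference

    requirement = required_workforce(
        workforce_ref,
        reference_needs,
        global_needs,
        global_population,
        sensitivity_factors=config.sensitivity_factors,
    )
    if n_prescribers is not None:
        requirement.prescribers_global = required_prescribers(
            n_prescribers,
            subset_need_band(reference_needs, config.prescriber_domains),
            subset_need_band(global_needs.by_domain, config.prescriber_domains),
        )
    log["stages"].append({"stage": "global_scaling", "global_population": global_population})

    results: dict[str, Any] = {
        "config": _config_provenance(config),
        "log": log,
        "workforce_reference": {
            **{
                d: {
                    "total_fte": w.total_fte,
                    "clinical_fte": w.clinical_fte,
                    "total_ftepm": w.total_ftepm,
                    "clinical_ftepm": w.clinical_ftepm,
                }
                for d, w in workforce_ref.domains.items()
            },
            "all_domains": {
                "total_fte": workforce_ref.all_domains.total_fte,
                "clinical_fte": workforce_ref.all_domains.clinical_fte,
                "total_ftepm": workforce_ref.all_domains.total_ftepm,
                "clinical_ftepm": workforce_ref.all_domains.clinical_ftepm,
            },
        },
        "reference_needs": {
            ne.domain: {"n_need": ne.n_need, "ci_low": ne.ci_low, "ci_high": ne.ci_high}
            for ne in reference_needs
        },
        "global_needs": {
            d: {"n_need": b.n_need, "ci_low": b.ci_low, "ci_high": b.ci_high}
            for d, b in global_needs.by_domain.items()
        },
        "workforce_requirement": _requirement_results(requirement),
    }
    if requirement.prescribers_global is not None:
        point, lo, hi = requirement.prescribers_global
        results["prescribers_global"] = {"point": point, "ci_low": lo, "ci_high": hi}

    result = RunResult(
        config=config,
        workforce_reference=workforce_ref,
        reference_needs=reference_needs,
        country_needs=country_needs,
        global_needs=global_needs,
        requirement=requirement,
        fit=fit,
        world=world,
        results=results,
        log=log,
    )
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "results.json").write_text(json.dumps(result.results, indent=1, sort_keys=True))
    national_estimate_frame(result.workforce_reference).to_csv(
        out_dir / "workforce_reference.csv", index=False
    )
    needs_frame(result.country_needs).to_csv(out_dir / "country_needs.csv", index=False)
    global_needs_frame(result.global_needs).to_csv(out_dir / "global_needs.csv", index=False)
    requirement_frame(result.requirement).to_csv(
        out_dir / "workforce_requirement.csv", index=False
    )
    if result.fit is not None:
        result.fit.summary().to_csv(out_dir / "posterior_summary.csv", index=False)
    (out_dir / "report.md").write_text(render_report(result))


def make_fixtures(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the synthetic input CSVs plus the ground-truth sidecar."""
    if config.synthetic is None:
        raise ValueError("make_fixtures requires a synthetic configuration block")
    synth_seed = _stage_seeds(config.seed)[0]
    world = generate_synthetic_world(dataclasses.replace(config.synthetic, seed=synth_seed))
    return write_fixtures(world, out_dir)


def render_report(result: RunResult) -> str:
    """Markdown report mirroring the four output tables.

    Every figure is taken from the results dictionary; the report does no
    arithmetic of its own.
    """
    r = result.results
    lines = [
        "# Assistive-technology workforce model — run report",
        "",
        f"Mode: `{r['config']['mode']}`, seed {r['config']['seed']}.",
        "",
        "## Reference-country workforce (extrapolated)",
        "",
        "| Domain | Total FTE | Total FTEPM | Clinical FTE | Clinical FTEPM |",
        "|---|---|---|---|---|",
    ]
    for d, w in r["workforce_reference"].items():
        lines.append(
            f"| {d} | {w['total_fte']:.1f} | {w['total_ftepm']:.1f} "
            f"| {w['clinical_fte']:.1f} | {w['clinical_ftepm']:.1f} |"
        )
    lines += [
        "",
        "## Global needs (millions of persons)",
        "",
        "| Domain | Need | 95% CI |",
        "|---|---|---|",
    ]
    for d, b in r["global_needs"].items():
        lines.append(
            f"| {d} | {b['n_need'] / 1e6:.1f} | ({b['ci_low'] / 1e6:.1f}; {b['ci_high'] / 1e6:.1f}) |"
        )
    lines += [
        "",
        "## Required global workforce (million FTE)",
        "",
        "| Domain | Total | 95% CI | Clinical | 95% CI | Sensitivity (total) |",
        "|---|---|---|---|---|---|",
    ]
    for d, row in r["workforce_requirement"].items():
        lines.append(
            f"| {d} | {row['total_mfte']:.3g} "
            f"| ({row['total_ci_mfte'][0]:.3g}; {row['total_ci_mfte'][1]:.3g}) "
            f"| {row['clinical_mfte']:.3g} "
            f"| ({row['clinical_ci_mfte'][0]:.3g}; {row['clinical_ci_mfte'][1]:.3g}) "
            f"| ({row['sensitivity_total_mfte'][0]:.3g}; {row['sensitivity_total_mfte'][1]:.3g}) |"
        )
    if "prescribers_global" in r:
        p = r["prescribers_global"]
        lines += [
            "",
            "## Prescribers (head count)",
            "",
            f"Required globally: {p['point'] / 1e6:.1f} million "
            f"(95% CI: {p['ci_low'] / 1e6:.1f}–{p['ci_high'] / 1e6:.1f}).",
        ]
    lines.append("")
    return "\n".join(lines)
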