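"""Synthetic world generator with known ground truth.

The real inputs — household-survey microdata and regional staffing tables —
are not public, so this module generates a complete synthetic study with a
known data-generating process, letting every downstream stage be tested
against ground truth:

* a country panel (populations, age split, median age, HDI) with true
  prevalences of need drawn from the same regression structure the model
  fits: fourth-root-scale linear predictor with domain-specific median-age
  and HDI slopes, domain intercepts and Gaussian noise, back-transformed by
  the fourth power;
* design-weighted household surveys for the surveyed countries (Bernoulli
  need indicators, lognormal design weights, non-integer weighted counts so
  the downstream rounding step is exercised);
* regional staffing tables scaled from a national ground-truth workforce,
  optionally with a shared administrative pool spanning two domains.

Covariates are drawn uniformly over plausible ranges (median age 15–48
years, HDI 0.35–0.97, populations 10^5–1.4x10^9 log-uniform) to cover the
predictor space.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import DOMAINS
from .prevalence_model import CountryRecord
from .survey_needs import SurveySummary
from .workforce import RegionalWorkforce, SharedAdminPool

# Default true coefficients on the fourth-root scale, chosen so prevalences
# span the realistic 0.2%–6% range over the covariate space (matching the
# order of observed national and global prevalences of need per domain).
DEFAULT_TRUE_INTERCEPTS = {
    "cognition_communication": 0.18,
    "hearing": 0.22,
    "mobility_selfcare": 0.30,
    "orthotics_prosthetics": 0.20,
    "vision": 0.17,
}
DEFAULT_TRUE_SLOPES = {
    "cognition_communication": (0.003, 0.05),
    "hearing": (0.005, -0.02),
    "mobility_selfcare": (0.004, 0.02),
    "orthotics_prosthetics": (0.003, -0.03),
    "vision": (0.004, -0.06),
}
# Ground-truth national workforce densities (clinical, admin FTE per million),
# of the same order as a well-resourced provision system.
DEFAULT_TRUE_WORKFORCE_FTEPM = {
    "cognition_communication": (15.5, 1.1),
    "hearing": (88.0, 24.0),
    "mobility_selfcare": (199.0, 68.0),
    "orthotics_prosthetics": (59.0, 14.0),
    "vision": (28.0, 4.0),
}


@dataclass
class SyntheticWorldConfig:
    """Study conditions for the synthetic world."""

    n_surveyed: int = 28
    n_unsurveyed: int = 161
    true_intercepts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_INTERCEPTS)
    )
    true_slopes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {d: tuple(v) for d, v in DEFAULT_TRUE_SLOPES.items()}
    )
    residual_sd: float = 0.02
    survey_n: int = 9_000  # of the order of the real surveys' average size
    weight_dispersion: float = 0.3
    child_factor_range: tuple[float, float] = (0.2, 0.5)
    n_adult_only: int = 2
    n_regions: int = 3
    region_population_fraction: float = 0.089
    true_workforce_ftepm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {d: tuple(v) for d, v in DEFAULT_TRUE_WORKFORCE_FTEPM.items()}
    )
    shared_admin: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_surveyed", "n_unsurveyed", "survey_n", "n_regions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"configuration error: {name} must be positive")
        if self.residual_sd <= 0:
            raise ValueError("configuration error: residual_sd must be positive")
        if self.weight_dispersion < 0:
            raise ValueError("configuration error: weight_dispersion must be non-negative")
        lo, hi = self.child_factor_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("configuration error: child_factor_range must lie within [0, 1]")
        if not 0.0 < self.region_population_fraction <= 1.0:
            raise ValueError(
                "configuration error: region_population_fraction must be in (0, 1]"
            )
        for table_name in ("true_intercepts", "true_slopes", "true_workforce_ftepm"):
            table = getattr(self, table_name)
            missing = set(DOMAINS) - set(table)
            if missing:
                raise ValueError(f"configuration error: {table_name} missing {sorted(missing)}")


@dataclass
class SyntheticWorld:
    """A generated study: panel, truths, surveys and workforce tables."""

    config: SyntheticWorldConfig
    countries: list[CountryRecord]
    true_prevalence: dict[tuple[str, str], float]  # (country_id, domain) -> fraction
    child_factors: dict[str, float]  # adult-only surveyed countries
    surveys: dict[str, SurveySummary] = field(default_factory=dict)
    regional_tables: list[RegionalWorkforce] = field(default_factory=list)
    true_national_workforce: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def reference_country(self) -> CountryRecord:
        """The first surveyed country doubles as the workforce reference."""
        return self.countries[0]

    def true_need(self, country_id: str, domain: str) -> float:
        """Ground-truth persons in need for one country-domain."""
        country = next(c for c in self.countries if c.country_id == country_id)
        p = self.true_prevalence[(country_id, domain)]
        if country_id in self.child_factors:
            cf = self.child_factors[country_id]
            return p * (country.population_18plus + cf * country.population_under18)
        return p * country.population_total

    def true_global_needs(self) -> dict[str, float]:
        """Ground-truth global persons in need, per domain."""
        return {
            d: sum(self.true_need(c.country_id, d) for c in self.countries) for d in DOMAINS
        }


def generate_country_panel(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate the country panel and true prevalences.

    True prevalence is the fourth power of the linear predictor
    ``intercept_d + b_age,d * medAge + b_hdi,d * HDI`` plus Gaussian noise,
    with the transformed value clamped to [0, 1] before back-transforming.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_surveyed + config.n_unsurveyed
    median_age = rng.uniform(15.0, 48.0, n)
    hdi = rng.uniform(0.35, 0.97, n)
    population = np.exp(rng.uniform(np.log(1e5), np.log(1.4e9), n))
    # younger populations have larger under-18 shares
    frac_u18 = np.clip(0.65 - 0.012 * median_age + rng.normal(0.0, 0.02, n), 0.12, 0.55)

    countries: list[CountryRecord] = []
    true_prev: dict[tuple[str, str], float] = {}
    for i in range(n):
        cid = f"C{i:03d}"
        pop = float(np.round(population[i]))
        u18 = float(np.round(pop * frac_u18[i]))
        countries.append(
            CountryRecord(
                country_id=cid,
                population_total=pop,
                population_under18=u18,
                population_18plus=pop - u18,
                median_age=float(median_age[i]),
                hdi=float(hdi[i]),
                surveyed=i < config.n_surveyed,
            )
        )
        for d in DOMAINS:
            b_age, b_hdi = config.true_slopes[d]
            y = (
                config.true_intercepts[d]
                + b_age * median_age[i]
                + b_hdi * hdi[i]
                + rng.normal(0.0, config.residual_sd)
            )
            true_prev[(cid, d)] = float(np.clip(y, 0.0, 1.0) ** 4)

    lo, hi = config.child_factor_range
    n_adult = min(config.n_adult_only, config.n_surveyed)
    child_factors = {
        countries[i].country_id: float(rng.uniform(lo, hi)) for i in range(n_adult)
    }
    return SyntheticWorld(
        config=config,
        countries=countries,
        true_prevalence=true_prev,
        child_factors=child_factors,
    )


def simulate_survey(
    country: CountryRecord,
    true_prevalence: Mapping[str, float],
    survey_n: int,
    weight_dispersion: float,
    seed: int,
    adult_only: bool = False,
    child_factor: float | None = None,
) -> SurveySummary:
    """Simulate one design-weighted household survey.

    Respondents' need indicators are Bernoulli(true prevalence) per domain;
    design weights are lognormal with the stated dispersion, scaled to mean
    one in expectation so weighted totals are non-integer reals near the
    sample size.  With zero dispersion all weights are exactly one.
    """
    if survey_n <= 0:
        raise ValueError("survey_n must be positive")
    for d, p in true_prevalence.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"true prevalence for {d} outside [0, 1]")
    rng = np.random.default_rng(seed)
    if weight_dispersion == 0:
        weights = np.ones(survey_n)
    else:
        weights = rng.lognormal(0.0, weight_dispersion, survey_n)
        weights /= np.exp(weight_dispersion**2 / 2)  # unit mean in expectation
    need_count: dict[str, float] = {}
    total: dict[str, float] = {}
    for d in DOMAINS:
        p = true_prevalence[d]
        indicator = rng.random(survey_n) < p
        need_count[d] = float(np.sum(weights[indicator]))
        total[d] = float(np.sum(weights))
    return SurveySummary(
        country_id=country.country_id,
        weighted_need_count=need_count,
        weighted_total=total,
        adult_only=adult_only,
        child_factor=child_factor if adult_only else None,
    )


def generate_regional_workforce(
    national_truth: Mapping[str, tuple[float, float]],
    national_population: float,
    n_regions: int,
    covered_fraction: float = 0.089,
    shared_admin: bool = False,
    seed: int = 0,
) -> list[RegionalWorkforce]:
    """Regional staffing tables scaled from a national ground truth.

    Each region's per-domain FTE is the national truth times its population
    share, so pooling and re-scaling recovers the truth exactly.  Region
    populations partition ``covered_fraction`` of the national population.
    With ``shared_admin`` the first region pools its hearing and vision
    administrative FTE into one shared pool spanning both domains.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be at least 1")
    rng = np.random.default_rng(seed)
    shares = rng.dirichlet(np.full(n_regions, 5.0)) if n_regions > 1 else np.array([1.0])
    covered = covered_fraction * national_population
    regions: list[RegionalWorkforce] = []
    for r in range(n_regions):
        pop = covered * shares[r]
        ratio = pop / national_population
        clinical = {d: national_truth[d][0] * ratio for d in DOMAINS}
        admin = {d: national_truth[d][1] * ratio for d in DOMAINS}
        pools: list[SharedAdminPool] = []
        if shared_admin and r == 0:
            pool_fte = admin["hearing"] + admin["vision"]
            admin["hearing"] = 0.0
            admin["vision"] = 0.0
            pools.append(SharedAdminPool(pool_fte=pool_fte, domains=("hearing", "vision")))
        regions.append(
            RegionalWorkforce(
                region_id=f"R{r}",
                population=pop,
                clinical_nonclinical_fte=clinical,
                admin_fte=admin,
                shared_admin_pools=pools,
            )
        )
    return regions


def generate_synthetic_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate the full synthetic study: panel, surveys, workforce tables."""
    world = generate_country_panel(config)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_surveyed + 1)
    for i, country in enumerate(c for c in world.countries if c.surveyed):
        adult_only = country.country_id in world.child_factors
        world.surveys[country.country_id] = simulate_survey(
            country,
            {d: world.true_prevalence[(country.country_id, d)] for d in DOMAINS},
            survey_n=config.survey_n,
            weight_dispersion=config.weight_dispersion,
            seed=int(seeds[i].generate_state(1)[0] % (2**31)),
            adult_only=adult_only,
            child_factor=world.child_factors.get(country.country_id),
        )
    ref = world.reference_country
    world.true_national_workforce = {
        d: (
            config.true_workforce_ftepm[d][0] * ref.population_total / 1e6,
            config.true_workforce_ftepm[d][1] * ref.population_total / 1e6,
        )
        for d in DOMAINS
    }
    world.regional_tables = generate_regional_workforce(
        world.true_national_workforce,
        national_population=ref.population_total,
        n_regions=config.n_regions,
        covered_fraction=config.region_population_fraction,
        shared_admin=config.shared_admin,
        seed=int(seeds[-1].generate_state(1)[0] % (2**31)),
    )
    return world


def write_fixtures(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write the three input CSVs plus a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    panel = pd.DataFrame(
        [
            {
                "country_id": c.country_id,
                "population_total": c.population_total,
                "population_under18": c.population_under18,
                "population_18plus": c.population_18plus,
                "median_age": c.median_age,
                "hdi": c.hdi,
                "surveyed": c.surveyed,
            }
            for c in world.countries
        ]
    )
    paths["country_panel"] = out / "country_panel.csv"
    panel.to_csv(paths["country_panel"], index=False)

    surveys = pd.DataFrame(
        [
            {
                "country_id": s.country_id,
                "domain": d,
                "weighted_need_count": s.weighted_need_count[d],
                "weighted_total": s.weighted_total[d],
                "adult_only": s.adult_only,
                "child_factor": s.child_factor if s.adult_only else "",
            }
            for s in world.surveys.values()
            for d in DOMAINS
        ]
    )
    paths["surveys"] = out / "survey_summaries.csv"
    surveys.to_csv(paths["surveys"], index=False)

    workforce_rows = []
    pool_rows = []
    for region in world.regional_tables:
        for d in DOMAINS:
            workforce_rows.append(
                {
                    "region_id": region.region_id,
                    "population": region.population,
                    "domain": d,
                    "clinical_nonclinical_fte": region.clinical_nonclinical_fte.get(d, 0.0),
                    "admin_fte": region.admin_fte.get(d, 0.0),
                }
            )
        for pool in region.shared_admin_pools:
            pool_rows.append(
                {
                    "region_id": region.region_id,
                    "pool_fte": pool.pool_fte,
                    "domains": ";".join(pool.domains),
                }
            )
    paths["regional_workforce"] = out / "regional_workforce.csv"
    pd.DataFrame(workforce_rows).to_csv(paths["regional_workforce"], index=False)
    paths["shared_admin_pools"] = out / "shared_admin_pools.csv"
    pd.DataFrame(pool_rows, columns=["region_id", "pool_fte", "domains"]).to_csv(
        paths["shared_admin_pools"], index=False
    )

    truth = {
        "config": {
            **{k: v for k, v in asdict(world.config).items() if not isinstance(v, dict)},
            "true_intercepts": world.config.true_intercepts,
            "true_slopes": {d: list(v) for d, v in world.config.true_slopes.items()},
            "true_workforce_ftepm": {
                d: list(v) for d, v in world.config.true_workforce_ftepm.items()
            },
        },
        "reference_country": world.reference_country.country_id,
        "true_national_workforce": {
            d: list(v) for d, v in world.true_national_workforce.items()
        },
        "true_global_needs": world.true_global_needs(),
        "child_factors": world.child_factors,
        "true_prevalence": {
            f"{cid}/{d}": p for (cid, d), p in world.true_prevalence.items()
        },
    }
    paths["ground_truth"] = out / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))

    readme = out / "README.md"
    readme.write_text(
        "# Synthetic-world fixtures\n\n"
        "- `country_panel.csv`: country_id, population_total, population_under18, "
        "population_18plus, median_age, hdi, surveyed\n"
        "- `survey_summaries.csv`: country_id, domain, weighted_need_count, "
        "weighted_total, adult_only, child_factor (blank unless adult_only)\n"
        "- `regional_workforce.csv`: region_id, population, domain, "
        "clinical_nonclinical_fte, admin_fte\n"
        "- `shared_admin_pools.csv`: region_id, pool_fte, domains (semicolon-joined)\n"
        "- `ground_truth.json`: generating coefficients, true national workforce, "
        "true prevalences and true global needs, for test assertions\n"
    )
    paths["readme"] = readme
    return paths
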