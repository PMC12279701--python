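"""Global needs aggregation and ratio scaling of the reference workforce.

Per-country need counts are aggregated to global per-domain totals N_G.  The
required global workforce per domain is then

    W_G = W_S * N_G / N_S,

where W_S is the reference country's workforce and N_S its need.  95%
intervals for the ratio are propagated with opposite bounds (numerator lower
bound over denominator upper bound, and vice versa), a conservative rule for
positive quantities.  Global CI aggregation defaults to summing country
bounds; a Monte-Carlo alternative samples each country's need from the
normal distribution implied by its interval (truncated at zero) and takes
percentiles of the summed draws.

A deterministic sensitivity analysis scales the point estimates by
productivity factors (default 0.5 and 1.5) to bracket plausible differences
in workforce productivity across countries.  Prescribers are scaled the same
way, using the summed needs of the domains they cover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .domains import DOMAINS
from .survey_needs import NeedsEstimate
from .workforce import NationalWorkforceEstimate, fte_per_million


@dataclass(frozen=True)
class NeedBand:
    """Point estimate and 95% CI for a number of persons needing products."""

    n_need: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.n_need <= self.ci_high:
            raise ValueError(f"invalid need band ({self.ci_low}, {self.n_need}, {self.ci_high})")


@dataclass
class GlobalNeeds:
    """Global per-domain needs with CIs and provenance counts."""

    by_domain: dict[str, NeedBand]
    n_countries_surveyed: int
    n_countries_modeled: int


@dataclass(frozen=True)
class DomainRequirement:
    """Required workforce for one domain (or the all-domain pool)."""

    w_total: float
    w_total_ci: tuple[float, float]
    w_clinical: float
    w_clinical_ci: tuple[float, float]
    ftepm_total: float
    ftepm_clinical: float
    sensitivity_total: tuple[float, float]
    sensitivity_clinical: tuple[float, float]


@dataclass
class WorkforceRequirement:
    """Required global workforce, per domain and pooled, with prescribers."""

    by_domain: dict[str, DomainRequirement]
    all_domains: DomainRequirement
    global_population: float
    sensitivity_factors: tuple[float, float]
    prescribers_global: tuple[float, float, float] | None = None  # (point, lo, hi)


def _ratio_with_bounds(
    numerator: NeedBand, denominator: NeedBand
) -> tuple[float, float, float]:
    """Point and opposite-bound interval of numerator/denominator."""
    if denominator.n_need <= 0:
        raise ValueError("reference need must be positive (ratio undefined)")
    point = numerator.n_need / denominator.n_need
    low = numerator.ci_low / denominator.ci_high if denominator.ci_high > 0 else 0.0
    high = numerator.ci_high / denominator.ci_low if denominator.ci_low > 0 else np.inf
    return point, low, high


def aggregate_global_needs(
    country_needs: Sequence[NeedsEstimate],
    method: str = "bound_sum",
    n_draws: int = 4_000,
    seed: int = 0,
    domains: tuple[str, ...] = DOMAINS,
) -> GlobalNeeds:
    """Sum per-country needs to global per-domain totals with 95% CIs.

    ``method="bound_sum"`` sums the country CI bounds (conservative);
    ``method="monte_carlo"`` samples each country-domain need independently
    from the normal distribution its interval implies (sd = width/3.92,
    truncated at zero) and reports percentiles of the summed draws.
    """
    seen: set[tuple[str, str]] = set()
    for ne in country_needs:
        key = (ne.country_id, ne.domain)
        if key in seen:
            raise ValueError(f"duplicate country-domain entry {key}")
        seen.add(key)
    countries = {ne.country_id for ne in country_needs}
    for c in countries:
        have = {ne.domain for ne in country_needs if ne.country_id == c}
        missing = set(domains) - have
        if missing:
            raise ValueError(f"country {c} is missing domains {sorted(missing)}")

    by_domain: dict[str, NeedBand] = {}
    rng = np.random.default_rng(seed)
    for d in domains:
        rows = [ne for ne in country_needs if ne.domain == d]
        point = sum(ne.n_need for ne in rows)
        if method == "bound_sum":
            low = sum(ne.ci_low for ne in rows)
            high = sum(ne.ci_high for ne in rows)
        elif method == "monte_carlo":
            total = np.zeros(n_draws)
            for ne in rows:
                sd = (ne.ci_high - ne.ci_low) / 3.92
                total += np.clip(rng.normal(ne.n_need, sd, n_draws), 0.0, None)
            low, high = np.percentile(total, [2.5, 97.5])
            low = min(float(low), point)
            high = max(float(high), point)
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
        by_domain[d] = NeedBand(n_need=point, ci_low=low, ci_high=high)

    surveyed = {ne.country_id for ne in country_needs if ne.source == "surveyed"}
    modeled = countries - surveyed
    return GlobalNeeds(
        by_domain=by_domain,
        n_countries_surveyed=len(surveyed),
        n_countries_modeled=len(modeled),
    )


def required_workforce(
    w_ref: NationalWorkforceEstimate,
    n_ref: Sequence[NeedsEstimate],
    n_global: GlobalNeeds,
    global_population: float,
    sensitivity_factors: tuple[float, float] = (0.5, 1.5),
    domains: tuple[str, ...] = DOMAINS,
) -> WorkforceRequirement:
    """Scale the reference workforce by the global/reference need ratio.

    Applied per domain to the total and to the clinical/non-clinical
    workforce; all-domain figures are sums over domains, and densities are
    relative to the global population.
    """
    ref_needs = {ne.domain: NeedBand(ne.n_need, ne.ci_low, ne.ci_high) for ne in n_ref}
    lo_f, hi_f = sensitivity_factors
    if lo_f <= 0 or hi_f <= 0:
        raise ValueError("sensitivity factors must be positive")

    by_domain: dict[str, DomainRequirement] = {}
    for d in domains:
        ratio, r_lo, r_hi = _ratio_with_bounds(n_global.by_domain[d], ref_needs[d])
        ws = w_ref.domains[d]
        by_domain[d] = DomainRequirement(
            w_total=ws.total_fte * ratio,
            w_total_ci=(ws.total_fte * r_lo, ws.total_fte * r_hi),
            w_clinical=ws.clinical_fte * ratio,
            w_clinical_ci=(ws.clinical_fte * r_lo, ws.clinical_fte * r_hi),
            ftepm_total=fte_per_million(ws.total_fte * ratio, global_population),
            ftepm_clinical=fte_per_million(ws.clinical_fte * ratio, global_population),
            sensitivity_total=(lo_f * ws.total_fte * ratio, hi_f * ws.total_fte * ratio),
            sensitivity_clinical=(lo_f * ws.clinical_fte * ratio, hi_f * ws.clinical_fte * ratio),
        )

    total = sum(r.w_total for r in by_domain.values())
    clinical = sum(r.w_clinical for r in by_domain.values())
    all_domains = DomainRequirement(
        w_total=total,
        w_total_ci=(
            sum(r.w_total_ci[0] for r in by_domain.values()),
            sum(r.w_total_ci[1] for r in by_domain.values()),
        ),
        w_clinical=clinical,
        w_clinical_ci=(
            sum(r.w_clinical_ci[0] for r in by_domain.values()),
            sum(r.w_clinical_ci[1] for r in by_domain.values()),
        ),
        ftepm_total=fte_per_million(total, global_population),
        ftepm_clinical=fte_per_million(clinical, global_population),
        sensitivity_total=(lo_f * total, hi_f * total),
        sensitivity_clinical=(lo_f * clinical, hi_f * clinical),
    )
    return WorkforceRequirement(
        by_domain=by_domain,
        all_domains=all_domains,
        global_population=global_population,
        sensitivity_factors=(lo_f, hi_f),
    )


def sensitivity_bounds(
    requirement: WorkforceRequirement,
    low_factor: float = 0.5,
    high_factor: float = 1.5,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Productivity sensitivity bands: point estimates times the factors."""
    if low_factor <= 0 or high_factor <= 0:
        raise ValueError("sensitivity factors must be positive")
    out: dict[str, dict[str, tuple[float, float]]] = {}
    rows = dict(requirement.by_domain)
    rows["all_domains"] = requirement.all_domains
    for name, row in rows.items():
        out[name] = {
            "total": (low_factor * row.w_total, high_factor * row.w_total),
            "clinical": (low_factor * row.w_clinical, high_factor * row.w_clinical),
        }
    return out


def required_prescribers(
    n_national: float,
    n_ref_subset: NeedBand,
    n_global_subset: NeedBand,
) -> tuple[float, float, float]:
    """Global prescriber head count from the covered-domain need ratio.

    ``n_ref_subset``/``n_global_subset`` are the summed needs over the
    product domains the prescribers cover (cognition & communication plus
    mobility & self-care); the interval uses the same opposite-bound rule as
    the workforce ratio.
    """
    ratio, r_lo, r_hi = _ratio_with_bounds(n_global_subset, n_ref_subset)
    return n_national * ratio, n_national * r_lo, n_national * r_hi


def subset_need_band(
    needs: Sequence[NeedsEstimate] | Mapping[str, NeedBand],
    domains: Sequence[str],
) -> NeedBand:
    """Sum needs (point and bounds) over a subset of domains."""
    if isinstance(needs, Mapping):
        bands = [needs[d] for d in domains]
    else:
        bands = [NeedBand(ne.n_need, ne.ci_low, ne.ci_high) for ne in needs if ne.domain in domains]
    return NeedBand(
        n_need=sum(b.n_need for b in bands),
        ci_low=sum(b.ci_low for b in bands),
        ci_high=sum(b.ci_high for b in bands),
    )
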