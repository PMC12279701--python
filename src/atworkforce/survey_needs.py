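"""Numbers of people needing assistive products from household-survey data.

Household surveys report, per product domain, a design-weighted count of
respondents needing assistive products and a weighted total.  The prevalence
of need is estimated by rounding both weighted counts to integers and
treating them as binomial data; 95% confidence intervals default to the
exact Clopper–Pearson interval, which is conservative and well defined at
the boundaries.  Prevalences and their CI bounds are multiplied by the
country population to give numbers of persons needing products.

Two surveys enrolled adults (18+) only.  For those countries the under-18
prevalence is taken as a country-specific fraction (the *child factor*) of
the adult prevalence, so the need count becomes

    n = p_adult * pop_18plus + child_factor * p_adult * pop_under18,

with CI bounds mapped through the same linear function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statsmodels.stats.proportion import proportion_confint

from .domains import DOMAINS

#: supported binomial CI types -> statsmodels method name
CI_METHODS = {
    "clopper-pearson": "beta",
    "wilson": "wilson",
    "normal": "normal",
}


@dataclass(frozen=True)
class PrevalenceInterval:
    """Point estimate and 95% CI for a prevalence of need, as fractions."""

    p_hat: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0:
            raise ValueError(
                f"invalid prevalence interval ({self.ci_low}, {self.p_hat}, {self.ci_high})"
            )

    def scale(self, factor: float) -> tuple[float, float, float]:
        return self.p_hat * factor, self.ci_low * factor, self.ci_high * factor


@dataclass
class SurveySummary:
    """Weighted survey counts for one country, per product domain."""

    country_id: str
    weighted_need_count: dict[str, float]
    weighted_total: dict[str, float]
    adult_only: bool = False
    child_factor: float | None = None

    def __post_init__(self) -> None:
        for domain, k in self.weighted_need_count.items():
            n = self.weighted_total.get(domain, 0.0)
            if k < 0 or n < 0:
                raise ValueError(f"{self.country_id}/{domain}: negative weighted count")
            if k > n:
                raise ValueError(
                    f"{self.country_id}/{domain}: weighted need count {k} exceeds total {n}"
                )
        if self.adult_only:
            if self.child_factor is None or not 0.0 <= self.child_factor <= 1.0:
                raise ValueError(
                    f"{self.country_id}: adult-only survey requires a child factor in [0, 1]"
                )
        elif self.child_factor is not None:
            raise ValueError(f"{self.country_id}: child factor given for a full-population survey")


@dataclass
class PrevalenceEstimate:
    """Per-domain prevalence-of-need intervals for one country."""

    country_id: str
    by_domain: dict[str, PrevalenceInterval] = field(default_factory=dict)


@dataclass(frozen=True)
class NeedsEstimate:
    """Persons needing assistive products in one country and domain."""

    country_id: str
    domain: str
    n_need: float
    ci_low: float
    ci_high: float
    source: str  # "surveyed" | "modeled"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.n_need <= self.ci_high:
            raise ValueError(
                f"{self.country_id}/{self.domain}: CI ({self.ci_low}, {self.ci_high}) "
                f"does not bracket {self.n_need}"
            )
        if self.source not in ("surveyed", "modeled"):
            raise ValueError(f"unknown source {self.source!r}")


def prevalence_from_counts(
    weighted_need_count: float,
    weighted_total: float,
    method: str = "clopper-pearson",
) -> PrevalenceInterval:
    """Prevalence of need with a 95% binomial CI from weighted counts.

    Both counts are rounded half-to-even to the nearest integer first; the
    rounded pair (k, n) is then treated as an exact binomial observation.
    """
    if weighted_total <= 0:
        raise ValueError("weighted_total must be positive")
    if weighted_need_count > weighted_total:
        raise ValueError("weighted need count exceeds weighted total")
    k = round(weighted_need_count)
    n = round(weighted_total)
    if n == 0:
        raise ValueError("weighted total rounds to zero observations")
    if k > n:
        raise ValueError(f"rounded need count {k} exceeds rounded total {n}")
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}; expected one of {sorted(CI_METHODS)}")
    low, high = proportion_confint(k, n, alpha=0.05, method=CI_METHODS[method])
    p_hat = k / n
    # normal-approximation intervals can escape [0, 1]
    low = min(max(float(low), 0.0), p_hat)
    high = max(min(float(high), 1.0), p_hat)
    return PrevalenceInterval(p_hat=p_hat, ci_low=low, ci_high=high)


def needs_from_prevalence(prev: PrevalenceInterval, country, domain: str) -> NeedsEstimate:
    """Persons needing products in a full-population survey country."""
    population = country.population_total
    if population is None or population <= 0:
        raise ValueError(f"{country.country_id}: missing or non-positive population")
    n, low, high = prev.scale(population)
    return NeedsEstimate(
        country_id=country.country_id,
        domain=domain,
        n_need=n,
        ci_low=low,
        ci_high=high,
        source="surveyed",
    )


def adjust_adult_only(
    prev_adult: PrevalenceInterval, country, child_factor: float, domain: str
) -> NeedsEstimate:
    """Persons needing products where the survey covered adults only.

    The under-18 prevalence is ``child_factor`` times the adult prevalence,
    so the count is a linear map of the adult prevalence and the CI bounds
    transform identically.
    """
    if not 0.0 <= child_factor <= 1.0:
        raise ValueError("child_factor must be in [0, 1]")
    if country.population_18plus is None or country.population_under18 is None:
        raise ValueError(f"{country.country_id}: missing under-18/18+ population split")
    effective_population = country.population_18plus + child_factor * country.population_under18
    n, low, high = prev_adult.scale(effective_population)
    return NeedsEstimate(
        country_id=country.country_id,
        domain=domain,
        n_need=n,
        ci_low=low,
        ci_high=high,
        source="surveyed",
    )


def survey_to_needs(
    summary: SurveySummary,
    country,
    method: str = "clopper-pearson",
    domains: tuple[str, ...] = DOMAINS,
) -> list[NeedsEstimate]:
    """Full conversion of one country's survey summary into need counts."""
    out = []
    for domain in domains:
        prev = prevalence_from_counts(
            summary.weighted_need_count[domain], summary.weighted_total[domain], method=method
        )
        if summary.adult_only:
            out.append(adjust_adult_only(prev, country, summary.child_factor, domain))
        else:
            out.append(needs_from_prevalence(prev, country, domain))
    return out


def survey_prevalences(
    summary: SurveySummary, method: str = "clopper-pearson", domains: tuple[str, ...] = DOMAINS
) -> PrevalenceEstimate:
    """Per-domain prevalence intervals for one country's survey."""
    return PrevalenceEstimate(
        country_id=summary.country_id,
        by_domain={
            d: prevalence_from_counts(
                summary.weighted_need_count[d], summary.weighted_total[d], method=method
            )
            for d in domains
        },
    )
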