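"""National workforce estimates from regional staffing tables.

Regional assistive-technology centres report full-time equivalents (FTE) per
product domain, split into a clinical/non-clinical workforce and an
administrative workforce.  The national workforce W_S is obtained by pooling
the regions and scaling by the population ratio,

    W_S = W_R * P_S / P_R,

where W_R is the pooled regional FTE, P_R the combined regional population
and P_S the national population.  Densities are expressed as FTE per million
population (FTEPM).  Administrative staff shared between two domains' centres
are first allocated proportionally to each domain's workforce, resolved to
integer FTE by largest-remainder rounding.

Prescribers — health professionals who prescribe assistive products as part
of broader duties, outside the provision centres — are head counts, not FTE,
and are extrapolated by the same population ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .domains import DOMAINS


@dataclass(frozen=True)
class SharedAdminPool:
    """Administrative FTE shared between the centres of several domains."""

    pool_fte: float
    domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pool_fte < 0:
            raise ValueError("pool_fte must be non-negative")
        if len(self.domains) < 2:
            raise ValueError("a shared pool must span at least two domains")


@dataclass
class RegionalWorkforce:
    """One region's staffing table: FTE per domain by workforce class."""

    region_id: str
    population: float
    clinical_nonclinical_fte: dict[str, float]
    admin_fte: dict[str, float]
    shared_admin_pools: list[SharedAdminPool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(f"region {self.region_id}: population must be positive")
        for table in (self.clinical_nonclinical_fte, self.admin_fte):
            for domain, fte in table.items():
                if fte < 0:
                    raise ValueError(f"region {self.region_id}: negative FTE for {domain}")

    def resolved_admin_fte(self) -> dict[str, float]:
        """Per-domain admin FTE with shared pools allocated to their domains."""
        admin = dict(self.admin_fte)
        for pool in self.shared_admin_pools:
            weights = {
                d: self.clinical_nonclinical_fte.get(d, 0.0) + self.admin_fte.get(d, 0.0)
                for d in pool.domains
            }
            for domain, fte in allocate_shared_admin(pool.pool_fte, weights).items():
                admin[domain] = admin.get(domain, 0.0) + fte
        return admin

    def total_fte(self, domain: str) -> float:
        return self.clinical_nonclinical_fte.get(domain, 0.0) + self.resolved_admin_fte().get(
            domain, 0.0
        )


@dataclass(frozen=True)
class DomainWorkforce:
    total_fte: float
    clinical_fte: float
    total_ftepm: float
    clinical_ftepm: float


@dataclass
class NationalWorkforceEstimate:
    """Extrapolated national workforce, per domain and all domains pooled."""

    domains: dict[str, DomainWorkforce]
    national_population: float

    @property
    def all_domains(self) -> DomainWorkforce:
        total = sum(d.total_fte for d in self.domains.values())
        clinical = sum(d.clinical_fte for d in self.domains.values())
        return DomainWorkforce(
            total_fte=total,
            clinical_fte=clinical,
            total_ftepm=fte_per_million(total, self.national_population),
            clinical_ftepm=fte_per_million(clinical, self.national_population),
        )


@dataclass(frozen=True)
class PrescriberCount:
    """Head count (persons, not FTE) of assistive-product prescribers."""

    n_prescribers: float
    covered_domains: frozenset[str]
    source_population: float

    def __post_init__(self) -> None:
        if self.n_prescribers < 0:
            raise ValueError("n_prescribers must be non-negative")


def allocate_shared_admin(pool_fte: float, domain_weights: Mapping[str, float]) -> dict[str, int]:
    """Split a shared administrative pool across domains, to whole FTE.

    The pool is allocated proportionally to ``domain_weights`` (typically the
    domains' total workforce) and resolved to non-negative integers summing to
    ``round(pool_fte)`` by the largest-remainder method.  Ties on the
    remainder are broken toward the larger weight, then by domain name.
    """
    if pool_fte < 0:
        raise ValueError("pool_fte must be non-negative")
    if any(w < 0 for w in domain_weights.values()):
        raise ValueError("domain weights must be non-negative")
    total_weight = sum(domain_weights.values())
    total = int(round(pool_fte))
    if total == 0:
        return {d: 0 for d in domain_weights}
    if total_weight == 0:
        raise ValueError("cannot allocate a positive pool with all-zero weights")
    shares = {d: total * w / total_weight for d, w in domain_weights.items()}
    alloc = {d: int(shares[d]) for d in domain_weights}
    remainder = total - sum(alloc.values())
    by_fraction = sorted(
        domain_weights,
        key=lambda d: (shares[d] - alloc[d], domain_weights[d], d),
        reverse=True,
    )
    for d in by_fraction[:remainder]:
        alloc[d] += 1
    return alloc


def fte_per_million(fte: float, population: float) -> float:
    """Workforce density: FTE per million population."""
    if population <= 0:
        raise ValueError("population must be positive")
    return fte * 1e6 / population


def extrapolate_national(
    regional: RegionalWorkforce | Sequence[RegionalWorkforce],
    national_population: float,
    domains: Iterable[str] = DOMAINS,
) -> NationalWorkforceEstimate:
    """Scale pooled regional FTE to the national population.

    Regions are pooled (summed FTE over summed population) before scaling, so
    a single population ratio applies to every domain and workforce class.
    """
    regions = [regional] if isinstance(regional, RegionalWorkforce) else list(regional)
    if not regions:
        raise ValueError("at least one region is required")
    pooled_population = sum(r.population for r in regions)
    if pooled_population <= 0:
        raise ValueError("combined regional population must be positive")
    if national_population < pooled_population:
        raise ValueError("national population cannot be below the combined regional population")
    ratio = national_population / pooled_population

    estimates: dict[str, DomainWorkforce] = {}
    for domain in domains:
        clinical_r = sum(r.clinical_nonclinical_fte.get(domain, 0.0) for r in regions)
        admin_r = sum(r.resolved_admin_fte().get(domain, 0.0) for r in regions)
        total = (clinical_r + admin_r) * ratio
        clinical = clinical_r * ratio
        estimates[domain] = DomainWorkforce(
            total_fte=total,
            clinical_fte=clinical,
            total_ftepm=fte_per_million(total, national_population),
            clinical_ftepm=fte_per_million(clinical, national_population),
        )
    return NationalWorkforceEstimate(domains=estimates, national_population=national_population)


def extrapolate_prescribers(
    counts: PrescriberCount, national_population: float, rounded: bool = False
) -> float:
    """Extrapolate a regional prescriber head count by the population ratio.

    With ``rounded=True`` the result is reported to the nearest thousand
    persons, the precision at which such head counts are meaningful.
    """
    if counts.source_population <= 0:
        raise ValueError("source_population must be positive")
    national = counts.n_prescribers * national_population / counts.source_population
    if rounded:
        return round(national, -3)
    return national
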