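"""Published reference inputs for the workforce model.

The reference country is Sweden, chosen for its high level of access to
assistive products (84% excluding ordinary spectacles) and adequate staffing
at all service levels.  This module carries the published inputs the scaling
model consumes:

* staffing tables from three healthcare regions (full-time equivalents by
  product domain, split into clinical/non-clinical and administrative staff),
* national and regional population figures (July 2023),
* numbers of people needing assistive products, nationally (from the WHO
  rapid assistive technology assessment survey) and globally (survey plus
  regression modelling), with 95% confidence intervals.

Workforce FTE are as printed, to one decimal; needs are in millions of
persons.  All-domain totals are computed from the per-domain rows rather
than stored, so internal arithmetic carries the per-domain precision.
"""

from __future__ import annotations

from .domains import DOMAINS
from .workforce import PrescriberCount, RegionalWorkforce
from .survey_needs import NeedsEstimate

# Populations, July 2023 (persons)
SWEDEN_POPULATION = 10_551_707
SWEDEN_POPULATION_UNDER18 = 2_176_224
SWEDEN_POPULATION_18PLUS = SWEDEN_POPULATION - SWEDEN_POPULATION_UNDER18
SWEDEN_MEDIAN_AGE = 41.0
REGIONS_POPULATION = 936_923  # combined, three surveyed healthcare regions
GLOBAL_POPULATION = 8_091_735_000

# Child-prevalence factors for the two adult-only surveys: the under-18
# prevalence is taken as this fraction of the adult prevalence of need.
CHILD_FACTORS = {"SWE": 0.30, "DOM": 0.40}

# Regional workforce, three healthcare regions pooled, FTE by product domain.
# (total, clinical_nonclinical, admin); totals include the shared
# hearing/vision administrative pool of 6 FTE already allocated 5/1.
_REGIONAL_FTE = {
    "cognition_communication": (15.5, 14.5, 1.0),
    "hearing": (105.3, 82.5, 22.8),
    "mobility_selfcare": (250.5, 186.5, 64.0),
    "orthotics_prosthetics": (68.7, 55.7, 13.0),
    "vision": (30.5, 26.2, 4.3),
}

# National and global numbers of people needing assistive products,
# millions of persons, point estimate with 95% CI (low, high).
_SWEDEN_NEEDS_M = {
    "cognition_communication": (0.40, 0.31, 0.51),
    "hearing": (0.49, 0.39, 0.61),
    "mobility_selfcare": (0.49, 0.39, 0.61),
    "orthotics_prosthetics": (0.079, 0.044, 0.14),
    "vision": (0.050, 0.023, 0.099),
}
_GLOBAL_NEEDS_M = {
    "cognition_communication": (115.5, 108.6, 122.4),
    "hearing": (158.3, 150.0, 166.6),
    "mobility_selfcare": (395.5, 379.7, 411.4),
    "orthotics_prosthetics": (115.6, 108.4, 122.8),
    "vision": (76.5, 71.6, 81.4),
}

# Prescribers of cognition, communication, mobility and self-care products
# working outside the provision centres: 1,500 persons listed in two of the
# three regions, extrapolating to nearly 28,000 nationally.
PRESCRIBER_DOMAINS = ("cognition_communication", "mobility_selfcare")
PRESCRIBERS_NATIONAL = 28_000


def regional_workforce() -> RegionalWorkforce:
    """The pooled three-region staffing table as a single region."""
    return RegionalWorkforce(
        region_id="three_regions_pooled",
        population=REGIONS_POPULATION,
        clinical_nonclinical_fte={d: _REGIONAL_FTE[d][1] for d in DOMAINS},
        admin_fte={d: _REGIONAL_FTE[d][2] for d in DOMAINS},
    )


def sweden_needs() -> list[NeedsEstimate]:
    """Per-domain national needs (persons) for the reference country."""
    return [
        NeedsEstimate(
            country_id="SWE",
            domain=d,
            n_need=_SWEDEN_NEEDS_M[d][0] * 1e6,
            ci_low=_SWEDEN_NEEDS_M[d][1] * 1e6,
            ci_high=_SWEDEN_NEEDS_M[d][2] * 1e6,
            source="surveyed",
        )
        for d in DOMAINS
    ]


def global_needs() -> list[NeedsEstimate]:
    """Per-domain global needs (persons), survey plus regression modelling."""
    return [
        NeedsEstimate(
            country_id="GLOBAL",
            domain=d,
            n_need=_GLOBAL_NEEDS_M[d][0] * 1e6,
            ci_low=_GLOBAL_NEEDS_M[d][1] * 1e6,
            ci_high=_GLOBAL_NEEDS_M[d][2] * 1e6,
            source="modeled",
        )
        for d in DOMAINS
    ]


def prescriber_count() -> PrescriberCount:
    """National prescriber head count with the domains it covers."""
    return PrescriberCount(
        n_prescribers=PRESCRIBERS_NATIONAL,
        covered_domains=frozenset(PRESCRIBER_DOMAINS),
        source_population=SWEDEN_POPULATION,
    )
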