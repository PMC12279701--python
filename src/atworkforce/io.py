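"""CSV readers and writers for the pipeline's tabular interfaces.

All tabular I/O is headered CSV.  Column layouts match the fixture files
documented in the synthetic-world fixtures README.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .global_scaling import GlobalNeeds, WorkforceRequirement
from .prevalence_model import CountryRecord, PrevalencePrediction
from .survey_needs import NeedsEstimate, SurveySummary
from .workforce import NationalWorkforceEstimate, RegionalWorkforce, SharedAdminPool


def read_country_panel(path: str | Path) -> list[CountryRecord]:
    df = pd.read_csv(path)
    return [
        CountryRecord(
            country_id=str(r.country_id),
            population_total=float(r.population_total),
            population_under18=float(r.population_under18),
            population_18plus=float(r.population_18plus),
            median_age=float(r.median_age),
            hdi=float(r.hdi),
            surveyed=bool(r.surveyed),
        )
        for r in df.itertuples()
    ]


def read_surveys(path: str | Path) -> dict[str, SurveySummary]:
    df = pd.read_csv(path)
    out: dict[str, SurveySummary] = {}
    for cid, grp in df.groupby("country_id", sort=False):
        adult_only = bool(grp["adult_only"].iloc[0])
        cf = grp["child_factor"].iloc[0]
        out[str(cid)] = SurveySummary(
            country_id=str(cid),
            weighted_need_count=dict(zip(grp["domain"], grp["weighted_need_count"].astype(float))),
            weighted_total=dict(zip(grp["domain"], grp["weighted_total"].astype(float))),
            adult_only=adult_only,
            child_factor=float(cf) if adult_only and pd.notna(cf) else None,
        )
    return out


def read_regional_workforce(
    path: str | Path, pools_path: str | Path | None = None
) -> list[RegionalWorkforce]:
    df = pd.read_csv(path)
    pools: dict[str, list[SharedAdminPool]] = {}
    if pools_path is not None and Path(pools_path).exists():
        pdf = pd.read_csv(pools_path)
        for r in pdf.itertuples():
            pools.setdefault(str(r.region_id), []).append(
                SharedAdminPool(pool_fte=float(r.pool_fte), domains=tuple(str(r.domains).split(";")))
            )
    regions = []
    for rid, grp in df.groupby("region_id", sort=False):
        regions.append(
            RegionalWorkforce(
                region_id=str(rid),
                population=float(grp["population"].iloc[0]),
                clinical_nonclinical_fte=dict(
                    zip(grp["domain"], grp["clinical_nonclinical_fte"].astype(float))
                ),
                admin_fte=dict(zip(grp["domain"], grp["admin_fte"].astype(float))),
                shared_admin_pools=pools.get(str(rid), []),
            )
        )
    return regions


def national_estimate_frame(estimate: NationalWorkforceEstimate) -> pd.DataFrame:
    rows = []
    items = list(estimate.domains.items()) + [("all_domains", estimate.all_domains)]
    for domain, w in items:
        rows.append(
            {
                "domain": domain,
                "total_fte": round(w.total_fte, 1),
                "total_ftepm": round(w.total_ftepm, 1),
                "clinical_nonclinical_fte": round(w.clinical_fte, 1),
                "clinical_nonclinical_ftepm": round(w.clinical_ftepm, 1),
            }
        )
    return pd.DataFrame(rows)


def needs_frame(needs: Sequence[NeedsEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "country_id": ne.country_id,
                "domain": ne.domain,
                "n_need": round(ne.n_need),
                "ci_low": round(ne.ci_low),
                "ci_high": round(ne.ci_high),
                "source": ne.source,
            }
            for ne in needs
        ]
    )


def predictions_frame(predictions: Sequence[PrevalencePrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "country_id": p.country_id,
                "domain": p.domain,
                "p_hat": p.p_hat,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
            }
            for p in predictions
        ]
    )


def global_needs_frame(needs: GlobalNeeds) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "domain": d,
                "n_need_millions": band.n_need / 1e6,
                "ci_low_millions": band.ci_low / 1e6,
                "ci_high_millions": band.ci_high / 1e6,
            }
            for d, band in needs.by_domain.items()
        ]
    )


def requirement_frame(req: WorkforceRequirement) -> pd.DataFrame:
    rows = []
    items = list(req.by_domain.items()) + [("all_domains", req.all_domains)]
    for domain, r in items:
        rows.append(
            {
                "domain": domain,
                "total_mfte": r.w_total / 1e6,
                "total_ci_low_mfte": r.w_total_ci[0] / 1e6,
                "total_ci_high_mfte": r.w_total_ci[1] / 1e6,
                "total_ftepm": round(r.ftepm_total),
                "clinical_mfte": r.w_clinical / 1e6,
                "clinical_ci_low_mfte": r.w_clinical_ci[0] / 1e6,
                "clinical_ci_high_mfte": r.w_clinical_ci[1] / 1e6,
                "clinical_ftepm": round(r.ftepm_clinical),
                "sensitivity_total_low_mfte": r.sensitivity_total[0] / 1e6,
                "sensitivity_total_high_mfte": r.sensitivity_total[1] / 1e6,
                "sensitivity_clinical_low_mfte": r.sensitivity_clinical[0] / 1e6,
                "sensitivity_clinical_high_mfte": r.sensitivity_clinical[1] / 1e6,
            }
        )
    return pd.DataFrame(rows)
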