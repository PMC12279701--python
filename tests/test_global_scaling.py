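"""Global aggregation, ratio scaling and the productivity sensitivity band."""

import numpy as np
import pytest

from atworkforce import refdata
from atworkforce.domains import DOMAINS
from atworkforce.global_scaling import (
    GlobalNeeds,
    NeedBand,
    aggregate_global_needs,
    required_prescribers,
    required_workforce,
    sensitivity_bounds,
    subset_need_band,
)
from atworkforce.survey_needs import NeedsEstimate
from atworkforce.workforce import extrapolate_national


def make_needs(cid, values, source="surveyed"):
    return [
        NeedsEstimate(cid, d, n, lo, hi, source)
        for d, (n, lo, hi) in zip(DOMAINS, values)
    ]


@pytest.fixture(scope="module")
def reference_requirement():
    w = extrapolate_national(refdata.regional_workforce(), refdata.SWEDEN_POPULATION)
    global_needs = GlobalNeeds(
        by_domain={
            ne.domain: NeedBand(ne.n_need, ne.ci_low, ne.ci_high)
            for ne in refdata.global_needs()
        },
        n_countries_surveyed=28,
        n_countries_modeled=161,
    )
    return required_workforce(
        w, refdata.sweden_needs(), global_needs, refdata.GLOBAL_POPULATION
    )


class TestAggregation:
    def test_single_country_identity(self):
        rows = make_needs("A", [(100.0, 80.0, 130.0)] * 5)
        agg = aggregate_global_needs(rows)
        for d in DOMAINS:
            band = agg.by_domain[d]
            assert (band.n_need, band.ci_low, band.ci_high) == (100.0, 80.0, 130.0)

    def test_bound_summation_adds_interval_widths(self):
        rows = make_needs("A", [(100.0, 90.0, 110.0)] * 5) + make_needs(
            "B", [(50.0, 45.0, 55.0)] * 5
        )
        agg = aggregate_global_needs(rows)
        band = agg.by_domain["hearing"]
        assert band.ci_high - band.ci_low == pytest.approx(20.0 + 10.0)

    def test_duplicate_country_rejected(self):
        rows = make_needs("A", [(1.0, 1.0, 1.0)] * 5)
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_global_needs(rows + rows)

    def test_missing_domain_rejected(self):
        rows = make_needs("A", [(1.0, 1.0, 1.0)] * 5)[:-1]
        with pytest.raises(ValueError, match="missing"):
            aggregate_global_needs(rows)

    def test_monte_carlo_never_wider_than_bound_summation(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(30):
            vals = []
            for _ in DOMAINS:
                n = float(rng.uniform(1e4, 1e6))
                half = float(rng.uniform(0.05, 0.4)) * n
                vals.append((n, n - half, n + half))
            rows.extend(make_needs(f"C{i}", vals))
        bound = aggregate_global_needs(rows, method="bound_sum")
        mc = aggregate_global_needs(rows, method="monte_carlo", seed=1)
        for d in DOMAINS:
            width_bound = bound.by_domain[d].ci_high - bound.by_domain[d].ci_low
            width_mc = mc.by_domain[d].ci_high - mc.by_domain[d].ci_low
            assert width_mc <= width_bound
            assert mc.by_domain[d].n_need == pytest.approx(bound.by_domain[d].n_need)


class TestRequiredWorkforce:
    def test_reproduces_published_cognition_row(self, reference_requirement):
        row = reference_requirement.by_domain["cognition_communication"]
        assert row.w_total / 1e6 == pytest.approx(0.050, abs=0.0005)
        assert row.w_total_ci[0] / 1e6 == pytest.approx(0.037, abs=0.0005)
        assert row.w_total_ci[1] / 1e6 == pytest.approx(0.069, abs=0.0005)

    def test_hearing_row_hand_ratio_oracle(self, reference_requirement):
        # W_S(hearing) x 158.3M / 0.49M with opposite-bound CI
        w = extrapolate_national(refdata.regional_workforce(), refdata.SWEDEN_POPULATION)
        row = reference_requirement.by_domain["hearing"]
        assert row.w_total == pytest.approx(
            w.domains["hearing"].total_fte * 158.3 / 0.49, rel=1e-9
        )
        assert row.w_total / 1e6 == pytest.approx(0.38, abs=0.005)
        assert row.w_total_ci[0] / 1e6 == pytest.approx(0.29, abs=0.005)
        assert row.w_total_ci[1] / 1e6 == pytest.approx(0.51, abs=0.005)

    def test_unit_ratio_returns_reference_workforce(self):
        w = extrapolate_national(refdata.regional_workforce(), refdata.SWEDEN_POPULATION)
        ref_needs = refdata.sweden_needs()
        same = GlobalNeeds(
            by_domain={
                ne.domain: NeedBand(ne.n_need, ne.ci_low, ne.ci_high) for ne in ref_needs
            },
            n_countries_surveyed=1,
            n_countries_modeled=0,
        )
        req = required_workforce(w, ref_needs, same, refdata.SWEDEN_POPULATION)
        for d in DOMAINS:
            assert req.by_domain[d].w_total == pytest.approx(w.domains[d].total_fte)

    def test_all_domain_total_is_sum_of_domains(self, reference_requirement):
        req = reference_requirement
        assert req.all_domains.w_total == pytest.approx(
            sum(r.w_total for r in req.by_domain.values()), rel=1e-12
        )
        assert req.all_domains.w_clinical == pytest.approx(
            sum(r.w_clinical for r in req.by_domain.values()), rel=1e-12
        )

    def test_intervals_bracket_points(self, reference_requirement):
        for row in list(reference_requirement.by_domain.values()) + [
            reference_requirement.all_domains
        ]:
            assert row.w_total_ci[0] <= row.w_total <= row.w_total_ci[1]
            assert row.w_clinical_ci[0] <= row.w_clinical <= row.w_clinical_ci[1]

    def test_scaling_needs_by_k_scales_workforce_by_k(self):
        w = extrapolate_national(refdata.regional_workforce(), refdata.SWEDEN_POPULATION)
        ref_needs = refdata.sweden_needs()
        base = GlobalNeeds(
            by_domain={
                ne.domain: NeedBand(ne.n_need, ne.ci_low, ne.ci_high)
                for ne in refdata.global_needs()
            },
            n_countries_surveyed=28,
            n_countries_modeled=161,
        )
        tripled = GlobalNeeds(
            by_domain={
                d: NeedBand(3 * b.n_need, 3 * b.ci_low, 3 * b.ci_high)
                for d, b in base.by_domain.items()
            },
            n_countries_surveyed=28,
            n_countries_modeled=161,
        )
        r1 = required_workforce(w, ref_needs, base, refdata.GLOBAL_POPULATION)
        r3 = required_workforce(w, ref_needs, tripled, refdata.GLOBAL_POPULATION)
        for d in DOMAINS:
            assert r3.by_domain[d].w_total == pytest.approx(3 * r1.by_domain[d].w_total)

    def test_zero_reference_need_rejected(self):
        w = extrapolate_national(refdata.regional_workforce(), refdata.SWEDEN_POPULATION)
        bad = [
            NeedsEstimate("SWE", d, 0.0, 0.0, 0.0, "surveyed") for d in DOMAINS
        ]
        needs = GlobalNeeds(
            by_domain={d: NeedBand(1.0, 1.0, 1.0) for d in DOMAINS},
            n_countries_surveyed=1,
            n_countries_modeled=0,
        )
        with pytest.raises(ValueError, match="ratio"):
            required_workforce(w, bad, needs, refdata.GLOBAL_POPULATION)


class TestSensitivity:
    def test_published_band(self, reference_requirement):
        bands = sensitivity_bounds(reference_requirement)
        lo, hi = bands["all_domains"]["total"]
        assert lo / 1e6 == pytest.approx(2.2, abs=0.05)
        assert hi / 1e6 == pytest.approx(6.5, abs=0.06)
        clo, chi = bands["all_domains"]["clinical"]
        assert clo / 1e6 == pytest.approx(1.7, abs=0.05)
        assert chi / 1e6 == pytest.approx(5.1, abs=0.05)

    def test_identity_factors(self, reference_requirement):
        bands = sensitivity_bounds(reference_requirement, 1.0, 1.0)
        for name, row in reference_requirement.by_domain.items():
            assert bands[name]["total"] == (row.w_total, row.w_total)

    def test_non_positive_factor_rejected(self, reference_requirement):
        with pytest.raises(ValueError):
            sensitivity_bounds(reference_requirement, 0.0, 1.5)


class TestPrescribers:
    def test_published_global_estimate(self):
        ref = subset_need_band(
            refdata.sweden_needs(), ("cognition_communication", "mobility_selfcare")
        )
        glob = subset_need_band(
            refdata.global_needs(), ("cognition_communication", "mobility_selfcare")
        )
        point, lo, hi = required_prescribers(refdata.PRESCRIBERS_NATIONAL, ref, glob)
        assert point / 1e6 == pytest.approx(16.07, abs=0.1)
        assert lo / 1e6 == pytest.approx(12.3, abs=0.2)
        assert hi / 1e6 == pytest.approx(21.1, abs=0.3)

    def test_unit_ratio_identity_and_linearity(self):
        band = NeedBand(5e5, 4e5, 6e5)
        point, lo, hi = required_prescribers(28_000, band, band)
        assert point == pytest.approx(28_000)
        p2, *_ = required_prescribers(56_000, band, band)
        assert p2 == pytest.approx(2 * point)

    def test_zero_reference_subset_rejected(self):
        with pytest.raises(ValueError):
            required_prescribers(28_000, NeedBand(0.0, 0.0, 0.0), NeedBand(1.0, 1.0, 1.0))
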