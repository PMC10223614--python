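"""Elasticity estimation and matched-pair variance classification."""

import logging

import numpy as np
import pytest

from gutflux.elasticity import (
    ElasticityRecord,
    abundance_parameter,
    compare_pair_variances,
    diet_parameter,
    elasticity,
    elasticity_profile,
    native_step_percent,
)
from gutflux.fba import TradeoffConfig
from gutflux.model import DietSpec, apply_diet, assemble_community, exchange_id
from gutflux.synthetic import (
    DEFAULT_ELASTIC_TAXA,
    EffectSpec,
    SCFA_PANEL,
    TaxonArchetype,
    community_for_sample,
    generate_diet,
    generate_paired_study,
    generate_taxon_model,
)

logging.getLogger("gutflux.model").setLevel(logging.ERROR)


def two_source_community(p=2.0, b0=2.0):
    """Two taxa on separate carbon sources, both secreting acetate.

    The lumen acetate flux is affine in the glucose bound p, giving an
    analytic elasticity p/(p + b0) against which the finite difference is
    checked.
    """
    t1 = generate_taxon_model(TaxonArchetype("t1", "glc", {"ac": 1.0}, growth_yield=0.05))
    t2 = generate_taxon_model(TaxonArchetype("t2", "strch", {"ac": 1.0}, growth_yield=0.05))
    comm = assemble_community([t1, t2], [0.5, 0.5])
    diet = DietSpec(
        "two-source", {exchange_id("glc"): p, exchange_id("strch"): b0}, {}, {},
    )
    return apply_diet(comm, diet)


class TestElasticity:
    def test_native_step_is_ten_and_a_half_percent(self):
        assert round(native_step_percent(0.1), 1) == 10.5

    def test_linear_response_unit_elasticity(self):
        # single taxon, uptake-limited chain: acetate flux proportional to the
        # glucose bound, so the log-derivative is exactly one
        taxon = generate_taxon_model(
            TaxonArchetype("solo", "glc", {"ac": 1.0}, growth_yield=0.05)
        )
        comm = apply_diet(
            assemble_community([taxon], [1.0]),
            DietSpec("p", {exchange_id("glc"): 2.0}, {}, {}),
        )
        rec = elasticity(comm, exchange_id("ac"), diet_parameter("glc"))
        assert rec.defined
        assert rec.elasticity == pytest.approx(1.0, abs=1e-6)
        assert rec.direction == "export"

    def test_forward_difference_first_order_accurate(self):
        # affine flux v = c (a1 p + a2 b0): the discretization error of the
        # forward log-difference halves when the step halves
        comm = two_source_community(p=2.0, b0=2.0)
        exact = 0.5  # p / (p + b0)
        errors = {}
        for h in (0.2, 0.1):
            rec = elasticity(comm, exchange_id("ac"), diet_parameter("glc"), h=h)
            errors[h] = abs(rec.elasticity - exact)
        assert errors[0.1] == pytest.approx(errors[0.2] / 2, rel=0.25)

    def test_flux_pinned_by_diet_ignores_disconnected_taxon(self):
        # the community glucose import saturates its diet bound; bumping the
        # starch specialist's abundance cannot move it
        comm = two_source_community(p=0.5, b0=2.0)
        rec = elasticity(comm, exchange_id("glc"), abundance_parameter("t2"))
        assert rec.defined
        assert rec.elasticity == pytest.approx(0.0, abs=1e-6)
        assert rec.direction == "import"

    def test_zero_baseline_flux_undefined_not_infinite(self):
        comm = two_source_community()
        rec = elasticity(comm, exchange_id("but"), diet_parameter("glc"))
        assert rec.status == "undefined"
        assert rec.elasticity is None

    def test_invalid_step_rejected(self):
        comm = two_source_community()
        with pytest.raises(ValueError):
            elasticity(comm, exchange_id("ac"), diet_parameter("glc"), h=0.0)

    def test_unknown_parameter_rejected(self):
        comm = two_source_community()
        with pytest.raises(ValueError):
            elasticity(comm, exchange_id("ac"), "abundance:nobody")


class TestElasticityProfile:
    def test_panel_cross_product(self):
        comm = two_source_community()
        fluxes = [exchange_id(m) for m in ("ac", "glc", "strch")]
        params = [
            abundance_parameter("t1"), abundance_parameter("t2"),
            diet_parameter("glc"), diet_parameter("strch"),
        ]
        records = elasticity_profile(comm, fluxes, params)
        assert len(records) == 12
        assert all(
            r.elasticity is None or np.isfinite(r.elasticity) for r in records
        )

    def test_reproducible(self):
        comm = two_source_community()
        fluxes = [exchange_id("ac")]
        params = [abundance_parameter("t1"), diet_parameter("glc")]
        a = elasticity_profile(comm, fluxes, params)
        b = elasticity_profile(comm, fluxes, params)
        assert [(r.flux_id, r.parameter_id, r.elasticity) for r in a] == [
            (r.flux_id, r.parameter_id, r.elasticity) for r in b
        ]


def make_profile(values, taxon="T"):
    pid = abundance_parameter(taxon)
    return [
        ElasticityRecord(f"flux{i}", pid, v, "export")
        for i, v in enumerate(values)
    ]


class TestComparePairVariances:
    def test_identical_profiles_same(self):
        prof = make_profile([0.1, 0.5, -0.2, 0.3])
        assert compare_pair_variances(prof, prof, "T").label == "Same"

    def test_wider_adhd_spread_labeled_adhd(self):
        adhd = make_profile([0.9, -0.7, 0.2, -0.4])
        control = make_profile([0.1, 0.2, 0.15, 0.12])
        assert compare_pair_variances(adhd, control, "T").label == "ADHD"
        assert compare_pair_variances(control, adhd, "T").label == "Control"

    def test_absent_taxon_na(self):
        prof = make_profile([0.1, 0.2, 0.3])
        out = compare_pair_variances(prof, prof, "T", control_present=False)
        assert out.label == "NA"

    def test_too_few_defined_na(self):
        thin = make_profile([0.4])
        full = make_profile([0.1, 0.2, 0.3])
        assert compare_pair_variances(thin, full, "T").label == "NA"

    def test_planted_inflation_recovered_in_pipeline(self):
        # the generator's strain-variant mechanism must surface as an ADHD
        # label when profiles come from actual community re-solves
        effect = EffectSpec(elastic_taxa=DEFAULT_ELASTIC_TAXA, seed=5)
        study = generate_paired_study(3, effect=effect)
        diet = generate_diet("western")
        taxon = next(iter(DEFAULT_ELASTIC_TAXA))
        fluxes = [exchange_id(m) for m in SCFA_PANEL]
        params = [abundance_parameter(taxon)]
        labels = []
        for pid in study.pair_ids():
            control, adhd = study.pair_members(pid)
            profiles = {
                sid: elasticity_profile(
                    community_for_sample(study, sid, diet=diet), fluxes, params
                )
                for sid in (control, adhd)
            }
            labels.append(
                compare_pair_variances(profiles[adhd], profiles[control], taxon).label
            )
        assert labels.count("ADHD") >= 2
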