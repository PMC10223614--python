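"""Generators: toy taxon models, diets, paired studies, trees."""

import json

import dendropy
import numpy as np
import pytest

from gutflux import io as gio
from gutflux.fba import fba
from gutflux.model import DietSpec, apply_diet, assemble_community, exchange_id
from gutflux.synthetic import (
    DEFAULT_ROSTER,
    DEFAULT_TAXA,
    EffectSpec,
    TaxonArchetype,
    diet_energy_fractions,
    generate_diet,
    generate_paired_study,
    generate_taxon_model,
    generate_tree,
)


class TestGenerateTaxonModel:
    def test_minimal_producer_grows_and_secretes(self):
        arch = TaxonArchetype("mini", "glc", {"ac": 1.0}, growth_yield=0.1)
        model = generate_taxon_model(arch, size=4)
        sol = fba(model)
        # hand LP: uptake 10 -> conversion 10 -> growth 1.0/h, acetate 10
        assert sol.community_growth == pytest.approx(1.0, rel=1e-8)
        assert sol.fluxes["EX_ac"] == pytest.approx(10.0, rel=1e-8)

    def test_zero_yields_leave_only_backbone_fluxes(self):
        arch = TaxonArchetype("dud", "glc", {"ac": 0.0, "but": 0.0})
        sol = fba(generate_taxon_model(arch))
        nonzero = {rid for rid, v in sol.fluxes.items() if abs(v) > 1e-9}
        assert "EX_ac" not in nonzero and "EX_but" not in nonzero
        assert "EX_glc" in nonzero and "biomass" in nonzero

    def test_deterministic(self):
        arch = DEFAULT_ROSTER["C_comes"]
        a = gio.taxon_to_dict(generate_taxon_model(arch, size=12, seed=5))
        b = gio.taxon_to_dict(generate_taxon_model(arch, size=12, seed=5))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    @pytest.mark.parametrize("size", [8, 15, 30])
    def test_size_and_mass_balance(self, size):
        arch = DEFAULT_ROSTER["B_adolescentis"]
        model = generate_taxon_model(arch, size=size)
        assert len(model.reactions) == size
        # every internal metabolite appears in at least two reactions
        exchange_mets = set(model.exchange_metabolites())
        for met in model.metabolites:
            touching = sum(1 for r in model.reactions if met.id in r.stoichiometry)
            assert touching >= (1 if met.id in exchange_mets else 2)

    def test_declared_exchanges_present(self):
        arch = DEFAULT_ROSTER["R_bromii"]
        model = generate_taxon_model(arch)
        mets = set(model.exchange_metabolites())
        assert mets == {"strch", "ac", "for"}

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="size"):
            generate_taxon_model(TaxonArchetype("x", "glc", {"ac": 1.0}), size=3)

    def test_no_energy_source_rejected(self):
        with pytest.raises(ValueError, match="energy"):
            generate_taxon_model(TaxonArchetype("x", "", {"ac": 1.0}))

    def test_secrete_consume_overlap_rejected(self):
        with pytest.raises(Exception, match="overlap"):
            TaxonArchetype("x", "glc", {"ac": 1.0}, co_substrate_yield={"ac": 0.5})


class TestGeneratePairedStudy:
    def test_matched_pairs_layout(self):
        study = generate_paired_study(10)
        assert len(study.samples) == 20
        assert len(study.pair_ids()) == 10
        for pid in study.pair_ids():
            control, adhd = study.pair_members(pid)
            assert study.metadata.loc[control, "age"] == study.metadata.loc[adhd, "age"]
            assert study.metadata.loc[control, "gender"] == study.metadata.loc[adhd, "gender"]
        np.testing.assert_allclose(study.abundance.sum(axis=1), 1.0, rtol=1e-9)
        assert (study.counts.to_numpy() >= 0).all()

    def test_zero_noise_zero_shift_pairs_identical(self):
        study = generate_paired_study(3, effect=EffectSpec(noise_sd=0.0))
        for pid in study.pair_ids():
            control, adhd = study.pair_members(pid)
            np.testing.assert_allclose(
                study.abundance.loc[control], study.abundance.loc[adhd], rtol=1e-12
            )

    def test_log_shift_realized_exactly_without_noise(self):
        taxon = DEFAULT_TAXA[0]
        other = DEFAULT_TAXA[1]
        effect = EffectSpec(abundance_shifts={taxon: 1.0}, noise_sd=0.0)
        study = generate_paired_study(4, effect=effect)
        for pid in study.pair_ids():
            control, adhd = study.pair_members(pid)
            # renormalization cancels in the double ratio
            double_ratio = (
                study.abundance.loc[adhd, taxon] / study.abundance.loc[control, taxon]
            ) / (study.abundance.loc[adhd, other] / study.abundance.loc[control, other])
            assert double_ratio == pytest.approx(np.e, rel=1e-9)

    def test_empty_taxa_rejected(self):
        with pytest.raises(ValueError):
            generate_paired_study(2, taxa=[])

    def test_seed_reproducible(self):
        a = generate_paired_study(3, effect=EffectSpec(seed=9))
        b = generate_paired_study(3, effect=EffectSpec(seed=9))
        assert a.abundance.equals(b.abundance) and a.counts.equals(b.counts)


class TestDiets:
    def test_atkins_lipid_energy(self):
        fractions = diet_energy_fractions(generate_diet("atkins"))
        assert fractions["lipid"] == pytest.approx(70.0, abs=0.1)
        assert fractions["carbohydrate"] == pytest.approx(1.7, abs=0.1)
        assert fractions["protein"] == pytest.approx(24.0, abs=0.1)

    def test_vegan_fractions(self):
        fractions = diet_energy_fractions(generate_diet("vegan"))
        assert fractions["carbohydrate"] == pytest.approx(63.35, abs=0.1)
        assert fractions["lipid"] == pytest.approx(20.99, abs=0.1)
        assert fractions["protein"] == pytest.approx(15.66, abs=0.1)
        assert sum(fractions.values()) == pytest.approx(100.0)

    @pytest.mark.parametrize("style", ["western", "atkins", "vegan"])
    def test_bounds_non_negative(self, style):
        diet = generate_diet(style)
        assert all(b >= 0 for b in diet.bounds.values())

    @pytest.mark.parametrize("style", ["western", "vegan"])
    def test_minerals_carry_no_energy(self, style):
        diet = generate_diet(style)
        fractions = diet_energy_fractions(diet)
        assert fractions["other"] == pytest.approx(0.0)

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError, match="unknown diet style"):
            generate_diet("carnivore")

    def test_single_nutrient_is_total(self):
        diet = DietSpec("fat", {"EX_ocdca(e)": 5.0}, {"EX_ocdca(e)": "lipid"},
                        {"EX_ocdca(e)": 2.5})
        assert diet_energy_fractions(diet)["lipid"] == pytest.approx(100.0)

    def test_equal_split(self):
        diet = DietSpec(
            "half", {"EX_glc(e)": 2.0, "EX_glu_L(e)": 4.0},
            {"EX_glc(e)": "carbohydrate", "EX_glu_L(e)": "protein"},
            {"EX_glc(e)": 1.0, "EX_glu_L(e)": 0.5},
        )
        fractions = diet_energy_fractions(diet)
        assert fractions["carbohydrate"] == pytest.approx(50.0)
        assert fractions["protein"] == pytest.approx(50.0)

    def test_zero_energy_diet_rejected(self):
        diet = DietSpec("water", {"EX_h2o(e)": 50.0}, {"EX_h2o(e)": "other"},
                        {"EX_h2o(e)": 0.0})
        with pytest.raises(ValueError, match="no energy"):
            diet_energy_fractions(diet)


class TestGenerateTree:
    def test_two_taxa_cherry(self):
        tree = dendropy.Tree.get(data=generate_tree(["A", "B"]), schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"A", "B"}

    def test_leaves_and_branch_lengths(self):
        taxa = [f"t{i}" for i in range(7)]
        tree = dendropy.Tree.get(data=generate_tree(taxa, seed=3), schema="newick")
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        assert sorted(leaves) == sorted(taxa)
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == len(taxa) - 1
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                assert edge.length > 0

    def test_deterministic(self):
        assert generate_tree(DEFAULT_TAXA, seed=7) == generate_tree(DEFAULT_TAXA, seed=7)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            generate_tree(["A", "A", "B"])

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            generate_tree(["A"])
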