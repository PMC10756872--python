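import numpy as np
import pytest
import scipy.stats

from famvar.synthetic_cohort import (
    CohortSpec,
    DECOY_KINDS,
    PlantedVariant,
    add_decoys,
    generate_cohort,
    generate_controls,
    generate_pedigrees,
    mendelian_violations,
    plant_causal,
    transmit_genotypes,
)
from famvar.types import CohortError, PedigreeIndividual, VariantRecord, genotype_dosage


class TestPedigrees:
    def test_study_shape(self):
        ped = generate_pedigrees(CohortSpec(seed=1))
        families = {p.family_id for p in ped}
        assert len(families) == 9
        for fam in families:
            affected = [p for p in ped if p.family_id == fam and p.affected]
            assert all(p.sequenced for p in affected)
            if fam.startswith("M"):
                assert len(affected) >= 2
            else:
                assert len(affected) == 1

    def test_empty_spec_gives_empty_pedigree(self):
        spec = CohortSpec(n_multiplex_families=0, n_sporadic_families=0,
                          n_planted_dominant=0, n_planted_recessive=0, n_decoys=0)
        assert generate_pedigrees(spec) == []

    def test_same_seed_identical(self):
        assert generate_pedigrees(CohortSpec(seed=9)) == generate_pedigrees(CohortSpec(seed=9))

    def test_invalid_family_size_rejected(self):
        with pytest.raises(CohortError):
            CohortSpec(members_per_family=(0, 4))


def trio(n_children=1):
    ped = [
        PedigreeIndividual("T", "dad", sex=1),
        PedigreeIndividual("T", "mom", sex=2),
    ]
    ped += [
        PedigreeIndividual("T", f"kid{i}", father_id="dad", mother_id="mom")
        for i in range(n_children)
    ]
    return ped


class TestTransmission:
    def test_monomorphic_founders_give_monomorphic_children(self):
        d = transmit_genotypes(trio(5), founder_af=0.0, seed=1)
        assert set(d.values()) == {0}
        d = transmit_genotypes(trio(5), founder_af=1.0, seed=1)
        assert set(d.values()) == {2}

    def test_hom_alt_by_hom_ref_always_heterozygous(self):
        # scan seeds until both (2,0) parent configurations are seen
        seen = 0
        for seed in range(400):
            d = transmit_genotypes(trio(3), founder_af=0.5, seed=seed)
            if {d["dad"], d["mom"]} == {0, 2}:
                seen += 1
                assert all(d[f"kid{i}"] == 1 for i in range(3))
        assert seen > 10

    def test_het_cross_segregates_one_two_one(self):
        # a het x het cross over 10,000 children follows the 1:2:1 law
        rng = np.random.default_rng(42)
        ped = trio(10_000)
        # keep redrawing until the founders land het/het under this seed
        while True:
            d = transmit_genotypes(ped, founder_af=0.5, rng=rng)
            if d["dad"] == 1 and d["mom"] == 1:
                break
        counts = np.bincount([d[f"kid{i}"] for i in range(10_000)], minlength=3)
        p = scipy.stats.chisquare(counts, f_exp=[2500, 5000, 2500]).pvalue
        assert p > 0.001

    def test_mendelian_consistency_across_seeds(self):
        ped = generate_pedigrees(CohortSpec(seed=2))
        for seed in range(25):
            d = transmit_genotypes(ped, founder_af=0.3, seed=seed)
            assert mendelian_violations(ped, d) == []

    def test_cyclic_pedigree_rejected(self):
        bad = [
            PedigreeIndividual("F", "a", father_id="b"),
            PedigreeIndividual("F", "b", father_id="a"),
        ]
        with pytest.raises(CohortError, match="cyclic"):
            transmit_genotypes(bad, founder_af=0.1)

    def test_invalid_founder_af_rejected(self):
        with pytest.raises(CohortError):
            transmit_genotypes(trio(), founder_af=1.2)


def planted(model, families, profile="high_impact"):
    v = VariantRecord(chrom="1", pos=1000, ref="G", alt="A", gene="TAD001",
                      impact="HIGH", maf_asn=0.005)
    return PlantedVariant(v, model, tuple(families), profile)


class TestPlanting:
    def test_dominant_all_affected_carry(self):
        ped = generate_pedigrees(CohortSpec(seed=3))
        d = plant_causal(ped, planted("dominant", ["M1"]), penetrance=1.0, seed=0)
        for p in ped:
            if p.family_id == "M1" and p.affected:
                assert d[p.individual_id] >= 1
            elif p.family_id != "M1":
                assert d[p.individual_id] == 0

    def test_recessive_case_is_hom_alt_with_carrier_parents(self):
        ped = generate_pedigrees(CohortSpec(seed=3))
        d = plant_causal(ped, planted("recessive", ["S2"]), penetrance=1.0, seed=0)
        case = next(p for p in ped if p.family_id == "S2" and p.affected)
        assert d[case.individual_id] == 2
        assert d[case.father_id] == 1 and d[case.mother_id] == 1
        assert mendelian_violations(ped, d) == []

    def test_model_family_mismatch_rejected(self):
        ped = generate_pedigrees(CohortSpec(seed=3))
        with pytest.raises(CohortError, match="non-multiplex"):
            plant_causal(ped, planted("dominant", ["S1"]), seed=0)
        with pytest.raises(CohortError, match="non-sporadic"):
            plant_causal(ped, planted("recessive", ["M1"]), seed=0)

    def test_full_penetrance_means_no_unaffected_carriers(self):
        # under penetrance 1 a dominant carrier is always affected
        for seed in range(100):
            ped = generate_pedigrees(CohortSpec(seed=seed))
            d = plant_causal(ped, planted("dominant", ["M1", "M2"]), penetrance=1.0,
                             seed=seed)
            for p in ped:
                if p.family_id in ("M1", "M2") and not p.affected and (p.father_id or p.mother_id):
                    assert d[p.individual_id] == 0


class TestControls:
    def variants(self, maf=None):
        return [VariantRecord(chrom="1", pos=100, ref="G", alt="A", gene="X",
                              impact="HIGH", maf_asn=maf)]

    def test_allele_number_is_twice_control_n(self):
        spec = CohortSpec(control_n=100)
        table = generate_controls(spec, self.variants(0.01), seed=1)
        assert (table["AN"] == 200).all()
        assert (table["AC"] <= table["AN"]).all()

    def test_zero_frequency_gives_zero_count(self):
        table = generate_controls(CohortSpec(), self.variants(0.0), seed=1)
        assert (table["AC"] == 0).all()

    def test_binomial_mean_recovered_over_seeds(self):
        # neutral site at af 0.25 with 100 controls: mean alt count over
        # 500 seeds within 3 standard errors of 50
        spec = CohortSpec(control_n=100)
        counts = [
            int(generate_controls(spec, self.variants(0.25), seed=s)["AC"].iloc[0])
            for s in range(500)
        ]
        se = np.sqrt(200 * 0.25 * 0.75 / 500)
        assert abs(np.mean(counts) - 50) < 3 * se


class TestGeneratedCohort:
    def test_deterministic_output(self):
        a = generate_cohort(CohortSpec(seed=5))
        b = generate_cohort(CohortSpec(seed=5))
        assert a.cohort.genotypes.equals(b.cohort.genotypes)
        assert a.cohort.controls.equals(b.cohort.controls)
        assert a.cohort.variants == b.cohort.variants
        assert a.decoy_labels == b.decoy_labels

    def test_decoy_taxonomy_covers_every_gate(self, sim):
        assert set(sim.decoy_labels.values()) == set(DECOY_KINDS)
        assert len(sim.decoy_labels) == 20

    def test_planted_targets_respect_model(self, sim):
        for p in sim.planted:
            prefix = "M" if p.model == "dominant" else "S"
            assert all(f.startswith(prefix) for f in p.target_families)

    def test_planted_genes_in_phenotype_lists(self, sim):
        union = set().union(*sim.gene_lists.values())
        for p in sim.planted:
            assert p.variant.gene in union

    def test_cohort_genotypes_have_valid_dosages(self, sim):
        for v in sim.cohort.variants:
            for iid in sim.cohort.genotypes.index:
                genotype_dosage(sim.cohort.genotype(iid, v.key), v.ref, v.alt)

    def test_add_decoys_leaves_input_untouched(self, bundle):
        before = bundle.cohort.genotypes.copy()
        n_var = len(bundle.cohort.variants)
        add_decoys(bundle.cohort, bundle.gene_lists, 10, seed=1)
        assert bundle.cohort.genotypes.equals(before)
        assert len(bundle.cohort.variants) == n_var
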