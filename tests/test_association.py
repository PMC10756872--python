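from fractions import Fraction
from math import comb

import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from famvar.association import (
    allele_table,
    assign_subgroups,
    associate,
    fisher_exact_two_sided,
    odds_ratio,
)
from famvar.types import CohortError, ContingencyTable, PedigreeIndividual

from conftest import KEYS


def enumeration_p(a, b, c, d):
    """Independent oracle: exhaustive enumeration of all 2x2 tables at the
    observed margins, exact rational arithmetic, point-probability rule."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    denom = comb(n, c1)
    weights = {}
    for k in range(min(r1, c1) + 1):
        bb, cc = r1 - k, c1 - k
        dd = n - r1 - cc
        if bb < 0 or cc < 0 or dd < 0:
            continue
        weights[k] = comb(r1, k) * comb(n - r1, c1 - k)
    total = sum(w for w in weights.values() if w <= weights[a])
    return float(Fraction(total, denom))


class TestSubgroups:
    def test_fixture_three_multiplex_plus_pool(self, fixture_cohort):
        groups = assign_subgroups(fixture_cohort.pedigree)
        kinds = [g.kind for g in groups]
        assert kinds.count("multiplex") == 3
        assert kinds.count("sporadic_pool") == 1
        pool = next(g for g in groups if g.kind == "sporadic_pool")
        assert len(pool.members) == 6

    def test_all_singletons_pool_into_one_subgroup(self):
        ped = [
            PedigreeIndividual(f"F{i}", f"F{i}_p", affected=True, sequenced=True)
            for i in range(4)
        ]
        groups = assign_subgroups(ped)
        assert len(groups) == 1 and groups[0].kind == "sporadic_pool"

    def test_three_affected_family_is_one_multiplex_subgroup(self):
        ped = [
            PedigreeIndividual("F", f"p{i}", affected=True, sequenced=True)
            for i in range(3)
        ]
        (group,) = assign_subgroups(ped)
        assert group.kind == "multiplex" and len(group.members) == 3

    def test_family_without_affected_excluded(self):
        ped = [PedigreeIndividual("F", "p", affected=False, sequenced=False)]
        assert assign_subgroups(ped) == []


class TestAlleleTable:
    def test_fixture_mast4_family1(self, fixture_cohort):
        groups = assign_subgroups(fixture_cohort.pedigree)
        f1 = next(g for g in groups if g.subgroup_id == "multiplex_F1")
        t = allele_table(fixture_cohort, KEYS["MAST4"], f1)
        assert (t.case_alt, t.case_ref) == (2, 2)
        assert (t.ctrl_alt, t.ctrl_ref) == (3, 197)

    def test_missing_genotype_contributes_no_alleles(self, fixture_cohort):
        groups = assign_subgroups(fixture_cohort.pedigree)
        f1 = next(g for g in groups if g.subgroup_id == "multiplex_F1")
        cohort = fixture_cohort
        saved = cohort.genotypes.at["F1_II-2", KEYS["MAST4"]]
        try:
            cohort.genotypes.at["F1_II-2", KEYS["MAST4"]] = "./."
            t = allele_table(cohort, KEYS["MAST4"], f1)
            assert t.case_alt + t.case_ref == 2  # one member dropped entirely
        finally:
            cohort.genotypes.at["F1_II-2", KEYS["MAST4"]] = saved

    def test_missing_control_entry_names_variant(self, fixture_cohort):
        groups = assign_subgroups(fixture_cohort.pedigree)
        cohort = fixture_cohort
        trimmed = cohort.controls.drop(index=KEYS["CDON"])
        from famvar.types import Cohort

        c2 = Cohort(cohort.variants, cohort.genotypes, cohort.pedigree, trimmed)
        with pytest.raises(CohortError, match=KEYS["CDON"]):
            allele_table(c2, KEYS["CDON"], groups[0])


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((0, 6, 0, 200), 1.0),   # no alt allele anywhere
            ((1, 1, 100, 100), 1.0),  # identical proportions
        ],
    )
    def test_degenerate_tables(self, table, expected):
        assert fisher_exact_two_sided(ContingencyTable(*table)) == expected

    def test_matches_enumeration_oracle(self):
        p = fisher_exact_two_sided(ContingencyTable(2, 2, 1, 199))
        assert p == pytest.approx(enumeration_p(2, 2, 1, 199), abs=1e-12)
        assert p < 0.05

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_agrees_with_enumeration_and_scipy(self, cells):
        a, b, c, d = cells
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(enumeration_p(a, b, c, d), abs=1e-9)
        # independent library cross-check
        p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert p == pytest.approx(p_scipy, abs=1e-7)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_invariant_under_simultaneous_row_and_column_swap(self, cells):
        a, b, c, d = cells
        p1 = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        p2 = fisher_exact_two_sided(ContingencyTable(c, d, a, b))  # swap rows
        p3 = fisher_exact_two_sided(ContingencyTable(b, a, d, c))  # swap cols
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert p1 == pytest.approx(p3, abs=1e-12)


class TestOddsRatio:
    def test_identity_table(self):
        assert odds_ratio(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_hand_computed(self):
        assert odds_ratio(ContingencyTable(3, 25, 1, 199)) == pytest.approx(
            3 * 199 / (25 * 1), rel=1e-12
        )
        assert odds_ratio(ContingencyTable(3, 25, 1, 199)) == pytest.approx(23.88, abs=0.01)

    def test_haldane_anscombe_on_zero_cell(self):
        expected = (2.5 * 199.5) / (0.5 * 1.5)
        assert odds_ratio(ContingencyTable(2, 0, 1, 199)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_adding_case_alt_never_decreases_or(self, cells):
        a, b, c, d = cells
        assert odds_ratio(ContingencyTable(a + 1, b, c, d)) >= odds_ratio(
            ContingencyTable(a, b, c, d)
        )


class TestAssociate:
    def test_pass_flag_matches_definition(self, fixture_cohort):
        groups = assign_subgroups(fixture_cohort.pedigree)
        passes, results = associate(fixture_cohort, groups, alpha=0.05)
        for r in results:
            assert r.passes == (r.p_value < 0.05 and r.odds_ratio > 1.0)
        for key, flag in passes.items():
            assert flag == any(r.passes for r in results if r.variant_key == key)

    def test_fixture_candidates_all_pass(self, fixture_cohort):
        groups = assign_subgroups(fixture_cohort.pedigree)
        passes, _ = associate(fixture_cohort, groups)
        assert all(passes.values())

    def test_absent_variant_fails(self, fixture_cohort):
        from famvar.types import Cohort, VariantRecord
        import pandas as pd

        v = VariantRecord(chrom="9", pos=999, ref="G", alt="A", gene="NUL", impact="HIGH")
        genotypes = fixture_cohort.genotypes.copy()
        genotypes[v.key] = "G/G"
        controls = pd.concat(
            [
                fixture_cohort.controls,
                pd.DataFrame([{"variant_key": v.key, "AC": 40, "AN": 200}]).set_index(
                    "variant_key"
                ),
            ]
        )
        c2 = Cohort(
            fixture_cohort.variants + [v], genotypes, fixture_cohort.pedigree, controls
        )
        passes, _ = associate(c2, assign_subgroups(c2.pedigree))
        assert passes[v.key] is False

    def test_alpha_validated(self, fixture_cohort):
        with pytest.raises(CohortError):
            associate(fixture_cohort, [], alpha=1.5)
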