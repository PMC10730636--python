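import math

import pytest
from hypothesis import given, strategies as st

from conftest import make_structure
from xtalmol import fixtures
from xtalmol.chem_tables import load_bond_classes
from xtalmol.ensemble import build_ensemble
from xtalmol.perception import perceive
from xtalmol.validation import (ValidationConfig, check_atom_charges,
                                check_bond_geometry, check_bond_length,
                                check_ensemble_charge, check_pi_count,
                                check_radicals, formula_compatible,
                                judge_entry, validate_structure)

HEADER = "elem_a\telem_b\torder\tpi_a\tpi_b\tmean\tsigma\tcount\n"


class TestPiCount:
    def test_sp3_carbon_with_double_bond(self):
        # tetrahedral carbon wrongly carrying a double bond
        d = 1.54
        t = math.radians(109.47)
        s = make_structure(
            [("C", (0, 0, 0)),
             ("C", (d, 0, 0)),
             ("C", (d * math.cos(t), d * math.sin(t), 0)),
             ("C", (d * math.cos(t), -d * math.sin(t) * 0.5,
                    d * math.sin(t) * 0.866)),
             ("C", (d * math.cos(t), -d * math.sin(t) * 0.5,
                    -d * math.sin(t) * 0.866))],
            [(0, 1, 2), (0, 2, 1), (0, 3, 1), (0, 4, 1)])
        issues = check_pi_count(s)
        assert any(i.atoms == (0,) for i in issues)

    def test_benzene_carbons_clean(self, benzene_structure):
        assert check_pi_count(benzene_structure) == []

    def test_metal_skipped(self, ferrocene_structure):
        issues = check_pi_count(ferrocene_structure)
        fe = next(i for i, a in enumerate(ferrocene_structure.atoms)
                  if a.element == "Fe")
        assert all(fe not in issue.atoms for issue in issues)

    def test_delocalized_counts_once(self, ferrocene_structure):
        # ring carbons participate in delocalized bonds: factual pi == 1
        assert check_pi_count(ferrocene_structure) == []


class TestBondGeometry:
    def _twisted_alkene(self, twist_deg):
        t = math.radians(twist_deg)
        s = make_structure(
            [("C", (-1.0, 0.8, 0), {"attached_hydrogens": 3}),
             ("C", (0, 0, 0), {"attached_hydrogens": 1}),
             ("C", (1.34, 0, 0), {"attached_hydrogens": 1}),
             ("C", (2.34, 0.8 * math.cos(t), 0.8 * math.sin(t)),
              {"attached_hydrogens": 3})],
            [(0, 1, 1), (1, 2, 2), (2, 3, 1)])
        return s

    def test_planar_ok(self):
        assert check_bond_geometry(self._twisted_alkene(2.0)) == []

    def test_twisted_flagged(self):
        issues = check_bond_geometry(self._twisted_alkene(40.0))
        assert any(i.category == "bond_geometry" for i in issues)

    def test_single_bond_any_geometry(self):
        s = self._twisted_alkene(40.0)
        for b in s.bonds:
            b.order = 1
        assert check_bond_geometry(s) == []


class TestBondLength:
    def _cc(self, d, order=1):
        return make_structure(
            [("C", (0, 0, 0), {"attached_hydrogens": 3}),
             ("C", (d, 0, 0), {"attached_hydrogens": 3 if order == 1 else 1})],
            [(0, 1, order)])

    def test_at_mean_clean(self):
        table = load_bond_classes(
            HEADER + "C\tC\t1\t*\t*\t1.54\t0.02\t10\n")
        assert check_bond_length(self._cc(1.54), table) == []

    def test_z3_exactly_not_flagged(self):
        table = load_bond_classes(
            HEADER + "C\tC\t1\t*\t*\t1.54\t0.02\t10\n"
                     "C\tC\t2\t*\t*\t1.60\t0.02\t10\n")
        # z = 3.0 does not exceed the threshold
        assert check_bond_length(self._cc(1.60), table) == []

    def test_flagged_with_better_alternative(self):
        table = load_bond_classes(
            HEADER + "C\tC\t1\t*\t*\t1.54\t0.02\t10\n"
                     "C\tC\t2\t*\t*\t1.61\t0.02\t10\n")
        issues = check_bond_length(self._cc(1.61), table)
        assert len(issues) == 1
        assert issues[0].category == "bond_length"

    def test_not_flagged_without_alternative(self):
        table = load_bond_classes(
            HEADER + "C\tC\t1\t*\t*\t1.54\t0.02\t10\n")
        assert check_bond_length(self._cc(1.61), table) == []

    def test_flag_rate_monotone_in_threshold(self):
        # lowering sigma_threshold can only add flags
        table = load_bond_classes(
            HEADER + "C\tC\t1\t*\t*\t1.54\t0.02\t10\n"
                     "C\tC\t2\t*\t*\t1.40\t0.02\t10\n")
        lengths = [1.54 + 0.013 * k for k in range(-8, 9)]
        prev = None
        for thresh in (5.0, 4.0, 3.0, 2.0, 1.0, 0.5):
            cfg = ValidationConfig(sigma_threshold=thresh)
            n = sum(len(check_bond_length(self._cc(d), table, cfg))
                    for d in lengths)
            if prev is not None:
                assert n >= prev
            prev = n


class TestRadicalsAndCharges:
    def test_methyl_radical(self):
        s = make_structure([("C", (0, 0, 0), {"attached_hydrogens": 3,
                                              "radical": True})], [])
        assert len(check_radicals(s)) == 1

    def test_water_clean(self):
        s = perceive(build_ensemble(fixtures.make_water()))
        assert check_radicals(s) == []

    def test_no_like_radical(self):
        s = make_structure([("N", (0, 0, 0)), ("O", (1.15, 0, 0))],
                           [(0, 1, 2)])
        from xtalmol.perception import assign_formal_charges
        assign_formal_charges(s)
        assert len(check_radicals(s)) == 1

    def test_fe2_allowed(self):
        s = make_structure([("Fe", (0, 0, 0), {"formal_charge": 2})], [])
        assert check_atom_charges(s) == []

    def test_c5minus_flagged(self):
        s = make_structure([("C", (0, 0, 0), {"formal_charge": -5})], [])
        assert len(check_atom_charges(s)) == 1

    def test_carboxylate_oxygen_ok(self):
        s = make_structure([("O", (0, 0, 0), {"formal_charge": -1})], [])
        assert check_atom_charges(s) == []

    def test_metal_oxidation_state_violation(self):
        s = make_structure([("Na", (0, 0, 0), {"formal_charge": 3})], [])
        assert len(check_atom_charges(s)) == 1


class TestEnsembleCharge:
    def test_nacl_sum_zero(self):
        s = perceive(build_ensemble(fixtures.make_nacl_contact()))
        assert check_ensemble_charge(s) == []

    def test_lone_anion_flagged(self):
        s = make_structure([("Cl", (0, 0, 0), {"formal_charge": -1})], [])
        assert len(check_ensemble_charge(s)) == 1

    def test_ferrocene_balanced(self, ferrocene_structure):
        assert check_ensemble_charge(ferrocene_structure) == []


class TestFormulaCompatible:
    def test_worked_example(self):
        computed = {"C": 12, "H": 24, "O": 12}
        declared = {"C": 6, "H": 12, "O": 6}
        assert formula_compatible(declared, computed)

    def test_identical(self):
        f = {"C": 6, "H": 12, "O": 6}
        assert formula_compatible(f, dict(f))

    def test_perturbed(self):
        assert not formula_compatible({"C": 6, "H": 12, "O": 6},
                                      {"C": 6, "H": 12, "O": 5})

    def test_non_integer_multiple(self):
        assert not formula_compatible({"C": 2}, {"C": 3})

    def test_mixed_multiples(self):
        assert not formula_compatible({"C": 2, "H": 2}, {"C": 4, "H": 6})

    @given(st.dictionaries(st.sampled_from(["C", "H", "N", "O", "S"]),
                           st.integers(1, 30), min_size=1),
           st.integers(1, 5))
    def test_multiple_property(self, formula, k):
        assert formula_compatible(formula, formula)
        scaled = {el: k * n for el, n in formula.items()}
        assert formula_compatible(formula, scaled)


class TestJudgeEntry:
    def test_clean_benzene_valid(self, benzene_desc, benzene_structure):
        ens = build_ensemble(benzene_desc)
        issues = validate_structure(benzene_structure)
        verdict = judge_entry(issues, benzene_desc, ens)
        assert verdict.overall_valid
        assert verdict.failed() == []

    def test_formula_mismatch_only(self, benzene_desc, benzene_structure):
        desc = fixtures.make_benzene()
        desc.declared_formula = {"C": 6, "H": 7}
        ens = build_ensemble(desc)
        verdict = judge_entry([], desc, ens)
        assert not verdict.overall_valid
        assert verdict.failed() == ["chemical_formula"]

    def test_compositional_disorder_marked_not_dropped(self):
        desc = fixtures.make_defect("compositional")
        ens = build_ensemble(desc)
        s = perceive(ens)
        issues = validate_structure(s)
        verdict = judge_entry(issues, desc, ens)
        assert "compositional_disorder" in verdict.failed()
        # the structure itself is still fully present
        assert len(s.atoms) == 3

    def test_markup_flags(self, benzene_desc):
        desc = fixtures.make_benzene()
        desc.markup_flags.add("theoretical")
        ens = build_ensemble(desc)
        verdict = judge_entry([], desc, ens)
        assert "cod_markup" in verdict.failed()
        desc.markup_flags = {"manual-exclusion"}
        verdict = judge_entry([], desc, ens)
        assert "manual_review" in verdict.failed()

    def test_provenance_requires_doi_or_citation(self):
        desc = fixtures.make_benzene()
        ens = build_ensemble(desc)
        desc.doi = None
        desc.journal = None
        verdict = judge_entry([], desc, ens)
        assert "data_provenance" in verdict.failed()
        desc.journal = "Some Journal"
        desc.year = "2020"
        verdict = judge_entry([], desc, ens)
        assert "data_provenance" not in verdict.failed()


class TestFlaggedButKept:
    @pytest.mark.parametrize("checker", [
        check_pi_count, check_bond_geometry, check_radicals,
        check_atom_charges, check_ensemble_charge])
    def test_checks_do_not_mutate(self, checker, ferrocene_structure):
        before = ([(b.i, b.j, b.order) for b in ferrocene_structure.bonds],
                  [(a.element, a.formal_charge)
                   for a in ferrocene_structure.atoms])
        checker(ferrocene_structure)
        after = ([(b.i, b.j, b.order) for b in ferrocene_structure.bonds],
                 [(a.element, a.formal_charge)
                  for a in ferrocene_structure.atoms])
        assert before == after
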