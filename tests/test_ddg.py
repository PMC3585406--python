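"""Folding/binding energy-change bookkeeping."""

import numpy as np
import pytest

from mutsmith.ddg import (
    additivity_check,
    aggregate,
    binding_ddg,
    classify_binding_effect,
    fit_adjustment,
    folding_ddg,
    pka_shift_table,
)
from mutsmith.energy import DEFAULT_PARAMETERIZATIONS, EnergyParams, total_energy
from mutsmith.mutate import apply_mutations
from mutsmith.structure import Atom, MolecularStructure, MutationSpec, Residue
from mutsmith.synthetic import load_fixture, toy_structure

PARAMS2 = DEFAULT_PARAMETERIZATIONS[:2]


class TestFoldingDdg:
    def test_identity_mutation_exactly_zero(self, dimer12):
        specs = [MutationSpec("C", 4, "A", "D")]
        result = folding_ddg(dimer12, dimer12, specs, PARAMS2, minimize=False)
        assert all(v == 0.0 for v in result.values.values())

    def test_antisymmetry(self, dimer12):
        specs = [MutationSpec("C", 4, "A", "D"), MutationSpec("D", 4, "A", "D")]
        mut = apply_mutations(dimer12, specs)
        fwd = folding_ddg(dimer12, mut, specs, PARAMS2, minimize=False)
        back_specs = [MutationSpec("C", 4, "D", "A"), MutationSpec("D", 4, "D", "A")]
        rev = folding_ddg(mut, dimer12, back_specs, PARAMS2, minimize=False)
        for key in fwd.values:
            assert fwd.values[key] == pytest.approx(-rev.values[key], abs=1e-9)

    def test_empty_site_list_rejected(self, dimer12):
        with pytest.raises(ValueError):
            folding_ddg(dimer12, dimer12, [], PARAMS2)

    def test_isolated_interaction_term_oracle(self, params_a):
        """A charge far from the segment interacts only in the folded state;
        the ddG must equal that pairwise interaction difference."""

        def build(q_far):
            chain = [
                Residue("GLY", n, atoms=[
                    Atom("CA", "C", np.array([n * 3.8, 0.0, 0.0]), 1.7, 0.0)
                ])
                for n in range(1, 6)
            ]
            chain[2].atoms[0].partial_charge = 1.0  # mutated site
            chain.append(
                Residue("GLY", 6, atoms=[Atom("CA", "C", np.array([11.4, 8.0, 0.0]), 1.7, q_far)])
            )
            return MolecularStructure(chains={"A": chain})

        wt, mut = build(0.0), build(-1.0)
        specs = [MutationSpec("A", 3, "G", "G")]
        # direct evaluation path (no wt-residue mismatch: both glycine)
        result = folding_ddg(wt, mut, [MutationSpec("A", 3, "G", "A")], [params_a], minimize=False)
        # oracle: folded-state energy difference minus segment difference,
        # computed term-by-term from full evaluations
        g_wt = total_energy(wt, params_a).total
        g_mut = total_energy(mut, params_a).total
        from mutsmith.structure import tripeptide_segment

        seg_wt = total_energy(tripeptide_segment(wt, "A", 3)[0], params_a).total
        seg_mut = total_energy(tripeptide_segment(mut, "A", 3)[0], params_a).total
        expected = (g_wt - seg_wt) - (g_mut - seg_mut)
        (value,) = result.values.values()
        assert value == pytest.approx(expected, abs=1e-9)

    def test_stabilizing_contact_in_folded_state_positive(self, params_a):
        """An attractive contact present only in the mutant folded state
        (absent from its tripeptide) must yield ddG > 0."""

        def build(q_site):
            chain = [
                Residue("GLY", n, atoms=[
                    Atom("CA", "C", np.array([n * 3.8, 0.0, 0.0]), 1.7, 0.0)
                ])
                for n in range(1, 6)
            ]
            chain[2].atoms[0].partial_charge = q_site
            # fixed opposite charge far in sequence, close in space to site 3
            chain.append(
                Residue("GLY", 9, atoms=[Atom("CA", "C", np.array([11.4, 4.0, 0.0]), 1.7, 1.0)])
            )
            return MolecularStructure(chains={"A": chain})

        wt, mut = build(0.0), build(-1.0)
        result = folding_ddg(wt, mut, [MutationSpec("A", 3, "G", "A")], [params_a], minimize=False)
        (value,) = result.values.values()
        assert value > 0


class TestBindingDdg:
    def test_non_interacting_limit(self):
        far = toy_structure("two_domain_dimer", cleft=200.0, n_residues=6)
        result = binding_ddg(far, far, ("C", "D"), PARAMS2[:1], minimize=False)
        assert abs(result.wt["setA"]) < 1e-3

    def test_identical_structures_zero_difference(self, dimer12):
        result = binding_ddg(dimer12, dimer12, ("C", "D"), PARAMS2, minimize=False)
        assert all(v == 0.0 for v in result.difference.values())

    def test_chain_swap_symmetric(self, dimer12, params_a):
        a = binding_ddg(dimer12, dimer12, ("C", "D"), [params_a], minimize=False)
        b = binding_ddg(dimer12, dimer12, ("D", "C"), [params_a], minimize=False)
        assert a.wt["setA"] == pytest.approx(b.wt["setA"], abs=1e-9)

    def test_salt_bridge_interaction_oracle(self, params_a):
        """Binding energy of a one-salt-bridge dimer equals the inter-chain
        pairwise terms computed directly."""
        c = Residue("GLY", 1, atoms=[Atom("CA", "C", np.array([0.0, 0.0, 0.0]), 1.7, 1.0)])
        d = Residue("GLY", 1, atoms=[Atom("CA", "C", np.array([4.0, 0.0, 0.0]), 1.7, -1.0)])
        dimer = MolecularStructure(chains={"C": [c], "D": [d]})
        result = binding_ddg(dimer, dimer, ("C", "D"), [params_a], minimize=False)
        bd_dimer = total_energy(dimer, params_a)
        bd_c = total_energy(MolecularStructure(chains={"C": [c]}), params_a)
        bd_d = total_energy(MolecularStructure(chains={"D": [d]}), params_a)
        expected = bd_dimer.total - bd_c.total - bd_d.total
        assert result.wt["setA"] == pytest.approx(expected, abs=1e-9)
        assert expected < 0  # attraction lowers the dimer energy


class TestAggregation:
    def test_published_parameterization_average(self):
        rec = load_fixture("folding_energy_records")["records"]["SDmut"]
        values = {}
        for ff in ("amber98", "charmm27", "oplsaa"):
            values[(ff, "C")] = rec["C"][ff]
            values[(ff, "D")] = rec["D"][ff]
        agg = aggregate(values)
        assert agg["ave_parameterizations"]["C"] == pytest.approx(83.96, abs=0.01)
        assert agg["ave_monomers"] == pytest.approx(83.28, abs=0.01)

    def test_published_binding_average(self):
        rec = load_fixture("binding_energy_records")["records"]["Fmut"]
        values = {(ff, "CD"): rec[ff] for ff in ("amber98", "charmm27", "oplsaa")}
        agg = aggregate(values)
        assert agg["ave_monomers"] == pytest.approx(-0.61, abs=0.01)

    def test_identical_replicates(self):
        agg = aggregate({("a", "C"): 5.0, ("b", "C"): 5.0})
        assert agg["ave_monomers"] == 5.0

    def test_incomplete_grid_rejected(self):
        with pytest.raises(KeyError):
            aggregate({("a", "C"): 1.0, ("b", "D"): 2.0})


class TestAdjustment:
    def test_calibration_pairs_predict_published_value(self):
        # solve the 2x2 system from two printed (raw, adjusted) pairs and
        # check the prediction for the third printed raw value
        model = fit_adjustment([(83.28, 6.66), (181.32, 15.77)])
        assert round(model.apply(90.05), 2) == 7.29

    def test_identity_pairs(self):
        model = fit_adjustment([(1.0, 1.0), (2.0, 2.0), (5.0, 5.0)])
        assert model.slope == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_collinear_pairs_zero_residuals(self):
        pairs = [(x, 0.1 * x - 1.0) for x in (10.0, 50.0, 90.0, 200.0)]
        model = fit_adjustment(pairs)
        for raw, adjusted in pairs:
            assert model.apply(raw) == pytest.approx(adjusted, abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            fit_adjustment([(1.0, 2.0)])
        with pytest.raises(ValueError):
            fit_adjustment([(1.0, 2.0), (1.0, 3.0)])


class TestAdditivity:
    def test_published_sum_row(self):
        report = additivity_check([83.28, 181.32, 90.05], 355.42, tolerance=0.05)
        assert report["sum"] == pytest.approx(354.65, abs=1e-9)
        assert report["abs_deviation"] == pytest.approx(0.77, abs=1e-9)
        assert report["verdict"] == "additive"

    def test_exact_sum(self):
        report = additivity_check([1.0, 2.0], 3.0)
        assert report["abs_deviation"] == 0.0

    def test_interacting_sites_detected(self, params_a):
        """Two charged mutations sharing a contact are non-additive."""

        def build(q1, q2):
            chain = [
                Residue("GLY", n, atoms=[
                    Atom("CA", "C", np.array([x, 0.0, 0.0]), 1.7, q)
                ])
                for n, (x, q) in enumerate([(0.0, q1), (4.0, q2), (40.0, 0.0)], start=1)
            ]
            return MolecularStructure(chains={"A": chain})

        wt = build(0.0, 0.0)
        single1 = folding_ddg(wt, build(1.0, 0.0), [MutationSpec("A", 1, "G", "A")], [params_a], minimize=False)
        single2 = folding_ddg(wt, build(0.0, 1.0), [MutationSpec("A", 2, "G", "A")], [params_a], minimize=False)
        combined = folding_ddg(
            wt, build(1.0, 1.0),
            [MutationSpec("A", 1, "G", "A"), MutationSpec("A", 2, "G", "A")],
            [params_a], minimize=False,
        )
        report = additivity_check(
            [single1.average, single2.average], combined.average, tolerance=0.01
        )
        assert report["verdict"] == "non-additive"


class TestClassification:
    @pytest.mark.parametrize("ddd,expected", [
        (-1.18, "no-effect"), (1.99, "no-effect"), (-0.73, "no-effect"), (-0.61, "no-effect"),
        (5.0, "increase"), (-5.0, "decrease"),
    ])
    def test_neutral_band(self, ddd, expected):
        assert classify_binding_effect(ddd, neutral_band=2.0) == expected


class TestPkaShifts:
    def test_published_shift(self):
        tables = load_fixture("pka_records")["tables"]
        result = pka_shift_table(tables["WT"], tables["Pmut"])
        assert result["shifts"]["ASP201"] == pytest.approx(14.0)
        assert "GLU175" in result["missing_in_wt"]

    def test_identical_tables_zero(self):
        result = pka_shift_table({"A1": 4.0}, {"A1": 4.0})
        assert result["shifts"] == {"A1": 0.0}

    def test_random_tables_elementwise_oracle(self, rng):
        keys = [f"R{i}" for i in range(20)]
        wt = {k: float(v) for k, v in zip(keys, rng.normal(7, 2, 20))}
        mut = {k: float(v) for k, v in zip(keys[5:], rng.normal(7, 2, 15))}
        result = pka_shift_table(wt, mut)
        for k in set(wt) & set(mut):
            assert result["shifts"][k] == pytest.approx(mut[k] - wt[k])
        assert set(result["missing_in_mutant"]) == set(keys[:5])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pka_shift_table({"A": float("nan")}, {"A": 1.0})
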