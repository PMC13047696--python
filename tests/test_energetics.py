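import pytest

from dimerpop.constants import HARTREE_IN_KCAL_MOL
from dimerpop.energetics import (
    DimerEntry,
    StoichiometryError,
    binding_energy,
    compute_energy_table,
    enthalpy_difference,
    monomer_relative_energies,
    rank_dimers,
    read_manifest,
)
from dimerpop.species_io import Role, SpeciesRecord
from dimerpop.synthetic_data import GeneratorConfig, make_species
from dimerpop.thermochem import composite_energy, thermal_enthalpy


def bare(label, formula, charge, role):
    return SpeciesRecord(label=label, formula=formula, charge=charge,
                         multiplicity=1, role=role)


@pytest.fixture()
def triple():
    return DimerEntry(
        name="D",
        dimer=bare("D", "C42H61O4", 1, Role.PROTON_BOUND_DIMER),
        protonated_monomer=bare("R1", "C21H31O2", 1, Role.PROTONATED_MONOMER),
        neutral_monomer=bare("R2", "C21H30O2", 0, Role.NEUTRAL_MONOMER),
    )


class TestBindingEnergy:
    def test_non_interacting_limit_is_zero(self, triple):
        e = {"D": -2000.0, "R1": -1000.0, "R2": -1000.0}
        assert binding_energy(triple, e) == 0.0

    def test_hand_arithmetic(self, triple):
        e = {"D": -2000.10, "R1": -1000.00, "R2": -1000.00}
        assert binding_energy(triple, e) == pytest.approx(
            -0.10 * HARTREE_IN_KCAL_MOL, abs=1e-9)
        assert round(binding_energy(triple, e), 1) == -62.8

    def test_element_conservation_enforced_before_arithmetic(self, triple):
        triple.neutral_monomer.formula = "C21H29O2"
        with pytest.raises(StoichiometryError):
            binding_energy(triple, {})

    def test_charge_conservation_enforced(self, triple):
        triple.dimer.charge = 0
        with pytest.raises(StoichiometryError, match="charge"):
            binding_energy(triple, {"D": 0, "R1": 0, "R2": 0})

    def test_translation_invariance_per_molecule(self, triple):
        # shifting every species by c per constituent monomer (2c for the
        # dimer) cancels in D - (R1 + R2)
        e = {"D": -2000.05, "R1": -1000.02, "R2": -1000.0}
        c = 7.5
        shifted = {"D": e["D"] + 2 * c, "R1": e["R1"] + c, "R2": e["R2"] + c}
        assert binding_energy(triple, e) == pytest.approx(
            binding_energy(triple, shifted), abs=1e-9)

    def test_flat_shift_moves_binding_energy_by_exactly_minus_c(self, triple):
        e = {"D": -2000.05, "R1": -1000.02, "R2": -1000.0}
        c = 7.5
        flat = {k: v + c for k, v in e.items()}
        assert binding_energy(triple, flat) == pytest.approx(
            binding_energy(triple, e) - c * HARTREE_IN_KCAL_MOL, abs=1e-9)


class TestEnthalpyDifference:
    def test_equals_binding_energy_at_zero_kelvin(self, config, triple):
        # with H = E0 the two formulas coincide exactly
        e0 = {"D": -2000.07, "R1": -1000.01, "R2": -1000.0}
        assert enthalpy_difference(triple, e0) == binding_energy(triple, e0)

    def test_matches_brute_force_on_synthetic_records(self):
        d = make_species(GeneratorConfig(seed=11), Role.PROTON_BOUND_DIMER,
                         "C12H17O2", label="D")
        r1 = make_species(GeneratorConfig(seed=12), Role.PROTONATED_MONOMER,
                          "C6H9O", label="R1")
        r2 = make_species(GeneratorConfig(seed=13), Role.NEUTRAL_MONOMER,
                          "C6H8O", label="R2")
        T = 623.15
        h = {r.label: thermal_enthalpy(r, T) for r in (d, r1, r2)}
        entry = DimerEntry("D", d, r1, r2)
        brute = (h["D"] - h["R1"] - h["R2"]) * HARTREE_IN_KCAL_MOL
        assert enthalpy_difference(entry, h) == pytest.approx(brute, abs=1e-10)


class TestRanking:
    def entries(self, dhs, names=None):
        out = []
        for k, dh in enumerate(dhs):
            e = DimerEntry(
                name=(names or [f"d{k}" for k in range(len(dhs))])[k],
                dimer=bare("D", "C42H61O4", 1, Role.PROTON_BOUND_DIMER),
                protonated_monomer=bare("R1", "C21H31O2", 1, Role.PROTONATED_MONOMER),
                neutral_monomer=bare("R2", "C21H30O2", 0, Role.NEUTRAL_MONOMER),
            )
            e.dH = dh
            out.append(e)
        return out

    def test_relative_enthalpies_from_stability_spread(self):
        ranked = rank_dimers(self.entries([-61.2, -60.8, -60.0]))
        assert [round(e.dH_rel, 6) for e in ranked] == [0.0, 0.4, 1.2]
        assert sum(e.dH_rel == 0.0 for e in ranked) == 1

    def test_single_entry(self):
        assert rank_dimers(self.entries([-48.5]))[0].dH_rel == 0.0

    def test_sort_stability_under_permutation(self):
        a = rank_dimers(self.entries([-60.0, -61.2, -60.8], ["x", "y", "z"]))
        b = rank_dimers(self.entries([-61.2, -60.8, -60.0], ["y", "z", "x"]))
        assert [e.name for e in a] == [e.name for e in b] == ["y", "z", "x"]

    def test_ties_flagged_and_broken_by_name(self):
        ranked = rank_dimers(self.entries([-60.0, -60.0], ["b", "a"]))
        assert [e.name for e in ranked] == ["a", "b"]
        assert all(e.tied for e in ranked)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            rank_dimers([])

    def test_more_negative_dh_ranks_more_stable(self):
        ranked = rank_dimers(self.entries([-44.2, -60.8]))
        assert ranked[0].dH == -60.8


class TestMonomerRelativeEnergies:
    def isomers(self):
        labels = ["CBD", "THC", "D8-THC", "CBT", "CBC"]
        return [bare(lbl, "C21H30O2", 0, Role.NEUTRAL_MONOMER) for lbl in labels]

    def test_reference_maps_to_zero(self):
        recs = self.isomers()
        e = {r.label: -1000.0 for r in recs}
        rel = monomer_relative_energies(recs, e, "CBD")
        assert rel["CBD"] == 0.0

    def test_injected_gaps_recovered_exactly(self):
        recs = self.isomers()
        gaps = {"CBD": 0.0, "THC": -13.8, "D8-THC": -18.1, "CBT": -19.0, "CBC": +0.5}
        e = {lbl: -1000.0 + g / HARTREE_IN_KCAL_MOL for lbl, g in gaps.items()}
        rel = monomer_relative_energies(recs, e, "CBD")
        for lbl, g in gaps.items():
            assert rel[lbl] == pytest.approx(g, abs=1e-9)
        # stability ordering by E0: CBT < D8-THC < THC < CBD < CBC
        assert sorted(gaps, key=rel.get) == ["CBT", "D8-THC", "THC", "CBD", "CBC"]

    def test_non_isomers_rejected(self):
        recs = self.isomers()
        recs[1].formula = "C21H32O2"
        with pytest.raises(StoichiometryError):
            monomer_relative_energies(recs, {}, "CBD")


class TestManifestPipeline:
    def test_end_to_end_energy_table(self):
        d = make_species(GeneratorConfig(seed=21), Role.PROTON_BOUND_DIMER,
                         "C12H17O2", label="dim-1")
        d2 = make_species(GeneratorConfig(seed=22), Role.PROTON_BOUND_DIMER,
                          "C12H17O2", label="dim-2")
        r1 = make_species(GeneratorConfig(seed=23), Role.PROTONATED_MONOMER,
                          "C6H9O", label="protH")
        r2 = make_species(GeneratorConfig(seed=24), Role.NEUTRAL_MONOMER,
                          "C6H8O", label="neut")
        records = {r.label: r for r in (d, d2, r1, r2)}
        manifest = read_manifest(
            "# name dimer prot neutral\n"
            "A\tdim-1\tprotH\tneut\n"
            "B\tdim-2\tprotH\tneut\n"
        )
        table = compute_energy_table(manifest, records)
        assert list(table.columns) == [
            "name", "dE_bind_kcal", "dH_kcal", "dH_rel_kcal", "tied"]
        assert table["dH_rel_kcal"].min() == 0.0
        assert table["dH_rel_kcal"].is_monotonic_increasing
        # 0 K: dH column equals the binding-energy column exactly
        assert (table["dE_bind_kcal"] == table["dH_kcal"]).all()
        # cross-check one row against a direct composite-energy computation
        e0 = {lbl: composite_energy(r) for lbl, r in records.items()}
        expected = (e0["dim-1"] - e0["protH"] - e0["neut"]) * HARTREE_IN_KCAL_MOL
        row = table.set_index("name").loc["A"]
        assert row["dE_bind_kcal"] == pytest.approx(expected, abs=1e-9)
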