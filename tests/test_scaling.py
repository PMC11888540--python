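"""Protein-water LJ scaling: classification, selection, cloning, HMR."""

import math

import numpy as np
import pytest

from ffbalance.fixtures import make_toy_topology, random_configuration
from ffbalance.energy import total_energy
from ffbalance.scaling import (
    AtomClass,
    ScalingMode,
    ScalingScheme,
    apply_water_scaling,
    classify_atom,
    combine_lj,
    find_water_oxygen_type,
    repartition_hydrogen_masses,
    select_scaling_targets,
)
from ffbalance.topology import AtomRecord, AtomTypeRecord, TopologyError


def _atom(name, res):
    return AtomRecord(
        index=1, type_name="X", residue_index=1, residue_name=res,
        atom_name=name, charge=0.0, mass=1.0,
    )


class TestClassification:
    @pytest.mark.parametrize(
        "name,res,expected",
        [
            ("CA", "ALA", AtomClass.BACKBONE),
            ("O", "GLY", AtomClass.BACKBONE),
            ("HA2", "GLY", AtomClass.BACKBONE),
            ("CB", "GLN", AtomClass.SIDECHAIN),
            ("NE2", "GLN", AtomClass.SIDECHAIN),
            ("OW", "SOL", AtomClass.WATER),
            ("NA", "NA", AtomClass.ION),
            ("CB", "HID", AtomClass.SIDECHAIN),  # tautomer alias
        ],
    )
    def test_examples(self, name, res, expected):
        assert classify_atom(_atom(name, res)) is expected

    def test_unrecognized_residue_is_other_never_scaled(self, caplog):
        with caplog.at_level("WARNING"):
            assert classify_atom(_atom("C1", "LIG")) is AtomClass.OTHER
        assert "unrecognized" in caplog.text

    def test_every_protein_atom_backbone_xor_sidechain(self, toy_aqa):
        for atom in toy_aqa.molecules["Protein"].atoms:
            assert classify_atom(atom) in (AtomClass.BACKBONE, AtomClass.SIDECHAIN)


class TestSelection:
    def test_uncharged_sidechain_scheme_excludes_aspartate(self, toy_adq):
        scheme = ScalingScheme(mode=ScalingMode.SIDECHAIN_UNCHARGED)
        targets = select_scaling_targets(toy_adq, scheme)
        mol = toy_adq.molecules["Protein"]
        target_res = {mol.atom_by_index(i).residue_name for _, i in targets}
        assert target_res == {"ALA", "GLN"}
        # and precisely the sidechain atoms of those residues
        for _, i in targets:
            assert classify_atom(mol.atom_by_index(i)) is AtomClass.SIDECHAIN

    def test_glycine_only_peptide_has_no_sidechain_targets(self):
        topo = make_toy_topology("GG")
        scheme = ScalingScheme(mode=ScalingMode.SIDECHAIN_ALL)
        assert select_scaling_targets(topo, scheme) == set()
        with pytest.raises(TopologyError, match="no protein atoms"):
            apply_water_scaling(topo, scheme)

    def test_all_is_superset_of_backbone_union_sidechain(self, toy_aaqaa3):
        t_all = select_scaling_targets(toy_aaqaa3, ScalingScheme(mode="all"))
        t_bb = select_scaling_targets(toy_aaqaa3, ScalingScheme(mode="backbone"))
        t_sc = select_scaling_targets(toy_aaqaa3, ScalingScheme(mode="sidechain"))
        assert t_bb | t_sc <= t_all
        assert t_bb.isdisjoint(t_sc)

    def test_backbone_mode_is_heavy_atoms_only(self, toy_aqa):
        mol = toy_aqa.molecules["Protein"]
        targets = select_scaling_targets(toy_aqa, ScalingScheme(mode="backbone"))
        names = {mol.atom_by_index(i).atom_name for _, i in targets}
        assert names == {"N", "CA", "C", "O"}


class TestCombineLJ:
    def test_identical_types_unchanged(self):
        t = AtomTypeRecord("A", 1.0, 0.0, 0.3, 0.5)
        assert combine_lj(t, t) == (pytest.approx(0.3), pytest.approx(0.5))

    def test_geometric_epsilon(self):
        a = AtomTypeRecord("A", 1.0, 0.0, 0.3, 0.4)
        b = AtomTypeRecord("B", 1.0, 0.0, 0.5, 0.9)
        sigma, eps = combine_lj(a, b)
        assert eps == pytest.approx(0.6)
        assert sigma == pytest.approx(0.4)
        sigma_g, _ = combine_lj(a, b, rule="geometric")
        assert sigma_g == pytest.approx(math.sqrt(0.15))

    def test_zero_epsilon_dominates(self):
        a = AtomTypeRecord("A", 1.0, 0.0, 0.3, 0.0)
        b = AtomTypeRecord("B", 1.0, 0.0, 0.5, 0.9)
        assert combine_lj(a, b)[1] == 0.0


class TestApplyWaterScaling:
    def test_override_epsilon_exactly_gamma_times_combination(self, toy_adq):
        scheme = ScalingScheme(mode="sidechain-uncharged", gamma=1.10)
        scaled = apply_water_scaling(toy_adq, scheme)
        ow = find_water_oxygen_type(scaled)
        ow_rec = scaled.atom_types[ow]
        assert len(scaled.overrides) > 0
        for ov in scaled.overrides.values():
            other = ov.type_a if ov.type_b == ow else ov.type_b
            _, eps = combine_lj(scaled.atom_types[other], ow_rec)
            assert ov.epsilon == pytest.approx(1.10 * eps, rel=1e-12)

    def test_excluded_residue_types_carry_no_override(self, toy_adq):
        scheme = ScalingScheme(mode="sidechain-uncharged", gamma=1.10)
        scaled = apply_water_scaling(toy_adq, scheme)
        ow = find_water_oxygen_type(scaled)
        mol = scaled.molecules["Protein"]
        for atom in mol.atoms:
            if atom.residue_name == "ASP" and classify_atom(atom) is AtomClass.SIDECHAIN:
                assert scaled.lookup_override(atom.type_name, ow) is None

    def test_all_mode_override_count_equals_distinct_protein_types(self, toy_aqa):
        scaled = apply_water_scaling(toy_aqa, ScalingScheme(mode="all", gamma=1.10))
        protein_types = {
            a.type_name for a in toy_aqa.molecules["Protein"].atoms
        }
        assert len(scaled.overrides) == len(protein_types)

    def test_cloned_type_inherits_parent_parameters(self, toy_aqa):
        scaled = apply_water_scaling(
            toy_aqa, ScalingScheme(mode="sidechain", gamma=1.10)
        )
        clones = set(scaled.atom_types) - set(toy_aqa.atom_types)
        assert clones
        for cname in clones:
            parent = toy_aqa.atom_types[cname.removesuffix("_ws")]
            clone = scaled.atom_types[cname]
            assert (clone.sigma, clone.epsilon, clone.mass, clone.charge) == (
                parent.sigma, parent.epsilon, parent.mass, parent.charge,
            )

    def test_charge_and_mass_invariant(self, toy_aqa):
        scaled = apply_water_scaling(toy_aqa, ScalingScheme(mode="all", gamma=1.10))
        for name in toy_aqa.molecules:
            assert scaled.molecules[name].total_charge() == pytest.approx(
                toy_aqa.molecules[name].total_charge(), abs=1e-12
            )
            assert scaled.molecules[name].total_mass() == pytest.approx(
                toy_aqa.molecules[name].total_mass(), abs=1e-12
            )

    def test_preexisting_override_requires_force(self, toy_aqa):
        scheme = ScalingScheme(mode="backbone", gamma=1.10)
        scaled = apply_water_scaling(toy_aqa, scheme)
        with pytest.raises(TopologyError, match="pre-existing"):
            apply_water_scaling(scaled, scheme)
        again = apply_water_scaling(scaled, scheme, force=True)
        assert len(again.overrides) == len(scaled.overrides)

    def test_gamma_one_is_energy_neutral(self, toy_aqa, aqa_config):
        ident = apply_water_scaling(toy_aqa, ScalingScheme(mode="all", gamma=1.0))
        e0 = total_energy(toy_aqa, aqa_config)
        e1 = total_energy(ident, aqa_config)
        for term in ("lj", "coulomb", "dihedral"):
            assert abs(e1[term] - e0[term]) <= 1e-10 * max(1.0, abs(e0[term]))

    def test_coulomb_and_protein_only_energies_invariant(self, toy_aqa, aqa_config):
        scaled = apply_water_scaling(toy_aqa, ScalingScheme(mode="all", gamma=1.10))
        e0 = total_energy(toy_aqa, aqa_config)
        e1 = total_energy(scaled, aqa_config)
        assert e1["coulomb"] == e0["coulomb"]  # charges never modified
        # protein-only configuration: no water present, so LJ identical too
        protein_only = make_toy_topology("AQA", n_water=0)
        scaled_po = apply_water_scaling(
            protein_only, ScalingScheme(mode="all", gamma=1.10)
        )
        coords = random_configuration(protein_only, seed=3)
        assert total_energy(scaled_po, coords) == total_energy(protein_only, coords)


class TestHydrogenMassRepartitioning:
    def test_total_mass_conserved_and_h_set(self, toy_aqa):
        out = repartition_hydrogen_masses(toy_aqa, 1.5)
        for name in toy_aqa.molecules:
            assert out.molecules[name].total_mass() == pytest.approx(
                toy_aqa.molecules[name].total_mass(), abs=1e-9
            )
        for atom in out.molecules["Protein"].atoms:
            if atom.atom_name.startswith("H"):
                assert atom.mass == 1.5
        # water untouched
        assert [a.mass for a in out.molecules["SOL"].atoms] == [
            a.mass for a in toy_aqa.molecules["SOL"].atoms
        ]

    def test_methyl_carbon_loses_three_deltas(self, toy_aqa):
        out = repartition_hydrogen_masses(toy_aqa, 1.5)
        mol, old = out.molecules["Protein"], toy_aqa.molecules["Protein"]
        # alanine CB carries HB1-3
        cb_new = next(a for a in mol.atoms if a.atom_name == "CB" and a.residue_index == 1)
        cb_old = next(a for a in old.atoms if a.atom_name == "CB" and a.residue_index == 1)
        assert cb_new.mass == pytest.approx(cb_old.mass - 3 * (1.5 - 1.008), abs=1e-12)

    def test_identity_when_target_equals_current_mass(self, toy_aqa):
        out = repartition_hydrogen_masses(toy_aqa, 1.008)
        assert [a.mass for a in out.molecules["Protein"].atoms] == [
            a.mass for a in toy_aqa.molecules["Protein"].atoms
        ]

    def test_driving_heavy_atom_nonpositive_is_hard_error(self, toy_aqa):
        with pytest.raises(TopologyError, match="non-positive"):
            repartition_hydrogen_masses(toy_aqa, 13.0)
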