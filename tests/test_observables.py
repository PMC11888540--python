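"""Trajectory and shift observables against closed forms and
independent references."""

import io

import numpy as np
import pandas as pd
import pytest

from ffbalance.fixtures import (
    cone_s2,
    gaussian_chain,
    rigid_tumbling_trajectory,
    tumbling_vectors,
    wobble_vectors,
)
from ffbalance.observables import (
    ObservableSeries,
    Trajectory,
    agreement_rmsd,
    debye_saxs,
    dssp_assign,
    guinier_rg,
    helix_fraction,
    ired_s2,
    kabsch_rmsd,
    radius_of_gyration,
    read_shift_table,
    rmsf,
    secondary_shift_delta,
)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0

    def test_two_unit_masses_half_separation(self):
        frame = np.array([[0.0, 0.0, 0.0], [0.2, 0.0, 0.0]])
        assert radius_of_gyration(frame) == pytest.approx(0.1)

    def test_uniform_sphere_moment(self):
        rng = np.random.default_rng(0)
        n = 100_000
        direc = rng.normal(size=(n, 3))
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        radius = 1.7 * rng.uniform(size=(n, 1)) ** (1 / 3)
        rg = radius_of_gyration(direc * radius)
        assert rg == pytest.approx(np.sqrt(3 / 5) * 1.7, rel=0.01)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((0, 3)))


class TestKabsch:
    def test_identical_frames_zero(self):
        frame = np.random.default_rng(1).normal(size=(10, 3))
        assert kabsch_rmsd(frame, frame) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_superposes_to_zero(self):
        from scipy.spatial.transform import Rotation

        frame = np.random.default_rng(2).normal(size=(25, 3))
        moved = Rotation.from_euler("zyx", [0.7, -1.1, 2.0]).apply(frame) + [1, 2, 3]
        assert kabsch_rmsd(frame, moved) <= 1e-9

    def test_single_displacement_without_alignment(self):
        frame = np.random.default_rng(3).normal(size=(16, 3))
        moved = frame.copy()
        moved[4] += [0.3, 0.0, 0.0]
        assert kabsch_rmsd(frame, moved, align=False) == pytest.approx(
            0.3 / np.sqrt(16)
        )

    def test_collinear_selection_rejected(self):
        line = np.c_[np.linspace(0, 1, 5), np.zeros(5), np.zeros(5)]
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_rmsd(line, line)

    def test_rmsf_of_rigid_tumbling_is_zero(self):
        frame = np.random.default_rng(4).normal(size=(12, 3))
        traj = rigid_tumbling_trajectory(frame, n_frames=50, seed=5)
        series = rmsf(traj)
        assert np.all(series.values < 1e-9)


class TestDebyeSaxs:
    def test_forward_scattering_is_total_f_squared(self):
        frame = np.random.default_rng(6).normal(size=(20, 3))
        f = np.arange(1.0, 21.0)
        s = debye_saxs(frame, np.array([0.0]), form_factors=f)
        assert s.values[0] == pytest.approx(f.sum() ** 2)

    def test_single_atom_flat_curve(self):
        s = debye_saxs(np.zeros((1, 3)), np.linspace(0, 5, 11), form_factors=3.0)
        assert np.allclose(s.values, 9.0)

    def test_two_atom_closed_form(self):
        d = 0.5
        q = np.linspace(0.0, 10.0, 200)
        s = debye_saxs(np.array([[0, 0, 0], [0, 0, d]]), q, form_factors=2.0)
        expected = 2 * 4.0 * (1 + np.sinc(q * d / np.pi))
        assert np.allclose(s.values, expected, rtol=1e-9)

    def test_relabeling_symmetry_and_positivity(self):
        rng = np.random.default_rng(7)
        frame = rng.normal(size=(15, 3))
        q = np.linspace(0, 4, 40)
        s1 = debye_saxs(frame, q)
        perm = rng.permutation(15)
        s2 = debye_saxs(frame[perm], q)
        assert np.allclose(s1.values, s2.values)
        assert np.all(s1.values > 0)


class TestGuinier:
    def test_exact_gaussian_curve_recovered(self):
        rg_true = 1.27
        q = np.linspace(0.01, 2.0, 150)
        curve = ObservableSeries(q, 42.0 * np.exp(-(q**2) * rg_true**2 / 3))
        res = guinier_rg(curve)
        assert res.rg == pytest.approx(rg_true, abs=1e-6)
        assert res.i0 == pytest.approx(42.0, rel=1e-6)

    def test_sphere_form_factor_curve(self):
        radius = 2.0
        q = np.linspace(0.01, 1.5, 400)
        x = q * radius
        intensity = (3 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
        res = guinier_rg(ObservableSeries(q, intensity))
        assert res.rg == pytest.approx(np.sqrt(3 / 5) * radius, rel=0.02)

    def test_two_atom_molecule_within_five_percent(self):
        frame = np.array([[0, 0, 0], [0, 0, 0.2]])
        rg_direct = radius_of_gyration(frame)
        q = np.linspace(0.01, 12.0, 500)
        res = guinier_rg(debye_saxs(frame, q), qrg_max=1.0)
        assert res.rg == pytest.approx(rg_direct, rel=0.05)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_compact_cluster_recovery_within_three_percent(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=0.5, size=(300, 3))
        rg_direct = radius_of_gyration(pts)
        q = np.linspace(0.01, 2.0 / rg_direct, 300)
        res = guinier_rg(debye_saxs(pts, q), qrg_max=1.0)
        assert res.rg == pytest.approx(rg_direct, rel=0.03)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 points"):
            guinier_rg(ObservableSeries(np.array([0.1, 0.2]), np.array([1.0, 0.9])))


class TestSecondaryStructure:
    def test_ideal_helix_interior_assigned_h(self, helix15):
        ss = dssp_assign(helix15)
        assert set(ss[2:13]) == {"H"}

    def test_extended_chain_no_helix(self, extended15):
        series, _ = helix_fraction(extended15)
        assert np.all(series.values == 0.0)

    def test_alternating_frames_half_fraction(self, helix15, extended15):
        traj = Trajectory(
            np.concatenate([helix15.coords, extended15.coords]),
            helix15.atom_names,
            helix15.residue_indices,
            helix15.residue_names,
        )
        series, assignments = helix_fraction(traj)
        assert len(assignments) == 2
        assert np.all(series.values[4:11] == 0.5)

    def test_matches_reference_dssp_implementation(self, helix15, extended15):
        mdtraj = pytest.importorskip("mdtraj")
        for fixture in (helix15, extended15):
            top = mdtraj.Topology()
            chain = top.add_chain()
            for ri in sorted(set(fixture.residue_indices.tolist())):
                res = top.add_residue("ALA", chain, resSeq=ri)
                for nm, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                    top.add_atom(nm, mdtraj.element.get_by_symbol(el), res)
            ref = mdtraj.compute_dssp(
                mdtraj.Trajectory(fixture.coords, top), simplified=True
            )[0]
            ours = dssp_assign(fixture)
            assert "".join(ref) == ours

    def test_missing_backbone_oxygen_is_hard_error(self, helix15):
        keep = [i for i, n in enumerate(helix15.atom_names) if n != "O"]
        traj = Trajectory(
            helix15.coords[:, keep],
            [helix15.atom_names[i] for i in keep],
            helix15.residue_indices[keep],
            [helix15.residue_names[i] for i in keep],
        )
        with pytest.raises(ValueError, match="missing backbone O"):
            dssp_assign(traj)


SHIFTS_OBS = """\
# res name ca cb
1 ALA 54.3 18.1
2 GLN 58.0 28.0
3 GLY 45.2 nan
"""
SHIFTS_COIL = """\
1 ALA 52.3 19.1
2 GLN 56.0 29.0
3 GLY 45.0 nan
"""


class TestSecondaryShifts:
    def _tables(self):
        return (
            read_shift_table(io.StringIO(SHIFTS_OBS)),
            read_shift_table(io.StringIO(SHIFTS_COIL)),
        )

    def test_identical_tables_all_zero(self):
        obs, _ = self._tables()
        series = secondary_shift_delta(obs, obs)
        assert np.allclose(series.values, 0.0)

    def test_helical_sign_convention(self):
        obs, coil = self._tables()
        series = secondary_shift_delta(obs, coil)
        # Ca +2 ppm and Cb -1 ppm vs coil -> +3 ppm (helical)
        assert series.values[0] == pytest.approx(3.0)
        assert series.values[1] == pytest.approx(3.0)

    def test_glycine_uses_ca_only_and_is_flagged(self):
        obs, coil = self._tables()
        series = secondary_shift_delta(obs, coil)
        assert series.values[2] == pytest.approx(0.2)
        assert "3" in series.units

    def test_row_order_independence(self):
        obs, coil = self._tables()
        shuffled = obs.iloc[[2, 0, 1]].reset_index(drop=True)
        a = secondary_shift_delta(obs, coil)
        b = secondary_shift_delta(shuffled, coil)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.values, b.values)

    def test_residue_mismatch_lists_rows(self):
        obs, coil = self._tables()
        coil2 = coil.copy()
        coil2.loc[2, "residue_index"] = 7
        with pytest.raises(ValueError, match="mismatch"):
            secondary_shift_delta(obs, coil2)


class TestIredS2:
    def test_rigid_tumbling_near_one(self):
        base = np.random.default_rng(2).normal(size=(10, 3))
        vectors = tumbling_vectors(base, n_frames=10_000, seed=3)
        s2 = ired_s2(vectors)
        assert np.all(s2.values >= 0.95)

    def test_independent_vectors_near_zero(self):
        vectors = np.random.default_rng(4).normal(size=(10_000, 100, 3))
        s2 = ired_s2(vectors)
        assert np.all(s2.values <= 0.2)

    def test_single_frame_repeated_gives_one(self):
        u = np.tile(np.array([0.0, 0.0, 1.0]), (12, 1))
        vectors = np.tile(u, (20, 1, 1))
        assert np.allclose(ired_s2(vectors).values, 1.0)

    def test_bounded_and_monotone_in_cone_angle(self):
        base = np.random.default_rng(5).normal(size=(50, 3))
        means = []
        for theta in (0.0, 15.0, 30.0, 45.0):
            v = wobble_vectors(base, theta, n_frames=4000, seed=6)
            s2 = ired_s2(v)
            assert np.all((s2.values >= 0.0) & (s2.values <= 1.0))
            means.append(s2.values.mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_cone_closed_form(self):
        base = np.random.default_rng(7).normal(size=(50, 3))
        for theta in (10.0, 20.0, 30.0):
            v = wobble_vectors(base, theta, n_frames=10_000, seed=8)
            s2 = ired_s2(v)
            assert s2.values.mean() == pytest.approx(cone_s2(theta), abs=0.05)

    def test_block_averaging_reports_spread(self):
        base = np.random.default_rng(9).normal(size=(10, 3))
        v = wobble_vectors(base, 20.0, n_frames=2000, seed=10)
        s2 = ired_s2(v, n_blocks=4)
        assert s2.uncertainty is not None
        assert np.all(s2.uncertainty >= 0)

    def test_few_residues_warns(self):
        v = tumbling_vectors(np.eye(3)[:2], n_frames=100, seed=1)
        with pytest.warns(UserWarning, match="fewer than 6"):
            ired_s2(v)


class TestAgreement:
    def test_identical_series_zero(self):
        s = ObservableSeries(np.arange(5), np.linspace(0, 1, 5))
        assert agreement_rmsd(s, s) == 0.0

    def test_constant_offset(self):
        a = ObservableSeries(np.arange(5), np.zeros(5))
        b = ObservableSeries(np.arange(5), np.full(5, 0.7))
        assert agreement_rmsd(a, b) == pytest.approx(0.7)

    def test_hand_computed_example(self):
        a = ObservableSeries(np.arange(3), np.array([1.0, 2.0, 3.0]))
        b = ObservableSeries(np.arange(3), np.array([1.0, 2.0, 5.0]))
        assert agreement_rmsd(a, b) == pytest.approx(np.sqrt(4 / 3))

    def test_label_mismatch_rejected(self):
        a = ObservableSeries(np.arange(3), np.zeros(3))
        b = ObservableSeries(np.arange(1, 4), np.zeros(3))
        with pytest.raises(ValueError, match="labels"):
            agreement_rmsd(a, b)
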