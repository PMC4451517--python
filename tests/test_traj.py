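"""Trajectory I/O, superposition, and the MD-derived metrics."""

import numpy as np
import pytest

from lipidsite import (
    DegenerateInputError,
    HBondCriteria,
    InputError,
    ParseError,
    Trajectory,
    contact_occupancy,
    hbond_occupancy,
    neutralizing_ions,
    penetration_depth,
    pocket_hydration,
    read_trajectory,
    rmsf,
    superpose_frames,
    write_trajectory,
)
from lipidsite.synthetic import gen_trajectory, toy_complex
from lipidsite.traj import Atom, Topology


def _static_traj(toy_system, n_frames=5):
    topo, base = toy_system
    return Trajectory(topology=topo,
                      frames=np.tile(base, (n_frames, 1, 1)))


class TestTrajectoryIO:
    def test_single_frame_pdb(self, tmp_path, toy_system):
        traj = _static_traj(toy_system, n_frames=1)
        path = tmp_path / "one.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 1
        assert len(back.topology) == len(traj.topology)

    @pytest.mark.parametrize("fmt", ["pdb", "xyz"])
    def test_round_trip_at_format_precision(self, tmp_path, toy_system, fmt):
        topo, base = toy_system
        traj, _ = gen_trajectory(topo, base, n_frames=4, jitter_sigma=0.3, seed=5)
        path = tmp_path / f"t.{fmt}"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        tol = 5e-4 if fmt == "pdb" else 5e-7
        assert np.allclose(back.frames, traj.frames, atol=tol)
        # a second write of the re-read trajectory is byte-identical
        path2 = tmp_path / f"t2.{fmt}"
        write_trajectory(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_pdb_metadata_preserved(self, tmp_path, toy_system):
        traj = _static_traj(toy_system, 2)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        for a, b in zip(traj.topology.atoms, back.topology.atoms):
            assert (a.name, a.element, a.resname, a.resid, a.chain) == (
                b.name, b.element, b.resname, b.resid, b.chain
            )
        for name in ("protein", "ligand", "water-oxygen", "heme", "dioxygen"):
            assert np.array_equal(
                back.topology.selections[name], traj.topology.selections[name]
            )

    def test_atom_count_drift_names_frame(self, tmp_path, toy_system):
        traj = _static_traj(toy_system, 3)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        lines = path.read_text().splitlines()
        # drop one atom line from the third MODEL
        third_model = [i for i, ln in enumerate(lines) if ln.startswith("MODEL")][2]
        del lines[third_model + 1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="frame 3"):
            read_trajectory(path)

    def test_unknown_element_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("1\nframe 1\nXx 0.0 0.0 0.0\n")
        with pytest.raises(ParseError, match="unknown element"):
            read_trajectory(path)

    def test_mdanalysis_reads_our_pdb_identically(self, tmp_path, toy_system):
        mda = pytest.importorskip("MDAnalysis")
        topo, base = toy_system
        traj, _ = gen_trajectory(topo, base, n_frames=3, jitter_sigma=0.2, seed=9)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        u = mda.Universe(str(path))
        assert len(u.atoms) == len(topo)
        got = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        ours = read_trajectory(path).frames
        assert np.allclose(got, ours, atol=1e-3)


class TestSuperposition:
    def test_rigid_motion_removed(self, rng, toy_system):
        topo, base = toy_system
        from scipy.spatial.transform import Rotation

        frames = [base]
        for _ in range(4):
            rot = Rotation.random(random_state=rng).as_matrix()
            frames.append(base @ rot.T + rng.normal(scale=5.0, size=3))
        traj = Trajectory(topology=topo, frames=np.array(frames))
        fitted = superpose_frames(traj, 0)
        for m in range(5):
            assert np.abs(fitted.frames[m] - base).max() < 1e-6

    def test_reference_onto_itself_is_identity(self, toy_system):
        traj = _static_traj(toy_system, 3)
        fitted = superpose_frames(traj, 0)
        assert np.allclose(fitted.frames, traj.frames, atol=1e-9)

    def test_matches_mdanalysis_fit_rmsd(self, rng, toy_system):
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.align import rotation_matrix

        topo, base = toy_system
        heavy = topo.heavy
        traj, _ = gen_trajectory(topo, base, n_frames=5, jitter_sigma=0.8, seed=4)
        fitted = superpose_frames(traj, 0, fit_selection=heavy)
        ref = traj.frames[0, heavy]
        for m in range(traj.n_frames):
            mob = traj.frames[m, heavy]
            _R, mda_rmsd = rotation_matrix(
                mob - mob.mean(axis=0), ref - ref.mean(axis=0)
            )
            ours = np.sqrt(
                ((fitted.frames[m, heavy] - ref) ** 2).sum(axis=1).mean()
            )
            assert ours == pytest.approx(mda_rmsd, abs=1e-6)

    def test_too_few_fit_atoms_rejected(self, toy_system):
        traj = _static_traj(toy_system)
        with pytest.raises(InputError, match="3 fit atoms"):
            superpose_frames(traj, 0, fit_selection=np.array([0, 1]))


class TestRmsf:
    def test_static_trajectory_is_zero(self, toy_system):
        assert np.all(rmsf(_static_traj(toy_system)) == 0.0)

    def test_two_frame_hand_case(self, toy_system):
        topo, base = toy_system
        frames = np.tile(base, (2, 1, 1))
        frames[1, 0, 0] += 2.0  # one atom moves 0 -> 2 along x
        traj = Trajectory(topology=topo, frames=frames)
        values = rmsf(traj, selection=np.arange(3))
        assert values[0] == pytest.approx(1.0)
        assert np.all(values[1:] == 0.0)

    def test_gaussian_jitter_matches_sigma_sqrt3(self, toy_system):
        topo, base = toy_system
        traj, gt = gen_trajectory(topo, base, n_frames=4000, jitter_sigma=0.5,
                                  seed=12)
        values = rmsf(traj)
        assert np.allclose(values, gt.expected_rmsf, rtol=0.05)

    def test_hydrogens_excluded_by_default(self):
        atoms = [
            Atom("CA", "C", "GLY", 1, "A", False),
            Atom("HA", "H", "GLY", 1, "A", True),
            Atom("CB", "C", "GLY", 1, "A", False),
        ]
        topo = Topology(atoms=atoms)
        frames = np.zeros((3, 3, 3))
        frames[:, 1, 0] = [0.0, 5.0, 10.0]  # only the hydrogen moves
        values = rmsf(Trajectory(topology=topo, frames=frames))
        assert values.shape == (2,)
        assert np.all(values == 0.0)

    def test_per_residue_averaging(self, toy_system):
        topo, base = toy_system
        traj, _ = gen_trajectory(topo, base, n_frames=50, jitter_sigma=0.3, seed=3)
        series = rmsf(traj, per_residue=True)
        assert "A:LYS:5" in series.index
        per_atom = rmsf(traj, selection=topo.select(resid=5, heavy_only=True))
        assert series["A:LYS:5"] == pytest.approx(per_atom.mean())

    def test_single_frame_is_degenerate(self, toy_system):
        with pytest.raises(DegenerateInputError):
            rmsf(_static_traj(toy_system, n_frames=1))

    def test_invariant_under_frame_reordering(self, rng, toy_system):
        topo, base = toy_system
        traj, _ = gen_trajectory(topo, base, n_frames=40, jitter_sigma=0.4, seed=7)
        perm = rng.permutation(traj.n_frames)
        shuffled = Trajectory(topology=topo, frames=traj.frames[perm])
        assert np.allclose(rmsf(traj), rmsf(shuffled))


class TestHbondOccupancy:
    def test_all_frames_bound_gives_100(self, toy_system, toy_indices):
        topo, base = toy_system
        traj, _ = gen_trajectory(
            topo, base, 50, hbond_pair=(toy_indices["donor"], toy_indices["acceptor"]),
            hbond_fraction=1.0, seed=1,
        )
        occ, flags = hbond_occupancy(traj, [toy_indices["donor"]],
                                     [toy_indices["acceptor"]])
        assert occ == 100.0 and flags.all()

    def test_never_bound_gives_0(self, toy_system, toy_indices):
        topo, base = toy_system
        traj, _ = gen_trajectory(
            topo, base, 50, hbond_pair=(toy_indices["donor"], toy_indices["acceptor"]),
            hbond_fraction=0.0, seed=1,
        )
        occ, flags = hbond_occupancy(traj, [toy_indices["donor"]],
                                     [toy_indices["acceptor"]])
        assert occ == 0.0 and not flags.any()

    def test_constructed_fraction_recovered_exactly(self, toy_system, toy_indices):
        topo, base = toy_system
        for frac in (0.1, 0.25, 0.6):
            traj, gt = gen_trajectory(
                topo, base, 200,
                hbond_pair=(toy_indices["donor"], toy_indices["acceptor"]),
                hbond_fraction=frac, seed=21,
            )
            occ, flags = hbond_occupancy(traj, [toy_indices["donor"]],
                                         [toy_indices["acceptor"]])
            assert occ == pytest.approx(100.0 * frac)
            assert np.array_equal(np.nonzero(flags)[0], gt.bound_frames)

    def test_angle_criterion_with_hydrogens(self):
        # donor N with its H pointing at the acceptor -> accepted; pointing
        # away -> rejected although the distance criterion passes
        atoms = [
            Atom("N", "N", "LYS", 1, "A", False),
            Atom("HN", "H", "LYS", 1, "A", True),
            Atom("O", "O", "PLM", 2, "L", False, True),
        ]
        topo = Topology(atoms=atoms)
        toward = np.array([[[0, 0, 0], [1.0, 0, 0], [2.8, 0, 0]]])
        away = np.array([[[0, 0, 0], [-1.0, 0, 0], [2.8, 0, 0]]])
        occ_t, _ = hbond_occupancy(
            Trajectory(topology=topo, frames=toward), [0], [2]
        )
        occ_a, _ = hbond_occupancy(
            Trajectory(topology=topo, frames=away), [0], [2]
        )
        assert occ_t == 100.0
        assert occ_a == 0.0

    def test_empty_selection_rejected(self, toy_system):
        traj = _static_traj(toy_system)
        with pytest.raises(InputError, match="empty"):
            hbond_occupancy(traj, [], [1])


class TestContactsDepthHydration:
    def test_far_ligand_gives_all_zero_table(self, toy_system):
        topo, _base = toy_system
        traj = _static_traj(toy_system)
        table = contact_occupancy(traj, topo.selections["ligand"], cutoff=4.0)
        assert (table["occupancy_pct"] == 0.0).all()

    def test_fixed_contact_at_100_percent(self, toy_system, toy_indices):
        topo, base = toy_system
        traj, _ = gen_trajectory(topo, base, 20, contact_plan={3: 1.0}, seed=2)
        table = contact_occupancy(traj, topo.selections["ligand"], cutoff=4.0)
        row = table[table.resid == 3].iloc[0]
        assert row.occupancy_pct == 100.0

    def test_planned_fractions_recovered_exactly(self, toy_system):
        topo, base = toy_system
        traj, gt = gen_trajectory(
            topo, base, 50, contact_plan={2: 0.6, 7: 0.3}, seed=6
        )
        table = contact_occupancy(traj, topo.selections["ligand"], cutoff=4.0)
        lookup = dict(zip(table.resid, table.occupancy_pct))
        assert lookup[2] == pytest.approx(60.0)
        assert lookup[7] == pytest.approx(30.0)
        assert list(table.occupancy_pct) == sorted(table.occupancy_pct,
                                                   reverse=True)

    def test_static_trajectory_zero_depth(self, toy_system, toy_indices):
        assert penetration_depth(_static_traj(toy_system),
                                 toy_indices["tail"]) == 0.0

    @pytest.mark.parametrize("d", [5.0, 5.98, 6.92])
    def test_constructed_displacement_recovered(self, toy_system, toy_indices, d):
        topo, base = toy_system
        traj, _ = gen_trajectory(topo, base, 30, tail_atom=toy_indices["tail"],
                                 tail_displacement=d, seed=8)
        assert penetration_depth(traj, toy_indices["tail"]) == pytest.approx(
            d, abs=1e-6
        )

    def test_three_four_five_displacement(self, toy_system):
        topo, base = toy_system
        frames = np.tile(base, (2, 1, 1))
        frames[1, 0] += np.array([3.0, 4.0, 0.0])
        traj = Trajectory(topology=topo, frames=frames)
        assert penetration_depth(traj, 0) == pytest.approx(5.0)

    def test_depth_out_of_range_index(self, toy_system):
        with pytest.raises(InputError, match="out of range"):
            penetration_depth(_static_traj(toy_system), 10_000)

    def test_planted_waters_counted_every_frame(self, toy_system, toy_indices):
        topo, base = toy_system
        traj, gt = gen_trajectory(
            topo, base, 15, water_plan=(2, 3), site_atom=toy_indices["anchor"],
            water_radius=3.5, seed=13,
        )
        counts, mean = pocket_hydration(traj, [toy_indices["anchor"]], radius=3.5)
        assert np.all(counts == 2)
        assert mean == 2.0

    def test_no_waters_in_topology_gives_zero(self):
        atoms = [Atom("CA", "C", "GLY", 1, "A", False)]
        topo = Topology(atoms=atoms)
        traj = Trajectory(topology=topo, frames=np.zeros((3, 1, 3)))
        counts, mean = pocket_hydration(traj, [0], radius=5.0)
        assert np.all(counts == 0) and mean == 0.0

    def test_metrics_invariant_under_global_rigid_transform(self, toy_system,
                                                            toy_indices):
        from scipy.spatial.transform import Rotation

        topo, base = toy_system
        traj, _ = gen_trajectory(
            topo, base, 30, jitter_sigma=0.2,
            hbond_pair=(toy_indices["donor"], toy_indices["acceptor"]),
            hbond_fraction=0.4, seed=17,
        )
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = Trajectory(
            topology=topo, frames=traj.frames @ rot.T + np.array([5.0, -3.0, 8.0])
        )
        assert np.allclose(rmsf(traj), rmsf(moved), atol=1e-9)
        occ_a, _ = hbond_occupancy(traj, [toy_indices["donor"]],
                                   [toy_indices["acceptor"]])
        occ_b, _ = hbond_occupancy(moved, [toy_indices["donor"]],
                                   [toy_indices["acceptor"]])
        assert occ_a == occ_b


class TestNeutralizingIons:
    @pytest.mark.parametrize(
        "pairs,charge,expected",
        [
            (0, 0, (0, 0)),
            (25, -1, (26, 25)),  # the published oxy-Mb recipe
            (10, 2, (10, 12)),
        ],
    )
    def test_examples(self, pairs, charge, expected):
        assert neutralizing_ions(pairs, charge) == expected

    def test_net_charge_always_zero(self, rng):
        for _ in range(200):
            pairs = int(rng.integers(0, 100))
            q = int(rng.integers(-20, 21))
            n_na, n_cl = neutralizing_ions(pairs, q)
            assert q + n_na - n_cl == 0
            assert n_na >= pairs and n_cl >= pairs

    def test_negative_pairs_rejected(self):
        with pytest.raises(InputError):
            neutralizing_ions(-1, 0)
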