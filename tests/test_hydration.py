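import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from csindel.hydration import (
    Atom,
    Frame,
    PdbParseError,
    Selection,
    Trajectory,
    WaterSiteSet,
    count_waters_within,
    extract_snapshots,
    hbond_count,
    hydration_series,
    read_multimodel_pdb,
    rmsd,
    site_occupancy,
    write_multimodel_pdb,
)
from csindel.synth import TrajSpec, generate_hydration_trajectory
from conftest import random_frame

LIGAND = Selection(residue_name="ADP")
TARGET = Selection(residue_number=185, atom_name="O")


def water(serial, resnum, pos, time_independent_chain="W"):
    return Atom(serial, "OW", "HOH", resnum, time_independent_chain, np.asarray(pos, float))


def simple_frame(*water_positions, ligand_at=(0.0, 0.0, 0.0), time=100.0):
    atoms = [Atom(1, "C1", "ADP", 1, "A", np.asarray(ligand_at, float))]
    for i, p in enumerate(water_positions):
        atoms.append(water(2 + i, 300 + i, p))
    return Frame(time, atoms)


# --- PDB I/O -----------------------------------------------------------------

def test_single_model_pdb(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(
        "ATOM      1  CA  GLY A   1       1.000   2.000   3.000\n"
        "ATOM      2  CB  GLY A   1       2.000   2.000   3.000\n"
        "HETATM    3  OW  HOH W 300       9.000   0.000   0.000\n"
    )
    traj = read_multimodel_pdb(str(p), frame_interval=100.0)
    assert len(traj) == 1
    f = traj.frames[0]
    assert len(f.atoms) == 3
    assert f.atoms[0].name == "CA" and f.atoms[0].residue_name == "GLY"
    np.testing.assert_allclose(f.atoms[0].position, [1, 2, 3])


def test_model_ordinal_times(tmp_path):
    p = tmp_path / "five.pdb"
    lines = []
    for m in range(1, 6):
        lines.append(f"MODEL {m:8d}")
        lines.append(
            "ATOM      1  CA  GLY A   1    "
            f"{float(m):8.3f}{0.0:8.3f}{0.0:8.3f}"
        )
        lines.append("ENDMDL")
    p.write_text("\n".join(lines) + "\n")
    traj = read_multimodel_pdb(str(p), frame_interval=100.0)
    assert [f.time for f in traj.frames] == [100.0, 200.0, 300.0, 400.0, 500.0]


def test_malformed_atom_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text(
        "ATOM      1  CA  GLY A   1       1.000   2.000   3.000\n"
        "ATOM      2  CB  GLY A   1       xxx      2.000   3.000\n"
    )
    with pytest.raises(PdbParseError, match="line 2"):
        read_multimodel_pdb(str(p))


def test_pdb_write_read_round_trip(tmp_path):
    traj, _ = generate_hydration_trajectory(TrajSpec(n_frames=3, seed=1))
    path = tmp_path / "rt.pdb"
    write_multimodel_pdb(traj, str(path))
    back = read_multimodel_pdb(str(path))
    assert len(back) == len(traj)
    for f1, f2 in zip(traj.frames, back.frames):
        assert f1.time == f2.time
        assert len(f1.atoms) == len(f2.atoms)
        for a1, a2 in zip(f1.atoms, f2.atoms):
            assert (a1.name, a1.residue_name, a1.residue_number) == (
                a2.name, a2.residue_name, a2.residue_number
            )
            np.testing.assert_allclose(a1.position, a2.position, atol=5e-4)


# --- snapshot extraction -----------------------------------------------------

def one_atom_frames(times):
    return Trajectory(
        [Frame(t, [Atom(1, "CA", "GLY", 1, "A", np.zeros(3))]) for t in times]
    )


def test_hundred_ns_at_hundred_ps_gives_thousand_snapshots():
    traj = one_atom_frames(np.arange(100.0, 100001.0, 100.0))
    out = extract_snapshots(traj, 100.0)
    assert len(out) == 1000
    assert out.frames[0].time == 100.0 and out.frames[-1].time == 100000.0


@pytest.mark.parametrize(
    "duration,interval,expected", [(1000.0, 100.0, 10), (50.0, 100.0, 0)]
)
def test_snapshot_counts(duration, interval, expected):
    traj = one_atom_frames(np.arange(10.0, duration + 1.0, 10.0))
    assert len(extract_snapshots(traj, interval)) == expected


def test_snapshot_grid_excludes_time_zero():
    traj = one_atom_frames([0.5, 100.0, 200.0])
    out = extract_snapshots(traj, 100.0)
    assert [f.time for f in out.frames] == [100.0, 200.0]


# --- shell-water counting ----------------------------------------------------

def test_boundary_inclusive_count():
    assert count_waters_within(simple_frame([8.9, 0, 0]), LIGAND, 9.0) == 1
    assert count_waters_within(simple_frame([9.0, 0, 0]), LIGAND, 9.0) == 1
    assert count_waters_within(simple_frame([9.1, 0, 0]), LIGAND, 9.0) == 0


def test_empty_ligand_selection_errors():
    with pytest.raises(ValueError, match="no atoms"):
        count_waters_within(simple_frame([1, 0, 0]), Selection(residue_name="ATP"))


def brute_force_count(frame, radius):
    waters = [a for a in frame.atoms if a.residue_name == "HOH" and a.name[0] == "O"]
    lig = [a for a in frame.atoms if a.residue_name == "ADP"]
    n = 0
    for w in waters:
        for l in lig:
            if np.linalg.norm(w.position - l.position) <= radius:
                n += 1
                break
    return n


def test_count_matches_brute_force(rng):
    for _ in range(30):
        frame = random_frame(rng, n_waters=200, n_ligand=10)
        r = float(rng.uniform(3, 15))
        assert count_waters_within(frame, LIGAND, r) == brute_force_count(frame, r)


def test_count_monotone_in_radius(rng):
    frame = random_frame(rng, n_waters=300, n_ligand=10)
    counts = [count_waters_within(frame, LIGAND, r) for r in np.linspace(1, 20, 15)]
    assert all(a <= b for a, b in zip(counts, counts[1:]))


# --- hydration series --------------------------------------------------------

def test_constant_occupancy_window_means_equal_overall():
    frames = [simple_frame([5, 0, 0], [6, 0, 0], time=t) for t in (100.0, 200.0, 300.0, 400.0)]
    traj = Trajectory(frames)
    s = hydration_series(traj, LIGAND, 9.0, {"a": (0, 250), "b": (250, 500)})
    assert s.mean == 2.0
    assert s.window_means == {"a": 2.0, "b": 2.0}


def test_two_window_step_straddles_overall_mean():
    frames = [simple_frame(*([[5, 0, 0]] * (1 if t <= 200 else 3)), time=t)
              for t in (100.0, 200.0, 300.0, 400.0)]
    traj = Trajectory(frames)
    s = hydration_series(traj, LIGAND, 9.0, {"lo": (0, 250), "hi": (250, 500)})
    assert s.window_means["lo"] < s.mean < s.window_means["hi"]


def test_empty_window_errors():
    traj = Trajectory([simple_frame([5, 0, 0], time=100.0)])
    with pytest.raises(ValueError, match="no frames"):
        hydration_series(traj, LIGAND, 9.0, {"w": (500.0, 600.0)})


# --- hydrogen bonds ----------------------------------------------------------

def target_frame(*water_positions):
    atoms = [Atom(1, "O", "GLU", 185, "A", np.zeros(3))]
    for i, p in enumerate(water_positions):
        atoms.append(water(2 + i, 300 + i, p))
    return Frame(100.0, atoms)


def test_hbond_distance_criterion():
    assert hbond_count(target_frame([3.4, 0, 0]), TARGET) == 1
    # within the 4 A search shell but beyond the 3.5 A bond cutoff
    assert hbond_count(target_frame([3.6, 0, 0]), TARGET) == 0
    assert hbond_count(target_frame([4.1, 0, 0]), TARGET) == 0


def test_hbond_requires_unique_target():
    f = target_frame([3.0, 0, 0])
    f.atoms.append(Atom(99, "O", "GLU", 185, "B", np.array([10.0, 0, 0])))
    with pytest.raises(ValueError, match="exactly 1"):
        hbond_count(f, Selection(residue_number=185, atom_name="O"))


def test_hbond_angle_mode():
    f = target_frame([3.0, 0.0, 0.0])
    # hydrogen pointing at the acceptor: angle 0, bond accepted
    f.atoms.append(Atom(50, "HW1", "HOH", 300, "W", np.array([2.0, 0.0, 0.0])))
    f.atoms.append(Atom(51, "HW2", "HOH", 300, "W", np.array([3.3, 0.9, 0.0])))
    assert hbond_count(f, TARGET, angle_cutoff=30.0) == 1
    # hydrogens pointing away: rejected
    f2 = target_frame([3.0, 0.0, 0.0])
    f2.atoms.append(Atom(50, "HW1", "HOH", 300, "W", np.array([3.5, 0.8, 0.0])))
    f2.atoms.append(Atom(51, "HW2", "HOH", 300, "W", np.array([3.5, -0.8, 0.0])))
    assert hbond_count(f2, TARGET, angle_cutoff=30.0) == 0


def test_hbond_never_exceeds_shell_population(rng):
    for _ in range(20):
        waters = [rng.uniform(-6, 6, 3) for _ in range(30)]
        f = target_frame(*waters)
        in_shell = sum(
            1 for w in waters if np.linalg.norm(w) <= 4.0
        )
        assert hbond_count(f, TARGET) <= in_shell


# --- site occupancy ----------------------------------------------------------

def test_fixed_water_gives_full_occupancy():
    frames = [simple_frame([0, 0, 15], time=t) for t in (100.0, 200.0, 300.0)]
    traj = Trajectory(frames)
    sites = WaterSiteSet(sites=np.array([[0.0, 0.0, 15.0]]), match_radius=1.5)
    out = site_occupancy(traj, sites)
    assert out.occupancies[0] == 1.0
    assert out.longest_runs[0] == 3


def test_unvisited_site_has_zero_occupancy():
    frames = [simple_frame([5, 0, 0], time=t) for t in (100.0, 200.0)]
    traj = Trajectory(frames)
    sites = WaterSiteSet(sites=np.array([[30.0, 30.0, 30.0]]))
    out = site_occupancy(traj, sites)
    assert out.occupancies[0] == 0.0 and out.longest_runs[0] == 0


def test_longest_run_tracks_consecutive_frames():
    positions = [[0, 0, 15], [30, 0, 0], [0, 0, 15], [0, 0, 15], [0, 0, 15]]
    frames = [simple_frame(p, time=100.0 * (i + 1)) for i, p in enumerate(positions)]
    out = site_occupancy(
        Trajectory(frames), WaterSiteSet(sites=np.array([[0.0, 0.0, 15.0]]))
    )
    assert out.occupancies[0] == pytest.approx(0.8)
    assert out.longest_runs[0] == 3


# --- RMSD --------------------------------------------------------------------

def test_rmsd_identical_frames_is_zero(rng):
    f = random_frame(rng, n_waters=10, n_ligand=10)
    assert rmsd(f, f) == pytest.approx(0.0, abs=1e-12)


def test_rmsd_rigid_motion_superposes_to_zero(rng):
    f = random_frame(rng, n_waters=20, n_ligand=10)
    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-20, 20, 3)
    moved = Frame(
        f.time,
        [
            Atom(a.serial, a.name, a.residue_name, a.residue_number, a.chain,
                 rot.apply(a.position) + shift)
            for a in f.atoms
        ],
    )
    assert rmsd(moved, f, superpose=True) == pytest.approx(0.0, abs=1e-6)
    assert rmsd(moved, f, superpose=True) == pytest.approx(
        rmsd(f, moved, superpose=True), abs=1e-9
    )


def test_rmsd_single_displacement_closed_form(rng):
    n, d = 40, 2.5
    f = random_frame(rng, n_waters=n - 11, n_ligand=10)
    atoms = [
        Atom(a.serial, a.name, a.residue_name, a.residue_number, a.chain,
             a.position.copy())
        for a in f.atoms
    ]
    atoms[0].position = atoms[0].position + np.array([d, 0.0, 0.0])
    moved = Frame(f.time, atoms)
    assert rmsd(moved, f, superpose=False) == pytest.approx(
        d / np.sqrt(len(atoms)), rel=1e-12
    )


def test_rmsd_atom_count_mismatch_errors(rng):
    f1 = random_frame(rng, n_waters=5, n_ligand=5)
    f2 = random_frame(rng, n_waters=6, n_ligand=5)
    with pytest.raises(ValueError, match="differ"):
        rmsd(f1, f2)


# --- global rigid-motion invariance ------------------------------------------

def rigid_copy(frame, rot, shift):
    return Frame(
        frame.time,
        [
            Atom(a.serial, a.name, a.residue_name, a.residue_number, a.chain,
                 rot.apply(a.position) + shift)
            for a in frame.atoms
        ],
    )


def test_geometric_ops_invariant_under_global_motion(rng):
    frame = random_frame(rng, n_waters=100, n_ligand=10)
    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-30, 30, 3)
    moved = rigid_copy(frame, rot, shift)
    assert count_waters_within(frame, LIGAND, 9.0) == count_waters_within(
        moved, LIGAND, 9.0
    )
    assert hbond_count(frame, TARGET) == hbond_count(moved, TARGET)
    sites = rng.uniform(-10, 10, (4, 3))
    occ1 = site_occupancy(Trajectory([frame]), WaterSiteSet(sites=sites))
    occ2 = site_occupancy(
        Trajectory([moved]), WaterSiteSet(sites=rot.apply(sites) + shift)
    )
    np.testing.assert_array_equal(occ1.occupancies, occ2.occupancies)
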