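"""Hydration and stability analysis of trajectory snapshots.

Operates on multi-model PDB snapshot sets taken from an MD trajectory:
counts of water molecules in a shell around a ligand (e.g. waters within
9 Å of bound ADP), occupancy of conserved water sites defined by
crystallographic water positions, geometric hydrogen-bond time series for a
chosen acceptor atom (e.g. the backbone O of a conserved Glu), and
superposition RMSD against a reference frame.

All cutoffs are inclusive.  Periodic boundary conditions are not applied:
snapshots are assumed whole and clustered around the solute, which is the
form in which per-frame PDB extracts are normally written.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

#: residue names recognised as water
WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT"})


@dataclass
class Atom:
    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray  # (3,) in Å

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: bad coordinates")


@dataclass
class Frame:
    """One trajectory snapshot: a time stamp (ps) and its atoms."""

    time: float
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("frame time must be >= 0")
        if not self.atoms:
            raise ValueError("frame has no atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def water_oxygens(
        self, water_resnames: frozenset[str] = WATER_RESNAMES
    ) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.residue_name in water_resnames and a.name.startswith("O")
        ]


@dataclass
class Trajectory:
    frames: list[Frame]

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def duration(self) -> float:
        """Time of the last frame, in ps."""
        return self.frames[-1].time if self.frames else 0.0

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class Selection:
    """Conjunctive atom predicate; None fields are wildcards."""

    residue_name: str | None = None
    residue_number: int | None = None
    atom_name: str | None = None
    chain: str | None = None

    def matches(self, atom: Atom) -> bool:
        return (
            (self.residue_name is None or atom.residue_name == self.residue_name)
            and (
                self.residue_number is None
                or atom.residue_number == self.residue_number
            )
            and (self.atom_name is None or atom.name == self.atom_name)
            and (self.chain is None or atom.chain == self.chain)
        )

    def apply(self, frame: Frame) -> list[Atom]:
        return [a for a in frame.atoms if self.matches(a)]

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse 'resname=ADP,resnum=185,atom=O,chain=A' style selections."""
        kw: dict[str, object] = {}
        keymap = {
            "resname": "residue_name",
            "resnum": "residue_number",
            "atom": "atom_name",
            "chain": "chain",
        }
        for part in text.split(","):
            if not part.strip():
                continue
            key, _, val = part.partition("=")
            key = key.strip()
            if key not in keymap:
                raise ValueError(f"unknown selection key {key!r}")
            kw[keymap[key]] = int(val) if key == "resnum" else val.strip()
        return cls(**kw)  # type: ignore[arg-type]


@dataclass
class HydrationSeries:
    times: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    window_means: dict[str, float] = field(default_factory=dict)


@dataclass
class WaterSiteSet:
    """Reference water positions (crystallographic oxygens) with occupancy.

    Occupancy of a site is the fraction of frames in which at least one
    water oxygen lies within ``match_radius`` of the site coordinate;
    ``longest_runs`` reports the longest consecutive occupied stretch, in
    frames, as a residence summary.
    """

    sites: np.ndarray  # (k, 3)
    match_radius: float = 1.5
    occupancies: np.ndarray | None = None
    longest_runs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        if self.sites.shape[0] < 1 or self.match_radius <= 0:
            raise ValueError("need >= 1 site and positive match_radius")


@dataclass
class HBondSeries:
    times: np.ndarray
    counts: np.ndarray
    distance_cutoff: float
    angle_cutoff: float | None
    search_radius: float


class PdbParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# multi-model PDB I/O (fixed-column ATOM/HETATM dialect)

def _parse_atom_line(line: str, lineno: int, serial_fallback: int) -> Atom:
    try:
        serial_str = line[6:11].strip()
        serial = int(serial_str) if serial_str else serial_fallback
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"line {lineno}: malformed ATOM record: {exc}") from exc
    return Atom(serial, name, resname, resnum, chain, np.array([x, y, z]))


def read_multimodel_pdb(
    path: str, frame_interval: float = 100.0
) -> Trajectory:
    """Read a (multi-)model PDB file into a trajectory.

    Frame times are MODEL ordinal × ``frame_interval`` (ps), or the value of
    a ``REMARK TIME <ps>`` line inside the model when present.  A file with
    no MODEL records yields a single frame at time ``frame_interval``.
    """
    frames: list[Frame] = []
    atoms: list[Atom] = []
    model_ordinal = 0
    time_override: float | None = None
    saw_model = False

    def flush() -> None:
        nonlocal atoms, time_override
        if atoms:
            t = time_override if time_override is not None else (
                model_ordinal * frame_interval
            )
            frames.append(Frame(t, atoms))
        atoms = []
        time_override = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                model_ordinal += 1
            elif rec in ("ATOM  ", "HETATM"):
                if not saw_model:
                    model_ordinal = 1
                    saw_model = True
                atoms.append(_parse_atom_line(line, lineno, len(atoms) + 1))
            elif rec == "ENDMDL":
                flush()
            elif line.startswith("REMARK TIME"):
                time_override = float(line.split()[2])
    flush()
    if not frames:
        raise PdbParseError(f"no atoms found in {path}")
    return Trajectory(frames)


def write_multimodel_pdb(traj: Trajectory, path: str) -> None:
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.frames, 1):
            fh.write(f"MODEL {i:8d}\n")
            fh.write(f"REMARK TIME {frame.time:.3f}\n")
            for a in frame.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                record = "HETATM" if a.residue_name in WATER_RESNAMES | {
                    "ADP", "ATP"
                } else "ATOM  "
                fh.write(
                    f"{record}{a.serial % 100000:5d} {name}"
                    f" {a.residue_name:<3s} {a.chain:1s}{a.residue_number % 10000:4d}"
                    f"    {a.position[0]:8.3f}{a.position[1]:8.3f}"
                    f"{a.position[2]:8.3f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# snapshot extraction and shell-water counting

def extract_snapshots(traj: Trajectory, interval: float) -> Trajectory:
    """Take one frame per ``interval`` ps at times interval, 2·interval, …

    The grid excludes t = 0 so that a 100 ns trajectory sampled every 100 ps
    yields exactly 1000 snapshots; the frame nearest each grid time is
    taken (earlier frame on ties).  An interval longer than the duration
    yields an empty trajectory.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    n = int(np.floor(traj.duration / interval + 1e-9))
    if n == 0:
        return Trajectory(frames=[])
    times = np.array([f.time for f in traj.frames])
    picked: list[Frame] = []
    seen: set[int] = set()
    for k in range(1, n + 1):
        idx = int(np.argmin(np.abs(times - k * interval)))
        if idx not in seen:
            seen.add(idx)
            picked.append(traj.frames[idx])
    return Trajectory(picked)


def count_waters_within(
    frame: Frame,
    ligand: Selection,
    radius: float = 9.0,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> int:
    """Number of distinct water molecules whose oxygen lies within ``radius``
    Å (inclusive) of any ligand atom."""
    ligand_atoms = ligand.apply(frame)
    if not ligand_atoms:
        raise ValueError("ligand selection matches no atoms")
    waters = frame.water_oxygens(water_resnames)
    if not waters:
        return 0
    tree = cKDTree(np.array([a.position for a in ligand_atoms]))
    d, _ = tree.query(np.array([a.position for a in waters]))
    return int(np.sum(d <= radius))


def hydration_series(
    traj: Trajectory,
    ligand: Selection,
    radius: float = 9.0,
    windows: dict[str, tuple[float, float]] | None = None,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> HydrationSeries:
    """Per-frame shell-water counts with overall and per-window means.

    Windows are half-open time intervals [t0, t1) in ps; each must overlap
    the trajectory's time span.
    """
    times = np.array([f.time for f in traj.frames])
    counts = np.array(
        [count_waters_within(f, ligand, radius, water_resnames) for f in traj.frames]
    )
    window_means: dict[str, float] = {}
    if windows:
        for label, (t0, t1) in windows.items():
            sel = (times >= t0) & (times < t1)
            if not sel.any():
                raise ValueError(
                    f"window {label} [{t0}, {t1}) contains no frames"
                )
            window_means[label] = float(counts[sel].mean())
    return HydrationSeries(
        times=times,
        counts=counts,
        mean=float(counts.mean()),
        sd=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        window_means=window_means,
    )


def hbond_count(
    frame: Frame,
    target: Selection,
    search_radius: float = 4.0,
    distance_cutoff: float = 3.5,
    angle_cutoff: float | None = None,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> int:
    """Count water molecules hydrogen-bonded to a single target atom.

    Candidate waters are those with an oxygen within ``search_radius`` of
    the target.  The default criterion is hydrogen-free: donor-acceptor
    heavy-atom distance <= ``distance_cutoff`` (3.5 Å).  When
    ``angle_cutoff`` is given and the water carries hydrogens, the
    H-donor-acceptor angle must additionally be <= the cutoff (degrees) for
    at least one water hydrogen.
    """
    targets = target.apply(frame)
    if len(targets) != 1:
        raise ValueError(
            f"target selection must resolve to exactly 1 atom, got {len(targets)}"
        )
    t = targets[0].position
    count = 0
    hydrogens_by_res: dict[tuple[str, int], list[Atom]] = {}
    if angle_cutoff is not None:
        for a in frame.atoms:
            if a.residue_name in water_resnames and a.name.startswith("H"):
                hydrogens_by_res.setdefault(
                    (a.residue_name, a.residue_number), []
                ).append(a)
    for w in frame.water_oxygens(water_resnames):
        d = float(np.linalg.norm(w.position - t))
        if d > search_radius or d > distance_cutoff:
            continue
        if angle_cutoff is not None:
            hs = hydrogens_by_res.get((w.residue_name, w.residue_number), [])
            if hs:
                ok = False
                for h in hs:
                    v1 = h.position - w.position
                    v2 = t - w.position
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if ang <= angle_cutoff:
                        ok = True
                        break
                if not ok:
                    continue
        count += 1
    return count


def hbond_series(
    traj: Trajectory,
    target: Selection,
    search_radius: float = 4.0,
    distance_cutoff: float = 3.5,
    angle_cutoff: float | None = None,
) -> HBondSeries:
    times = np.array([f.time for f in traj.frames])
    counts = np.array(
        [
            hbond_count(f, target, search_radius, distance_cutoff, angle_cutoff)
            for f in traj.frames
        ]
    )
    return HBondSeries(times, counts, distance_cutoff, angle_cutoff, search_radius)


def site_occupancy(
    traj: Trajectory,
    sites: WaterSiteSet,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> WaterSiteSet:
    """Occupancy of each reference water site over the trajectory.

    A site is occupied in a frame when at least one water oxygen lies within
    ``match_radius`` (inclusive) of the site coordinate.  Returns a new
    WaterSiteSet with per-site occupancy fractions and the longest
    consecutive occupied run (frames)."""
    k = sites.sites.shape[0]
    nframes = len(traj)
    occupied = np.zeros((nframes, k), dtype=bool)
    for i, frame in enumerate(traj.frames):
        waters = frame.water_oxygens(water_resnames)
        if not waters:
            continue
        tree = cKDTree(np.array([a.position for a in waters]))
        d, _ = tree.query(sites.sites)
        occupied[i] = d <= sites.match_radius
    occ = occupied.mean(axis=0) if nframes else np.zeros(k)
    runs = np.zeros(k, dtype=int)
    for j in range(k):
        best = cur = 0
        for v in occupied[:, j]:
            cur = cur + 1 if v else 0
            best = max(best, cur)
        runs[j] = best
    return WaterSiteSet(
        sites=sites.sites,
        match_radius=sites.match_radius,
        occupancies=occ,
        longest_runs=runs,
    )


# ---------------------------------------------------------------------------
# superposition RMSD

def _selected_coords(frame: Frame, selection: Selection | None) -> np.ndarray:
    atoms = selection.apply(frame) if selection else frame.atoms
    if not atoms:
        raise ValueError("selection matches no atoms")
    return np.array([a.position for a in atoms])


def rmsd(
    frame: Frame,
    reference: Frame,
    selection: Selection | None = None,
    superpose: bool = True,
) -> float:
    """Root-mean-square deviation (Å) between matched selections.

    With ``superpose`` the mobile coordinates are first fitted onto the
    reference by the optimal least-squares rigid-body transform (Kabsch,
    via SVD); atoms are matched by order within the selection, so both
    frames must share atom identity."""
    x = _selected_coords(frame, selection)
    y = _selected_coords(reference, selection)
    if x.shape != y.shape:
        raise ValueError(f"selection atom counts differ: {x.shape[0]} vs {y.shape[0]}")
    if superpose:
        if x.shape[0] < 3:
            raise ValueError("superposition needs at least 3 atoms")
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        rot, _ = Rotation.align_vectors(yc, xc)
        x = rot.apply(xc)
        y = yc
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
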