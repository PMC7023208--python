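"""Synthetic data with known ground truth for every analysis stage.

Three generators mirror the statistical structure the pipeline assumes:

* a protein-family alignment with a group-specific insert flanked by
  conserved residues (the premise of signature-indel detection);
* a labeled phylogeny whose indel-presence tips are either monophyletic or
  deliberately split across separated clades (the two competing origin
  hypotheses);
* a trajectory of snapshot frames with planted water-site occupation
  probabilities, shell waters around a ligand, and a target acceptor atom
  with a configurable water-contact probability.

Everything is driven by ``numpy.random.default_rng`` from an explicit seed,
so outputs are byte-identical across runs for the same spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, AlignedSequence, Alignment, GroupAssignment
from .detection import CsiRecord, GapBlock
from .hydration import Atom, Frame, Trajectory
from .phylo import BinaryCharacter, PhyloTree, parse_newick

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# alignment generator

@dataclass
class MsaSpec:
    """Recipe for a conserved protein family with one planted insert.

    ``groups`` maps a taxon-group label to its number of sequences;
    ``insert_bearers`` lists the labels whose members carry the insert.
    The insert itself is identical across bearers (signature indels are
    strongly conserved); non-bearers are gapped over its columns.
    ``substitution_prob`` is the per-site, per-sequence replacement
    probability outside the insert; within ``flank_span`` columns of the
    insert it is overridden by ``1 - flank_conservation``.
    """

    groups: dict[str, int] = field(
        default_factory=lambda: {
            "Thermotogales": 6,
            "Aquificales": 5,
            "Petrotogales": 4,
            "Kosmotogales": 4,
            "Desulfurobacteriales": 4,
        }
    )
    insert_bearers: tuple[str, ...] = ("Thermotogales", "Aquificales")
    core_length: int = 400
    insert_length: int = 50
    insert_position: int = 180
    flank_conservation: float = 1.0
    flank_span: int = 40
    substitution_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flank_conservation", "substitution_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 < self.insert_position < self.core_length:
            raise ValueError("insert_position must fall inside the core")
        unknown = set(self.insert_bearers) - set(self.groups)
        if unknown:
            raise ValueError(f"insert_bearers not in groups: {sorted(unknown)}")


def _mutate(seq: str, probs: np.ndarray, rng: np.random.Generator) -> str:
    hits = rng.random(len(seq)) < probs
    if not hits.any():
        return seq
    chars = list(seq)
    for j in np.nonzero(hits)[0]:
        alternatives = AA.replace(chars[j], "")
        chars[j] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def generate_family_alignment(
    spec: MsaSpec,
) -> tuple[Alignment, GroupAssignment, CsiRecord]:
    """Simulate the family and return (alignment, groups, ground truth).

    The returned CsiRecord holds the planted block span (alignment columns),
    bearer set, and consensus insert length — the quantities a detector must
    recover.
    """
    rng = np.random.default_rng(spec.seed)
    core = "".join(rng.choice(list(AA), size=spec.core_length))
    insert = "".join(rng.choice(list(AA), size=spec.insert_length))
    pos, L = spec.insert_position, spec.insert_length

    # per-site substitution probabilities over core coordinates
    probs = np.full(spec.core_length, spec.substitution_prob)
    lo = max(0, pos - spec.flank_span)
    hi = min(spec.core_length, pos + spec.flank_span)
    probs[lo:hi] = 1.0 - spec.flank_conservation

    rows: list[AlignedSequence] = []
    labels: dict[str, str] = {}
    bearers: list[str] = []
    bearer_groups = set(spec.insert_bearers)
    for label, n in spec.groups.items():
        for i in range(1, n + 1):
            sid = f"{label}_{i}"
            labels[sid] = label
            seq = _mutate(core, probs, rng)
            if label in bearer_groups:
                aligned = seq[:pos] + insert + seq[pos:]
                bearers.append(sid)
            else:
                aligned = seq[:pos] + GAP * L + seq[pos:]
            rows.append(AlignedSequence(sid, aligned))

    alignment = Alignment(rows)
    groups = GroupAssignment(labels)
    block = GapBlock(
        start=pos,
        end=pos + L,
        bearer_set=frozenset(bearers),
        non_bearer_set=frozenset(set(labels) - set(bearers)),
    )
    truth = CsiRecord(
        block=block,
        per_member_length={b: L for b in bearers},
        consensus_length=L,
        left_flank_conserved=-1,  # not planted explicitly
        right_flank_conserved=-1,
        target_groups=frozenset(spec.insert_bearers),
        specific=True,
    )
    return alignment, groups, truth


# ---------------------------------------------------------------------------
# tree generator

def _random_join(labels: list[str], rng: np.random.Generator) -> str:
    """Random binary newick subtree over the given labels."""
    nodes = list(labels)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a},{b})")
    return nodes[0]


def random_tree(labels: list[str], seed: int | np.random.Generator) -> PhyloTree:
    """Uniformly random sequential-join binary tree over the labels."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return parse_newick(_random_join(list(labels), rng) + ";")


def generate_labeled_tree(
    groups: dict[str, int],
    monophyletic_presence: bool,
    seed: int = 0,
    presence_labels: tuple[str, ...] | None = None,
) -> tuple[PhyloTree, BinaryCharacter]:
    """Random binary tree with group-structured tips and an indel character.

    ``presence_labels`` (default: the first two groups) mark the groups whose
    tips carry the indel.  With ``monophyletic_presence`` the presence tips
    form one clade; without it they are split across two clades, each paired
    with absence tips, so that at least two independent gains are required
    to explain the character.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    if presence_labels is None:
        presence_labels = tuple(list(groups)[:2])
    presence_set = set(presence_labels)
    absence_set = [g for g in groups if g not in presence_set]

    tips = {g: [f"{g}_{i}" for i in range(1, n + 1)] for g, n in groups.items()}
    sub = {g: _random_join(tips[g], rng) for g in groups}

    if monophyletic_presence:
        p = _random_join([sub[g] for g in presence_labels], rng)
        a = _random_join([sub[g] for g in absence_set], rng)
        newick = f"({p},{a});"
    else:
        if len(presence_labels) < 2 or len(absence_set) < 2:
            raise ValueError(
                "non-monophyletic presence needs >= 2 presence and"
                " >= 2 absence groups"
            )
        p1, p2 = sub[presence_labels[0]], sub[presence_labels[1]]
        extra_p = [sub[g] for g in presence_labels[2:]]
        half = len(absence_set) // 2 or 1
        a1 = _random_join([sub[g] for g in absence_set[:half]], rng)
        a2 = _random_join([sub[g] for g in absence_set[half:]], rng)
        if extra_p:
            p1 = _random_join([p1] + extra_p, rng)
        newick = f"(({p1},{a1}),({p2},{a2}));"

    tree = parse_newick(newick)
    states = {
        t: 1 if g in presence_set else 0 for g, ts in tips.items() for t in ts
    }
    return tree, BinaryCharacter(states)


# ---------------------------------------------------------------------------
# trajectory generator

@dataclass
class TrajSpec:
    """Recipe for snapshot frames with planted hydration statistics.

    The ligand is a compact heavy-atom cluster at the origin; conserved
    water sites sit outside its 9 Å shell so that site occupancy and shell
    counts stay statistically independent.  ``shell_lambda`` waters
    (Poisson-distributed per frame) are placed inside the shell;
    ``n_bulk_waters`` are placed uniformly in the box but rejected from the
    shell and from the target's hydrogen-bond neighbourhood.  The target
    acceptor atom receives one contact water within hydrogen-bond distance
    with probability ``target_contact_prob`` per frame.
    """

    n_frames: int = 1000
    frame_interval: float = 100.0  # ps — one snapshot per 100 ps
    ligand_coords: np.ndarray | None = None
    n_ligand_atoms: int = 27  # heavy-atom count of ADP
    water_sites: np.ndarray | None = None
    site_probs: tuple[float, ...] = (0.7, 0.7, 0.7)
    site_match_radius: float = 1.5
    shell_lambda: float = 10.0
    shell_radius: float = 9.0
    n_bulk_waters: int = 50
    box_extent: float = 60.0
    target_position: np.ndarray | None = None
    target_contact_prob: float = 0.9
    jitter_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for p in self.site_probs + (self.target_contact_prob,):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.ligand_coords is None:
            rng = np.random.default_rng(12345)  # fixed ligand geometry
            self.ligand_coords = rng.normal(0.0, 1.5, size=(self.n_ligand_atoms, 3))
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float)
        if self.water_sites is None:
            self.water_sites = np.array(
                [[0.0, 0.0, 15.0], [0.0, 15.0, 0.0], [15.0, 0.0, 0.0]]
            )[: len(self.site_probs)]
        self.water_sites = np.atleast_2d(np.asarray(self.water_sites, dtype=float))
        if len(self.site_probs) != self.water_sites.shape[0]:
            raise ValueError("site_probs and water_sites length mismatch")
        if self.target_position is None:
            self.target_position = np.array([25.0, 0.0, 0.0])
        self.target_position = np.asarray(self.target_position, dtype=float)


@dataclass
class TrajGroundTruth:
    site_probs: np.ndarray
    target_contact_prob: float
    shell_lambda: float
    shell_counts: np.ndarray  # realized planted shell waters per frame
    site_occupied: np.ndarray  # (n_frames, k) planted occupation indicators
    contact_placed: np.ndarray  # (n_frames,) indicator


def _jitter_within(radius: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Isotropic Gaussian jitter truncated to norm <= radius."""
    for _ in range(100):
        v = rng.normal(0.0, sd, size=3)
        if np.linalg.norm(v) <= radius:
            return v
    return np.zeros(3)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_hydration_trajectory(
    spec: TrajSpec,
) -> tuple[Trajectory, TrajGroundTruth]:
    """Simulate snapshot frames per the spec; returns (trajectory, truth)."""
    rng = np.random.default_rng(spec.seed)
    lig = spec.ligand_coords
    sites = spec.water_sites
    k = sites.shape[0]
    target = spec.target_position

    site_occupied = np.zeros((spec.n_frames, k), dtype=bool)
    contact_placed = np.zeros(spec.n_frames, dtype=bool)
    shell_counts = np.zeros(spec.n_frames, dtype=int)

    frames: list[Frame] = []
    for fi in range(spec.n_frames):
        t = (fi + 1) * spec.frame_interval
        atoms: list[Atom] = []
        serial = 1
        for j, xyz in enumerate(lig, 1):
            atoms.append(Atom(serial, f"C{j}", "ADP", 1, "A", xyz.copy()))
            serial += 1
        atoms.append(Atom(serial, "O", "GLU", 185, "A", target.copy()))
        serial += 1

        resnum = 300
        # conserved-site waters
        for j in range(k):
            if rng.random() < spec.site_probs[j]:
                site_occupied[fi, j] = True
                pos = sites[j] + _jitter_within(
                    spec.site_match_radius, spec.jitter_sd, rng
                )
                atoms.append(Atom(serial, "OW", "HOH", resnum, "W", pos))
                serial += 1
                resnum += 1
        # shell waters around the ligand (Poisson count)
        n_shell = int(rng.poisson(spec.shell_lambda))
        shell_counts[fi] = n_shell
        for _ in range(n_shell):
            anchor = lig[rng.integers(len(lig))]
            d = rng.uniform(3.0, spec.shell_radius)
            pos = anchor + d * _random_unit(rng)
            atoms.append(Atom(serial, "OW", "HOH", resnum, "W", pos))
            serial += 1
            resnum += 1
        # target contact water within hydrogen-bond distance
        if rng.random() < spec.target_contact_prob:
            contact_placed[fi] = True
            d = rng.uniform(2.6, 3.2)
            pos = target + d * _random_unit(rng)
            atoms.append(Atom(serial, "OW", "HOH", resnum, "W", pos))
            serial += 1
            resnum += 1
        # bulk waters, kept out of the shell, the sites, and the target zone
        placed = 0
        while placed < spec.n_bulk_waters:
            pos = rng.uniform(-spec.box_extent / 2, spec.box_extent / 2, size=3)
            if np.min(np.linalg.norm(lig - pos, axis=1)) <= spec.shell_radius + 0.5:
                continue
            if np.linalg.norm(pos - target) <= 5.0:
                continue
            if k and np.min(np.linalg.norm(sites - pos, axis=1)) <= (
                spec.site_match_radius + 0.5
            ):
                continue
            atoms.append(Atom(serial, "OW", "HOH", resnum, "W", pos))
            serial += 1
            resnum += 1
            placed += 1

        frames.append(Frame(t, atoms))

    truth = TrajGroundTruth(
        site_probs=np.array(spec.site_probs),
        target_contact_prob=spec.target_contact_prob,
        shell_lambda=spec.shell_lambda,
        shell_counts=shell_counts,
        site_occupied=site_occupied,
        contact_placed=contact_placed,
    )
    return Trajectory(frames), truth
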