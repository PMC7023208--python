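"""Detection of conserved signature indels (CSIs) in protein alignments.

A CSI is an insertion/deletion block shared by a defined taxon group, absent
from the others, and embedded in a conserved sequence neighbourhood: the
criterion applied here requires at least ``min_flank_conserved`` conserved
columns within a ``flank_window``-column neighbourhood on *both* sides of the
indel.  "Conserved" for a column means that the most frequent residue among
non-gap rows reaches ``conservation_threshold`` (default 0.90); the literature
does not fix a numeric definition, and strict identity fails on realistic
divergence.

Coordinates are 0-based half-open alignment columns throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .alignment import GAP, AlignedSequence, Alignment, GroupAssignment


@dataclass(frozen=True)
class CsiParams:
    """Tunable detection thresholds.

    min_flank_conserved / flank_window encode the published rule of thumb of
    at least 5 conserved residues within the neighbouring 30-40 aa on each
    side; 35 splits that range.  min_target_presence / max_other_presence
    default to strict specificity (all target members bear the indel, no
    outsider does).  ragged_membership_fraction controls when a partially
    gapped row counts as insert-bearing.
    """

    min_flank_conserved: int = 5
    flank_window: int = 35
    conservation_threshold: float = 0.90
    min_target_presence: float = 1.0
    max_other_presence: float = 0.0
    ragged_membership_fraction: float = 0.5
    min_insert_length: int = 2

    def __post_init__(self) -> None:
        for name in (
            "conservation_threshold",
            "min_target_presence",
            "max_other_presence",
            "ragged_membership_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_flank_conserved > self.flank_window:
            raise ValueError("min_flank_conserved exceeds flank_window")


@dataclass
class GapBlock:
    """A maximal run of alignment columns with a uniform gap/non-gap pattern
    in which at least one row is gapped and at least one is not."""

    start: int
    end: int
    bearer_set: frozenset[str]
    non_bearer_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty block")
        if not self.bearer_set or not self.non_bearer_set:
            raise ValueError("bearer and non-bearer sets must be non-empty")

    @property
    def columns(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CsiRecord:
    """A detected conserved signature indel."""

    block: GapBlock
    per_member_length: dict[str, int]
    consensus_length: int
    left_flank_conserved: int
    right_flank_conserved: int
    target_groups: frozenset[str]
    specific: bool
    exceptions: list[tuple[str, str]] = field(default_factory=list)


def insert_length(row: AlignedSequence, block: GapBlock) -> int:
    """Ungapped residue count of a row inside the block columns."""
    return sum(1 for c in row.residues[block.start : block.end] if c != GAP)


def find_gap_blocks(
    alignment: Alignment, params: CsiParams | None = None
) -> list[GapBlock]:
    """Segment the alignment into maximal gap-pattern blocks.

    Adjacent columns with identical gap/non-gap presence bitmasks are merged;
    a block is emitted when its pattern mixes gapped and non-gapped rows.
    Bearer status within a block is then resolved raggedly: a row counts as
    insert-bearing when it is non-gap in at least
    ``ragged_membership_fraction`` of the block's columns.
    """
    params = params or CsiParams()
    ncol = alignment.column_count
    ids = alignment.ids

    def mask(j: int) -> tuple[bool, ...]:
        return tuple(r.residues[j] != GAP for r in alignment.rows)

    blocks: list[GapBlock] = []
    j = 0
    while j < ncol:
        m = mask(j)
        k = j + 1
        while k < ncol and mask(k) == m:
            k += 1
        if any(m) and not all(m):
            width = k - j
            bearers = []
            for row in alignment.rows:
                nongap = sum(1 for c in row.residues[j:k] if c != GAP)
                if nongap >= params.ragged_membership_fraction * width:
                    bearers.append(row.id)
            non_bearers = [i for i in ids if i not in set(bearers)]
            if bearers and non_bearers:
                blocks.append(
                    GapBlock(j, k, frozenset(bearers), frozenset(non_bearers))
                )
        j = k
    return blocks


def flank_conservation(
    alignment: Alignment,
    block: GapBlock,
    side: str,
    params: CsiParams | None = None,
) -> int:
    """Count conserved columns in the flank window beside a block.

    Walks outward from the block edge; columns gapped in more than
    (1 - conservation_threshold) of rows are skipped without consuming a
    window slot, so a neighbouring indel does not deflate the count.  A
    retained column is conserved when its modal residue frequency among
    non-gap rows is >= conservation_threshold.  The window truncates at the
    alignment edge.
    """
    params = params or CsiParams()
    if side == "left":
        cols = range(block.start - 1, -1, -1)
    elif side == "right":
        cols = range(block.end, alignment.column_count)
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    nrows = len(alignment)
    max_gap_frac = 1.0 - params.conservation_threshold
    examined = 0
    conserved = 0
    for j in cols:
        col = alignment.column(j)
        n_gap = col.count(GAP)
        if n_gap > max_gap_frac * nrows:
            continue  # mostly-gapped column: skipped, does not consume a slot
        examined += 1
        residues = [c for c in col if c != GAP]
        _, top_count = Counter(residues).most_common(1)[0]
        if top_count >= params.conservation_threshold * len(residues):
            conserved += 1
        if examined >= params.flank_window:
            break
    return conserved


def assess_specificity(
    block: GapBlock,
    groups: GroupAssignment,
    target: set[str],
    params: CsiParams | None = None,
) -> tuple[bool, list[tuple[str, str]]]:
    """Decide whether a block's bearer set is specific to the target groups.

    Specific iff the fraction of target-group members bearing the insert is
    >= min_target_presence and the fraction of non-target members bearing it
    is <= max_other_presence.  Every violating id is listed with a reason.
    """
    params = params or CsiParams()
    known = set(groups.groups)
    unknown = target - known
    if unknown:
        raise KeyError(f"unknown group labels: {sorted(unknown)}")

    all_ids = block.bearer_set | block.non_bearer_set
    target_ids = {i for i in all_ids if groups.group_of(i) in target}
    other_ids = all_ids - target_ids

    exceptions: list[tuple[str, str]] = []
    n_target_with = len(target_ids & block.bearer_set)
    n_other_with = len(other_ids & block.bearer_set)
    for i in sorted(target_ids - block.bearer_set):
        exceptions.append((i, "target member lacks insert"))
    for i in sorted(other_ids & block.bearer_set):
        exceptions.append((i, "non-target member bears insert"))

    ok_target = (
        not target_ids
        or n_target_with / len(target_ids) >= params.min_target_presence
    )
    ok_other = (
        not other_ids
        or n_other_with / len(other_ids) <= params.max_other_presence
    )
    specific = ok_target and ok_other
    if specific:
        exceptions = []
    return specific, exceptions


def _consensus_length(lengths: list[int]) -> int:
    """Mode of bearer insert lengths, smallest value on ties."""
    counts = Counter(lengths)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def detect_csis(
    alignment: Alignment,
    groups: GroupAssignment,
    target: set[str],
    params: CsiParams | None = None,
) -> list[CsiRecord]:
    """Full CSI scan: gap-block segmentation, specificity, flank conservation.

    A gap block becomes a CsiRecord when (a) its bearer set is specific to the
    target groups, (b) the consensus insert length (smallest mode of bearer
    ungapped lengths) reaches min_insert_length, and (c) both flanks carry at
    least min_flank_conserved conserved columns.  Records are ordered by
    start column; output is invariant to row order up to that ordering.
    """
    params = params or CsiParams()
    groups.validate_against(alignment)
    records: list[CsiRecord] = []
    for block in find_gap_blocks(alignment, params):
        specific, exceptions = assess_specificity(block, groups, target, params)
        if not specific:
            continue
        lengths = {
            i: insert_length(alignment[i], block) for i in sorted(block.bearer_set)
        }
        consensus = _consensus_length(list(lengths.values()))
        if consensus < params.min_insert_length:
            continue
        left = flank_conservation(alignment, block, "left", params)
        right = flank_conservation(alignment, block, "right", params)
        if left < params.min_flank_conserved or right < params.min_flank_conserved:
            continue
        records.append(
            CsiRecord(
                block=block,
                per_member_length=lengths,
                consensus_length=consensus,
                left_flank_conserved=left,
                right_flank_conserved=right,
                target_groups=frozenset(target),
                specific=True,
                exceptions=exceptions,
            )
        )
    records.sort(key=lambda r: r.block.start)
    return records
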