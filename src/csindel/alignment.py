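"""Protein alignment containers, FASTA I/O, and signature-block rendering.

A *signature block* is the compact display format used for group-specific
indels in protein families: a reference ("top") sequence is printed verbatim
and every other row shows a dash wherever it matches the top row, so the
conserved flanks collapse visually and the indel stands out.  Here the dash
is reserved for identity and ``.`` marks an alignment gap, which makes the
rendering invertible; a strict-facsimile mode collapses both to ``-`` for
figures at the cost of the round-trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: non-standard one-letter codes folded to X on input
AMBIGUOUS = set("BZUOJ")
VALID_CHARS = AMINO_ACIDS | {"X", GAP}


class MalformedAlignmentError(ValueError):
    """Rows of unequal length, duplicate ids, or other structural defects."""


@dataclass(frozen=True)
class AlignedSequence:
    """One row of an alignment: an id and a gapped residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise MalformedAlignmentError("sequence id must be non-empty")
        bad = set(self.residues) - VALID_CHARS
        if bad:
            raise MalformedAlignmentError(
                f"invalid characters {sorted(bad)} in sequence {self.id!r}"
            )

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class Alignment:
    """An ordered protein multiple sequence alignment (>= 2 equal-length rows)."""

    rows: list[AlignedSequence]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise MalformedAlignmentError("alignment needs at least 2 rows")
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            raise MalformedAlignmentError(
                f"rows have unequal lengths: {sorted(lengths)}"
            )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MalformedAlignmentError(f"duplicate sequence ids: {dupes}")
        self._index = {r.id: r for r in self.rows}

    @property
    def column_count(self) -> int:
        return len(self.rows[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, seq_id: str) -> AlignedSequence:
        return self._index[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)


@dataclass
class GroupAssignment:
    """Map from sequence id to taxon-group label (e.g. an order name)."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        for sid, lab in self.labels.items():
            if not lab:
                raise ValueError(f"empty group label for {sid!r}")

    def group_of(self, seq_id: str) -> str:
        return self.labels[seq_id]

    def members(self, label: str) -> set[str]:
        return {s for s, g in self.labels.items() if g == label}

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.labels.values():
            seen.setdefault(g)
        return list(seen)

    def validate_against(self, alignment: Alignment) -> None:
        missing = [i for i in alignment.ids if i not in self.labels]
        if missing:
            raise ValueError(f"alignment ids without group label: {missing}")


@dataclass
class SignatureBlock:
    """Rendered identity-dash display of an alignment window.

    ``rendered`` maps row id -> display string over the window; the top row is
    shown verbatim.  ``group_counts`` maps group label -> (n_with_insert,
    n_total) where a row "has the insert" when it carries at least one non-gap
    residue inside the window.  ``top_ungapped_start`` is the 1-based position
    of the window start in the top sequence's ungapped coordinates, the
    convention used when labelling a signature with positions in a reference
    organism.
    """

    top_id: str
    window: tuple[int, int]  # 0-based half-open alignment columns
    rendered: dict[str, str]
    group_counts: dict[str, tuple[int, int]]
    top_ungapped_start: int
    identity_char: str = "-"
    gap_char: str = "."

    @property
    def width(self) -> int:
        return self.window[1] - self.window[0]


def _normalize(residues: str, seq_id: str) -> str:
    s = residues.upper().replace(".", GAP)
    if set(s) & AMBIGUOUS:
        warnings.warn(
            f"non-standard residue letters in {seq_id!r} mapped to X",
            stacklevel=3,
        )
        s = "".join("X" if c in AMBIGUOUS else c for c in s)
    return s


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Letters are uppercased, ``.`` gaps normalized to ``-`` and rare
    non-standard letters (B, Z, U, O, J) mapped to X with a warning.
    Raises :class:`MalformedAlignmentError` on unequal row lengths or
    duplicate ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MalformedAlignmentError(f"no FASTA records in {path}")
    rows = [
        AlignedSequence(rec.id, _normalize(str(rec.seq), rec.id))
        for rec in records
    ]
    return Alignment(rows)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.residues), id=r.id, description="")
        for r in alignment.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def read_groups(path: str | Path) -> GroupAssignment:
    """Read a 2-column TSV (seq_id, group label)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
            labels[parts[0]] = parts[1]
    return GroupAssignment(labels)


def write_groups(groups: GroupAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in groups.labels.items():
            fh.write(f"{sid}\t{lab}\n")


def ungapped_position(row: AlignedSequence, column: int) -> int:
    """1-based position in the row's ungapped sequence of the residue at or
    after the given alignment column (count of non-gap chars up to and
    including the first non-gap char at >= column)."""
    n = sum(1 for c in row.residues[:column] if c != GAP)
    return n + 1


def render_signature(
    alignment: Alignment,
    window: tuple[int, int],
    top_id: str,
    groups: GroupAssignment | None = None,
    strict_facsimile: bool = False,
) -> SignatureBlock:
    """Render the identity-dash signature display of an alignment window.

    The top row prints verbatim; every other row shows ``-`` where it matches
    the top row's residue at that column and the residue itself otherwise.
    Gap characters in non-top rows render as ``.`` so the block stays
    invertible (``strict_facsimile=True`` emits ``-`` for both, which is the
    published figure convention but loses the round-trip).
    """
    start, end = window
    if top_id not in alignment:
        raise KeyError(f"unknown top_id {top_id!r}")
    if not (0 <= start < end <= alignment.column_count):
        raise ValueError(f"window {window} out of bounds")
    top = alignment[top_id].residues[start:end]
    gap_char = GAP if strict_facsimile else "."
    rendered: dict[str, str] = {}
    for row in alignment.rows:
        seg = row.residues[start:end]
        if row.id == top_id:
            rendered[row.id] = seg
            continue
        out = []
        for t, c in zip(top, seg):
            if c == GAP:
                out.append(gap_char)
            elif c == t:
                out.append("-")
            else:
                out.append(c)
        rendered[row.id] = "".join(out)

    group_counts: dict[str, tuple[int, int]] = {}
    if groups is not None:
        groups.validate_against(alignment)
        for label in groups.groups:
            members = [i for i in alignment.ids if groups.group_of(i) == label]
            n_with = sum(
                1
                for i in members
                if any(c != GAP for c in alignment[i].residues[start:end])
            )
            group_counts[label] = (n_with, len(members))

    return SignatureBlock(
        top_id=top_id,
        window=window,
        rendered=rendered,
        group_counts=group_counts,
        top_ungapped_start=ungapped_position(alignment[top_id], start),
        gap_char=gap_char,
    )


def expand_signature(block: SignatureBlock) -> dict[str, str]:
    """Invert :func:`render_signature`: recover each row's original window
    content by substituting the top-row residue for identity dashes and the
    alignment gap for the block's gap character."""
    if block.gap_char == block.identity_char:
        raise ValueError(
            "strict-facsimile blocks are not invertible (gap == identity char)"
        )
    top = block.rendered[block.top_id]
    out: dict[str, str] = {}
    for sid, seg in block.rendered.items():
        if len(seg) != block.width:
            raise ValueError(
                f"row {sid!r} width {len(seg)} != block width {block.width}"
            )
        if sid == block.top_id:
            out[sid] = seg
            continue
        chars = []
        for t, c in zip(top, seg):
            if c == block.gap_char:
                chars.append(GAP)
            elif c == block.identity_char:
                chars.append(t)
            else:
                chars.append(c)
        out[sid] = "".join(chars)
    return out


def format_signature(block: SignatureBlock) -> str:
    """Plain-text rendering: header with the top-sequence start position,
    then one line per row, then per-group insert counts."""
    lines = [f"# window {block.window[0]}:{block.window[1]} "
             f"(pos {block.top_ungapped_start} in {block.top_id})"]
    pad = max(len(s) for s in block.rendered)
    for sid, seg in block.rendered.items():
        lines.append(f"{sid:<{pad}}  {seg}")
    for label, (n_with, n_tot) in block.group_counts.items():
        lines.append(f"# {label}: {n_with}/{n_tot} with insert")
    return "\n".join(lines) + "\n"
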