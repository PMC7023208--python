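"""Phylogenetic congruence testing for a binary indel character.

A group-specific indel shared by two distantly related taxon groups admits
two explanations: a single origin followed by horizontal transfer of the
gene (in which case the bearers should cluster together in the gene tree),
or independent origins in each lineage.  Given the gene tree and the
presence/absence character, the test here is purely topological: the
single-origin explanation is consistent exactly when the presence set is
monophyletic on the unrooted topology, equivalently when the parsimony
minimum number of state changes is at most 1.

Trees are handled through dendropy; multifurcations are supported exactly
(the minimum-change count uses a Sankoff dynamic programme with unit costs,
which reduces to Fitch/Hartigan counting on binary characters).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy


@dataclass
class PhyloTree:
    """A phylogeny with uniquely labeled tips (thin wrapper over dendropy)."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) < 3:
            raise ValueError("tree needs at least 3 tips")
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")

    @property
    def tip_labels(self) -> list[str]:
        return [
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        ]


@dataclass
class BinaryCharacter:
    """Presence(1)/absence(0) state per tip label."""

    states: dict[str, int]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.states.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"states must be 0/1, got {bad}")

    @property
    def presence_set(self) -> set[str]:
        return {k for k, v in self.states.items() if v == 1}


@dataclass
class CongruenceReport:
    monophyletic: bool
    fitch_min_changes: int
    min_origins_single_gain_consistent: bool
    verdict: str  # consistent_with_single_origin | independent_origins_supported


class NewickParseError(ValueError):
    pass


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string, preserving labels and branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"newick parse failure: {exc}") from exc
    return PhyloTree(tree)


def serialize_newick(tree: PhyloTree) -> str:
    return tree.tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def read_newick(path: str) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_character(path: str) -> BinaryCharacter:
    """Read a 2-column TSV (tip label, 0/1)."""
    states: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(f"{path}:{ln}: expected '<tip>\\t<0|1>'")
            states[parts[0]] = int(parts[1])
    return BinaryCharacter(states)


def _clades(tree: PhyloTree) -> list[frozenset[str]]:
    """Leaf-label set under every node (each internal edge's bipartition)."""
    out = []
    for node in tree.tree.postorder_node_iter():
        leaves = frozenset(
            l.taxon.label for l in node.leaf_iter()
        )
        out.append(leaves)
    return out


def is_monophyletic(tree: PhyloTree, tip_set: set[str]) -> bool:
    """True iff some edge of the unrooted tree splits the tips into exactly
    (tip_set, complement)."""
    all_tips = set(tree.tip_labels)
    unknown = tip_set - all_tips
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")
    if not tip_set or tip_set == all_tips:
        raise ValueError("tip_set must be a non-empty proper subset of tips")
    target = frozenset(tip_set)
    complement = frozenset(all_tips - tip_set)
    return any(c in (target, complement) for c in _clades(tree))


def fitch_min_changes(tree: PhyloTree, character: BinaryCharacter) -> int:
    """Minimum number of 0<->1 state changes on the tree (parsimony score).

    Sankoff dynamic programme with unit substitution costs, evaluated on the
    (arbitrarily) rooted representation; with a symmetric cost the score is
    invariant under rerooting.  Exact on multifurcating nodes.
    """
    tips = set(tree.tip_labels)
    missing = tips - set(character.states)
    if missing:
        raise KeyError(f"tips without character state: {sorted(missing)}")

    INF = float("inf")
    cost: dict[int, tuple[float, float]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            s = character.states[node.taxon.label]
            cost[id(node)] = (0.0, INF) if s == 0 else (INF, 0.0)
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                k0, k1 = cost[id(child)]
                c0 += min(k0, k1 + 1)
                c1 += min(k0 + 1, k1)
            cost[id(node)] = (c0, c1)
    root = tree.tree.seed_node
    return int(min(cost[id(root)]))


def assess_congruence(
    tree: PhyloTree, character: BinaryCharacter
) -> CongruenceReport:
    """Decide between single-origin and independent-origin explanations.

    The bearers clustering together (presence set monophyletic on the
    unrooted tree) is consistent with one gain — vertical descent or a
    single horizontal transfer.  Bearers split across clades separated by
    non-bearers require at least two changes, supporting independent
    origins of the indel.
    """
    presence = character.presence_set
    all_tips = set(tree.tip_labels)
    changes = fitch_min_changes(tree, character)
    if presence and presence != all_tips:
        mono = is_monophyletic(tree, presence)
    else:
        mono = True  # all-present or all-absent: zero changes needed
    single = changes <= 1
    verdict = (
        "consistent_with_single_origin"
        if mono
        else "independent_origins_supported"
    )
    return CongruenceReport(
        monophyletic=mono,
        fitch_min_changes=changes,
        min_origins_single_gain_consistent=single,
        verdict=verdict,
    )
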