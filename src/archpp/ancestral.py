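"""Dollo-parsimony reconstruction of ancestral architecture repertoires.

Domain architectures are treated as presence/absence characters on a rooted,
fully resolved binary species tree.  Because independent re-invention of the
same architecture is rare, each architecture is allowed exactly one gain and
any number of losses (Dollo parsimony).  For presence at a set of leaves the
unique minimum-loss single-gain solution marks the architecture present at
every node of the minimal subtree connecting those leaves: the gain sits at
their most recent common ancestor, losses at the maximal absent subtrees
below it.  Counting reconstructed architectures per domain at each internal
node yields the ancestral architecture-count matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .genome_model import (
    GAP,
    ArchCountMatrix,
    Architecture,
    GenomeAssignmentTable,
    architecture_to_string,
)


class NotBinaryError(ValueError):
    """Tree contains a polytomy (or a degree-1 internal node)."""


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class Phylogeny:
    """Rooted binary tree with stable node ids.

    Leaves carry genome ids; unlabeled internal nodes get deterministic
    ids ``N<postorder index>`` so repeated runs name nodes identically.
    """

    root: str
    children: dict[str, tuple[str, str]]  # internal id -> (left, right)
    parent: dict[str, str | None]
    postorder: tuple[str, ...] = field(default_factory=tuple)

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(n for n in self.postorder if n not in self.children)

    @property
    def internal_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.postorder if n in self.children)

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.postorder

    def is_leaf(self, node: str) -> bool:
        return node not in self.children

    def depth(self, node: str) -> int:
        d = 0
        while self.parent[node] is not None:
            node = self.parent[node]
            d += 1
        return d

    def path_to_root(self, node: str) -> list[str]:
        path = [node]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path

    def mrca(self, nodes) -> str:
        nodes = list(nodes)
        if not nodes:
            raise TreeError("mrca of empty node set")
        common = set(self.path_to_root(nodes[0]))
        for n in nodes[1:]:
            common &= set(self.path_to_root(n))
        # deepest node on every root path
        return max(common, key=self.depth)


def _from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    seen: set[str] = set()
    children: dict[str, tuple[str, str]] = {}
    parent: dict[str, str | None] = {}
    ids: dict[int, str] = {}
    postorder: list[str] = []
    for i, nd in enumerate(tree.postorder_node_iter()):
        kids = nd.child_nodes()
        if kids and len(kids) != 2:
            raise NotBinaryError(
                f"internal node with {len(kids)} children; the tree must be "
                "fully resolved binary (polytomies are not silently resolved)"
            )
        if not kids:
            label = nd.taxon.label if nd.taxon else nd.label
            if label is None:
                raise TreeError("leaf without a label")
        else:
            label = nd.label or (nd.taxon.label if nd.taxon else None) or f"N{i}"
        label = str(label).strip()
        if label in seen:
            raise TreeError(f"duplicate node label {label!r}")
        seen.add(label)
        ids[id(nd)] = label
        postorder.append(label)
        if kids:
            children[label] = (ids[id(kids[0])], ids[id(kids[1])])
            for c in kids:
                parent[ids[id(c)]] = label
    root = ids[id(tree.seed_node)]
    parent[root] = None
    return Phylogeny(root=root, children=children, parent=parent,
                     postorder=tuple(postorder))


def parse_newick(source: str) -> Phylogeny:
    """Parse a rooted binary Newick tree (string or file path).

    Polytomies raise :class:`NotBinaryError`; duplicate leaf labels raise
    :class:`TreeError`.  A fully resolved tree with L leaves has exactly
    L − 1 internal nodes.
    """
    text = source
    if "(" not in str(source):  # looks like a path
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeError(f"duplicate leaf label: {exc}") from exc
    return _from_dendropy(tree)


def dollo_presence(tree: Phylogeny, leaves_with) -> set[str]:
    """Nodes where an architecture is reconstructed present.

    Exactly the minimal spanning subtree of the possessing leaves: their
    MRCA (the single gain) plus every node on a path from it to a member
    leaf.  This is the unique single-gain, minimum-loss Dollo solution.
    """
    leaves_with = set(leaves_with)
    if not leaves_with:
        raise TreeError("empty leaf set")
    all_leaves = set(tree.leaves)
    unknown = leaves_with - all_leaves
    if unknown:
        raise TreeError(f"unknown leaves: {sorted(unknown)}")
    gain = tree.mrca(leaves_with)
    present = {gain}
    for leaf in leaves_with:
        node = leaf
        while node != gain:
            present.add(node)
            node = tree.parent[node]
    return present


def dollo_events(tree: Phylogeny, leaves_with) -> tuple[str, list[str]]:
    """Gain node and loss nodes (roots of maximal absent subtrees)."""
    present = dollo_presence(tree, leaves_with)
    gain = tree.mrca(set(leaves_with))
    losses = sorted(
        n for n in tree.nodes
        if n not in present and tree.parent[n] in present
    )
    return gain, losses


def brute_force_dollo(tree: Phylogeny, leaves_with) -> tuple[int, set[str]]:
    """Exhaustive minimum-loss single-gain search (test oracle, ≤ 8 leaves).

    Tries every assignment of presence to internal nodes consistent with the
    observed leaf states, keeps those forming a connected set with a unique
    highest (gain) node, and returns (loss count, presence set) of a
    minimum-loss solution.
    """
    leaves_with = set(leaves_with)
    if len(tree.leaves) > 8:
        raise TreeError("brute-force oracle capped at 8 leaves")
    if not leaves_with or not leaves_with <= set(tree.leaves):
        raise TreeError("leaves_with must be a non-empty subset of the leaves")
    internals = tree.internal_nodes
    best: tuple[int, set[str]] | None = None
    for states in itertools.product((False, True), repeat=len(internals)):
        present = set(leaves_with)
        present.update(n for n, s in zip(internals, states) if s)
        # single gain: exactly one present node with no present parent
        tops = [n for n in present
                if tree.parent[n] is None or tree.parent[n] not in present]
        if len(tops) != 1:
            continue
        losses = sum(
            1 for n in tree.nodes
            if n not in present and tree.parent[n] in present
        )
        if best is None or losses < best[0]:
            best = (losses, present)
    assert best is not None  # gain-at-root with losses elsewhere always valid
    return best


def ancestral_count_matrix(
    table: GenomeAssignmentTable, tree: Phylogeny
) -> ArchCountMatrix:
    """Reconstruct N_d at every internal node from leaf assignment tables.

    Every distinct architecture observed across the leaves is reconstructed
    independently by Dollo parsimony; at each internal node v, N_d(v) counts
    the distinct present architectures containing domain d.  An architecture
    seen in a single leaf contributes to no ancestral node.
    """
    leaves = tree.leaves
    missing = [lf for lf in leaves if lf not in set(table.genome_ids)]
    if missing:
        raise TreeError(f"leaf genomes without assignments: {missing}")
    arch_leaves: dict[Architecture, set[str]] = {}
    for (g, _), arch in table.records.items():
        if g in set(leaves):
            arch_leaves.setdefault(arch, set()).add(g)
    internal = set(tree.internal_nodes)
    counts: dict[str, dict[str, int]] = {n: {} for n in tree.internal_nodes}
    for arch, lw in arch_leaves.items():
        present = dollo_presence(tree, lw) & internal
        if not present:
            continue
        for node in present:
            col = counts[node]
            for d in set(arch):
                if d != GAP:
                    col[d] = col.get(d, 0) + 1
    data = pd.DataFrame(counts).fillna(0).astype(int).sort_index()
    data = data.reindex(sorted(data.columns), axis=1)
    return ArchCountMatrix(data, kind="ancestral")


def architecture_events_table(
    table: GenomeAssignmentTable, tree: Phylogeny
) -> pd.DataFrame:
    """Per-architecture gain/loss placement: one row per distinct architecture."""
    arch_leaves: dict[Architecture, set[str]] = {}
    for (g, _), arch in table.records.items():
        arch_leaves.setdefault(arch, set()).add(g)
    rows = []
    for arch in sorted(arch_leaves):
        gain, losses = dollo_events(tree, arch_leaves[arch])
        rows.append({
            "architecture": architecture_to_string(arch),
            "gain_node": gain,
            "loss_nodes": ",".join(losses),
        })
    return pd.DataFrame(rows, columns=["architecture", "gain_node", "loss_nodes"])
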