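"""Synthetic datasets with the statistical structure the method assumes.

Three generative pieces, each controllable and seed-reproducible:

* per-superfamily architecture-diversity targets drawn from a discrete
  power law (most domains occur in one architecture, a few in many);
* genomes realised from those targets by tandem-repeat architectures, so
  the rebuilt count matrix reproduces the targets exactly;
* architecture evolution on a pure-birth tree under the Dollo model —
  exactly one gain per architecture, independent losses per branch — with
  the true presence matrix returned for reconstruction tests.

Planted high/low-diversity terms give scoring tests a known expected sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ancestral import Phylogeny, parse_newick
from .annotation import Term
from .genome_model import Architecture, GenomeAssignmentTable
from .ppscore import ConfigError


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults reflect the regime the method targets: ~10^3 superfamilies
    whose diversity is power-law-like (Zipf exponent 3 puts >60% of mass at
    a single architecture), a few-dozen-leaf binary tree, and moderate
    per-branch loss so most architectures survive in several leaves."""

    n_superfamilies: int = 1000
    zipf_exponent: float = 3.0
    n_leaves: int = 16
    loss_prob: float = 0.2
    gain_rule: str = "root"  # or "uniform"
    planted_k: int = 10
    n_random_terms: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.zipf_exponent <= 1:
            raise ConfigError("zipf exponent must be > 1")
        if not 0 <= self.loss_prob < 1:
            raise ConfigError("loss probability must be in [0, 1)")
        if self.gain_rule not in ("root", "uniform"):
            raise ConfigError(f"unknown gain rule {self.gain_rule!r}")
        if self.planted_k > self.n_superfamilies:
            raise ConfigError("planted term size exceeds superfamily count")


def _sf_name(i: int) -> str:
    return f"SF{i + 1:05d}"


def sample_superfamily_diversity(
    n: int, exponent: float, rng: np.random.Generator
) -> dict[str, int]:
    """Per-superfamily architecture-count targets from a Zipf law.

    Heavy mass at 1 (for exponent 3, about 83% of draws) with a long tail
    of highly plastic domains, mirroring the empirical shape of
    per-domain architecture diversity.
    """
    if exponent <= 1:
        raise ConfigError("zipf exponent must be > 1")
    if n == 0:
        return {}
    draws = stats.zipf(exponent).rvs(size=n, random_state=rng)
    return {_sf_name(i): int(c) for i, c in enumerate(draws)}


def build_genome_from_counts(
    counts: dict[str, int],
    genome_id: str = "G1",
    rng: np.random.Generator | None = None,
    n_mixed: int = 0,
) -> GenomeAssignmentTable:
    """Realise a genome whose rebuilt count matrix equals ``counts`` exactly.

    Each domain d with target N contributes N distinct architectures as
    tandem repeats of d of lengths 1…N — no architecture is shared between
    domains, so per-domain counts are fully decoupled.  ``n_mixed`` extra
    random two-domain architectures (requires ``rng``) trade that exact
    control for combinatorial realism; rebuilt counts then exceed targets.
    """
    rows: list[tuple[str, str, str]] = []
    for d in sorted(counts):
        n = counts[d]
        if n < 0:
            raise ValueError(f"negative count for {d}")
        for length in range(1, n + 1):
            rows.append((genome_id, f"{d}.p{length}", ",".join([d] * length)))
    if n_mixed:
        if rng is None:
            raise ValueError("mixed mode needs an rng")
        doms = sorted(d for d, n in counts.items() if n > 0)
        for j in range(n_mixed):
            a, b = rng.choice(doms, size=2, replace=False)
            rows.append((genome_id, f"mix.p{j}", f"{a},{b}"))
    return GenomeAssignmentTable.from_rows(rows)


def yule_tree(n_leaves: int, rng: np.random.Generator) -> Phylogeny:
    """Pure-birth topology: repeatedly split a uniformly chosen leaf.

    Branch lengths are irrelevant downstream and omitted.  Leaves are
    named ``G001``…; internal nodes get deterministic postorder ids.
    """
    if n_leaves < 2:
        raise ConfigError("need at least 2 leaves")
    children: dict[int, tuple[int, int]] = {0: (1, 2)}
    tips = [1, 2]
    next_id = 3
    while len(tips) < n_leaves:
        i = int(rng.integers(len(tips)))
        u = tips.pop(i)
        children[u] = (next_id, next_id + 1)
        tips.extend((next_id, next_id + 1))
        next_id += 2
    names = {u: f"G{j + 1:03d}" for j, u in enumerate(sorted(tips))}

    def render(u: int) -> str:
        if u in children:
            left, right = children[u]
            return f"({render(left)},{render(right)})"
        return names[u]

    return parse_newick(render(0) + ";")


def evolve_architectures_on_tree(
    tree: Phylogeny,
    counts: dict[str, int],
    loss_prob: float,
    rng: np.random.Generator,
    gain_rule: str = "root",
) -> tuple[GenomeAssignmentTable, dict[Architecture, frozenset[str]]]:
    """Forward-simulate Dollo-consistent architecture evolution.

    Architectures are the tandem-repeat realisations of ``counts``.  Each
    gets exactly one gain node (the root, or uniform over nodes), is
    inherited down the tree, and is lost independently on each descendant
    branch with probability ``loss_prob``.  Returns the leaf assignment
    table (surviving architectures only) and the true presence matrix over
    all nodes, for containment tests against reconstruction.
    """
    if not 0 <= loss_prob < 1:
        raise ConfigError("loss probability must be in [0, 1)")
    archs: list[Architecture] = []
    for d in sorted(counts):
        for length in range(1, counts[d] + 1):
            archs.append(tuple([d] * length))
    nodes = tree.nodes
    truth: dict[Architecture, frozenset[str]] = {}
    leaf_rows: dict[str, list[Architecture]] = {lf: [] for lf in tree.leaves}
    for arch in archs:
        if gain_rule == "root":
            gain = tree.root
        else:
            gain = nodes[int(rng.integers(len(nodes)))]
        present: set[str] = set()
        stack = [gain]
        while stack:
            node = stack.pop()
            present.add(node)
            for child in tree.children.get(node, ()):
                if rng.random() >= loss_prob:
                    stack.append(child)
        truth[arch] = frozenset(present)
        for lf in present:
            if tree.is_leaf(lf):
                leaf_rows[lf].append(arch)
    rows: list[tuple[str, str, str]] = []
    for lf in tree.leaves:
        for j, arch in enumerate(leaf_rows[lf]):
            rows.append((lf, f"p{j + 1}", ",".join(arch)))
    return GenomeAssignmentTable.from_rows(rows), truth


def plant_term(
    counts: dict[str, int],
    direction: str,
    k: int,
    term_id: str | None = None,
) -> tuple[Term, int]:
    """A term built from the k most (``high``) or least (``low``) diverse
    domains with count > 0; returns (term, expected PP-score sign)."""
    if k == 0:
        raise ConfigError("planted term size must be >= 1")
    if direction not in ("high", "low"):
        raise ConfigError(f"direction must be high|low, got {direction!r}")
    live = [(d, n) for d, n in counts.items() if n > 0]
    if k > len(live):
        raise ConfigError(f"k={k} exceeds {len(live)} domains with count > 0")
    reverse = direction == "high"
    # sort by count then id so ties break deterministically
    ranked = sorted(live, key=lambda dn: (dn[1], dn[0]), reverse=reverse)
    members = frozenset(d for d, _ in ranked[:k])
    term = Term(
        term_id=term_id or f"PLANT:{direction}",
        name=f"planted {direction}-diversity set (k={k})",
        level="specific",
        members=members,
    )
    return term, (1 if reverse else -1)


@dataclass(frozen=True)
class SyntheticDataset:
    tree: Phylogeny
    assignments: GenomeAssignmentTable
    truth_presence: dict[Architecture, frozenset[str]]
    terms: list[Term]
    truth_terms: pd.DataFrame  # term_id, direction, expected_sign
    counts: dict[str, int] = field(default_factory=dict)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Full fixture: tree + evolved leaf genomes + annotation terms.

    Planted high/low terms are defined on the simulated diversity targets;
    random terms of the same size cover the rest of the repertoire so the
    annotatable universe is broad.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = sample_superfamily_diversity(
        cfg.n_superfamilies, cfg.zipf_exponent, rng
    )
    tree = yule_tree(cfg.n_leaves, rng)
    table, truth = evolve_architectures_on_tree(
        tree, counts, cfg.loss_prob, rng, cfg.gain_rule
    )
    hi, _ = plant_term(counts, "high", cfg.planted_k, "PLANT:high")
    lo, _ = plant_term(counts, "low", cfg.planted_k, "PLANT:low")
    terms = [hi, lo]
    doms = sorted(d for d, n in counts.items() if n > 0)
    for j in range(cfg.n_random_terms):
        members = rng.choice(doms, size=min(cfg.planted_k, len(doms)),
                             replace=False)
        terms.append(Term(
            term_id=f"RAND:{j:03d}", name=f"random set {j}",
            level="general", members=frozenset(str(m) for m in members),
        ))
    truth_terms = pd.DataFrame(
        [("PLANT:high", "high", 1), ("PLANT:low", "low", -1)]
        + [(f"RAND:{j:03d}", "none", 0) for j in range(cfg.n_random_terms)],
        columns=["term_id", "direction", "expected_sign"],
    )
    return SyntheticDataset(tree=tree, assignments=table,
                            truth_presence=truth, terms=terms,
                            truth_terms=truth_terms, counts=counts)


def newick_of(tree: Phylogeny) -> str:
    """Render a Phylogeny back to Newick with internal labels."""
    def rec(node: str) -> str:
        if tree.is_leaf(node):
            return node
        left, right = tree.children[node]
        return f"({rec(left)},{rec(right)}){node}"

    return rec(tree.root) + ";"


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the standard inputs (+ truth tables) as TSV/Newick files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "assignments": os.path.join(outdir, "assignments.tsv"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "tree": os.path.join(outdir, "tree.nwk"),
        "truth_terms": os.path.join(outdir, "truth_terms.tsv"),
        "truth_presence": os.path.join(outdir, "truth_presence.tsv"),
    }
    rows = [(g, p, ",".join(a)) for (g, p), a in sorted(ds.assignments.records.items())]
    pd.DataFrame(rows, columns=["genome_id", "protein_id", "architecture"]).to_csv(
        paths["assignments"], sep="\t", index=False
    )
    ann = [
        (t.term_id, t.name, t.level, m)
        for t in ds.terms for m in sorted(t.members)
    ]
    pd.DataFrame(ann, columns=["term_id", "term_name", "level", "superfamily_id"]).to_csv(
        paths["annotations"], sep="\t", index=False
    )
    with open(paths["tree"], "w") as fh:
        fh.write(newick_of(ds.tree) + "\n")
    ds.truth_terms.to_csv(paths["truth_terms"], sep="\t", index=False)
    pres = [(",".join(a), ",".join(sorted(nodes)))
            for a, nodes in sorted(ds.truth_presence.items())]
    pd.DataFrame(pres, columns=["architecture", "present_nodes"]).to_csv(
        paths["truth_presence"], sep="\t", index=False
    )
    return paths
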