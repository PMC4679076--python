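"""Lineage trajectories: PP-scores for terms at every genome on a
root-to-leaf path, across ancestral (internal-node) and extant (leaf)
architecture-count matrices.
"""

from __future__ import annotations

import pandas as pd

from .ancestral import Phylogeny, TreeError
from .annotation import annotatable_universe
from .genome_model import ArchCountMatrix
from .ppscore import RESULT_COLUMNS, ScoreConfig, attach_fdr, score_terms

TRAJECTORY_COLUMNS = ("node_id", "depth") + RESULT_COLUMNS[:2] + RESULT_COLUMNS[3:]


def root_to_leaf_path(tree: Phylogeny, leaf_id: str) -> list[str]:
    """The unique simple path from the root to a leaf, inclusive."""
    if leaf_id not in set(tree.leaves):
        raise TreeError(f"unknown leaf {leaf_id!r}")
    return list(reversed(tree.path_to_root(leaf_id)))


def score_lineage(
    terms,
    tree: Phylogeny,
    extant: ArchCountMatrix,
    ancestral: ArchCountMatrix,
    leaf_id: str,
    cfg: ScoreConfig = ScoreConfig(),
) -> pd.DataFrame:
    """Score every term at every node on the root→leaf lineage.

    Leaves are looked up in the extant matrix and internal nodes in the
    ancestral one; each node is scored against its own annotatable
    universe.  With ``cfg.fdr_family == "global"`` the BH adjustment pools
    all (term, node) rows of the trajectory instead of per node.
    """
    terms = list(terms)
    path = root_to_leaf_path(tree, leaf_id)
    per_node_fdr = cfg.fdr_family == "per-genome"
    pieces = []
    for depth, node in enumerate(path):
        m = extant if tree.is_leaf(node) else ancestral
        if node not in m.genome_ids:
            raise TreeError(
                f"node {node!r} missing from the {m.kind} count matrix"
            )
        universe = annotatable_universe(node, m, terms)
        res = score_terms(terms, node, m, cfg, universe=universe)
        res.insert(0, "node_id", node)
        res.insert(1, "depth", depth)
        pieces.append(res)
    out = pd.concat(pieces, ignore_index=True)
    if not per_node_fdr:
        out = attach_fdr(out)
    return out.drop(columns=["genome_id"])


def trajectory_to_tsv(trajectory: pd.DataFrame, path_or_buf=None):
    return trajectory.to_csv(path_or_buf, sep="\t", index=False,
                             float_format="%.6g")


def plot_trajectory(trajectory: pd.DataFrame, path: str):
    """Optional term × node heatmap of PP-scores (diverging, centred at 0)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = trajectory.pivot_table(index="term_id", columns="depth",
                                  values="pp_score")
    lim = float(wide.abs().max().max()) or 1.0
    fig, ax = plt.subplots(figsize=(1 + 0.5 * wide.shape[1],
                                    1 + 0.4 * wide.shape[0]))
    im = ax.imshow(wide.to_numpy(), cmap="RdBu_r", vmin=-lim, vmax=lim,
                   aspect="auto")
    ax.set_xticks(range(wide.shape[1]), [str(c) for c in wide.columns])
    ax.set_yticks(range(wide.shape[0]), list(wide.index))
    ax.set_xlabel("node depth (root → leaf)")
    fig.colorbar(im, ax=ax, label="PP-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
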