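import itertools

import pytest

from archpp import build_arch_count_matrix, build_genome_from_counts
from archpp.annotation import AnnotatableUniverse


@pytest.fixture(scope="session")
def fig_counts():
    """Four-superfamily genome: A, B, C, D in 7, 5, 3, 6 architectures."""
    return {"A": 7, "B": 5, "C": 3, "D": 6}


@pytest.fixture(scope="session")
def fig_matrix(fig_counts):
    return build_arch_count_matrix(build_genome_from_counts(fig_counts))


@pytest.fixture(scope="session")
def fig_universe(fig_counts):
    return AnnotatableUniverse("G1", frozenset(fig_counts))


def all_tree_shapes(leaves):
    """Yield Newick strings for every rooted binary tree on the leaf labels.

    Recursive bipartition enumeration; the first label is pinned to the left
    side so each shape appears exactly once ((2L-3)!! trees for L leaves).
    """
    leaves = list(leaves)
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for r in range(len(rest)):
        for combo in itertools.combinations(rest, r):
            left = [first, *combo]
            right = [x for x in rest if x not in combo]
            if not right:
                continue
            for lt in all_tree_shapes(left):
                for rt in all_tree_shapes(right):
                    yield f"({lt},{rt})"


def all_rooted_trees(leaves):
    for shape in all_tree_shapes(leaves):
        if "(" not in shape:
            continue
        yield shape + ";"
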