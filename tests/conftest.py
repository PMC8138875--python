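import itertools

import pytest

from orthoeval.orthology_io import GeneId, Orthology
from orthoeval.taxonomy import (
    Side,
    SpeciesTaxonomy,
    SupergroupMap,
    parse_species_tree,
)


@pytest.fixture
def quartet_taxonomy() -> SpeciesTaxonomy:
    """((A,B),(C,D)) with A,B on the Amorphae side and C,D opposite."""
    tree = parse_species_tree("((A,B),(C,D));")
    sg = SupergroupMap(
        {
            "A": ("Amoebozoa", Side.AMORPHAE),
            "B": ("Obazoa", Side.AMORPHAE),
            "C": ("SAR", Side.DIAPHORETICKES),
            "D": ("Archaeplastida", Side.DIAPHORETICKES),
        }
    )
    return SpeciesTaxonomy(tree, sg)


def make_orthology(spec: dict[str, list[str]], name: str = "toy") -> Orthology:
    """Build an orthology from og_id -> ["SP|prot", ...] shorthand."""
    groups = {
        og: frozenset(GeneId(*g.split("|", 1)) for g in genes)
        for og, genes in spec.items()
    }
    return Orthology(name, groups)


def brute_force_dollo(tree, presence: dict[str, int]) -> int:
    """Minimum number of loss edges explaining the pattern, gain at root.

    Exhaustive search over all loss-edge subsets: a leaf is present iff
    no chosen edge lies on its root path.
    """
    nodes = list(tree.preorder_node_iter())
    edges = [n for n in nodes if n.parent_node is not None]
    leaf_paths = {}
    for leaf in tree.leaf_node_iter():
        path = set()
        node = leaf
        while node.parent_node is not None:
            path.add(id(node))
            node = node.parent_node
        leaf_paths[leaf.taxon.label] = path
    best = None
    for k in range(len(edges) + 1):
        if best is not None:
            break
        for combo in itertools.combinations(edges, k):
            chosen = {id(e) for e in combo}
            ok = all(
                presence[lb] == int(not (chosen & path))
                for lb, path in leaf_paths.items()
            )
            if ok:
                best = k
                break
    return best


def pair_agreement_ari(labels_a: list, labels_b: list):
    """ARI from exhaustive classification of all gene pairs.

    Returns None when the pair-table denominator is zero (both
    partitions trivial).
    """
    n = len(labels_a)
    n11 = n10 = n01 = n00 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = labels_a[i] == labels_a[j]
            sb = labels_b[i] == labels_b[j]
            if sa and sb:
                n11 += 1
            elif sa and not sb:
                n10 += 1
            elif not sa and sb:
                n01 += 1
            else:
                n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return None
    return 2.0 * (n11 * n00 - n10 * n01) / denom
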