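"""Rooted species tree and supergroup/side annotation.

Every downstream stage (Dollo parsimony, LECA calling, phylogenetic
profiles) works on a rooted species tree whose leaves are the analyzed
species, together with a map assigning each species to a eukaryotic
supergroup and each supergroup to one of the two sides of the eukaryotic
root, Amorphae or Diaphoretickes (formerly opimoda/diphoda). Branch
lengths are irrelevant: Dollo counting uses topology only. Multifurcating
nodes are accepted throughout, since the deep eukaryote phylogeny is
often unresolved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum

import dendropy

__all__ = [
    "Side",
    "SupergroupMap",
    "SpeciesTaxonomy",
    "TaxonomyReport",
    "TaxonomyError",
    "read_species_tree",
    "parse_species_tree",
    "write_species_tree",
    "read_supergroup_map",
    "validate_taxonomy",
    "leaf_labels",
]


class TaxonomyError(ValueError):
    """Malformed tree or supergroup map."""


class Side(str, Enum):
    AMORPHAE = "Amorphae"
    DIAPHORETICKES = "Diaphoretickes"


@dataclass(frozen=True)
class SupergroupMap:
    """species_id -> (supergroup, side), with each supergroup on one side."""

    species: dict[str, tuple[str, Side]]

    def __post_init__(self) -> None:
        side_of: dict[str, Side] = {}
        for sp, (sg, side) in self.species.items():
            if not isinstance(side, Side):
                raise TaxonomyError(
                    f"species {sp!r}: side {side!r} is not one of "
                    f"{[s.value for s in Side]}"
                )
            if sg in side_of and side_of[sg] is not side:
                raise TaxonomyError(
                    f"supergroup {sg!r} listed under both sides"
                )
            side_of[sg] = side

    def supergroup(self, species_id: str) -> str:
        return self.species[species_id][0]

    def side(self, species_id: str) -> Side:
        return self.species[species_id][1]

    @property
    def supergroups(self) -> dict[str, Side]:
        """Supergroup -> side over all entries."""
        return {sg: side for sg, side in self.species.values()}

    def species_of_supergroup(self, sg: str) -> set[str]:
        return {sp for sp, (g, _) in self.species.items() if g == sg}

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.species

    def __len__(self) -> int:
        return len(self.species)


def _check_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if any(lb is None for lb in labels):
        raise TaxonomyError("tree contains unnamed leaves")
    dupes = {lb for lb in labels if labels.count(lb) > 1}
    if dupes:
        raise TaxonomyError(f"duplicate leaf labels: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) < 2:
            # unifurcations carry no Dollo information; collapse them
            tree.suppress_unifurcations()
            break
    tree.is_rooted = True
    return tree


def read_species_tree(path) -> dendropy.Tree:
    """Read a rooted newick species tree with uniquely named leaves."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderError as exc:
        raise TaxonomyError(f"newick parse failed ({'duplicate leaf' if 'Duplicate' in str(exc) else 'malformed'}): {exc}") from exc
    return _check_tree(tree)


def parse_species_tree(newick: str) -> dendropy.Tree:
    """Parse a newick string (convenience for simulation and tests)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderError as exc:
        raise TaxonomyError(f"newick parse failed ({'duplicate leaf' if 'Duplicate' in str(exc) else 'malformed'}): {exc}") from exc
    return _check_tree(tree)


def write_species_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", unquoted_underscores=True))


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    """Leaf labels in tree traversal order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def read_supergroup_map(path) -> SupergroupMap:
    """Read a headered TSV with columns species_id, supergroup, side."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_id", "supergroup", "side"}
    if not required.issubset(df.columns):
        raise TaxonomyError(
            f"supergroup map must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df["species_id"].duplicated().any():
        dup = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise TaxonomyError(f"duplicate species entries: {dup}")
    entries: dict[str, tuple[str, Side]] = {}
    for row in df.itertuples(index=False):
        try:
            side = Side(row.side)
        except ValueError:
            raise TaxonomyError(
                f"species {row.species_id!r}: side {row.side!r} is not one "
                f"of {[s.value for s in Side]}"
            ) from None
        entries[row.species_id] = (row.supergroup, side)
    return SupergroupMap(entries)


def write_supergroup_map(sg_map: SupergroupMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tsupergroup\tside\n")
        for sp, (sg, side) in sg_map.species.items():
            fh.write(f"{sp}\t{sg}\t{side.value}\n")


@dataclass
class TaxonomyReport:
    """Cross-validation of tree leaves against the supergroup map."""

    leaves_missing_from_map: list[str] = field(default_factory=list)
    map_entries_missing_from_tree: list[str] = field(default_factory=list)
    species_per_supergroup: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return (
            not self.leaves_missing_from_map
            and not self.map_entries_missing_from_tree
        )

    @property
    def problems(self) -> list[str]:
        out = [
            f"tree leaf {lb!r} missing from supergroup map"
            for lb in self.leaves_missing_from_map
        ]
        out += [
            f"map entry {sp!r} is not a tree leaf"
            for sp in self.map_entries_missing_from_tree
        ]
        return out


@dataclass
class SpeciesTaxonomy:
    """Bundle of the species tree and its supergroup annotation."""

    tree: dendropy.Tree
    sg_map: SupergroupMap

    @property
    def species(self) -> list[str]:
        return leaf_labels(self.tree)

    def validate(self) -> "TaxonomyReport":
        return validate_taxonomy(self.tree, self.sg_map)


def validate_taxonomy(
    tree: dendropy.Tree, sg_map: SupergroupMap
) -> TaxonomyReport:
    """Report leaves/entries missing on either side; never raises."""
    leaves = set(leaf_labels(tree))
    mapped = set(sg_map.species)
    counts: dict[str, int] = {}
    for sp in leaves & mapped:
        sg = sg_map.supergroup(sp)
        counts[sg] = counts.get(sg, 0) + 1
    return TaxonomyReport(
        leaves_missing_from_map=sorted(leaves - mapped),
        map_entries_missing_from_tree=sorted(mapped - leaves),
        species_per_supergroup=counts,
    )
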