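"""LECA orthologous-group calling and independent-loss counting.

An orthologous group (OG) is called a LECA OG — present in the last
eukaryotic common ancestor — when its genes occur in at least
``min_supergroups`` eukaryotic supergroups distributed over both sides
of the eukaryotic root (Amorphae and Diaphoretickes). The default of
three supergroups is the standard criterion; two and four are the
less/more stringent sensitivity variants.

Loss counting follows Dollo parsimony: a gene is gained exactly once
(fixed at the root for a LECA OG) and every absence is explained by
losses, minimized in number. With gain at the root, the minimum is
obtained by marking each internal node present iff any descendant leaf
is present; an independent loss is then an edge from a present parent
into an entirely absent subtree. The rule is well defined on
multifurcations, so polytomies need no binarization.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import dendropy
from scipy import stats as _stats

from .orthology_io import GeneId
from .taxonomy import Side, SpeciesTaxonomy, SupergroupMap

__all__ = [
    "PresenceProfile",
    "LecaCall",
    "LossCount",
    "profile_from_group",
    "call_leca",
    "count_independent_losses",
    "retained_per_species",
    "loss_summary",
    "compare_loss_distributions",
]


@dataclass(frozen=True)
class PresenceProfile:
    """Binary presence (1) / absence (0) of one OG over all species."""

    og_id: str
    presence: dict[str, int]

    def present_species(self) -> set[str]:
        return {sp for sp, v in self.presence.items() if v}

    @property
    def n_present(self) -> int:
        return sum(self.presence.values())


@dataclass(frozen=True)
class LecaCall:
    og_id: str
    n_supergroups: int
    sides_covered: frozenset[Side]
    is_leca: bool
    min_supergroups: int


@dataclass(frozen=True)
class LossCount:
    og_id: str
    n_independent_losses: int


def profile_from_group(
    og_id: str, group: frozenset[GeneId] | set[GeneId], taxonomy: SpeciesTaxonomy
) -> PresenceProfile:
    """Presence[s] = 1 iff at least one gene of species s is in the group."""
    leaves = taxonomy.species
    leaf_set = set(leaves)
    present: set[str] = set()
    for gene in group:
        if gene.species_id not in leaf_set:
            raise ValueError(
                f"{og_id}: gene {gene} has species not in the taxonomy"
            )
        present.add(gene.species_id)
    return PresenceProfile(
        og_id, {sp: int(sp in present) for sp in leaves}
    )


def call_leca(
    profile: PresenceProfile,
    sg_map: SupergroupMap,
    min_supergroups: int = 3,
) -> LecaCall:
    """Apply the supergroup/both-sides criterion to one profile."""
    if min_supergroups < 1:
        raise ValueError("min_supergroups must be >= 1")
    supergroups: set[str] = set()
    sides: set[Side] = set()
    for sp in profile.present_species():
        supergroups.add(sg_map.supergroup(sp))
        sides.add(sg_map.side(sp))
    is_leca = len(supergroups) >= min_supergroups and len(sides) == 2
    return LecaCall(
        og_id=profile.og_id,
        n_supergroups=len(supergroups),
        sides_covered=frozenset(sides),
        is_leca=is_leca,
        min_supergroups=min_supergroups,
    )


def count_independent_losses(
    profile: PresenceProfile, tree: dendropy.Tree
) -> LossCount:
    """Dollo-minimum number of loss edges, gain fixed at the root.

    Postorder: an internal node is present iff any descendant leaf is
    present. A loss is an edge whose parent is present and whose child
    subtree is entirely absent. This is the unique minimum explaining
    the pattern under single gain at the root.
    """
    if profile.n_present == 0:
        raise ValueError(f"{profile.og_id}: all-absent profile cannot be a LECA OG")
    state: dict[int, bool] = {}
    losses = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state[id(node)] = bool(profile.presence[node.taxon.label])
        else:
            child_states = [state[id(c)] for c in node.child_nodes()]
            state[id(node)] = any(child_states)
            if state[id(node)]:
                losses += child_states.count(False)
    return LossCount(profile.og_id, losses)


def retained_per_species(profiles: list[PresenceProfile]) -> dict[str, int]:
    """Per species, the number of LECA OGs it retains (column sums)."""
    counts: dict[str, int] = {}
    for prof in profiles:
        for sp, v in prof.presence.items():
            counts[sp] = counts.get(sp, 0) + v
    return counts


def loss_summary(
    losses: list[LossCount], sizes: list[int]
) -> dict:
    """Fig-1-style per-method summary of LECA OG sizes and losses."""
    if not losses or len(losses) != len(sizes):
        raise ValueError("need non-empty, aligned loss and size lists")
    loss_vals = [lc.n_independent_losses for lc in losses]
    degenerate = len(loss_vals) < 2

    def _sd(vals: list) -> float:
        return 0.0 if degenerate else statistics.stdev(vals)

    return {
        "n_leca_ogs": len(loss_vals),
        "size_median": float(statistics.median(sizes)),
        "size_mean": statistics.fmean(sizes),
        "size_sd": _sd(sizes),
        "loss_median": float(statistics.median(loss_vals)),
        "loss_mean": statistics.fmean(loss_vals),
        "loss_sd": _sd(loss_vals),
        "sd_degenerate": degenerate,
    }


def compare_loss_distributions(
    losses_a: list[int], losses_b: list[int]
) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p for two samples.

    Identical samples give H=0, p=1; used to test whether two methods'
    independent-loss distributions differ.
    """
    if len(losses_a) < 2 or len(losses_b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if set(losses_a) == set(losses_b) and sorted(losses_a) == sorted(losses_b):
        # scipy raises on all-identical data; H is exactly 0 there
        if len(set(losses_a)) == 1:
            return 0.0, 1.0
    res = _stats.kruskal(losses_a, losses_b)
    return float(res.statistic), float(res.pvalue)
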