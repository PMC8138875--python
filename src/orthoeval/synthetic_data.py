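"""Synthetic study generator: trees, gene content, mock orthologies, interactions.

The generator emulates the structure of a eukaryote-wide orthology
benchmark at desk scale:

* a balanced rooted species tree whose first split separates the
  Amorphae from the Diaphoretickes side, with monophyletic supergroup
  clades;
* gene families, all present at the root (LECA), eroded top-down along
  tree edges by loss events that are never reversed — the generative
  mirror of Dollo parsimony. Families can belong to functional modules
  (complexes); with coupling rho, loss strikes whole modules together
  (probability p_loss * rho per edge) rather than single members
  (p_loss * (1 - rho)), producing the correlated co-loss that makes
  phylogenetic profiles predictive of interaction;
* a ground-truth orthology (one OG per family, one gene per present
  species) plus mock "method" outputs derived from it by merge, split,
  drop and misassignment error operators;
* an interaction table whose well-supported pairs are module
  co-members (reference-species proteins), with weakly supported decoy
  records between modules.

A designated reference species is shielded from loss for module
families (the shield applies along its root path, so recorded loss
events stay consistent with the emitted patterns); this guarantees the
interaction table can always be mapped to OGs.

All randomness flows from one master seed through named substreams
(taxonomy, content, perturb, interactions), so stages can be
regenerated independently and reruns are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .orthology_io import GeneId, Orthology, ReferenceGeneIndex, build_reference_index
from .taxonomy import Side, SpeciesTaxonomy, SupergroupMap, parse_species_tree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_taxonomy",
    "simulate_gene_content",
    "emit_truth_orthology",
    "perturb_orthology",
    "simulate_interactions",
    "simulate_study",
]

_SUBSTREAMS = ("taxonomy", "content", "perturb", "interactions")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent child stream of the master seed."""
    if name not in _SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}")
    idx = _SUBSTREAMS.index(name)
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(idx,))
    )


@dataclass
class SimulationConfig:
    n_supergroups_per_side: int = 2
    species_per_supergroup: int = 3
    n_families: int = 200
    p_loss: float = 0.1  # per-edge, per-family loss probability
    module_size_mean: float = 4.0
    module_size_max: int = 8
    n_modules: int = 10
    rho: float = 0.5  # co-loss coupling within modules
    error_rates: dict = field(
        default_factory=lambda: {
            "p_merge": 0.05,
            "p_split": 0.05,
            "p_drop": 0.02,
            "p_misassign": 0.02,
        }
    )
    n_pub_positive: int = 6
    n_decoys_per_positive: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_loss", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name, v in self.error_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.species_per_supergroup < 1:
            raise ValueError("species_per_supergroup must be >= 1")


@dataclass
class GroundTruth:
    truth: Orthology
    loss_events: dict[str, int]  # family -> simulated loss-event count
    modules: dict[str, str]  # family -> module id ("" = no module)
    reference_species: str
    reference_index: ReferenceGeneIndex
    interaction_positive_pairs: list[tuple[str, str]] = field(default_factory=list)


def _balanced_clade(names: list[str]) -> str:
    if len(names) == 1:
        return names[0]
    mid = len(names) // 2
    return f"({_balanced_clade(names[:mid])},{_balanced_clade(names[mid:])})"


def simulate_taxonomy(
    config: SimulationConfig,
) -> SpeciesTaxonomy:
    """Balanced rooted tree; first split = Amorphae vs Diaphoretickes.

    Supergroups are monophyletic; names are deterministic (the seed
    fixes nothing here beyond the config itself, so identical configs
    give identical trees).
    """
    sides = {
        Side.AMORPHAE: [
            f"AMO{g + 1}" for g in range(config.n_supergroups_per_side)
        ],
        Side.DIAPHORETICKES: [
            f"DIA{g + 1}" for g in range(config.n_supergroups_per_side)
        ],
    }
    entries: dict[str, tuple[str, Side]] = {}
    side_clades = []
    for side, sgs in sides.items():
        sg_clades = []
        for sg in sgs:
            species = [
                f"{sg}_s{k + 1}" for k in range(config.species_per_supergroup)
            ]
            for sp in species:
                entries[sp] = (sg, side)
            sg_clades.append(_balanced_clade(species))
        side_clades.append(
            sg_clades[0] if len(sg_clades) == 1 else f"({','.join(sg_clades)})"
        )
    newick = f"({side_clades[0]},{side_clades[1]});"
    tree = parse_species_tree(newick)
    return SpeciesTaxonomy(tree, SupergroupMap(entries))


def default_reference_species(taxonomy: SpeciesTaxonomy) -> str:
    """First Amorphae species in leaf order (the 'human-like' proteome)."""
    for sp in taxonomy.species:
        if taxonomy.sg_map.side(sp) is Side.AMORPHAE:
            return sp
    raise ValueError("taxonomy has no Amorphae species")


def _assign_modules(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """family -> module id; module sizes ~ 2 + Poisson, capped."""
    fams = [f"F{i:04d}" for i in range(config.n_families)]
    modules: dict[str, str] = {f: "" for f in fams}
    cursor = 0
    for m in range(config.n_modules):
        size = int(
            min(
                config.module_size_max,
                max(2, 2 + rng.poisson(max(config.module_size_mean - 2, 0))),
            )
        )
        if cursor + size > len(fams):
            break
        for f in fams[cursor : cursor + size]:
            modules[f] = f"M{m:02d}"
        cursor += size
    return modules


def simulate_gene_content(
    taxonomy: SpeciesTaxonomy,
    config: SimulationConfig,
    reference_species: str | None = None,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, str]]:
    """Top-down loss simulation; returns (presence df, loss events, modules).

    Every family is present at the root. On each edge, for each module
    with surviving members on the lineage, a module-level event fires
    with probability p_loss * rho and removes all surviving members;
    each surviving family is additionally lost alone with probability
    p_loss * (1 - rho). Loss is permanent (no regain). Edges on the
    root path of the reference species are shielded for module
    families.
    """
    rng = substream(config.seed, "content")
    ref = reference_species or default_reference_species(taxonomy)
    fams = [f"F{i:04d}" for i in range(config.n_families)]
    modules = _assign_modules(config, rng)
    module_members: dict[str, list[str]] = {}
    for fam, m in modules.items():
        if m:
            module_members.setdefault(m, []).append(fam)

    tree = taxonomy.tree
    # nodes on the root -> reference-leaf path (shielded for module families)
    ref_leaf = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == ref
    )
    ref_path = set()
    node = ref_leaf
    while node is not None:
        ref_path.add(id(node))
        node = node.parent_node

    loss_events = {f: 0 for f in fams}
    fam_idx = {f: i for i, f in enumerate(fams)}
    root_state = np.ones(len(fams), dtype=bool)
    leaf_presence: dict[str, np.ndarray] = {}
    state_at: dict[int, np.ndarray] = {id(tree.seed_node): root_state}

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = state_at[id(node.parent_node)]
        state = parent_state.copy()
        shielded = id(node) in ref_path
        # module-level co-loss events
        for m, members in module_members.items():
            idxs = [fam_idx[f] for f in members]
            if not any(state[i] for i in idxs):
                continue
            if shielded:
                continue
            if rng.random() < config.p_loss * config.rho:
                for i in idxs:
                    if state[i]:
                        state[i] = False
                        loss_events[fams[i]] += 1
        # member-level events
        p_single = config.p_loss * (1.0 - config.rho)
        draws = rng.random(len(fams))
        for i in np.nonzero(state)[0]:
            if shielded and modules[fams[i]]:
                continue
            if draws[i] < p_single:
                state[i] = False
                loss_events[fams[i]] += 1
        state_at[id(node)] = state
        if node.is_leaf():
            leaf_presence[node.taxon.label] = state

    species = taxonomy.species
    presence = pd.DataFrame(
        {sp: leaf_presence[sp].astype(np.int8) for sp in species}, index=fams
    )
    return presence, loss_events, modules


def emit_truth_orthology(
    presence: pd.DataFrame,
    taxonomy: SpeciesTaxonomy,
    reference_species: str | None = None,
    method_name: str = "truth",
) -> tuple[Orthology, ReferenceGeneIndex]:
    """One OG per family, one gene per present species."""
    ref = reference_species or default_reference_species(taxonomy)
    groups: dict[str, frozenset[GeneId]] = {}
    for fam, row in presence.iterrows():
        genes = frozenset(
            GeneId(sp, f"{fam}p") for sp, v in row.items() if v
        )
        if genes:
            groups[str(fam)] = genes
    orthology = Orthology(method_name, groups, disjoint=True)
    return orthology, build_reference_index(orthology, ref)


def perturb_orthology(
    truth: Orthology,
    error_rates: dict,
    seed: int,
    method_name: str = "mock",
) -> Orthology:
    """Mock method output: merge, split, drop, misassign — in that order.

    * merge: each OG (in sorted order) is unioned into a random other
      surviving OG with probability p_merge — producing undersplitting;
    * split: each OG of size >= 2 is bipartitioned at random with
      probability p_split — producing oversplitting;
    * drop: each gene is removed with probability p_drop (empty groups
      vanish) — lowering assignment;
    * misassign: each gene moves to a random other OG with probability
      p_misassign.

    Output remains disjoint.
    """
    for k, v in error_rates.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{k}={v} outside [0, 1]")
    p_merge = error_rates.get("p_merge", 0.0)
    p_split = error_rates.get("p_split", 0.0)
    p_drop = error_rates.get("p_drop", 0.0)
    p_mis = error_rates.get("p_misassign", 0.0)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))

    groups: dict[str, set[GeneId]] = {
        og: set(genes) for og, genes in truth.groups.items()
    }
    # merges
    for og in sorted(truth.groups):
        if og not in groups or len(groups) < 2:
            continue
        if rng.random() < p_merge:
            others = sorted(o for o in groups if o != og)
            target = others[rng.integers(0, len(others))]
            groups[target] |= groups.pop(og)
    # splits
    for og in sorted(groups):
        genes = sorted(groups[og])
        if len(genes) >= 2 and rng.random() < p_split:
            perm = rng.permutation(len(genes))
            cut = int(rng.integers(1, len(genes)))
            part_a = {genes[i] for i in perm[:cut]}
            part_b = {genes[i] for i in perm[cut:]}
            groups[og] = part_a
            groups[f"{og}_sp"] = part_b
    # drops
    if p_drop > 0:
        for og in sorted(groups):
            kept = {g for g in groups[og] if rng.random() >= p_drop}
            if kept:
                groups[og] = kept
            else:
                del groups[og]
    # misassignments
    if p_mis > 0 and len(groups) >= 2:
        og_ids = sorted(groups)
        moves: list[tuple[str, GeneId, str]] = []
        for og in og_ids:
            for gene in sorted(groups[og]):
                if rng.random() < p_mis:
                    others = [o for o in og_ids if o != og]
                    moves.append(
                        (og, gene, others[rng.integers(0, len(others))])
                    )
        for src, gene, dst in moves:
            if gene in groups.get(src, ()) and dst in groups:
                groups[src].discard(gene)
                groups[dst].add(gene)
                if not groups[src]:
                    del groups[src]
    return Orthology(
        method_name,
        {og: frozenset(g) for og, g in groups.items() if g},
        disjoint=True,
    )


def simulate_interactions(
    modules: dict[str, str],
    config: SimulationConfig,
    reference_species: str,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Interaction table over reference-species proteins.

    Positives: all within-module protein pairs, supported by
    ``n_pub_positive`` publications. Decoys: random cross-module pairs
    with 1-4 publications (below the positive-filter threshold). True
    negatives are the unrecorded cross-module pairs.
    """
    rng = substream(config.seed, "interactions")
    by_module: dict[str, list[str]] = {}
    for fam, m in modules.items():
        if m:
            by_module.setdefault(m, []).append(fam)
    if not any(len(v) >= 2 for v in by_module.values()):
        raise ValueError("need at least one module of size >= 2")

    def prot(fam: str) -> str:
        return f"{fam}p"

    records = []
    positive_pairs: list[tuple[str, str]] = []
    for m in sorted(by_module):
        members = sorted(by_module[m])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = prot(members[i]), prot(members[j])
                records.append((a, b, config.n_pub_positive))
                positive_pairs.append((a, b))
    module_fams = sorted(f for f, m in modules.items() if m)
    n_decoys = int(round(len(positive_pairs) * config.n_decoys_per_positive))
    seen = {tuple(sorted(p)) for p in positive_pairs}
    attempts = 0
    while n_decoys > 0 and attempts < 50 * max(n_decoys, 1):
        attempts += 1
        fa, fb = rng.choice(module_fams, size=2, replace=False)
        if modules[fa] == modules[fb]:
            continue
        pair = tuple(sorted((prot(fa), prot(fb))))
        if pair in seen:
            continue
        seen.add(pair)
        records.append((pair[0], pair[1], int(rng.integers(1, 5))))
        n_decoys -= 1
    df = pd.DataFrame(
        records, columns=["protein_a", "protein_b", "n_publications"]
    )
    return df, positive_pairs


def simulate_study(
    config: SimulationConfig,
    mock_methods: dict[str, dict] | None = None,
) -> tuple[SpeciesTaxonomy, GroundTruth, dict[str, Orthology], pd.DataFrame]:
    """Full scenario: taxonomy, truth, mock methods, interaction table.

    ``mock_methods`` maps method names to error-rate dicts; by default
    one mock method uses ``config.error_rates``.
    """
    taxonomy = simulate_taxonomy(config)
    ref = default_reference_species(taxonomy)
    presence, loss_events, modules = simulate_gene_content(taxonomy, config, ref)
    truth, index = emit_truth_orthology(presence, taxonomy, ref)
    interactions, positive_pairs = simulate_interactions(modules, config, ref)
    gt = GroundTruth(
        truth=truth,
        loss_events=loss_events,
        modules=modules,
        reference_species=ref,
        reference_index=index,
        interaction_positive_pairs=positive_pairs,
    )
    if mock_methods is None:
        mock_methods = {"mock": config.error_rates}
    orthologies = {}
    for i, (name, rates) in enumerate(sorted(mock_methods.items())):
        orthologies[name] = perturb_orthology(
            truth, rates, seed=config.seed + 7919 * (i + 1), method_name=name
        )
    return taxonomy, gt, orthologies, interactions


def write_study(
    outdir,
    taxonomy: SpeciesTaxonomy,
    gt: GroundTruth,
    orthologies: dict[str, Orthology],
    interactions: pd.DataFrame,
) -> dict[str, str]:
    """Write the scenario in the exact formats the pipeline reads."""
    import pathlib

    from .cooccurrence import InteractionTable
    from .orthology_io import write_orthogroups_long
    from .taxonomy import write_species_tree, write_supergroup_map

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_species_tree(taxonomy.tree, out / "species_tree.nwk")
    paths["tree"] = str(out / "species_tree.nwk")
    write_supergroup_map(taxonomy.sg_map, out / "supergroups.tsv")
    paths["supergroup_map"] = str(out / "supergroups.tsv")
    write_orthogroups_long(gt.truth, out / "orthology_truth.tsv")
    paths["orthology_truth"] = str(out / "orthology_truth.tsv")
    for name, orth in orthologies.items():
        p = out / f"orthology_{name}.tsv"
        write_orthogroups_long(orth, p)
        paths[f"orthology_{name}"] = str(p)
    InteractionTable(interactions).to_tsv(out / "interactions.tsv")
    paths["interactions"] = str(out / "interactions.tsv")
    truth_json = {
        "reference_species": gt.reference_species,
        "loss_events": gt.loss_events,
        "modules": gt.modules,
        "positive_pairs": [list(p) for p in gt.interaction_positive_pairs],
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    paths["ground_truth"] = str(out / "ground_truth.json")
    return paths
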