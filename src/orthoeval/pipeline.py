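"""Orchestration of the four evaluations over one or more orthologies.

Stages: LECA calling + loss statistics (per method), co-occurrence
ROC/AUC against interaction sets, cluster-overlap comparison against a
curated reference and between methods, and a run manifest recording
seeds, parameters and input hashes for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cooccurrence import (
    InteractionTable,
    build_pseudo_negative,
    build_random_pairs,
    filter_positive,
    map_pairs_to_ogs,
    roc_auc,
)
from .leca import (
    call_leca,
    compare_loss_distributions,
    count_independent_losses,
    loss_summary,
    profile_from_group,
    retained_per_species,
)
from .orthology_io import Orthology, build_reference_index
from .overlap import (
    adjusted_rand,
    fgkcs,
    overlap_fraction_matrix,
    partition_from_orthology,
    perfect_overlap_groups,
    splitting_report,
)
from .profiles import (
    DEFAULT_MEASURE,
    build_matrix,
    cross_method_profile_distance,
    pairwise_distances,
)
from .taxonomy import SpeciesTaxonomy

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    min_supergroups: int = 3
    min_pubs: int = 5
    measure: str = DEFAULT_MEASURE
    n_bootstrap: int = 1000
    max_pairs: int = 100_000
    shuffle_fractions: tuple = (0, 10, 30, 60, 100)
    seed: int = 0
    reference_species: str | None = None
    universe_policy: str = "intersection"


@dataclass
class LecaEvalResult:
    method: str
    calls: list
    losses: list
    summary: dict
    retained: dict[str, int]


def leca_eval_method(
    orthology: Orthology,
    taxonomy: SpeciesTaxonomy,
    min_supergroups: int = 3,
) -> LecaEvalResult:
    """LECA calls, loss counts and the Fig-1-style summary for one method."""
    calls, losses, sizes = [], [], []
    for og_id in sorted(orthology.groups):
        prof = profile_from_group(og_id, orthology.groups[og_id], taxonomy)
        call = call_leca(prof, taxonomy.sg_map, min_supergroups)
        calls.append(call)
        if call.is_leca:
            losses.append(count_independent_losses(prof, taxonomy.tree))
            sizes.append(len(orthology.groups[og_id]))
    leca_profiles = [
        profile_from_group(c.og_id, orthology.groups[c.og_id], taxonomy)
        for c in calls
        if c.is_leca
    ]
    summary = (
        loss_summary(losses, sizes)
        if losses
        else {"n_leca_ogs": 0}
    )
    return LecaEvalResult(
        method=orthology.method_name,
        calls=calls,
        losses=losses,
        summary=summary,
        retained=retained_per_species(leca_profiles),
    )


def run_leca_eval(
    orthologies: dict[str, Orthology],
    taxonomy: SpeciesTaxonomy,
    config: RunConfig,
) -> dict:
    """Per-method LECA/loss tables plus the pairwise Kruskal-Wallis table."""
    results = {
        name: leca_eval_method(orth, taxonomy, config.min_supergroups)
        for name, orth in orthologies.items()
    }
    usable = {
        name: r for name, r in results.items() if r.summary.get("n_leca_ogs", 0) > 1
    }
    kw_rows = []
    names = sorted(usable)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            h, p = compare_loss_distributions(
                [lc.n_independent_losses for lc in usable[a].losses],
                [lc.n_independent_losses for lc in usable[b].losses],
            )
            kw_rows.append({"method_a": a, "method_b": b, "H": h, "p_value": p})
    return {
        "per_method": results,
        "kruskal_wallis": pd.DataFrame(
            kw_rows, columns=["method_a", "method_b", "H", "p_value"]
        ),
    }


def run_cooccurrence_eval(
    orthologies: dict[str, Orthology],
    taxonomy: SpeciesTaxonomy,
    interactions: InteractionTable,
    config: RunConfig,
    reference_species: str,
) -> dict:
    """Per-method ROC over positives vs pseudo-negatives.

    Positive protein pairs (>= min_pubs publications) and pseudo-
    negative pairs are mapped to OG pairs through each method's
    reference index; distances are pooled per method for the
    divide-by-max conversions.
    """
    positives = filter_positive(interactions, config.min_pubs)
    pos_pairs_prot = list(
        zip(positives.records["protein_a"], positives.records["protein_b"])
    )
    neg_pairs_prot = build_pseudo_negative(
        interactions, config.min_pubs, config.max_pairs, seed=config.seed
    )
    out = {}
    matrices: dict[str, object] = {}
    indices: dict[str, object] = {}
    for name, orth in sorted(orthologies.items()):
        leca = run_leca_eval({name: orth}, taxonomy, config)["per_method"][name]
        try:
            matrix = build_matrix(orth, taxonomy, leca.calls)
        except ValueError:
            logger.warning("%s: skipped (no LECA OGs)", name)
            continue
        index = build_reference_index(orth, reference_species)
        matrices[name] = matrix
        indices[name] = index
        pos_og, pos_drops = map_pairs_to_ogs(pos_pairs_prot, index)
        neg_og, neg_drops = map_pairs_to_ogs(neg_pairs_prot, index)
        pos_og = [p for p in pos_og if p[0] in matrix and p[1] in matrix]
        neg_og = [p for p in neg_og if p[0] in matrix and p[1] in matrix]
        if not pos_og or not neg_og:
            raise ValueError(f"{name}: no mappable interaction pairs")
        pooled = pos_og + neg_og
        dists = pairwise_distances(matrix, pooled, config.measure)
        kept = dict(zip(dists.pairs, dists.distances))
        pos_d = np.array([kept[p] for p in pos_og if p in kept])
        neg_d = np.array([kept[p] for p in neg_og if p in kept])
        roc = roc_auc(
            pos_d, neg_d, n_bootstrap=config.n_bootstrap, seed=config.seed
        )
        roc.metadata.update(
            {
                "method": name,
                "measure": config.measure,
                "pos_drops": pos_drops,
                "neg_drops": neg_drops,
                "max_raw": dists.max_raw,
            }
        )
        out[name] = roc
    cross_rows = []
    usable = sorted(matrices)
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            try:
                df = cross_method_profile_distance(
                    matrices[a], matrices[b], indices[a], indices[b],
                    config.measure,
                )
            except ValueError:
                continue
            df = df.assign(method_a=a, method_b=b)
            cross_rows.append(df)
    cross = (
        pd.concat(cross_rows, ignore_index=True)
        if cross_rows
        else pd.DataFrame(
            columns=["gene", "og_a", "og_b", "distance", "measure",
                     "method_a", "method_b"]
        )
    )
    return {"roc": out, "cross_method_distances": cross}


def run_overlap_eval(
    orthologies: dict[str, Orthology],
    taxonomy: SpeciesTaxonomy,
    config: RunConfig,
    manual: Orthology | None = None,
) -> dict:
    """All-vs-all ARS/FGKCS matrix, splitting reports, perfect-overlap list.

    Partitions are restricted to LECA, non-singleton OGs before
    scoring; the shared universe is the intersection of genes clustered
    by both sides.
    """
    leca_ogs: dict[str, set[str]] = {}
    pool = dict(orthologies)
    if manual is not None:
        pool = {**pool, manual.method_name: manual}
    for name, orth in pool.items():
        res = leca_eval_method(orth, taxonomy, config.min_supergroups)
        leca_ogs[name] = {c.og_id for c in res.calls if c.is_leca}
    partitions = {
        name: partition_from_orthology(orth, keep_og_ids=leca_ogs[name])
        for name, orth in pool.items()
    }
    names = sorted(pool)
    ars = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    fg = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            s = adjusted_rand(partitions[a], partitions[b]).value
            ars.loc[a, b] = ars.loc[b, a] = s
            fg.loc[a, b] = fgkcs(partitions[a], partitions[b]).value
            fg.loc[b, a] = fgkcs(partitions[b], partitions[a]).value
    split_reports = {}
    if manual is not None:
        manual_leca = manual.subset(leca_ogs[manual.method_name])
        for name, orth in sorted(orthologies.items()):
            inferred_leca = orth.subset(leca_ogs[name])
            m = overlap_fraction_matrix(manual_leca, inferred_leca)
            split_reports[name] = splitting_report(m, method=name)
        split_reports = dict(
            sorted(
                split_reports.items(),
                key=lambda kv: -kv[1].assignment_pct,
            )
        )
    perfect = (
        perfect_overlap_groups(
            [pool[n].subset(leca_ogs[n]) for n in sorted(orthologies)]
        )
        if len(orthologies) >= 2
        else []
    )
    return {
        "ars_matrix": ars,
        "fgkcs_matrix": fg,
        "split_reports": split_reports,
        "perfect_overlap": perfect,
    }


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_manifest(
    config: RunConfig,
    input_paths: dict[str, str],
    outputs: dict,
    timestamp: str | None = None,
) -> dict:
    """Reproducibility record: versions, seeds, parameters, input hashes."""
    for name, path in input_paths.items():
        if not pathlib.Path(path).exists():
            raise FileNotFoundError(f"manifest input {name!r}: {path} missing")
    manifest = {
        "orthoeval_version": __version__,
        "python_version": platform.python_version(),
        "parameters": {
            "min_supergroups": config.min_supergroups,
            "min_pubs": config.min_pubs,
            "measure": config.measure,
            "n_bootstrap": config.n_bootstrap,
            "max_pairs": config.max_pairs,
            "seed": config.seed,
            "universe_policy": config.universe_policy,
        },
        "input_hashes": {
            name: _hash_file(p) for name, p in sorted(input_paths.items())
        },
        "outputs": sorted(outputs),
    }
    if timestamp is not None:
        manifest["timestamp"] = timestamp
    return manifest
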