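"""Interaction sets and co-occurrence ROC evaluation.

Positive pairs come from a physical-interaction table (BioGRID-like)
filtered to pairs supported by at least five independent publications.
Pseudo-negatives pair well-studied proteins (appearing in at least one
well-supported interaction) that were never reported to interact with
each other — excluding "not observed for technical reasons" as an
explanation for the missing interaction. A random OG-pair set provides
a chance baseline.

Scores are profile distances with the convention that a smaller
distance predicts interaction. The AUC is computed as the Mann-Whitney
probability P(d_pos < d_neg) + 0.5 * P(d_pos = d_neg) with midrank tie
handling, which equals the trapezoidal area under the ROC curve;
confidence intervals come from a percentile bootstrap resampling both
sets with replacement.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .orthology_io import GeneId, ReferenceGeneIndex

__all__ = [
    "InteractionTable",
    "RocResult",
    "read_interaction_table",
    "filter_positive",
    "build_pseudo_negative",
    "build_random_pairs",
    "map_pairs_to_ogs",
    "roc_auc",
    "mann_whitney_auc",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_PUBS = 5
DEFAULT_MAX_PAIRS = 100_000


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionTable:
    """Undirected protein pairs with publication support counts."""

    records: pd.DataFrame  # columns protein_a, protein_b, n_publications

    def __post_init__(self) -> None:
        df = self.records
        required = {"protein_a", "protein_b", "n_publications"}
        if not required.issubset(df.columns):
            raise ValueError(f"interaction table needs columns {sorted(required)}")
        if (df["protein_a"] == df["protein_b"]).any():
            raise ValueError("self-interaction records are not allowed")
        if (df["n_publications"] < 1).any():
            raise ValueError("n_publications must be >= 1")
        a = df[["protein_a", "protein_b"]].min(axis=1)
        b = df[["protein_a", "protein_b"]].max(axis=1)
        canon = df.assign(protein_a=a, protein_b=b)
        canon = (
            canon.groupby(["protein_a", "protein_b"], as_index=False)[
                "n_publications"
            ].max()
        )
        self.records = canon.sort_values(
            ["protein_a", "protein_b"], ignore_index=True
        )

    def __len__(self) -> int:
        return len(self.records)

    def pair_set(self) -> set[tuple[str, str]]:
        return set(
            zip(self.records["protein_a"], self.records["protein_b"])
        )

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def read_interaction_table(path) -> InteractionTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"protein_a": str, "protein_b": str}
    )
    df["n_publications"] = df["n_publications"].astype(int)
    return InteractionTable(df)


def filter_positive(
    table: InteractionTable, min_pubs: int = DEFAULT_MIN_PUBS
) -> InteractionTable:
    """Keep pairs supported by at least ``min_pubs`` publications."""
    kept = table.records[table.records["n_publications"] >= min_pubs]
    if kept.empty:
        logger.warning("positive filter at min_pubs=%d left no pairs", min_pubs)
    return InteractionTable(kept.reset_index(drop=True))


def build_pseudo_negative(
    table: InteractionTable,
    min_pubs: int = DEFAULT_MIN_PUBS,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int | None = None,
    well_studied: str = "publications",
) -> list[tuple[str, str]]:
    """Pairs of well-studied proteins never recorded as interacting.

    Under the default ``well_studied="publications"`` reading a protein
    qualifies when it takes part in at least one interaction with
    >= min_pubs publications; under ``"partners"`` it must have
    >= min_pubs distinct interaction partners (at any support level).
    Candidate pairs are all unordered pairs of qualifying proteins with
    no record (at any support level) in the full table. If the
    candidate space exceeds ``max_pairs``, a uniform seeded subsample
    is returned.
    """
    if well_studied == "publications":
        strong = table.records[table.records["n_publications"] >= min_pubs]
        candidates = sorted(
            set(strong["protein_a"]) | set(strong["protein_b"])
        )
    elif well_studied == "partners":
        degree = pd.concat(
            [table.records["protein_a"], table.records["protein_b"]]
        ).value_counts()
        candidates = sorted(degree[degree >= min_pubs].index)
    else:
        raise ValueError(
            f"well_studied must be 'publications' or 'partners', got {well_studied!r}"
        )
    if len(candidates) < 2:
        raise ValueError(
            "fewer than 2 well-studied proteins; cannot build pseudo-negatives"
        )
    recorded = table.pair_set()
    negatives = [
        pair
        for pair in itertools.combinations(candidates, 2)
        if pair not in recorded
    ]
    if not negatives:
        logger.warning("all candidate pairs are recorded; empty pseudo-negative set")
        return []
    if len(negatives) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(negatives), size=max_pairs, replace=False)
        negatives = [negatives[i] for i in sorted(idx)]
    return negatives


def build_random_pairs(
    index: ReferenceGeneIndex, n_pairs: int, seed: int | None = None
) -> list[tuple[str, str]]:
    """Distinct unordered pairs of distinct OGs, drawn with replacement.

    OGs may recur across pairs (as in the positive set, where one OG
    participates in several interactions), but a pair never repeats and
    an OG is never paired with itself.
    """
    ogs = sorted(set(index.gene_to_og.values()))
    n_possible = len(ogs) * (len(ogs) - 1) // 2
    if n_pairs > n_possible:
        raise ValueError(
            f"requested {n_pairs} pairs but only {n_possible} distinct pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    while len(out) < n_pairs:
        a, b = rng.choice(len(ogs), size=2)
        if a == b:
            continue
        pair = _canonical(ogs[a], ogs[b])
        if pair in chosen:
            continue
        chosen.add(pair)
        out.append(pair)
    return out


def map_pairs_to_ogs(
    protein_pairs: list[tuple[str, str]],
    index: ReferenceGeneIndex,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Translate protein pairs to distinct-OG pairs via the reference index.

    Returns the mapped unique pairs and drop counts by reason
    (unmapped_a, unmapped_b, same_og, duplicate). Same-OG pairs are
    excluded: their profile distance is 0 by construction and the
    evaluation compares distinct OGs.
    """
    by_protein = {
        gene.protein_id: og for gene, og in index.gene_to_og.items()
    }
    drops = {"unmapped_a": 0, "unmapped_b": 0, "same_og": 0, "duplicate": 0}
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for a, b in protein_pairs:
        og_a = by_protein.get(a)
        og_b = by_protein.get(b)
        if og_a is None:
            drops["unmapped_a"] += 1
            continue
        if og_b is None:
            drops["unmapped_b"] += 1
            continue
        if og_a == og_b:
            drops["same_og"] += 1
            continue
        pair = _canonical(og_a, og_b)
        if pair in seen:
            drops["duplicate"] += 1
            continue
        seen.add(pair)
        out.append(pair)
    return out, drops


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(d_pos < d_neg) + 0.5 P(d_pos = d_neg), by midranks."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    ranks = _stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u_pos = r_pos - len(pos) * (len(pos) + 1) / 2.0  # pairs where pos > neg
    return 1.0 - u_pos / (len(pos) * len(neg))


def roc_curve_points(
    pos: np.ndarray, neg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (fpr, tpr), thresholding distance from small to large."""
    pos = np.sort(np.asarray(pos, float))
    neg = np.sort(np.asarray(neg, float))
    thresholds = np.unique(np.concatenate([pos, neg]))
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(np.searchsorted(pos, t, side="right") / len(pos))
        fpr.append(np.searchsorted(neg, t, side="right") / len(neg))
    return np.asarray(fpr), np.asarray(tpr)


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int | None
    n_pos: int
    n_neg: int
    metadata: dict = field(default_factory=dict)

    def to_json_record(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            **self.metadata,
        }


def roc_auc(
    pos_distances: np.ndarray,
    neg_distances: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> RocResult:
    """AUC with percentile-bootstrap 95% CI; smaller distance = interacting.

    Note the ROC curve is built on thresholds "distance <= t predicts
    interaction"; the trapezoidal area under it equals the Mann-Whitney
    AUC including the tie-midpoint convention.
    """
    pos = np.asarray(pos_distances, float)
    neg = np.asarray(neg_distances, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both distance sets must be non-empty")
    auc = mann_whitney_auc(pos, neg)
    fpr, tpr = roc_curve_points(pos, neg)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        bp = pos[rng.integers(0, pos.size, pos.size)]
        bn = neg[rng.integers(0, neg.size, neg.size)]
        boot[i] = mann_whitney_auc(bp, bn)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    return RocResult(
        auc=float(auc),
        fpr=fpr,
        tpr=tpr,
        ci_low=float(min(ci_low, auc)),
        ci_high=float(max(ci_high, auc)),
        n_bootstrap=n_bootstrap,
        seed=seed,
        n_pos=pos.size,
        n_neg=neg.size,
    )
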