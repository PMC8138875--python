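"""Cluster-overlap diagnostics between orthologies and a curated reference.

Two partition-agreement scores compare OG sets as clusterings of a
shared gene universe:

* ARS (adjusted Rand score): pair-counting agreement corrected for
  chance, 1 for identical partitions, ~0 at chance level. Computed from
  the contingency table as (Index - E[Index]) / (MaxIndex - E[Index]).
* FGKCS (F-grand K-clique score): for every reference cluster, the best
  F-score (harmonic mean of precision and recall of shared members)
  over all predicted clusters, averaged over reference clusters.

Because pair-counting over-penalizes methods that emit many singletons,
comparisons are restricted to LECA (non-singleton) OGs; the shared
universe is by default the intersection of genes clustered by both
inputs, with drop counts reported (coverage differences are measured
separately by the assignment percentage).

The overlap-fraction matrix and the splitting report localize the
disagreement: a manual OG spread over several inferred OGs is
oversplit; one inferred OG absorbing several manual OGs undersplits
them.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.special import comb

from .orthology_io import GeneId, Orthology

__all__ = [
    "Partition",
    "ClusterScore",
    "OverlapMatrix",
    "SplitReport",
    "partition_from_orthology",
    "adjusted_rand",
    "fgkcs",
    "shuffle_calibration",
    "overlap_fraction_matrix",
    "splitting_report",
    "perfect_overlap_groups",
    "heatmap_layout",
    "load_manual_og_registry",
]

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    """gene -> cluster_id over a recorded gene universe."""

    assignment: dict
    universe_policy: str = "as_given"

    def __post_init__(self) -> None:
        if any(v is None for v in self.assignment.values()):
            raise ValueError("every universe gene needs a cluster")

    @property
    def n_genes(self) -> int:
        return len(self.assignment)

    def clusters(self) -> dict:
        out: dict = {}
        for gene, cl in self.assignment.items():
            out.setdefault(cl, set()).add(gene)
        return out

    def restrict(self, genes: set) -> "Partition":
        return Partition(
            {g: c for g, c in self.assignment.items() if g in genes},
            universe_policy="restricted",
        )


def partition_from_orthology(
    orthology: Orthology,
    keep_og_ids: set[str] | None = None,
    drop_singletons: bool = True,
) -> Partition:
    """Flatten an orthology into gene -> og_id.

    ``keep_og_ids`` typically holds the LECA-positive OGs; singleton
    groups are dropped by default since pair-counting scores cannot see
    them.
    """
    if not orthology.disjoint:
        raise ValueError(
            f"{orthology.method_name}: partition requires disjoint groups"
        )
    assignment: dict[GeneId, str] = {}
    for og_id, genes in orthology.groups.items():
        if keep_og_ids is not None and og_id not in keep_og_ids:
            continue
        if drop_singletons and len(genes) < 2:
            continue
        for gene in genes:
            assignment[gene] = og_id
    return Partition(assignment)


@dataclass(frozen=True)
class ClusterScore:
    score_type: str  # "ARS" or "FGKCS"
    value: float
    n_genes: int
    degenerate: bool = False


def _shared_universe(a: Partition, b: Partition) -> set:
    return set(a.assignment) & set(b.assignment)


def adjusted_rand(a: Partition, b: Partition) -> ClusterScore:
    """Adjusted Rand score on the intersection universe.

    Degenerate case (expected index equals maximum index, e.g. both
    partitions a single block or both all-singletons): returns 1 when
    the partitions agree on the universe, else 0, flagged.
    """
    universe = _shared_universe(a, b)
    if len(universe) < 2:
        raise ValueError("shared universe has fewer than 2 genes")
    genes = sorted(universe, key=repr)
    la = [a.assignment[g] for g in genes]
    lb = [b.assignment[g] for g in genes]
    ct = pd.crosstab(pd.Series(la), pd.Series(lb)).to_numpy()
    n = len(genes)
    sum_ij = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        identical = sum_ij == sum_a == sum_b
        return ClusterScore("ARS", 1.0 if identical else 0.0, n, degenerate=True)
    value = (sum_ij - expected) / (max_index - expected)
    return ClusterScore("ARS", float(value), n)


def fgkcs(reference: Partition, predicted: Partition) -> ClusterScore:
    """Grand mean over reference clusters of the best-match F-score.

    For reference cluster R and predicted cluster P sharing k members,
    precision = k/|P|, recall = k/|R|, F = 2pr/(p+r); each reference
    cluster contributes its best F over all predicted clusters.
    """
    universe = _shared_universe(reference, predicted)
    if not universe:
        raise ValueError("shared universe is empty")
    ref_clusters = reference.restrict(universe).clusters()
    pred_clusters = predicted.restrict(universe).clusters()
    if not ref_clusters:
        raise ValueError("reference has no clusters on the shared universe")
    best_fs = []
    for r_members in ref_clusters.values():
        best = 0.0
        for p_members in pred_clusters.values():
            k = len(r_members & p_members)
            if k == 0:
                continue
            p = k / len(p_members)
            r = k / len(r_members)
            best = max(best, 2 * p * r / (p + r))
        best_fs.append(best)
    return ClusterScore("FGKCS", float(np.mean(best_fs)), len(universe))


def shuffle_calibration(
    orthology: Orthology,
    fractions: list[float],
    n_reps: int = 10,
    seed: int | None = None,
    keep_og_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Score decay when a percentage of cluster labels is shuffled.

    For each fraction f (percent), a uniformly chosen f% of genes are
    reassigned to a uniformly random existing cluster (possibly their
    own, keeping the cluster count fixed); ARS and FGKCS against the
    unshuffled partition are averaged over ``n_reps`` replicates.
    Calibrates what a given score means in terms of actual label
    agreement. f=0 returns exactly 1 for both scores.
    """
    base = partition_from_orthology(orthology, keep_og_ids=keep_og_ids)
    genes = sorted(base.assignment, key=repr)
    cluster_ids = sorted(set(base.assignment.values()))
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        if not 0 <= f <= 100:
            raise ValueError(f"fraction {f} outside [0, 100]")
        ars_vals, fg_vals = [], []
        for _ in range(n_reps):
            shuffled = dict(base.assignment)
            n_shuffle = int(round(len(genes) * f / 100.0))
            if n_shuffle:
                picks = rng.choice(len(genes), size=n_shuffle, replace=False)
                for i in picks:
                    shuffled[genes[i]] = cluster_ids[
                        rng.integers(0, len(cluster_ids))
                    ]
            pert = Partition(shuffled)
            ars_vals.append(adjusted_rand(base, pert).value)
            fg_vals.append(fgkcs(base, pert).value)
        rows.append(
            {
                "fraction_shuffled": f,
                "ars_mean": float(np.mean(ars_vals)),
                "ars_sd": float(np.std(ars_vals, ddof=1)) if n_reps > 1 else 0.0,
                "fgkcs_mean": float(np.mean(fg_vals)),
                "fgkcs_sd": float(np.std(fg_vals, ddof=1)) if n_reps > 1 else 0.0,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class OverlapMatrix:
    """Manual-OG x inferred-OG overlap counts and manual-size fractions."""

    manual_ids: list[str]
    inferred_ids: list[str]
    counts: np.ndarray  # shared-protein counts
    manual_sizes: np.ndarray  # total proteins per manual OG

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.manual_sizes[:, None]

    def to_frame(self, which: str = "fractions") -> pd.DataFrame:
        data = self.fractions if which == "fractions" else self.counts
        return pd.DataFrame(data, index=self.manual_ids, columns=self.inferred_ids)


@dataclass
class SplitReport:
    method: str
    oversplit_pct: float
    undersplit_pct: float
    assignment_pct: float
    n_manual_sequences: int
    n_assigned: int
    notes: dict = field(default_factory=dict)


def overlap_fraction_matrix(
    manual: Orthology, inferred: Orthology
) -> OverlapMatrix:
    """Shared-protein counts between every manual and inferred OG.

    Fractions divide by the manual OG's total size, so a row sums to
    <1 when some manual proteins are unassigned by the method.
    """
    manual_ids = sorted(manual.groups)
    inferred_ids = sorted(inferred.groups)
    counts = np.zeros((len(manual_ids), len(inferred_ids)), dtype=int)
    gene_to_inferred: dict[GeneId, list[int]] = {}
    for j, og in enumerate(inferred_ids):
        for gene in inferred.groups[og]:
            gene_to_inferred.setdefault(gene, []).append(j)
    for i, og in enumerate(manual_ids):
        for gene in manual.groups[og]:
            for j in gene_to_inferred.get(gene, ()):
                counts[i, j] += 1
    if counts.sum() == 0:
        logger.warning(
            "no overlap between %s and %s", manual.method_name, inferred.method_name
        )
    sizes = np.array([len(manual.groups[og]) for og in manual_ids])
    return OverlapMatrix(manual_ids, inferred_ids, counts, sizes)


def splitting_report(
    matrix: OverlapMatrix, method: str = ""
) -> SplitReport:
    """Percent of sequences over-/undersplit, and assignment coverage.

    Per manual OG (row), sequences outside the single largest-overlap
    inferred OG are oversplit; per inferred OG (column), sequences
    outside its largest manual OG are undersplit — assuming the
    largest-overlap OG is the correct one. Percentages pool counts over
    all rows (columns). Assignment is the share of all manual
    sequences placed in any inferred OG.
    """
    counts = matrix.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    used_rows = row_sums > 0
    used_cols = col_sums > 0
    over_num = (row_sums[used_rows] - counts[used_rows].max(axis=1)).sum()
    over_den = row_sums[used_rows].sum()
    under_num = (col_sums[used_cols] - counts[:, used_cols].max(axis=0)).sum()
    under_den = col_sums[used_cols].sum()
    total_manual = int(matrix.manual_sizes.sum())
    # a manual sequence is assigned if it occurs in >= 1 inferred OG;
    # with disjoint inferred OGs this equals the summed overlap counts
    n_assigned = int(counts.sum())
    return SplitReport(
        method=method,
        oversplit_pct=100.0 * over_num / over_den if over_den else 0.0,
        undersplit_pct=100.0 * under_num / under_den if under_den else 0.0,
        assignment_pct=100.0 * n_assigned / total_manual if total_manual else 0.0,
        n_manual_sequences=total_manual,
        n_assigned=n_assigned,
        notes={
            "n_zero_rows": int((~used_rows).sum()),
            "n_zero_cols": int((~used_cols).sum()),
        },
    )


def perfect_overlap_groups(orthologies: list[Orthology]) -> list[frozenset]:
    """Gene sets appearing as an identical OG in every supplied orthology."""
    if len(orthologies) < 2:
        raise ValueError("need at least 2 orthologies")
    shared = set(map(frozenset, orthologies[0].groups.values()))
    for other in orthologies[1:]:
        shared &= set(map(frozenset, other.groups.values()))
    return sorted(shared, key=lambda s: (-len(s), sorted(map(repr, s))))


def heatmap_layout(matrix: OverlapMatrix) -> tuple[list[str], list[str]]:
    """Row/column ordering that puts the best matches on a diagonal.

    Manual OGs are sorted by their maximum overlap fraction,
    descending (ties by id); each contributes its argmax inferred OG to
    the diagonal, in order. Remaining inferred OGs are appended ordered
    by weighted-average-linkage (WPGMA) hierarchical clustering of
    their fraction columns, with deterministic leaf order.
    """
    frac = matrix.fractions
    row_order = sorted(
        range(len(matrix.manual_ids)),
        key=lambda i: (-frac[i].max(initial=0.0), matrix.manual_ids[i]),
    )
    diag_cols: list[int] = []
    taken = set()
    for i in row_order:
        if frac[i].max(initial=0.0) <= 0:
            continue
        j = int(frac[i].argmax())
        if j not in taken:
            taken.add(j)
            diag_cols.append(j)
    rest = [j for j in range(len(matrix.inferred_ids)) if j not in taken]
    if len(rest) > 2:
        sub = frac[:, rest].T
        link = _hier.linkage(sub, method="weighted")
        leaves = _hier.leaves_list(link)
        rest = [rest[i] for i in leaves]
    rows = [matrix.manual_ids[i] for i in row_order]
    cols = [matrix.inferred_ids[j] for j in diag_cols + rest]
    return rows, cols


def load_manual_og_registry(path=None) -> pd.DataFrame:
    """Load the curated reference-set registry and check its bookkeeping.

    The packaged registry (synthetic placeholder OG identifiers; real
    complex-level bookkeeping) lists one row per curated OG with its
    complex of origin: intraflagellar transport (26 OGs), kinetochore
    (91) and TBP-associated factors (8), 125 in total. The reader
    asserts that the per-complex counts sum to the recorded total.
    """
    if path is None:
        ref = importlib.resources.files("orthoeval.data").joinpath(
            "manual_og_registry.tsv"
        )
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"og_id", "complex"}
    if not required.issubset(df.columns):
        raise ValueError(f"registry needs columns {sorted(required)}")
    if df["og_id"].duplicated().any():
        raise ValueError("duplicate og_id in registry")
    counts = df.groupby("complex").size()
    if counts.sum() != len(df):
        raise AssertionError("per-complex counts do not sum to the total")
    return df
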