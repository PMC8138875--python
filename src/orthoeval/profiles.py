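"""Phylogenetic-profile matrix and profile distance measures.

Profiles are binary presence/absence vectors of LECA OGs across the
analyzed species. Thirteen distance or correlation measures quantify
profile (dis)similarity; correlation measures (Kendall tau, Spearman)
are mapped to distances by (1 - C) / 2, and unbounded distances
(cityblock, euclidean, yule) are normalized by the maximum value
observed in the analyzed pair set, so every reported distance lies in
[0, 1].

Formulas for the binary measures use the 2x2 contingency counts of two
profiles x, y over n species: ntt (1/1), ntf (1/0), nft (0/1), nff
(0/0). ``kulsinski`` is (ntf + nft - ntt + n) / (ntf + nft + n) and
``sokalmichener`` is 2(ntf + nft) / (n + ntf + nft), the classic
dissimilarity forms; the remaining set-based measures are delegated to
scipy.spatial.distance. Rank correlations on binary vectors use
midranks for ties and are undefined for constant profiles; such pairs
are dropped and counted rather than given an arbitrary value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.spatial import distance as _ssd

from .leca import LecaCall, PresenceProfile, profile_from_group
from .orthology_io import Orthology, ReferenceGeneIndex
from .taxonomy import SpeciesTaxonomy

__all__ = [
    "Conversion",
    "MEASURES",
    "CONVERSIONS",
    "DEFAULT_MEASURE",
    "ProfileMatrix",
    "PairDistances",
    "build_matrix",
    "pairwise_distances",
    "cross_method_profile_distance",
    "raw_distance",
]

logger = logging.getLogger(__name__)


class Conversion(str, Enum):
    NONE = "none"
    ONE_MINUS_C_OVER_2 = "one_minus_c_over_2"
    DIVIDE_BY_MAX = "divide_by_max"


def _contingency(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    ntt = int(np.sum((x == 1) & (y == 1)))
    ntf = int(np.sum((x == 1) & (y == 0)))
    nft = int(np.sum((x == 0) & (y == 1)))
    nff = int(np.sum((x == 0) & (y == 0)))
    return ntt, ntf, nft, nff


def _kulsinski(x: np.ndarray, y: np.ndarray) -> float:
    ntt, ntf, nft, _ = _contingency(x, y)
    n = x.size
    return (ntf + nft - ntt + n) / (ntf + nft + n)


def _sokalmichener(x: np.ndarray, y: np.ndarray) -> float:
    _, ntf, nft, _ = _contingency(x, y)
    r = 2.0 * (ntf + nft)
    return r / (x.size + ntf + nft)


def _yule(x: np.ndarray, y: np.ndarray) -> float:
    ntt, ntf, nft, nff = _contingency(x, y)
    half_denom = ntt * nff + ntf * nft
    if half_denom == 0:
        if ntf * nft == 0:
            return 0.0
        return math.nan
    return 2.0 * ntf * nft / half_denom


def _kendalltau(x: np.ndarray, y: np.ndarray) -> float:
    return float(_stats.kendalltau(x, y).statistic)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    return float(_stats.spearmanr(x, y).statistic)


# name -> raw measure on two binary vectors (distance, or correlation
# for kendalltau/spearman prior to conversion)
MEASURES = {
    "braycurtis": _ssd.braycurtis,
    "cityblock": _ssd.cityblock,
    "cosine": _ssd.cosine,
    "dice": _ssd.dice,
    "euclidean": _ssd.euclidean,
    "jaccard": _ssd.jaccard,
    "kendalltau": _kendalltau,
    "kulsinski": _kulsinski,
    "rogerstanimoto": _ssd.rogerstanimoto,
    "russellrao": _ssd.russellrao,
    "sokalmichener": _sokalmichener,
    "spearman": _spearman,
    "yule": _yule,
}

CONVERSIONS: dict[str, Conversion] = {
    "braycurtis": Conversion.NONE,
    "cityblock": Conversion.DIVIDE_BY_MAX,
    "cosine": Conversion.NONE,
    "dice": Conversion.NONE,
    "euclidean": Conversion.DIVIDE_BY_MAX,
    "jaccard": Conversion.NONE,
    "kendalltau": Conversion.ONE_MINUS_C_OVER_2,
    "kulsinski": Conversion.NONE,
    "rogerstanimoto": Conversion.NONE,
    "russellrao": Conversion.NONE,
    "sokalmichener": Conversion.NONE,
    "spearman": Conversion.ONE_MINUS_C_OVER_2,
    "yule": Conversion.DIVIDE_BY_MAX,
}

#: cosine gives the best AUC for co-occurrence prediction, hence default
DEFAULT_MEASURE = "cosine"

_RANK_MEASURES = {"kendalltau", "spearman"}


def raw_distance(name: str, x: np.ndarray, y: np.ndarray) -> float:
    """Unconverted measure value; NaN when undefined for the pair."""
    if name not in MEASURES:
        raise KeyError(f"unknown measure {name!r}; choose from {sorted(MEASURES)}")
    if name in _RANK_MEASURES and (len(set(x)) < 2 or len(set(y)) < 2):
        return math.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        return float(MEASURES[name](np.asarray(x, float), np.asarray(y, float)))


@dataclass
class ProfileMatrix:
    """Binary OG x species matrix (LECA OGs only, no all-zero rows)."""

    og_ids: list[str]
    species_ids: list[str]
    values: np.ndarray  # shape (n_ogs, n_species), dtype int8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.og_ids), len(self.species_ids)):
            raise ValueError("matrix shape does not match row/column ids")
        if len(set(self.og_ids)) != len(self.og_ids):
            raise ValueError("duplicate og_ids")
        if self.values.size and (self.values.sum(axis=1) == 0).any():
            raise ValueError("all-zero profile rows are not allowed")
        self._row_index = {og: i for i, og in enumerate(self.og_ids)}

    def row(self, og_id: str) -> np.ndarray:
        return self.values[self._row_index[og_id]]

    def __contains__(self, og_id: str) -> bool:
        return og_id in self._row_index

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.og_ids, columns=self.species_ids
        )

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("og_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())

    @classmethod
    def from_profiles(
        cls, profiles: Sequence[PresenceProfile], species_ids: list[str]
    ) -> "ProfileMatrix":
        values = np.array(
            [[p.presence[sp] for sp in species_ids] for p in profiles],
            dtype=np.int8,
        )
        return cls([p.og_id for p in profiles], species_ids, values)


@dataclass
class PairDistances:
    """Converted distances for a set of OG pairs under one measure."""

    measure: str
    conversion: Conversion
    pairs: list[tuple[str, str]]
    distances: np.ndarray
    max_raw: float | None = None
    n_dropped_undefined: int = 0
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "og_a": [a for a, _ in self.pairs],
                "og_b": [b for _, b in self.pairs],
                "distance": self.distances,
                "measure": self.measure,
            }
        )


def build_matrix(
    orthology: Orthology,
    taxonomy: SpeciesTaxonomy,
    leca_calls: Iterable[LecaCall],
) -> ProfileMatrix:
    """One profile row per LECA-positive OG of the orthology."""
    keep = sorted(c.og_id for c in leca_calls if c.is_leca)
    if not keep:
        raise ValueError(
            f"{orthology.method_name}: no LECA OGs, cannot build profile matrix"
        )
    species = taxonomy.species
    profiles = [
        profile_from_group(og, orthology.groups[og], taxonomy) for og in keep
    ]
    return ProfileMatrix.from_profiles(profiles, species)


def pairwise_distances(
    matrix: ProfileMatrix,
    pairs: Sequence[tuple[str, str]],
    measure: str = DEFAULT_MEASURE,
) -> PairDistances:
    """Converted distances for the supplied OG pairs.

    divide_by_max normalizes by the maximum raw value over this pair
    set (the evaluation pool), recorded in ``max_raw``. Pairs with an
    undefined measure value (constant profile under a rank correlation,
    degenerate yule) are dropped and counted.
    """
    conversion = CONVERSIONS[measure]
    kept: list[tuple[str, str]] = []
    raw: list[float] = []
    dropped = 0
    for og_a, og_b in pairs:
        val = raw_distance(measure, matrix.row(og_a), matrix.row(og_b))
        if math.isnan(val):
            dropped += 1
            continue
        kept.append((og_a, og_b))
        raw.append(val)
    if dropped:
        logger.warning(
            "%s: dropped %d pair(s) with undefined value", measure, dropped
        )
    arr = np.asarray(raw, dtype=float)
    max_raw: float | None = None
    if conversion is Conversion.ONE_MINUS_C_OVER_2:
        arr = (1.0 - arr) / 2.0
    elif conversion is Conversion.DIVIDE_BY_MAX:
        max_raw = float(arr.max()) if arr.size else None
        if max_raw and max_raw > 0:
            arr = arr / max_raw
    return PairDistances(
        measure=measure,
        conversion=conversion,
        pairs=kept,
        distances=arr,
        max_raw=max_raw,
        n_dropped_undefined=dropped,
    )


def cross_method_profile_distance(
    matrix_a: ProfileMatrix,
    matrix_b: ProfileMatrix,
    index_a: ReferenceGeneIndex,
    index_b: ReferenceGeneIndex,
    measure: str = DEFAULT_MEASURE,
) -> pd.DataFrame:
    """Distance between two methods' profiles for each shared reference gene.

    Only genes mapped to a LECA OG by both methods (OG present in both
    matrices) are compared; ideally the profiles agree and distances
    are 0.
    """
    if index_a.reference_species != index_b.reference_species:
        raise ValueError("reference indices use different reference species")
    shared = sorted(
        g
        for g in index_a.genes() & index_b.genes()
        if index_a.gene_to_og[g] in matrix_a and index_b.gene_to_og[g] in matrix_b
    )
    if not shared:
        raise ValueError("no reference genes shared between the two methods")
    rows = []
    for gene in shared:
        og_a = index_a.gene_to_og[gene]
        og_b = index_b.gene_to_og[gene]
        val = raw_distance(measure, matrix_a.row(og_a), matrix_b.row(og_b))
        if CONVERSIONS[measure] is Conversion.ONE_MINUS_C_OVER_2:
            val = (1.0 - val) / 2.0
        rows.append(
            {
                "gene": str(gene),
                "og_a": og_a,
                "og_b": og_b,
                "distance": val,
                "measure": measure,
            }
        )
    return pd.DataFrame(rows)
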