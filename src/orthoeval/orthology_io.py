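"""Reading orthology assignments into a common representation.

Two on-disk dialects are supported: the OrthoFinder-style wide table
(one row per orthologous group, one column per species holding
comma-separated protein ids) and a long two-column table
(og_id, gene_id). Gene identifiers embed the species with a separator,
"SPECIES|PROTEIN" by default, matching common proteome-concatenation
practice.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

__all__ = [
    "GeneId",
    "Orthology",
    "ReferenceGeneIndex",
    "OrthologyFormatError",
    "parse_gene_id",
    "read_orthogroups_wide",
    "read_orthogroups_long",
    "write_orthogroups_long",
    "build_reference_index",
    "orthology_stats",
]

logger = logging.getLogger(__name__)

DEFAULT_SEPARATOR = "|"


class OrthologyFormatError(ValueError):
    pass


class GeneId(NamedTuple):
    species_id: str
    protein_id: str

    def __str__(self) -> str:  # long-format serialization
        return f"{self.species_id}{DEFAULT_SEPARATOR}{self.protein_id}"


def parse_gene_id(text: str, separator: str = DEFAULT_SEPARATOR) -> GeneId:
    if separator not in text:
        raise OrthologyFormatError(
            f"gene id {text!r} lacks species separator {separator!r}"
        )
    species, protein = text.split(separator, 1)
    return GeneId(species, protein)


@dataclass
class Orthology:
    """A named method's og_id -> gene-set mapping.

    ``disjoint`` is True when no gene is shared between groups; readers
    detect violations (possible for profile-search based assignment) and
    flag rather than reject them.
    """

    method_name: str
    groups: dict[str, frozenset[GeneId]]
    disjoint: bool = True

    def __post_init__(self) -> None:
        for og, genes in self.groups.items():
            if not genes:
                raise OrthologyFormatError(f"empty group {og!r}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def all_genes(self) -> set[GeneId]:
        out: set[GeneId] = set()
        for genes in self.groups.values():
            out |= genes
        return out

    def genes_of_species(self, species_id: str) -> set[GeneId]:
        return {g for g in self.all_genes() if g.species_id == species_id}

    def subset(self, og_ids: Iterable[str], method_name: str | None = None) -> "Orthology":
        keep = set(og_ids)
        return Orthology(
            method_name=method_name or self.method_name,
            groups={og: g for og, g in self.groups.items() if og in keep},
            disjoint=self.disjoint,
        )


def _check_disjoint(groups: dict[str, frozenset[GeneId]], method: str) -> bool:
    seen: set[GeneId] = set()
    for genes in groups.values():
        if seen & genes:
            logger.warning(
                "%s: some genes appear in multiple groups; disjoint=False",
                method,
            )
            return False
        seen |= genes
    return True


def read_orthogroups_wide(
    path, method_name: str | None = None, separator: str = DEFAULT_SEPARATOR
) -> Orthology:
    """Read an OrthoFinder-style Orthogroups.tsv.

    First column: og_id; header row names the species; each cell holds
    comma-separated protein ids of that species. Empty rows are skipped
    with a warning.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    species_cols = list(df.columns[1:])
    if not species_cols:
        raise OrthologyFormatError("wide orthogroup table has no species columns")
    name = method_name or str(path)
    groups: dict[str, frozenset[GeneId]] = {}
    n_skipped = 0
    for row in df.itertuples(index=False):
        og_id = row[0]
        genes = set()
        for sp, cell in zip(species_cols, row[1:]):
            for protein in str(cell).split(","):
                protein = protein.strip()
                if protein:
                    genes.add(GeneId(sp, protein))
        if not genes:
            n_skipped += 1
            continue
        if og_id in groups:
            raise OrthologyFormatError(f"duplicate og_id {og_id!r}")
        groups[og_id] = frozenset(genes)
    if n_skipped:
        logger.warning("%s: skipped %d empty orthogroup rows", name, n_skipped)
    return Orthology(name, groups, disjoint=_check_disjoint(groups, name))


def read_orthogroups_long(
    path, method_name: str | None = None, separator: str = DEFAULT_SEPARATOR
) -> Orthology:
    """Read a two-column (og_id, gene_id) TSV; no header expected."""
    name = method_name or str(path)
    groups: dict[str, set[GeneId]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OrthologyFormatError(
                    f"line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            og_id, gene_text = parts
            try:
                gene = parse_gene_id(gene_text, separator)
            except OrthologyFormatError as exc:
                raise OrthologyFormatError(f"line {lineno}: {exc}") from None
            groups.setdefault(og_id, set()).add(gene)
    frozen = {og: frozenset(g) for og, g in groups.items()}
    return Orthology(name, frozen, disjoint=_check_disjoint(frozen, name))


def write_orthogroups_long(
    orthology: Orthology, path, separator: str = DEFAULT_SEPARATOR
) -> None:
    with open(path, "w") as fh:
        for og_id in sorted(orthology.groups):
            for gene in sorted(orthology.groups[og_id]):
                fh.write(
                    f"{og_id}\t{gene.species_id}{separator}{gene.protein_id}\n"
                )


@dataclass
class ReferenceGeneIndex:
    """reference-species gene -> single og_id.

    Genes hit by several groups (possible with HMM-profile annotation)
    resolve to the largest group, ties broken lexicographically by og_id;
    the rule is deterministic so profile comparisons are reproducible.
    """

    reference_species: str
    gene_to_og: dict[GeneId, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_to_og)

    def genes(self) -> set[GeneId]:
        return set(self.gene_to_og)


def build_reference_index(
    orthology: Orthology, reference_species: str
) -> ReferenceGeneIndex:
    candidates: dict[GeneId, list[str]] = {}
    for og_id, genes in orthology.groups.items():
        for gene in genes:
            if gene.species_id == reference_species:
                candidates.setdefault(gene, []).append(og_id)
    if not candidates:
        logger.warning(
            "%s: reference species %r absent from all groups",
            orthology.method_name,
            reference_species,
        )
    resolved = {
        gene: min(ogs, key=lambda og: (-len(orthology.groups[og]), og))
        for gene, ogs in candidates.items()
    }
    return ReferenceGeneIndex(reference_species, resolved)


def orthology_stats(orthology: Orthology) -> dict:
    """Bookkeeping summary: group counts, size moments, per-species totals."""
    sizes = [len(g) for g in orthology.groups.values()]
    per_species: dict[str, int] = {}
    for genes in orthology.groups.values():
        for gene in genes:
            per_species[gene.species_id] = per_species.get(gene.species_id, 0) + 1
    if not sizes:
        return {
            "method": orthology.method_name,
            "n_groups": 0,
            "n_genes": 0,
            "size_mean": 0.0,
            "size_median": 0.0,
            "size_sd": 0.0,
            "n_singletons": 0,
            "genes_per_species": {},
        }
    return {
        "method": orthology.method_name,
        "n_groups": len(sizes),
        "n_genes": sum(sizes),
        "size_mean": statistics.fmean(sizes),
        "size_median": float(statistics.median(sizes)),
        "size_sd": statistics.stdev(sizes) if len(sizes) > 1 else 0.0,
        "n_singletons": sum(1 for s in sizes if s == 1),
        "genes_per_species": dict(sorted(per_species.items())),
    }
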