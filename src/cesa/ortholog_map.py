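"""Gene-identifier resolution and ortholog expansion under a confidence-rank filter."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

from .formats_io import OrthologPair, PhosphoSiteRecord, ProteinRecord, RANK_ORDER

__all__ = [
    "GeneIndex",
    "ResolutionFailure",
    "resolve_gene",
    "orthologs_of",
    "select_isoforms",
]


@dataclass
class GeneIndex:
    """Alias→gene-id mapping plus gene-id→protein isoform lists.

    Alias keys are casefolded; an alias may map to several gene ids, which
    resolution treats as an ambiguity rather than guessing.
    """

    alias_to_gene: dict[str, set[str]] = field(default_factory=dict)
    gene_to_proteins: dict[str, list[ProteinRecord]] = field(default_factory=dict)

    def add_alias(self, alias: str, gene_id: str) -> None:
        self.alias_to_gene.setdefault(alias.casefold(), set()).add(gene_id)
        self.gene_to_proteins.setdefault(gene_id, [])

    def add_protein(self, protein: ProteinRecord) -> None:
        self.gene_to_proteins.setdefault(protein.gene_id, []).append(protein)
        if protein.accession:
            self.add_alias(protein.accession, protein.gene_id)
        if protein.gene_symbol:
            self.add_alias(protein.gene_symbol, protein.gene_id)

    @classmethod
    def build(
        cls,
        proteins: Iterable[ProteinRecord] = (),
        alias_maps: Iterable[dict[str, set[str]]] = (),
    ) -> "GeneIndex":
        index = cls()
        for p in proteins:
            if p.gene_id:
                index.add_protein(p)
        for amap in alias_maps:
            for alias, gene_ids in amap.items():
                for gid in gene_ids:
                    index.add_alias(alias, gid)
        return index


@dataclass(frozen=True)
class ResolutionFailure:
    reason: str  # unresolved_gene | ambiguous_alias
    record: PhosphoSiteRecord


def resolve_gene(
    record: PhosphoSiteRecord, index: GeneIndex
) -> Union[str, ResolutionFailure]:
    """Map a catalog record to a gene id: accession first, then symbol.

    Symbol matching is case-insensitive.  An alias mapping to two distinct gene
    ids is reported as ambiguous rather than guessed.
    """
    for alias in (record.protein_accession, record.gene_symbol):
        if not alias:
            continue
        gene_ids = index.alias_to_gene.get(alias.casefold())
        if not gene_ids:
            continue
        if len(gene_ids) > 1:
            return ResolutionFailure("ambiguous_alias", record)
        return next(iter(gene_ids))
    return ResolutionFailure("unresolved_gene", record)


def orthologs_of(
    gene_id: str, pairs: Iterable[OrthologPair], min_rank: str = "moderate"
) -> list[str]:
    """Target gene ids orthologous to ``gene_id`` at or above ``min_rank``, sorted."""
    threshold = RANK_ORDER[min_rank]
    hits = {
        p.target_gene_id
        for p in pairs
        if p.source_gene_id == gene_id and RANK_ORDER[p.rank] >= threshold
    }
    return sorted(hits)


def select_isoforms(
    gene_id: str, index: GeneIndex, mode: str = "all"
) -> list[ProteinRecord]:
    """Return a gene's protein isoforms.

    ``mode="all"`` returns every isoform; ``mode="longest"`` exactly one (maximum
    sequence length, ties broken by lexicographic accession).  An unknown gene or
    a gene with no proteins yields an empty list.
    """
    proteins = index.gene_to_proteins.get(gene_id, [])
    if not proteins:
        return []
    if mode == "all":
        return list(proteins)
    if mode == "longest":
        return [min(proteins, key=lambda p: (-len(p.sequence), p.accession))]
    raise ValueError(f"unknown isoform mode {mode!r}")
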