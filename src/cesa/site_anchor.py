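"""Validate catalog sites against current full-length protein sequences.

Catalog metadata drifts: protein accessions go stale and claimed coordinates can
shift between releases.  The immunogen peptide itself is the ground truth, so
anchoring scans for an exact occurrence of the (unpadded) ±7 flanking peptide and
records how each site was placed:

* ``direct`` — the peptide occurs on the claimed accession with the phospho-residue
  exactly at the claimed position;
* ``position_shifted`` — the peptide occurs at exactly one place on the claimed
  accession but the implied coordinate differs (the peptide wins);
* ``rescued_by_symbol`` — the accession failed, but proteins looked up by gene
  symbol contain the peptide.

Failures are data, not exceptions: ``accession_not_found``, ``peptide_not_found``,
``ambiguous_peptide``, ``peptide_too_short``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Union

from .formats_io import FormatError, PhosphoSiteRecord, ProteinRecord

__all__ = [
    "AnchoredSite",
    "AnchorFailure",
    "ProteomeIndex",
    "unpad_flank",
    "anchor_direct",
    "rescue_by_symbol",
    "anchor_all",
    "MIN_CORE_LENGTH",
]

#: exact-match scanning below 4-mers is effectively random
MIN_CORE_LENGTH = 4


@dataclass(frozen=True)
class AnchoredSite:
    """A catalog site validated against a current protein sequence."""

    record: PhosphoSiteRecord
    protein: ProteinRecord
    position: int  # 1-based on protein.sequence
    provenance: str  # direct | position_shifted | rescued_by_symbol
    core_peptide: str
    core_site_offset: int  # 0-based index of the phospho-residue in core_peptide

    def __post_init__(self) -> None:
        seq = self.protein.sequence
        start = self.position - 1 - self.core_site_offset
        if seq[start : start + len(self.core_peptide)] != self.core_peptide:
            raise ValueError("anchored core peptide does not match protein sequence")
        if seq[self.position - 1] != self.core_peptide[self.core_site_offset]:
            raise ValueError("anchored residue does not match peptide center")

    def reconstruct_flank(self) -> str:
        """Rebuild the 15-character ±7 flank, padding termini with ``_``."""
        seq = self.protein.sequence
        pos0 = self.position - 1
        left = seq[max(0, pos0 - 7) : pos0]
        right = seq[pos0 + 1 : pos0 + 8]
        return "_" * (7 - len(left)) + left + seq[pos0] + right + "_" * (7 - len(right))


@dataclass(frozen=True)
class AnchorFailure:
    reason: str
    record: PhosphoSiteRecord


AnchorOutcome = Union[AnchoredSite, AnchorFailure]


def unpad_flank(flank_peptide: str) -> tuple[str, int]:
    """Strip terminus ``_`` padding; return (core peptide, 0-based site offset).

    The site offset is 7 minus the number of leading pads, i.e. it keeps pointing
    at the former center of the 15-mer.
    """
    if len(flank_peptide) != 15:
        raise FormatError("flank peptide must be 15 characters")
    core = flank_peptide.strip("_")
    if "_" in core:
        raise FormatError(f"interior '_' in flank peptide {flank_peptide!r}")
    leading = len(flank_peptide) - len(flank_peptide.lstrip("_"))
    return core, 7 - leading


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All 0-based start indices of exact occurrences (overlaps included)."""
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def _build(
    record: PhosphoSiteRecord,
    protein: ProteinRecord,
    core: str,
    offset: int,
    start0: int,
    provenance: str,
) -> AnchoredSite:
    return AnchoredSite(
        record=record,
        protein=protein,
        position=start0 + offset + 1,
        provenance=provenance,
        core_peptide=core,
        core_site_offset=offset,
    )


def anchor_direct(record: PhosphoSiteRecord, protein: ProteinRecord) -> AnchorOutcome:
    """Anchor a site on the protein matching its claimed accession.

    The implied position (from the peptide occurrence) wins over the claimed one;
    multiple occurrences none of which matches the claim are ambiguous.
    """
    core, offset = unpad_flank(record.flank_peptide)
    if len(core) < MIN_CORE_LENGTH:
        return AnchorFailure("peptide_too_short", record)
    hits = _occurrences(protein.sequence, core)
    if not hits:
        return AnchorFailure("peptide_not_found", record)
    claimed_start = record.position - 1 - offset
    if claimed_start in hits:
        return _build(record, protein, core, offset, claimed_start, "direct")
    if len(hits) == 1:
        return _build(record, protein, core, offset, hits[0], "position_shifted")
    return AnchorFailure("ambiguous_peptide", record)


def rescue_by_symbol(
    record: PhosphoSiteRecord, candidates: list[ProteinRecord]
) -> AnchorOutcome:
    """Anchor via proteins looked up by gene symbol when the accession failed.

    Among candidates containing the core peptide exactly once, the longest wins
    (ties broken by lexicographic accession).  A candidate containing the peptide
    more than once is ambiguous and never used.
    """
    if not candidates:
        return AnchorFailure("accession_not_found", record)
    core, offset = unpad_flank(record.flank_peptide)
    if len(core) < MIN_CORE_LENGTH:
        return AnchorFailure("peptide_too_short", record)
    matching: list[tuple[ProteinRecord, int]] = []
    saw_ambiguous = False
    for cand in candidates:
        hits = _occurrences(cand.sequence, core)
        if len(hits) == 1:
            matching.append((cand, hits[0]))
        elif len(hits) > 1:
            saw_ambiguous = True
    if not matching:
        return AnchorFailure(
            "ambiguous_peptide" if saw_ambiguous else "peptide_not_found", record
        )
    best, start0 = min(matching, key=lambda m: (-len(m[0].sequence), m[0].accession))
    return _build(record, best, core, offset, start0, "rescued_by_symbol")


class ProteomeIndex:
    """Lookup of a proteome by accession and by (casefolded) gene symbol."""

    def __init__(self, proteins: Iterable[ProteinRecord]):
        self.by_accession: dict[str, ProteinRecord] = {}
        self.by_symbol: dict[str, list[ProteinRecord]] = {}
        for p in proteins:
            self.by_accession[p.accession] = p
            if p.gene_symbol:
                self.by_symbol.setdefault(p.gene_symbol.casefold(), []).append(p)

    def candidates_for_symbol(self, symbol: str) -> list[ProteinRecord]:
        return self.by_symbol.get(symbol.casefold(), [])


def anchor_all(
    records: Iterable[PhosphoSiteRecord], index: ProteomeIndex
) -> tuple[list[AnchoredSite], Counter]:
    """Anchor every record: direct first, then gene-symbol rescue.

    Every record lands in exactly one bucket; the returned tally counts the
    failure reasons of records that could not be anchored either way.
    """
    anchored: list[AnchoredSite] = []
    tally: Counter = Counter()
    for record in records:
        protein = index.by_accession.get(record.protein_accession)
        if protein is not None:
            outcome = anchor_direct(record, protein)
            if isinstance(outcome, AnchoredSite):
                anchored.append(outcome)
                continue
        rescue = rescue_by_symbol(record, index.candidates_for_symbol(record.gene_symbol))
        if isinstance(rescue, AnchoredSite):
            anchored.append(rescue)
        else:
            tally[rescue.reason] += 1
    return anchored, tally
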