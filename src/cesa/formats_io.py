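"""Readers and writers for every external table/sequence format the pipeline touches.

The phosphosite catalog follows the PhosphoSitePlus ``Phosphorylation_site_dataset``
dialect: tab-separated, a few preamble banner lines before the header, the modified
residue written like ``S473-p``, and a 15-character ±7-aa flanking peptide with the
phospho-residue lowercased at the center (index 8 of 15, 1-based) and ``_`` padding
where the window overruns a protein terminus.  All readers accept a file path
(gzip-compressed transparently, by ``.gz`` suffix) or an open text stream.
"""

from __future__ import annotations

import csv
import gzip
import io
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "PhosphoSiteRecord",
    "ProteinRecord",
    "OrthologPair",
    "RANK_ORDER",
    "read_phosphosite_catalog",
    "write_phosphosite_catalog",
    "read_fasta",
    "write_fasta",
    "read_ortholog_table",
    "read_gene_map",
    "read_protein_gene_table",
    "build_protein_records",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]


class FormatError(ValueError):
    """An input file violates the expected dialect."""


#: DIOPT-style confidence ranks, highest first.
RANK_ORDER = {"high": 2, "moderate": 1, "low": 0}

_PHOSPHO_RESIDUES = frozenset("STY")
_MOD_RSD_RE = re.compile(r"^([A-Za-z])(\d+)-(\w+)$")
_FLANK_RE = re.compile(r"^_*[A-Z]+_*$")
_SEQ_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXUBZ")


@dataclass(frozen=True)
class PhosphoSiteRecord:
    """One catalog row: a phospho-residue with its ±7-aa peptide and antibody ids.

    ``flank_peptide`` is stored uppercased; the modified residue sits at index 7
    (0-based) and ``_`` padding appears only as a contiguous prefix/suffix.
    ``center_mismatch`` flags rows whose claimed residue letter disagrees with the
    peptide center; such rows are kept so that anchoring can adjudicate.
    """

    gene_symbol: str
    protein_accession: str
    organism: str
    residue: str
    position: int
    flank_peptide: str
    antibody_ids: tuple[str, ...] = ()
    site_label: str = ""
    center_mismatch: bool = False

    def __post_init__(self) -> None:
        if len(self.flank_peptide) != 15:
            raise FormatError(
                f"flank peptide must be 15 characters, got {len(self.flank_peptide)!r}"
            )
        if not _FLANK_RE.match(self.flank_peptide):
            raise FormatError(
                f"flank peptide {self.flank_peptide!r} has interior '_' or bad characters"
            )
        if self.residue not in _PHOSPHO_RESIDUES:
            raise FormatError(f"residue must be S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class ProteinRecord:
    """A full-length protein isoform with its gene assignment."""

    accession: str
    gene_id: str
    gene_symbol: str
    organism: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.accession}: empty sequence")
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"protein {self.accession}: invalid residues {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class OrthologPair:
    """A source→target gene relationship with a DIOPT-style confidence rank."""

    source_gene_id: str
    target_gene_id: str
    rank: str

    def __post_init__(self) -> None:
        if self.rank not in RANK_ORDER:
            raise FormatError(f"unknown ortholog rank {self.rank!r}")


PathOrStream = Union[str, Path, IO[str]]


def _open_text(source: PathOrStream) -> tuple[IO[str], bool]:
    """Return (text handle, should_close). Paths ending in .gz are decompressed."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".gz":
            return gzip.open(path, "rt", encoding="utf-8"), True
        return open(path, "rt", encoding="utf-8"), True
    return source, False


# ---------------------------------------------------------------------------
# Phosphosite catalog
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = {
    "gene": ("GENE", "GENE_SYMBOL"),
    "accession": ("ACC_ID", "ACCESSION", "PROTEIN_ACCESSION"),
    "organism": ("ORGANISM", "ORG"),
    "mod_rsd": ("MOD_RSD", "MODIFIED_RESIDUE"),
    "peptide": ("SITE_+/-7_AA", "SITE_SEQ", "FLANK_PEPTIDE"),
    "antibody": ("CST_CAT#", "CST_CAT", "AB_CAT#", "ANTIBODY", "ANTIBODY_IDS"),
}


def _split_antibodies(cell: str) -> tuple[str, ...]:
    parts = re.split(r"[;,]", cell)
    return tuple(p.strip() for p in parts if p.strip())


def read_phosphosite_catalog(
    source: PathOrStream,
    organisms: Iterable[str],
    require_antibody: bool = True,
) -> tuple[list[PhosphoSiteRecord], Counter]:
    """Parse a PhosphoSitePlus-dialect catalog.

    Leading non-header lines (release banners) are skipped until a line naming the
    modified-residue column is found.  Only rows with a ``-p`` modification suffix
    on an S/T/Y residue and an organism in ``organisms`` are returned; rows failing
    the grammar are skipped and tallied.  Returns ``(records, skip_tally)``.
    """
    wanted = {o.lower() for o in organisms}
    handle, close = _open_text(source)
    tally: Counter = Counter()
    records: list[PhosphoSiteRecord] = []
    try:
        header: list[str] | None = None
        for line in handle:
            cells = line.rstrip("\n").split("\t")
            upper = [c.strip().upper() for c in cells]
            if any(name in upper for name in _CATALOG_COLUMNS["mod_rsd"]):
                header = upper
                break
        if header is None:
            # an entirely empty stream is an empty catalog, not an error
            if tally or records:  # pragma: no cover - defensive
                raise FormatError("no header line found")
            return [], tally

        idx: dict[str, int] = {}
        for key, names in _CATALOG_COLUMNS.items():
            for name in names:
                if name in header:
                    idx[key] = header.index(name)
                    break
            else:
                raise FormatError(f"missing required column: {names[0]}")

        for line in handle:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) <= max(idx.values()):
                tally["malformed_row"] += 1
                continue
            mod = cells[idx["mod_rsd"]].strip()
            m = _MOD_RSD_RE.match(mod)
            if m is None:
                tally["bad_mod_rsd"] += 1
                continue
            res, pos, suffix = m.group(1).upper(), int(m.group(2)), m.group(3)
            if suffix != "p":
                tally["not_phospho"] += 1
                continue
            if res not in _PHOSPHO_RESIDUES:
                tally["bad_residue"] += 1
                continue
            organism = cells[idx["organism"]].strip()
            if organism.lower() not in wanted:
                tally["organism_filtered"] += 1
                continue
            antibodies = _split_antibodies(cells[idx["antibody"]])
            if require_antibody and not antibodies:
                tally["no_antibody"] += 1
                continue
            flank = cells[idx["peptide"]].strip().upper()
            if len(flank) != 15 or not _FLANK_RE.match(flank) or flank[7] == "_":
                tally["bad_flank"] += 1
                continue
            records.append(
                PhosphoSiteRecord(
                    gene_symbol=cells[idx["gene"]].strip(),
                    protein_accession=cells[idx["accession"]].strip(),
                    organism=organism,
                    residue=res,
                    position=pos,
                    flank_peptide=flank,
                    antibody_ids=antibodies,
                    site_label=mod,
                    center_mismatch=(flank[7] != res),
                )
            )
    finally:
        if close:
            handle.close()
    return records, tally


def write_phosphosite_catalog(records: Iterable[PhosphoSiteRecord], stream: IO[str]) -> None:
    """Write records back in catalog dialect (center residue lowercased)."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["GENE", "ACC_ID", "ORGANISM", "MOD_RSD", "SITE_+/-7_AA", "CST_CAT#"])
    for r in records:
        flank = r.flank_peptide[:7] + r.flank_peptide[7].lower() + r.flank_peptide[8:]
        writer.writerow(
            [r.gene_symbol, r.protein_accession, r.organism, r.site_label, flank,
             ";".join(r.antibody_ids)]
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: PathOrStream) -> list[tuple[str, str]]:
    """Read protein FASTA; accession is the first whitespace token of the header.

    Sequences are uppercased with trailing ``*`` stop characters stripped.  ``-``
    or ``_`` inside a sequence is a format error (gaps are not residues).
    """
    handle, close = _open_text(source)
    try:
        out = []
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper().rstrip("*")
            if "-" in seq or "_" in seq:
                raise FormatError(f"record {rec.id}: gap characters are not valid residues")
            out.append((rec.id, seq))
        return out
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[tuple[str, str]], stream: IO[str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=acc, description="") for acc, seq in records),
        stream,
        "fasta",
    )


# ---------------------------------------------------------------------------
# Ortholog and gene-id mapping tables
# ---------------------------------------------------------------------------

def read_ortholog_table(source: PathOrStream, min_rank: str = "moderate") -> list[OrthologPair]:
    """Read a DIOPT-style ortholog pair table, dropping rows below ``min_rank``."""
    if min_rank not in RANK_ORDER:
        raise FormatError(f"unknown rank {min_rank!r}")
    handle, close = _open_text(source)
    try:
        pairs: list[OrthologPair] = []
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            cells = [c.strip() for c in line.rstrip("\n").split("\t")]
            if len(cells) < 3:
                raise FormatError(f"ortholog table line {lineno}: expected 3 columns")
            if lineno == 1 and cells[2].lower() not in RANK_ORDER:
                continue  # header row
            rank = cells[2].lower()
            if rank not in RANK_ORDER:
                raise FormatError(
                    f"ortholog table line {lineno}: unknown rank {cells[2]!r}"
                )
            if RANK_ORDER[rank] >= RANK_ORDER[min_rank]:
                pairs.append(OrthologPair(cells[0], cells[1], rank))
        return pairs
    finally:
        if close:
            handle.close()


def read_gene_map(source: PathOrStream) -> dict[str, set[str]]:
    """Read a two-column (alias, gene id) table into alias→{gene ids}.

    Aliases are matched case-insensitively downstream, so keys are casefolded.
    """
    handle, close = _open_text(source)
    try:
        mapping: dict[str, set[str]] = {}
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            cells = [c.strip() for c in line.rstrip("\n").split("\t")]
            if len(cells) < 2:
                raise FormatError(f"gene map line {lineno}: expected 2 columns")
            if lineno == 1 and cells[0].lower() in ("alias", "symbol", "accession"):
                continue
            mapping.setdefault(cells[0].casefold(), set()).add(cells[1])
        return mapping
    finally:
        if close:
            handle.close()


def read_protein_gene_table(source: PathOrStream) -> dict[str, tuple[str, str, str]]:
    """Read a protein→gene table: accession → (gene_id, gene_symbol, organism)."""
    handle, close = _open_text(source)
    try:
        mapping: dict[str, tuple[str, str, str]] = {}
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            cells = [c.strip() for c in line.rstrip("\n").split("\t")]
            if len(cells) < 4:
                raise FormatError(
                    f"protein-gene table line {lineno}: expected 4 columns"
                )
            if lineno == 1 and cells[0].lower() in ("accession", "acc_id"):
                continue
            mapping[cells[0]] = (cells[1], cells[2], cells[3])
        return mapping
    finally:
        if close:
            handle.close()


def build_protein_records(
    fasta: list[tuple[str, str]],
    protein_gene: dict[str, tuple[str, str, str]],
    default_organism: str = "",
) -> list[ProteinRecord]:
    """Join FASTA sequences with the protein→gene table into ProteinRecords.

    Proteins missing from the table keep empty gene fields rather than failing:
    downstream gene resolution simply cannot use them.
    """
    out = []
    for acc, seq in fasta:
        gene_id, symbol, organism = protein_gene.get(acc, ("", "", default_organism))
        out.append(ProteinRecord(acc, gene_id, symbol, organism or default_organism, seq))
    return out


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "source_organism",
    "source_gene",
    "source_accession",
    "site_label",
    "target_gene",
    "target_accession",
    "identity_run",
    "best_strict",
    "best_relaxed",
    "qualifies_at_6",
    "qualifies_at_7",
    "qualifies_at_8",
    "qualifies_at_9",
    "qualifies_at_10",
    "qualifies_at_11",
    "provenance",
]


def write_report(results, stream: IO[str]) -> None:
    """Write per (site × target isoform) conservation results as TSV."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(REPORT_COLUMNS)
    for r in results:
        rec = r.anchored.record
        writer.writerow(
            [
                rec.organism,
                rec.gene_symbol,
                rec.protein_accession,
                rec.site_label,
                r.target.gene_symbol or r.target.gene_id,
                r.target.accession,
                r.identity_run,
                r.best_strict,
                r.best_relaxed,
            ]
            + [str(bool(r.qualifies_at.get(L, False))) for L in range(6, 12)]
            + [r.anchored.provenance]
        )


def read_report(source: PathOrStream) -> list[dict[str, str]]:
    """Re-parse a written report into a list of row dicts (round-trip helper)."""
    handle, close = _open_text(source)
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        return list(reader)
    finally:
        if close:
            handle.close()
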