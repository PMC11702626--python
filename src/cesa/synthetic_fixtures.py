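"""Self-contained toy inputs with planted conservation outcomes.

The generator emits a complete input bundle — phosphosite catalog, source and
target proteomes (FASTA plus protein→gene tables), ortholog pairs and alias
tables — in which every phosphosite has a *designed* ±7 neighborhood embedded in
random flanking context.  Each plant fixes the contiguous identical run length
around the site (the "level", 0–11) and optionally adds exactly one conservative
substitution, either legally (distance ≥ 2 from the site, extending the relaxed
window by one) or adjacent to the site (which must not help).  The expected
strict/relaxed outcomes are recorded with each plant, so an end-to-end pipeline
run can be checked for exact parameter recovery.

Also ships the golden fixture of twelve validated human↔fly epitope pairs with
their known conserved-region lengths.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .conservation import DEFAULT_GROUPS

__all__ = [
    "PlantedOutcome",
    "FixtureSpec",
    "PlantedSite",
    "FixtureBundle",
    "SpecificationError",
    "generate",
    "validated_pairs",
]

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: residues with at least one conservative partner under the default groups
_GROUPED = sorted({aa for g in DEFAULT_GROUPS.groups for aa in g})


class SpecificationError(ValueError):
    """A planted outcome that cannot be realized in a 15-mer neighborhood."""


@dataclass(frozen=True)
class PlantedOutcome:
    """One designed conservation outcome.

    ``level`` is the contiguous identical run length to plant around the site
    (0 means the site residue itself differs); qualifying window lengths are
    6–11, so levels below 6 yield no qualifying window.
    """

    level: int
    use_conservative_sub: bool = False
    break_adjacency: bool = False


@dataclass(frozen=True)
class FixtureSpec:
    n_genes: int
    sites_per_gene: int
    planted_outcomes: tuple[PlantedOutcome, ...]
    seed: int
    flank_context_length: int = 30


@dataclass(frozen=True)
class PlantedSite:
    """Provenance of one plant: where it lives and what the pipeline must find."""

    gene_symbol: str
    accession: str
    site_label: str
    position: int
    outcome: PlantedOutcome
    expected_identity_run: int
    expected_best_strict: int
    expected_best_relaxed: int


@dataclass
class FixtureBundle:
    """All pipeline inputs as in-memory text, plus the planted expectations."""

    catalog_text: str
    source_fasta_text: str
    target_fasta_text: str
    source_protein_gene_text: str
    target_protein_gene_text: str
    ortholog_text: str
    alias_text: str
    expected: list[PlantedSite] = field(default_factory=list)

    _FILES = {
        "catalog_text": "catalog.tsv",
        "source_fasta_text": "source.fasta",
        "target_fasta_text": "target.fasta",
        "source_protein_gene_text": "source_protein2gene.tsv",
        "target_protein_gene_text": "target_protein2gene.tsv",
        "ortholog_text": "orthologs.tsv",
        "alias_text": "aliases.tsv",
    }

    def write(self, directory: Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for attr, name in self._FILES.items():
            path = directory / name
            path.write_text(getattr(self, attr), encoding="utf-8")
            paths[attr.replace("_text", "")] = path
        return paths


def _expected(outcome: PlantedOutcome) -> tuple[int, int, int]:
    """(identity_run, best_strict, best_relaxed) implied by a plant."""
    r = outcome.level
    strict = min(r, 11) if r >= 6 else 0
    if outcome.use_conservative_sub and not outcome.break_adjacency:
        relaxed = min(r + 1, 11) if r + 1 >= 6 else 0
    else:
        relaxed = strict
    return r, strict, relaxed


def _check_feasible(outcome: PlantedOutcome) -> None:
    if not 0 <= outcome.level <= 11:
        raise SpecificationError(f"planted level must be 0..11, got {outcome.level}")
    if outcome.break_adjacency and not outcome.use_conservative_sub:
        raise SpecificationError("break_adjacency requires use_conservative_sub")
    if outcome.break_adjacency and outcome.level > 7:
        raise SpecificationError(
            "an adjacent substitution requires the run to end at the site; "
            f"level {outcome.level} > 7 cannot fit in the 15-mer neighborhood"
        )
    if outcome.use_conservative_sub and outcome.level == 0:
        raise SpecificationError(
            "a site mismatch (level 0) already voids every window; "
            "a conservative substitution cannot be the only replacement"
        )


def _noncons_substitute(rng: random.Random, aa: str) -> str:
    while True:
        cand = rng.choice(_ALPHABET)
        if cand != aa and not DEFAULT_GROUPS.conservative(aa, cand):
            return cand


def _cons_substitute(rng: random.Random, aa: str) -> str:
    group = next(g for g in DEFAULT_GROUPS.groups if aa in g)
    return rng.choice(sorted(group - {aa}))


def _plant_neighborhood(
    rng: random.Random, outcome: PlantedOutcome
) -> tuple[str, str]:
    """Build (source 15-mer, target 15-mer) realizing the outcome at index 7."""
    base = [rng.choice(_GROUPED) for _ in range(15)]
    base[7] = rng.choice("STY")
    target = list(base)
    r = outcome.level

    if r == 0:
        # site mismatch: any non-conservative, non-identical residue
        target[7] = _noncons_substitute(rng, base[7])
        return "".join(base), "".join(target)

    if outcome.break_adjacency:
        # run of length r ending exactly at the site; conservative sub at site+1
        s = 8 - r
        target[8] = _cons_substitute(rng, base[8])
        if s - 1 >= 0:
            target[s - 1] = _noncons_substitute(rng, base[s - 1])
        return "".join(base), "".join(target)

    # centered run of length r: positions s .. s+r-1, boundaries inside the 15-mer
    s = 7 - r // 2
    s = max(1, min(s, 7))
    if outcome.use_conservative_sub:
        # conservative sub right after the run (distance s+r-7 >= 2 from site),
        # then a non-conservative break one further out
        if s + r - 7 < 2:
            s = 9 - r  # shift the run left so the sub is not adjacent to the site
        cons_pos = s + r
        brk = cons_pos + 1
        if s < 1 or brk > 14 or s > 7 or s + r - 1 < 7:
            raise SpecificationError(
                f"cannot fit run {r} plus a detached conservative substitution"
            )
        target[cons_pos] = _cons_substitute(rng, base[cons_pos])
        target[brk] = _noncons_substitute(rng, base[brk])
        target[s - 1] = _noncons_substitute(rng, base[s - 1])
    else:
        target[s - 1] = _noncons_substitute(rng, base[s - 1])
        if s + r <= 14:
            target[s + r] = _noncons_substitute(rng, base[s + r])
    return "".join(base), "".join(target)


def _random_context(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_ALPHABET) for _ in range(n))


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Deterministically generate a full input bundle from a fixture spec.

    Each gene carries ``sites_per_gene`` planted neighborhoods separated by
    random context; source and target proteins share the context, so the global
    alignment is gapless and every plant's window outcome is exactly recovered.
    Context is re-drawn if a planted peptide accidentally recurs elsewhere.
    """
    for outcome in spec.planted_outcomes:
        _check_feasible(outcome)
    if not spec.planted_outcomes:
        raise SpecificationError("at least one planted outcome is required")

    rng = random.Random(spec.seed)
    catalog = io.StringIO()
    catalog.write("Release banner line\nSynthetic fixture bundle\n\n")
    catalog.write("GENE\tACC_ID\tORGANISM\tMOD_RSD\tSITE_+/-7_AA\tCST_CAT#\n")
    src_fasta, tgt_fasta = io.StringIO(), io.StringIO()
    src_p2g = io.StringIO("accession\tgene_id\tgene_symbol\torganism\n")
    tgt_p2g = io.StringIO("accession\tgene_id\tgene_symbol\torganism\n")
    ortho = io.StringIO("source_gene_id\ttarget_gene_id\trank\n")
    alias = io.StringIO("alias\tgene_id\n")
    for s in (src_p2g, tgt_p2g, ortho, alias):
        s.seek(0, io.SEEK_END)
    expected: list[PlantedSite] = []

    site_counter = 0
    for g in range(spec.n_genes):
        symbol = f"GENE{g:03d}"
        src_gene_id, tgt_gene_id = f"S{g:04d}", f"T{g:04d}"
        src_acc, tgt_acc = f"SP{g:03d}.1", f"TP{g:03d}.1"

        for attempt in range(100):
            outcomes, neighborhoods, positions = [], [], []
            src_parts, tgt_parts = [], []
            offset = 0
            for _ in range(spec.sites_per_gene):
                outcome = spec.planted_outcomes[
                    (site_counter + len(outcomes)) % len(spec.planted_outcomes)
                ]
                ctx = _random_context(rng, spec.flank_context_length)
                src_n, tgt_n = _plant_neighborhood(rng, outcome)
                src_parts += [ctx, src_n]
                tgt_parts += [ctx, tgt_n]
                positions.append(offset + spec.flank_context_length + 8)
                offset += spec.flank_context_length + 15
                outcomes.append(outcome)
                neighborhoods.append(src_n)
            tail = _random_context(rng, spec.flank_context_length)
            src_seq = "".join(src_parts) + tail
            tgt_seq = "".join(tgt_parts) + tail
            if all(src_seq.count(n) == 1 for n in neighborhoods):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not avoid peptide collisions")

        src_fasta.write(f">{src_acc} synthetic source gene {symbol}\n{src_seq}\n")
        tgt_fasta.write(f">{tgt_acc} synthetic target ortholog of {symbol}\n{tgt_seq}\n")
        src_p2g.write(f"{src_acc}\t{src_gene_id}\t{symbol}\thuman\n")
        tgt_p2g.write(f"{tgt_acc}\t{tgt_gene_id}\t{symbol.lower()}\tfly\n")
        rank = "high" if g % 3 else "moderate"
        ortho.write(f"{src_gene_id}\t{tgt_gene_id}\t{rank}\n")
        alias.write(f"{symbol}\t{src_gene_id}\n{src_acc}\t{src_gene_id}\n")

        for outcome, neighborhood, pos in zip(outcomes, neighborhoods, positions):
            residue = neighborhood[7]
            label = f"{residue}{pos}-p"
            flank = neighborhood[:7] + neighborhood[7].lower() + neighborhood[8:]
            catalog.write(
                f"{symbol}\t{src_acc}\thuman\t{label}\t{flank}\t#{1000 + site_counter}\n"
            )
            run, strict, relaxed = _expected(outcome)
            expected.append(
                PlantedSite(
                    gene_symbol=symbol,
                    accession=src_acc,
                    site_label=label,
                    position=pos,
                    outcome=outcome,
                    expected_identity_run=run,
                    expected_best_strict=strict,
                    expected_best_relaxed=relaxed,
                )
            )
            site_counter += 1

    return FixtureBundle(
        catalog_text=catalog.getvalue(),
        source_fasta_text=src_fasta.getvalue(),
        target_fasta_text=tgt_fasta.getvalue(),
        source_protein_gene_text=src_p2g.getvalue(),
        target_protein_gene_text=tgt_p2g.getvalue(),
        ortholog_text=ortho.getvalue(),
        alias_text=alias.getvalue(),
        expected=expected,
    )


#: twelve validated human↔fly phospho-epitope pairs: (human gene, fly gene,
#: human ±7 15-mer, fly ±7 15-mer, conserved-region length). Typesetting
#: whitespace inside the fly sequences has been stripped.
_VALIDATED_PAIRS: tuple[tuple[str, str, str, str, int], ...] = (
    ("AKT1", "Akt1", "RPHFPQFSYSASGTA", "EPLFPQFSYQGDMAS", 6),
    ("PRKAA1", "AMPKalpha", "SDGEFLRTSCGSPNY", "LDGEFLRTSCGSPNY", 14),
    ("MAPK10", "bsk", "AGTSFMMTPYVVTRY", "AGTTFMMTPYVVTRY", 11),
    ("MAPK10", "bsk", "TSFMMTPYVVTRYYR", "TTFMMTPYVVTRYYR", 13),
    ("EIF2S1", "eIF2alpha", "MILLSELSRRRIRSI", "MILLSELSRRRIRSI", 15),
    ("MAPK12", "p38a", "RQADSEMTGYVVTRW", "RPTENEMTGYVATRW", 6),
    ("MAPK12", "p38a", "ADSEMTGYVVTRWYR", "TENEMTGYVATRWYR", 6),
    ("MAPK1", "rl", "HDHTGFLTEYVATRW", "HDHTGFLTEYVATRW", 15),
    ("MAPK1", "rl", "HTGFLTEYVATRWYR", "HTGFLTEYVATRWYR", 15),
    ("RPS6KB1", "S6k", "NQVFLGFTYVAPSVL", "NLIFQGFTYVAPSIL", 8),
    ("EIF4EBP1", "Thor", "PPGDYSTTPGGTLFS", "MPEVYSSTPGGTLYS", 6),
    ("EIF4EBP1", "Thor", "GGTLFSTTPGGTRII", "GGTLYSTTPGGTKLI", 7),
)


def validated_pairs(
    with_genes: bool = False,
) -> list[tuple]:
    """The golden set of 12 validated cross-reactive epitope pairs.

    Returns ``(source 15-mer, target 15-mer, conserved-region length)`` tuples,
    or 5-tuples prefixed with (human gene, fly gene) when ``with_genes``.
    """
    if with_genes:
        return [tuple(row) for row in _VALIDATED_PAIRS]
    return [(h, f, n) for (_, _, h, f, n) in _VALIDATED_PAIRS]
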