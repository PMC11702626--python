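"""Window conservation scoring around anchored phosphosites.

This is the decision rule of the whole pipeline.  For a phosphosite anchored on a
source protein and globally aligned to a target isoform, we ask whether *any*
contiguous window of 6–11 residues spanning the site is conserved:

* **strict** — every aligned position in the window identical;
* **relaxed** — at most one position may instead be a *conservative* substitution
  (same physicochemical group), and that position must not be the phosphosite
  itself nor either immediate neighbor (distance ≥ 2 from the site).

Windows are enumerated in source coordinates and must be gap-free in both aligned
rows: an epitope is a contiguous peptide, so a window touching any gap column is
disqualified rather than re-spliced.  Alongside the window rule we report the
longest contiguous run of identical aligned residues containing the site within
its ±7 neighborhood — the per-antibody statistic typically tabulated for
validated cross-reactive epitopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

from .alignment import GAP, AlignmentResult
from .formats_io import ProteinRecord
from .site_anchor import AnchoredSite

__all__ = [
    "SimilarityGroups",
    "DEFAULT_GROUPS",
    "blosum62_positive_groups",
    "similarity_scheme",
    "ConservationResult",
    "identity_run",
    "window_qualifies",
    "evaluate_site",
    "summarize",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS = tuple(range(6, 12))


class SimilarityGroups:
    """Disjoint residue groups defining the conservative-substitution predicate.

    ``conservative(a, b)`` is true iff ``a != b`` and both residues share a group;
    it is symmetric and never true for identical residues.  A BLOSUM62-positive
    predicate can be supplied instead via an explicit pair set.
    """

    def __init__(
        self,
        groups: Sequence[frozenset[str]] = (),
        pairs: Optional[frozenset[frozenset[str]]] = None,
    ):
        seen: set[str] = set()
        for g in groups:
            if seen & g:
                raise ValueError("similarity groups must be disjoint")
            seen |= g
        self.groups = tuple(frozenset(g) for g in groups)
        self._pairs = pairs
        self._member_group: dict[str, frozenset[str]] = {
            aa: g for g in self.groups for aa in g
        }

    def conservative(self, a: str, b: str) -> bool:
        if a == b:
            return False
        if self._pairs is not None:
            return frozenset((a, b)) in self._pairs
        g = self._member_group.get(a)
        return g is not None and b in g


#: classic physicochemical classes (C and P stand alone: no conservative partner)
DEFAULT_GROUPS = SimilarityGroups(
    [
        frozenset("ILVM"),
        frozenset("FWY"),
        frozenset("KRH"),
        frozenset("DE"),
        frozenset("ST"),
        frozenset("NQ"),
        frozenset("AG"),
    ]
)


def blosum62_positive_groups() -> SimilarityGroups:
    """Alternative predicate: a substitution is conservative iff BLOSUM62 > 0."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    aas = [a for a in m.alphabet if a not in "BZX*"]
    pairs = frozenset(
        frozenset((a, b)) for a in aas for b in aas if a != b and m[a, b] > 0
    )
    return SimilarityGroups(pairs=pairs)


def similarity_scheme(name: str) -> SimilarityGroups:
    if name == "physicochemical":
        return DEFAULT_GROUPS
    if name == "blosum62_positive":
        return blosum62_positive_groups()
    raise ValueError(f"unknown similarity scheme {name!r}")


@dataclass(frozen=True)
class ConservationResult:
    """Conservation outcome for one (anchored site × target isoform)."""

    anchored: AnchoredSite
    target: ProteinRecord
    identity_run: int
    best_strict: int
    best_relaxed: int
    qualifies_at: Dict[int, bool]


def identity_run(source_window: str, target_window: str, site_index: int) -> int:
    """Longest contiguous run of identical positions containing ``site_index``.

    Both windows must be gap-free and of equal length.  Returns 0 iff the site
    position itself differs.
    """
    if len(source_window) != len(target_window):
        raise ValueError("windows must have equal length")
    if not 0 <= site_index < len(source_window):
        raise ValueError(f"site index {site_index} out of range")
    if source_window[site_index] != target_window[site_index]:
        return 0
    lo = site_index
    while lo > 0 and source_window[lo - 1] == target_window[lo - 1]:
        lo -= 1
    hi = site_index
    while hi + 1 < len(source_window) and source_window[hi + 1] == target_window[hi + 1]:
        hi += 1
    return hi - lo + 1


def window_qualifies(
    source_window: str,
    target_window: str,
    site_index: int,
    groups: SimilarityGroups = DEFAULT_GROUPS,
    allow_conservative: bool = True,
) -> bool:
    """Does this gap-free window pass the conservation rule?

    Strict mode requires identity everywhere.  With ``allow_conservative``, at
    most one position may instead be a conservative substitution, and only at
    distance ≥ 2 from the site (never the phospho-residue or its neighbors).
    """
    if len(source_window) != len(target_window):
        raise ValueError("windows must have equal length")
    if not 0 <= site_index < len(source_window):
        raise ValueError(f"site index {site_index} out of range")
    mismatches = [
        i for i, (a, b) in enumerate(zip(source_window, target_window)) if a != b
    ]
    if not mismatches:
        return True
    if not allow_conservative or len(mismatches) > 1:
        return False
    i = mismatches[0]
    return (
        abs(i - site_index) >= 2
        and groups.conservative(source_window[i], target_window[i])
    )


def _neighborhood_run(aln: AlignmentResult, site_col: int, lo_col: int, hi_col: int) -> int:
    """Identity run around the site column, truncated at the first gap column."""
    src, tgt = aln.aligned_source, aln.aligned_target
    if src[site_col] == GAP or tgt[site_col] == GAP or src[site_col] != tgt[site_col]:
        return 0
    run = 1
    c = site_col - 1
    while c >= lo_col and src[c] != GAP and tgt[c] != GAP and src[c] == tgt[c]:
        run += 1
        c -= 1
    c = site_col + 1
    while c <= hi_col and src[c] != GAP and tgt[c] != GAP and src[c] == tgt[c]:
        run += 1
        c += 1
    return run


def evaluate_site(
    aln: AlignmentResult,
    anchored: AnchoredSite,
    target: ProteinRecord,
    cutoffs: Iterable[int] = DEFAULT_CUTOFFS,
    groups: SimilarityGroups = DEFAULT_GROUPS,
    allow_conservative: bool = True,
) -> ConservationResult:
    """Evaluate every 6–11-aa source window spanning the site against the target.

    For each cutoff L, every contiguous source window of length L containing the
    site (clipped to the sequence bounds) is extracted through the alignment;
    windows touching any gap column are discarded; the rest are tested strictly
    and with the one-conservative-substitution relaxation.  ``qualifies_at[L]``
    reflects the active regime (relaxed when ``allow_conservative``).  The
    identity run is computed over the aligned ±7 neighborhood of the site,
    truncated at gap columns.
    """
    cutoffs = sorted(set(cutoffs))
    source_len = len(aln.source_sequence)
    pos = anchored.position
    if not 1 <= pos <= source_len:
        raise ValueError("anchored site lies outside the aligned source sequence")

    cols = aln.source_column_map()
    site_col = cols[pos - 1]
    lo_col = cols[max(1, pos - 7) - 1]
    hi_col = cols[min(source_len, pos + 7) - 1]
    run = _neighborhood_run(aln, site_col, lo_col, hi_col)

    best_strict = 0
    best_relaxed = 0
    if aln.aligned_target[site_col] != GAP:
        for L in cutoffs:
            for start in range(max(1, pos - L + 1), min(pos, source_len - L + 1) + 1):
                lo = cols[start - 1]
                hi = cols[start + L - 2]
                src = aln.aligned_source[lo : hi + 1]
                tgt = aln.aligned_target[lo : hi + 1]
                if GAP in src or GAP in tgt:
                    continue
                site_index = pos - start
                if window_qualifies(src, tgt, site_index, groups, False):
                    best_strict = max(best_strict, L)
                    best_relaxed = max(best_relaxed, L)
                elif window_qualifies(src, tgt, site_index, groups, True):
                    best_relaxed = max(best_relaxed, L)

    best_active = best_relaxed if allow_conservative else best_strict
    qualifies_at = {L: best_active >= L for L in cutoffs}
    return ConservationResult(
        anchored=anchored,
        target=target,
        identity_run=run,
        best_strict=best_strict,
        best_relaxed=best_relaxed,
        qualifies_at=qualifies_at,
    )


def summarize(
    results: Iterable[ConservationResult], cutoff: int
) -> tuple[int, int, int]:
    """Counts at a cutoff: (qualifying sites, source genes, target genes).

    Sites are identified by (organism, gene symbol, site label); isoforms collapse
    to genes, so a site qualifying on several target isoforms of one gene counts
    that gene once.
    """
    sites: set[tuple[str, str, str]] = set()
    source_genes: set[tuple[str, str]] = set()
    target_genes: set[str] = set()
    for r in results:
        if not r.qualifies_at.get(cutoff, False):
            continue
        rec = r.anchored.record
        sites.add((rec.organism, rec.gene_symbol, rec.site_label))
        source_genes.add((rec.organism, rec.gene_symbol))
        target_genes.add(r.target.gene_id or r.target.gene_symbol or r.target.accession)
    return len(sites), len(source_genes), len(target_genes)
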