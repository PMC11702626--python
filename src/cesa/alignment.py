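"""Optimal global pairwise protein alignment and coordinate projection.

The aligner is Needleman–Wunsch with Gotoh affine gaps (end gaps penalized — a
true global alignment), computed through :class:`Bio.Align.PairwiseAligner`.  A
gap of length *k* costs ``gap_open + (k-1) * gap_extend``.  The default scheme is
BLOSUM62 with open −10 / extend −0.5; nonstandard residues absent from the matrix
(e.g. U) score at the matrix minimum.  The first optimal alignment of the
aligner's deterministic traversal is returned, so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Union

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "ScoringScheme",
    "default_scheme",
    "simple_scheme",
    "global_align",
    "project_position",
    "extract_aligned_window",
    "GAP",
]

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores plus affine gap penalties (both ≤ 0).

    ``substitution_matrix`` maps unordered residue pairs to scores; pairs missing
    from it score at the matrix minimum.
    """

    substitution_matrix: Mapping[tuple[str, str], float]
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def score(self, a: str, b: str) -> float:
        m = self.substitution_matrix
        if (a, b) in m:
            return m[(a, b)]
        if (b, a) in m:
            return m[(b, a)]
        return min(m.values())


def _matrix_to_mapping(array) -> dict[tuple[str, str], float]:
    alphabet = array.alphabet
    return {
        (a, b): float(array[a, b])
        for a in alphabet
        for b in alphabet
        if a != "*" and b != "*"
    }


@lru_cache(maxsize=4)
def default_scheme(matrix_name: str = "BLOSUM62") -> ScoringScheme:
    """The pinned default: BLOSUM62, gap open −10, gap extend −0.5."""
    array = substitution_matrices.load(matrix_name)
    return ScoringScheme(_matrix_to_mapping(array))


def simple_scheme(match: float, mismatch: float, gap_open: float, gap_extend: float,
                  alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> ScoringScheme:
    """A match/mismatch scheme, mainly for tests and toy alphabets."""
    m = {
        (a, b): (match if a == b else mismatch)
        for a in alphabet
        for b in alphabet
    }
    return ScoringScheme(m, gap_open, gap_extend)


@dataclass(frozen=True)
class AlignmentResult:
    """A gapped global alignment; removing gaps reproduces the inputs exactly."""

    aligned_source: str
    aligned_target: str
    score: float
    source_accession: str = ""
    target_accession: str = ""

    def __post_init__(self) -> None:
        if len(self.aligned_source) != len(self.aligned_target):
            raise ValueError("aligned rows must have equal length")
        for s, t in zip(self.aligned_source, self.aligned_target):
            if s == GAP and t == GAP:
                raise ValueError("alignment column gapped in both rows")

    @property
    def source_sequence(self) -> str:
        return self.aligned_source.replace(GAP, "")

    @property
    def target_sequence(self) -> str:
        return self.aligned_target.replace(GAP, "")

    def source_column_map(self) -> list[int]:
        """Column index of each source residue (entry i ↔ source position i+1)."""
        return [i for i, c in enumerate(self.aligned_source) if c != GAP]


def _build_aligner(scheme: ScoringScheme, letters: set[str]) -> Align.PairwiseAligner:
    alphabet = sorted(letters | {a for pair in scheme.substitution_matrix for a in pair})
    floor = min(scheme.substitution_matrix.values())
    array = substitution_matrices.Array(alphabet="".join(alphabet), dims=2)
    for a in alphabet:
        for b in alphabet:
            array[a, b] = scheme.score(a, b) if (
                (a, b) in scheme.substitution_matrix or (b, a) in scheme.substitution_matrix
            ) else floor
    aligner = Align.PairwiseAligner(mode="global")
    aligner.substitution_matrix = array
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def global_align(
    source_seq: str,
    target_seq: str,
    scheme: Optional[ScoringScheme] = None,
    source_accession: str = "",
    target_accession: str = "",
) -> AlignmentResult:
    """Optimal-score global alignment of two protein sequences."""
    if not source_seq or not target_seq:
        raise ValueError("cannot align an empty sequence")
    if scheme is None:
        scheme = default_scheme()
    aligner = _build_aligner(scheme, set(source_seq) | set(target_seq))
    aln = aligner.align(source_seq, target_seq)[0]
    return AlignmentResult(
        aligned_source=str(aln[0]),
        aligned_target=str(aln[1]),
        score=float(aln.score),
        source_accession=source_accession,
        target_accession=target_accession,
    )


def project_position(
    aln: AlignmentResult, source_pos: int
) -> tuple[Optional[int], int]:
    """Map a 1-based source position through the alignment.

    Returns ``(target_pos, column_index)``; ``target_pos`` is ``None`` when the
    source residue is aligned to a gap in the target row.
    """
    cols = aln.source_column_map()
    if not 1 <= source_pos <= len(cols):
        raise ValueError(f"source position {source_pos} out of range 1..{len(cols)}")
    col = cols[source_pos - 1]
    if aln.aligned_target[col] == GAP:
        return None, col
    target_pos = sum(1 for c in aln.aligned_target[: col + 1] if c != GAP)
    return target_pos, col


def extract_aligned_window(
    aln: AlignmentResult, source_start: int, length: int
) -> tuple[str, str, bool]:
    """Alignment columns spanning a source window of ``length`` residues.

    The span runs from the column of ``source_start`` to the column of the window's
    last residue, so target-insertion columns inside the window are included.
    ``has_gap`` is true when any spanned column carries a gap in either row.
    """
    cols = aln.source_column_map()
    n = len(cols)
    if length < 1 or not 1 <= source_start or source_start + length - 1 > n:
        raise ValueError(
            f"window [{source_start}, +{length}] out of range for source of length {n}"
        )
    lo = cols[source_start - 1]
    hi = cols[source_start + length - 2]
    src = aln.aligned_source[lo : hi + 1]
    tgt = aln.aligned_target[lo : hi + 1]
    return src, tgt, (GAP in src or GAP in tgt)
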