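"""Anchoring catalog sites onto current protein sequences."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cesa.formats_io import FormatError, PhosphoSiteRecord, ProteinRecord
from cesa.site_anchor import (
    AnchoredSite,
    AnchorFailure,
    ProteomeIndex,
    anchor_all,
    anchor_direct,
    rescue_by_symbol,
    unpad_flank,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def protein(accession, sequence, symbol="GENE1"):
    return ProteinRecord(accession, "g1", symbol, "human", sequence)


def record(flank, position, accession="P1", symbol="GENE1", residue=None):
    return PhosphoSiteRecord(
        gene_symbol=symbol,
        protein_accession=accession,
        organism="human",
        residue=residue or flank.strip("_")[7 - (len(flank) - len(flank.lstrip("_")))],
        position=position,
        flank_peptide=flank,
        antibody_ids=("#1",),
        site_label="site",
    )


@pytest.mark.parametrize(
    "flank, core, offset",
    [
        ("RPHFPQFSYSASGTA", "RPHFPQFSYSASGTA", 7),
        ("____MKVSYTTPGGT", "MKVSYTTPGGT", 3),
        ("MILLSELSRRRIRS_", "MILLSELSRRRIRS", 7),
        ("_______SAAAAAAA", "SAAAAAAA", 0),
    ],
)
def test_unpad_flank(flank, core, offset):
    assert unpad_flank(flank) == (core, offset)


def test_unpad_rejects_interior_padding():
    with pytest.raises(FormatError):
        unpad_flank("AAA_AAASAAAAAAA")


class TestAnchorDirect:
    PROT = protein("P1", "AAAR" + "PHFPQFSYSASGTA" + "WWQK")
    # core peptide RPHFPQFSYSASGTA starts at 1-based 4; center S at 4 + 7 = 11

    def test_direct_when_claimed_position_matches(self):
        out = anchor_direct(record("RPHFPQFSYSASGTA", 11), self.PROT)
        assert isinstance(out, AnchoredSite)
        assert out.position == 11 and out.provenance == "direct"

    def test_unique_occurrence_overrides_claimed_position(self):
        out = anchor_direct(record("RPHFPQFSYSASGTA", 473), self.PROT)
        assert isinstance(out, AnchoredSite)
        assert out.position == 11 and out.provenance == "position_shifted"

    def test_peptide_not_found(self):
        out = anchor_direct(record("WWWWWWWSWWWWWWW", 8), self.PROT)
        assert isinstance(out, AnchorFailure) and out.reason == "peptide_not_found"

    def test_multiple_occurrences_are_ambiguous(self):
        # core GGTLFSTT occurs at 1-based 1 and 9; neither matches the claim
        prot = protein("P1", "GGTLFSTTGGTLFSTTK")
        out = anchor_direct(record("__GGTLFSTT_____", 99), prot)
        assert isinstance(out, AnchorFailure) and out.reason == "ambiguous_peptide"

    def test_repeated_core_with_matching_claim_is_direct(self):
        # same repeated core, but the claim matches the first occurrence
        prot = protein("P1", "GGTLFSTTGGTLFSTTK")
        out = anchor_direct(record("__GGTLFSTT_____", 6), prot)
        assert isinstance(out, AnchoredSite)
        assert out.position == 6 and out.provenance == "direct"

    def test_short_core_rejected(self):
        rec = record("_______SA______", 8)
        out = anchor_direct(rec, self.PROT)
        assert isinstance(out, AnchorFailure) and out.reason == "peptide_too_short"


class TestRescueBySymbol:
    CORE = "RPHFPQFSYSASGTA"

    def test_single_matching_candidate(self):
        cands = [
            protein("N1", "M" * 30),
            protein("N2", "AA" + self.CORE + "KK"),
            protein("N3", "W" * 20),
        ]
        out = rescue_by_symbol(record(self.CORE, 473, accession="OLD"), cands)
        assert isinstance(out, AnchoredSite)
        assert out.provenance == "rescued_by_symbol"
        assert out.protein.accession == "N2" and out.position == 10

    def test_longest_candidate_wins_then_accession(self):
        # brute-force check: both candidates contain the core exactly once
        long_seq = "L" * 200 + self.CORE + "L" * 285  # 500 aa
        short_seq = "K" * 100 + self.CORE + "K" * 185  # 300 aa
        assert long_seq.count(self.CORE) == short_seq.count(self.CORE) == 1
        out = rescue_by_symbol(
            record(self.CORE, 1, accession="OLD"),
            [protein("pB", short_seq), protein("pA", long_seq)],
        )
        assert out.protein.accession == "pA"
        # equal lengths: lexicographic accession breaks the tie
        out2 = rescue_by_symbol(
            record(self.CORE, 1, accession="OLD"),
            [protein("pB", long_seq), protein("pA", long_seq)],
        )
        assert out2.protein.accession == "pA"

    def test_no_candidate_contains_peptide(self):
        out = rescue_by_symbol(record(self.CORE, 1), [protein("N1", "M" * 30)])
        assert isinstance(out, AnchorFailure) and out.reason == "peptide_not_found"

    def test_empty_candidates(self):
        out = rescue_by_symbol(record(self.CORE, 1), [])
        assert isinstance(out, AnchorFailure) and out.reason == "accession_not_found"

    def test_candidate_with_multiple_occurrences_is_ambiguous(self):
        seq = "A" + self.CORE + "G" + self.CORE + "C"
        out = rescue_by_symbol(record(self.CORE, 1), [protein("N1", seq)])
        assert isinstance(out, AnchorFailure) and out.reason == "ambiguous_peptide"


class TestAnchorAll:
    def test_partition_into_buckets(self):
        p_direct = protein("P1", "AAARPHFPQFSYSASGTAWWQK", symbol="G1")
        p_rescue = protein("N9", "CCMILLSELSRRRIRSIKK", symbol="G2")
        index = ProteomeIndex([p_direct, p_rescue])
        records = [
            record("RPHFPQFSYSASGTA", 11, accession="P1", symbol="G1"),
            record("MILLSELSRRRIRSI", 10, accession="GONE", symbol="G2"),
            record("WWWWWWWSWWWWWWW", 8, accession="GONE2", symbol="G3"),
        ]
        anchored, tally = anchor_all(records, index)
        assert len(anchored) == 2
        assert {a.provenance for a in anchored} == {"direct", "rescued_by_symbol"}
        assert tally == {"accession_not_found": 1}
        assert len(anchored) + sum(tally.values()) == len(records)

    def test_empty_input(self):
        anchored, tally = anchor_all([], ProteomeIndex([]))
        assert anchored == [] and not tally

    def test_duplicates_not_deduplicated(self):
        p = protein("P1", "AAARPHFPQFSYSASGTAWWQK")
        rec = record("RPHFPQFSYSASGTA", 11)
        anchored, _ = anchor_all([rec, rec], ProteomeIndex([p]))
        assert len(anchored) == 2


@given(
    seq=st.text(alphabet=AA, min_size=15, max_size=120),
    data=st.data(),
)
def test_flank_roundtrip_at_anchored_position(seq, data):
    """The ±7 flank rebuilt at the anchored position equals the catalog peptide."""
    pos0 = data.draw(st.integers(min_value=0, max_value=len(seq) - 1))
    seq = seq[:pos0] + "S" + seq[pos0 + 1 :]
    left = seq[max(0, pos0 - 7) : pos0]
    right = seq[pos0 + 1 : pos0 + 8]
    flank = "_" * (7 - len(left)) + left + "S" + right + "_" * (7 - len(right))
    core = flank.strip("_")
    prot = protein("P1", seq)
    if seq.count(core) != 1:
        return  # ambiguous plants are rejected by contract, not round-tripped
    out = anchor_direct(record(flank, pos0 + 1), prot)
    assert isinstance(out, AnchoredSite)
    assert out.position == pos0 + 1
    assert out.reconstruct_flank() == flank
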