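"""Window-conservation rule, contiguous identity runs, per-cutoff summaries."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cesa.alignment import AlignmentResult, global_align
from cesa.conservation import (
    DEFAULT_GROUPS,
    ConservationResult,
    blosum62_positive_groups,
    evaluate_site,
    identity_run,
    summarize,
    window_qualifies,
)
from cesa.formats_io import PhosphoSiteRecord, ProteinRecord
from cesa.site_anchor import AnchoredSite
from cesa.synthetic_fixtures import validated_pairs

AA15 = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=15, max_size=15)


def make_anchored(peptide, organism="human", symbol="GENE", label="S8-p"):
    """Anchor a 15-mer on itself (site at 1-based 8), for peptide-scale tests."""
    record = PhosphoSiteRecord(
        gene_symbol=symbol,
        protein_accession=f"{symbol}_p",
        organism=organism,
        residue=peptide[7] if peptide[7] in "STY" else "S",
        position=8,
        flank_peptide=peptide,
        center_mismatch=peptide[7] not in "STY",
        site_label=label,
    )
    protein = ProteinRecord(record.protein_accession, "", symbol, organism, peptide)
    return AnchoredSite(record, protein, 8, "direct", peptide, 7)


def peptide_result(source_pep, target_pep, target_gene="tg", **kwargs):
    aln = global_align(source_pep, target_pep)
    target = ProteinRecord(f"{target_gene}_p", target_gene, target_gene, "fly", target_pep)
    return evaluate_site(aln, make_anchored(source_pep), target, **kwargs)


class TestIdentityRun:
    @pytest.mark.parametrize("source, target, expected", [
        (h, f, n) for h, f, n in validated_pairs()
    ])
    def test_golden_validated_epitope_pairs(self, source, target, expected):
        assert identity_run(source, target, 7) == expected

    def test_site_mismatch_forces_zero(self):
        assert identity_run("AAAA", "CCCC", 1) == 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            identity_run("AAA", "AAAA", 0)

    @given(AA15, st.integers(min_value=0, max_value=14))
    def test_self_comparison_spans_whole_window(self, window, i):
        assert identity_run(window, window, i) == len(window)

    @given(AA15, AA15, st.integers(min_value=0, max_value=14))
    def test_symmetric_in_windows(self, w1, w2, i):
        assert identity_run(w1, w2, i) == identity_run(w2, w1, i)


class TestWindowQualifies:
    def test_identical_windows_qualify(self):
        assert window_qualifies("AKTSPQFS", "AKTSPQFS", 3)

    def test_one_conservative_sub_far_from_site(self):
        # I↔L at distance 3 from the site
        assert window_qualifies("IKTSPQFD", "LKTSPQFD", 3, allow_conservative=True)
        assert not window_qualifies("IKTSPQFD", "LKTSPQFD", 3, allow_conservative=False)

    def test_conservative_sub_adjacent_to_site_disqualifies(self):
        assert not window_qualifies("AKISPQFD", "AKLSPQFD", 3, allow_conservative=True)

    def test_conservative_sub_at_site_disqualifies(self):
        assert not window_qualifies("AKTSPQFD", "AKTTPQFD", 3, allow_conservative=True)

    def test_two_conservative_subs_disqualify(self):
        assert not window_qualifies("IKTSPQFD", "LKTSPQFE", 3, allow_conservative=True)

    def test_non_conservative_sub_disqualifies(self):
        assert not window_qualifies("WKTSPQFD", "PKTSPQFD", 3, allow_conservative=True)

    @given(AA15, AA15, st.integers(min_value=0, max_value=14))
    def test_strict_implies_relaxed(self, w1, w2, i):
        if window_qualifies(w1, w2, i, allow_conservative=False):
            assert window_qualifies(w1, w2, i, allow_conservative=True)


class TestSimilarityGroups:
    def test_default_groups_predicate(self):
        assert DEFAULT_GROUPS.conservative("I", "L")
        assert DEFAULT_GROUPS.conservative("L", "I")  # symmetric
        assert not DEFAULT_GROUPS.conservative("I", "I")  # identity never counts
        assert not DEFAULT_GROUPS.conservative("I", "D")
        assert not DEFAULT_GROUPS.conservative("C", "P")  # ungrouped residues

    def test_blosum62_positive_alternative(self):
        groups = blosum62_positive_groups()
        assert groups.conservative("I", "V")
        assert not groups.conservative("G", "W")
        assert not groups.conservative("A", "A")


def brute_best_windows(source_pep, target_pep, site_index, cutoffs=range(6, 12)):
    """Independent enumeration of every (start, L) placement on gap-free 15-mers."""
    best_strict = best_relaxed = 0
    n = len(source_pep)
    for L in cutoffs:
        for start in range(0, n - L + 1):
            if not start <= site_index <= start + L - 1:
                continue
            sw = source_pep[start : start + L]
            tw = target_pep[start : start + L]
            mism = [k for k in range(L) if sw[k] != tw[k]]
            if not mism:
                best_strict = max(best_strict, L)
                best_relaxed = max(best_relaxed, L)
            elif len(mism) == 1:
                k = mism[0]
                if abs(k - (site_index - start)) >= 2 and DEFAULT_GROUPS.conservative(
                    sw[k], tw[k]
                ):
                    best_relaxed = max(best_relaxed, L)
    return best_strict, best_relaxed


class TestEvaluateSite:
    def test_identical_neighborhood_qualifies_everywhere(self):
        for pep in ("MILLSELSRRRIRSI", "HDHTGFLTEYVATRW"):
            result = peptide_result(pep, pep)
            assert all(result.qualifies_at[L] for L in range(6, 12))
            assert result.identity_run == 15
            assert result.best_strict == result.best_relaxed == 11

    def test_strict_cutoff_profile_of_partially_conserved_pair(self):
        # validated pair with a 7-residue conserved core: strict windows pass
        # at 6 and 7 but not 8
        result = peptide_result(
            "GGTLFSTTPGGTRII", "GGTLYSTTPGGTKLI", allow_conservative=False
        )
        assert result.best_strict == 7
        assert result.qualifies_at[6] and result.qualifies_at[7]
        assert not result.qualifies_at[8]

    def test_relaxed_regime_extends_past_conservative_subs(self):
        result = peptide_result("GGTLFSTTPGGTRII", "GGTLYSTTPGGTKLI")
        assert result.best_strict == 7
        assert result.best_relaxed > result.best_strict

    def test_site_aligned_to_gap_scores_zero(self):
        aln = AlignmentResult("MKVLSELSRRRIRSI", "MKVLSEL-RRRIRSI", 0)
        anchored = make_anchored("MKVLSELSRRRIRSI")
        target = ProteinRecord("t1", "tg", "tg", "fly", "MKVLSELRRRIRSI")
        result = evaluate_site(aln, anchored, target)
        assert result.identity_run == 0
        assert result.best_strict == result.best_relaxed == 0
        assert not any(result.qualifies_at.values())

    def test_gap_touching_windows_are_discarded(self):
        # a target insertion inside the neighborhood disqualifies spanning windows
        aln = AlignmentResult("MKVLSEL-SRRRIRSI", "MKVLSELASRRRIRSI", 0)
        anchored = make_anchored("MKVLSELSRRRIRSI")
        target = ProteinRecord("t1", "tg", "tg", "fly", "MKVLSELASRRRIRSI")
        result = evaluate_site(aln, anchored, target)
        # every window crossing the insertion is gone; right-side windows remain
        assert result.best_strict == 8

    @given(AA15, AA15)
    def test_best_windows_match_exhaustive_enumeration(self, source_pep, target_pep):
        result = peptide_result(source_pep, target_pep)
        aln = global_align(source_pep, target_pep)
        if "-" in aln.aligned_source or "-" in aln.aligned_target:
            return  # enumeration oracle is defined on gapless pairs
        strict, relaxed = brute_best_windows(source_pep, target_pep, 7)
        assert (result.best_strict, result.best_relaxed) == (strict, relaxed)

    @given(AA15, AA15)
    def test_result_invariants(self, source_pep, target_pep):
        r = peptide_result(source_pep, target_pep)
        assert r.best_relaxed >= r.best_strict
        assert all(r.qualifies_at[L] == (r.best_relaxed >= L) for L in range(6, 12))
        for L in range(6, 11):
            assert r.qualifies_at[L] or not r.qualifies_at[L + 1]
        if r.identity_run <= 11:
            assert r.best_strict <= r.identity_run


class TestSummarize:
    def _results(self):
        rows = []
        for i, (tg, best) in enumerate([("tgA", 11), ("tgA", 6), ("tgB", 6)]):
            anchored = make_anchored(
                "MILLSELSRRRIRSI", symbol=f"G{i}", label=f"S{i+1}-p"
            )
            target = ProteinRecord(f"{tg}_p", tg, tg, "fly", "MILLSELSRRRIRSI")
            rows.append(
                ConservationResult(
                    anchored=anchored,
                    target=target,
                    identity_run=best,
                    best_strict=best,
                    best_relaxed=best,
                    qualifies_at={L: best >= L for L in range(6, 12)},
                )
            )
        return rows

    def test_counts_at_cutoffs(self):
        results = self._results()
        assert summarize(results, 6) == (3, 3, 2)
        assert summarize(results, 11) == (1, 1, 1)

    def test_empty_results(self):
        assert summarize([], 6) == (0, 0, 0)

    def test_isoforms_collapse_to_genes(self):
        results = self._results()
        # duplicate the first result on a second isoform of the same target gene
        first = results[0]
        iso2 = ProteinRecord("tgA_p2", "tgA", "tgA", "fly", "MILLSELSRRRIRSI")
        results.append(
            ConservationResult(first.anchored, iso2, 15, 11, 11, first.qualifies_at)
        )
        n_sites, n_src, n_tgt = summarize(results, 11)
        assert (n_sites, n_src, n_tgt) == (1, 1, 1)

    def test_monotone_under_cutoff(self):
        results = self._results()
        counts = [summarize(results, L) for L in range(6, 12)]
        for earlier, later in zip(counts, counts[1:]):
            assert all(a >= b for a, b in zip(earlier, later))
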