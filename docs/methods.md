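# Methods

## Problem and model

An anti-phosphosite antibody recognizes a short linear epitope: the
phosphorylated S/T/Y plus a handful of flanking residues. Cross-reactivity with
an orthologous protein in another species is therefore predicted from local
sequence conservation around the aligned site, not from overall protein
similarity. Validated cross-reactive antibodies show contiguous identical
regions as short as 6 aa around the site, which sets the window-length range
tested here (6–11 aa).

The unit of analysis is a (phosphosite × target isoform) pair. A site
*qualifies at cutoff L* if at least one contiguous window of L residues
containing the site is conserved in the aligned target. Two regimes are
computed side by side:

* **strict** — all L aligned positions identical;
* **relaxed** — at most one position may instead be a conservative
  substitution, and only at distance ≥ 2 from the site. The site itself is the
  phospho-residue and its immediate neighbors dominate antibody contact, so
  substitutions there are never excused. "Distance ≥ 2" is the literal reading
  of "not right next to" the target residue.

The report also carries the *contiguous identity run*: the longest gap-free
stretch of identical aligned residues containing the site, computed over the
±7 aligned neighborhood (truncated at the first gap column). This is the
statistic conventionally tabulated for validated epitope pairs, and the twelve
golden pairs reproduce their known values (6, 14, 11, 13, 15, 6, 6, 15, 15, 8,
6, 7) exactly.

Note the two statistics measure different things: the run requires contiguous
identity through the site, while a qualifying window is capped at 11 and may
tolerate one conservative substitution, so `best_relaxed ≥ best_strict` always,
and `best_strict = min(run, 11)` whenever the run lies within the ±7
neighborhood.

## Conservative substitutions

No single definition of "conservative" is canonical. The default predicate
uses disjoint physicochemical groups {I,L,V,M}, {F,W,Y}, {K,R,H}, {D,E},
{S,T}, {N,Q}, {A,G} (C and P stand alone — they have no structurally safe
replacement). A BLOSUM62-positive predicate (`similarity_scheme:
blosum62_positive`) is selectable in the config; the group predicate is the
default because it is symmetric, parameter-free and matches how epitope
similarity is usually eyeballed.

## Anchoring rules

* The flanking peptide is unpadded (`_` prefix/suffix removed) and scanned for
  exact occurrences on the claimed accession's sequence. The occurrence
  consistent with the claimed coordinate wins (`direct`); a unique occurrence
  elsewhere wins over the claim (`position_shifted`) — coordinates drift across
  releases, immunogen sequences do not.
* Multiple occurrences with no coordinate match are a hard `ambiguous_peptide`
  failure: a guessed anchor silently corrupts every downstream window.
* If the accession is missing or fails, all proteins of the gene symbol are
  scanned; among single-occurrence candidates the longest sequence wins, ties
  broken by lexicographic accession (mirroring the longest-isoform reporting
  convention). Cores shorter than 4 aa after unpadding are rejected as
  unanchorable.
* Rows whose claimed residue letter disagrees with the peptide center are kept
  and flagged rather than dropped; the peptide center is treated as truth.

## Alignment

True global alignment (end gaps penalized), affine gaps, computed with
Biopython's `PairwiseAligner`. Defaults: BLOSUM62, gap open −10, gap extend
−0.5 — the de-facto protein global-alignment default; the downstream statistic
is identity within short windows, so results are robust to any reasonable
scheme, but the choice is pinned for reproducibility. A gap of length k costs
`open + (k−1)·extend`. The first optimal alignment of the aligner's
deterministic traversal is used, so repeated runs are bit-identical. Scores
are oracle-checked in the tests against exhaustive enumeration of all gap
placements on small pairs. Residues absent from the matrix (e.g. U) score at
the matrix minimum. Windows are enumerated in source coordinates; any window
touching a gap column in either row is disqualified rather than re-spliced,
because an epitope is a contiguous peptide.

## Isoforms and counting

All target isoforms are aligned and reported (`isoform_mode: all`), since an
antibody may detect several isoforms (multiple western-blot bands); per-gene
summaries collapse isoforms, counting distinct sites (organism, gene symbol,
site label) and distinct source/target genes with ≥ 1 qualifying site at each
cutoff. `isoform_mode: longest` restricts each target gene to its longest
isoform (ties by accession) for per-gene counting conventions. Summary counts
are non-increasing in the cutoff by construction. One-to-many orthology is
preserved through mapping; collapse happens only at reporting. An optional
second pair table with paralog relationships can be supplied with identical
semantics (off by default).

## Synthetic data

The generator emulates exactly the features the pipeline decides on: a
phosphosite-catalog dialect (banner preamble, `S473-p`-style labels, lowercase
center residue, `;`/`,`-separated antibody ids), two proteomes in which each
planted ±7 neighborhood is embedded in random 30-aa context shared between
source and target (so global alignments are gapless and window outcomes are
fully determined by the plant), ortholog/alias tables, and recorded expected
outcomes. A plant fixes the identity-run length (level 0–11: boundaries of the
run are non-conservative mismatches placed inside the 15-mer) and may add one
conservative substitution, either detached from the site (extending only the
relaxed window by one) or adjacent to it (which must change nothing). Context
is re-drawn on accidental peptide collisions so anchoring stays unambiguous.
Infeasible plants (level > 7 with an adjacent substitution; level 0 with a
conservative substitution) raise rather than silently degrade.

What the generator does **not** emulate: real indel patterns between orthologs
(shared context forces gapless alignments), compositional bias, stale
accessions needing rescue at scale, or many-to-many ortholog fan-out. Passing
the recovery tests therefore demonstrates correctness of the decision logic and
plumbing, not performance on diverged proteomes; the golden epitope fixture is
the real-data spot check.

## Problem sizes and numerical choices

Tests run the full pipeline on bundles of 29 genes × 2 sites (58 plants
covering every level, with and without conservative substitutions and
adjacency breakers) and check exhaustive alignment optimality on all ~7k
length ≤ 3 pairs plus 2,000 random length 4–6 pairs over a 4-letter alphabet —
sizes chosen so the whole suite completes in seconds while every code path is
exercised. All scores are exact integer/half-integer arithmetic; there are no
tolerances. The pipeline has no randomness; the only seeds are in the
synthetic generator and test oracles.

## Known limitations

* Dual-site antibodies (adjacent phospho-epitopes) are evaluated per site; no
  merging semantics are attempted.
* The relaxed rule admits exactly one substitution per window regardless of
  window length; longer windows arguably tolerate more, but the rule is kept
  as specified.
* Alignment-quality failure modes (e.g. a misaligned low-complexity region)
  propagate into window calls; no realignment or local refinement is done.
* `summarize` keys sites by (organism, gene symbol, site label); catalogs with
  duplicated symbols across accessions within one organism would under-count.
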