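# cesa — cross-species epitope sequence analysis for phospho-antibodies

Phospho-specific antibodies are raised against a short phosphopeptide — the
modified serine/threonine/tyrosine plus ±7 flanking residues — on a human,
mouse or rat protein. Because making such antibodies is hard, very few exist
for model organisms. `cesa` asks, for every phosphosite in an antibody catalog:
is the epitope region conserved well enough in the orthologous protein of
another species (say, *Drosophila*) that the existing antibody will likely
cross-react there?

It is a library plus a thin CLI for researchers who want to mine commercial
phospho-antibody collections for reagents usable in their organism.

## Method

Five stages, all deterministic:

1. **Site anchoring.** Each catalog row carries a 15-character flanking peptide
   (`_`-padded at protein termini, phosphosite at the center). The peptide is
   located exactly on the current full-length protein for the claimed
   accession; if the accession is stale, proteins retrieved by gene symbol are
   scanned instead. The peptide, not the claimed coordinate, is trusted —
   provenance (`direct`, `position_shifted`, `rescued_by_symbol`) is recorded.
2. **Gene resolution.** Accessions/symbols are mapped to gene identifiers
   through alias tables.
3. **Ortholog expansion.** A DIOPT-style pair table maps each source gene to
   target-species genes, keeping only high/moderate-confidence pairs by
   default.
4. **Global alignment.** Each anchored source protein is aligned to every
   isoform of each target ortholog with Needleman–Wunsch/Gotoh affine-gap
   global alignment (BLOSUM62, gap open −10, extend −0.5), and the site
   position is projected through the alignment.
5. **Window conservation.** For window lengths L = 6…11, every contiguous
   source window of length L spanning the site is tested against the aligned
   target residues. A window qualifies if it is identical position-by-position
   (**strict**), or — under the **relaxed** rule — identical except for at most
   one conservative substitution (same physicochemical group, e.g. I↔L) located
   at least two positions away from the phosphosite. Windows touching any
   alignment gap are disqualified. The report also gives the longest contiguous
   run of identical aligned residues containing the site (the *conserved
   region* statistic), computed over the ±7 neighborhood.

A site qualifying at cutoff L = 6 on some target isoform is a predicted
cross-reactive target; raising the cutoff trades recall for confidence.

## Worked example

Twelve commercial antibodies are known to cross-react with fly phosphoproteins;
their epitope pairs ship with the package as a golden fixture. Running

```bash
python examples/golden_epitope_pairs.py    # or: cesa validated
```

prints

```
human     fly          run  strict  relaxed
AKT1      Akt1           6       6        6
PRKAA1    AMPKalpha     14      11       11
MAPK10    bsk           11      11       11
MAPK10    bsk           13      11       11
EIF2S1    eIF2alpha     15      11       11
MAPK12    p38a           6       6        6
MAPK12    p38a           6       6        6
MAPK1     rl            15      11       11
MAPK1     rl            15      11       11
RPS6KB1   S6k            8       8       10
EIF4EBP1  Thor           6       6        8
EIF4EBP1  Thor           7       7       11
```

`run` is the contiguous identical region containing the phosphosite (6–15 aa
across these validated pairs — every known cross-reactive antibody reaches at
least 6, which motivates the default cutoff). `strict`/`relaxed` are the best
qualifying window lengths (capped at 11, the largest window tested); where
`relaxed` exceeds `strict` the ortholog differs only by conservative
substitutions away from the site.

`examples/synthetic_pipeline.py` generates a fully synthetic input bundle with
planted conservation outcomes and shows the pipeline recovering all of them
exactly, plus the per-cutoff summary table whose counts decline monotonically
from cutoff 6 to 11. `examples/align_and_project.py` demonstrates coordinate
projection through a global alignment.

For real inputs, write a flat YAML config (see `cesa run --print-config`) and:

```bash
cesa run --config run.yaml            # writes report.tsv and summary.tsv
cesa run --config run.yaml --peptide-only --min-rank high --no-conservative
cesa synth --out bundle/ --seed 7     # synthetic inputs for a dry run
```

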