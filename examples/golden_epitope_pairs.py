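"""Score the twelve validated human↔fly phospho-epitope pairs.

Each pair is a ±7-aa flanking peptide around a phosphosite on a human protein
and the corresponding region of its fly ortholog, for antibodies with confirmed
cross-reactivity.  We compute the contiguous-identity run containing the site
and the best qualifying window lengths under the strict and relaxed rules.
"""

from cesa import run_validated_pairs

rows = run_validated_pairs()
print(f"{'human':<10}{'fly':<12}{'run':>4}{'strict':>8}{'relaxed':>9}")
for row in rows:
    print(
        f"{row['source_gene']:<10}{row['target_gene']:<12}"
        f"{row['identity_run']:>4}{row['best_strict']:>8}{row['best_relaxed']:>9}"
    )

# The "run" column is the longest stretch of identical aligned residues
# containing the phosphosite (6-15 aa across these validated pairs); "strict"
# and "relaxed" are the longest 6-11-aa windows spanning the site that are
# fully identical, or identical up to one conservative substitution placed at
# least two positions away from the site.  Every validated antibody reaches the
# 6-aa qualification threshold, which is what motivates that default cutoff.
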