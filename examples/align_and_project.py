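"""Align two protein sequences and project a phosphosite through the alignment.

Global alignment (BLOSUM62, affine gaps) maps each source coordinate to its
aligned target coordinate; a site landing on a target gap has no counterpart
and is reported as such.
"""

from cesa import extract_aligned_window, global_align, project_position

source = "MSDVAIVKEGWLHKRGEYIKTWRPRYFLL"   # source kinase fragment
target = "MSDVTIVKEGWVHKRGEYIKNWRPRYFLL"   # ortholog fragment

aln = global_align(source, target)
print(aln.aligned_source)
print(aln.aligned_target)
print(f"score = {aln.score}")

site = 21  # 1-based position of a phospho-threonine on the source
target_pos, column = project_position(aln, site)
print(f"\nsource position {site} ({source[site - 1]}) -> "
      f"target position {target_pos} ({target[target_pos - 1]})")

src_win, tgt_win, has_gap = extract_aligned_window(aln, site - 3, 7)
print(f"aligned 7-aa window around the site: {src_win} / {tgt_win} (gap: {has_gap})")
# The projection is what lets window conservation be scored in source
# coordinates while reading the orthologous residues from the target row.
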