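"""Scan a transposase protein for the diagnostic Mariner motifs.

Takes the Mauritiana-subfamily consensus transposase and reports the DD34D
catalytic triad, the WVPHEL and YSPDL peptides, the helix-turn-helix
heuristic and the basic-residue NLS window.
"""

from marinerscan import PlantConfig, find_best_orf
from marinerscan.synthetic_data import build_consensi
from marinerscan.transposase_analysis import scan_motifs

cons = build_consensi(PlantConfig(genomes=[], seed=0))["Mauritiana"]
orf = find_best_orf(cons.element)
m = scan_motifs(orf.aa_seq)

print(f"transposase: {len(orf.aa_seq)} aa, intact={not orf.has_internal_stop}")
print(f"catalytic triad: {m.triad.triad_class} at positions {m.triad.positions}")
print(f"WVPHEL: span {m.wvphel[0]}, {m.wvphel[1]} substitutions")
print(f"YSPDL:  span {m.yspdl[0]}, {m.yspdl[1]} substitutions")
print(f"HTH candidates (N-terminal helix pairs): {len(m.hth_spans)}")
print(f"NLS window: {m.nls[0]} with {m.nls[1]} basic residues")
print("\nDD34D (third aspartate exactly 34 residues after the second) is the "
      "family signature separating Mariner from Tc1 (DD34E) and the "
      "maT/GT/VS families (DD37D/DD39D/DD41D).")
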