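"""Compare two toxin isoforms at the sequence level.

Uses the published N-terminal 20-mers of two fragaceatoxin isoforms (from
Edman degradation) to count differences, then shows cDNA translation, splicing
of an Edman prefix onto a translated body, and the theoretical average mass.
"""

from actinovar import (Alphabet, SequenceRecord, average_mass, pairwise_compare,
                       region_differences, splice_mature, translate_cds)

frab_nt = SequenceRecord("FraB", "SAEVAGAIIDGASLTFDVLQ")
frae_nt = SequenceRecord("FraE", "SADVAGAVIDGAGLGFDVLK")

cmp = pairwise_compare(frab_nt, frae_nt, mode="aligned")
print(f"FraB vs FraE over the first {cmp.n_aligned} residues: "
      f"{cmp.n_identical} identical, {cmp.n_different} different "
      f"({cmp.pct_identity:.0f}% identity)")
print(f"differences within residues 1-12: "
      f"{region_differences(frab_nt, frae_nt, 1, 12)}")

# reconstruct a mature sequence: Edman prefix + cDNA-translated body
cds = SequenceRecord("body", "TCTCTTACTTTTGATGTTCTTCAA", Alphabet.DNA)
body = translate_cds(cds)
mature = splice_mature("SAEVAGAIIDGA", body.seq)
print(f"mature sequence: {mature.full} "
      f"(prefix {len(mature.edman_prefix)} aa + body {len(mature.translated_body)} aa)")
print(f"theoretical average mass: {average_mass(mature.full):.1f} Da")
# The identity percentage counts only columns where both rows carry a residue;
# the mass is the sum of standard average residue masses plus one water.
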