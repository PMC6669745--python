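"""Side-chain accessibility ratios and burial classes on toy structures.

Computes the Shrake–Rupley ASA of residues in known contexts: the extended
Gly-X-Gly coil reference itself (ratio 1 by construction) and a residue
enclosed in a dummy-atom shell (ratio 0, class low).
"""

from actinovar import generate_toy_structure, sidechain_ratio, kabsch_superpose
import numpy as np

for kind, resnum, label in [("extended_tripeptide", 2, "coil reference"),
                            ("buried_residue", 1, "shell-buried")]:
    atoms = generate_toy_structure(kind, "LEU")
    entry = sidechain_ratio(atoms, "A", resnum)
    print(f"LEU ({label:>14s}): side-chain ASA {entry.sidechain_asa:7.2f} A^2, "
          f"ratio {entry.ratio:.2f}, class {entry.asa_class.value}")

# superposition: a rotated/translated copy superposes back to RMSD 0
helix = generate_toy_structure("helix", "ALA")
coords = np.array([a.xyz for a in helix])
rng = np.random.default_rng(0)
theta = np.pi / 5
R = np.array([[np.cos(theta), -np.sin(theta), 0],
              [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
moved = coords @ R.T + [8.0, -2.0, 3.0]
res = kabsch_superpose(coords, moved)
print(f"superposition RMSD of a rigidly moved copy: {res.rmsd:.2e} A")
# Ratios are side-chain ASA over the same side chain in the extended
# Gly-X-Gly reference; classes: low <20%, partial 20-50%, high >50%.
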