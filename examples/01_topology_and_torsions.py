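"""Build a molecule from its bond graph and find its rotatable bonds.

A molecule here is just an element list plus bonds; internal coordinates
(bonds, angles, proper dihedrals) are enumerated from the graph, and the
torsion-CV rule picks one representative dihedral per rotatable bond
(single, non-ring, both endpoints with further neighbors).
"""

import numpy as np

from mlpforge import build_molecule, enumerate_internal_coords, measure, select_torsion_cvs
from mlpforge.moltopo import Conformation

# a six-ring with a two-atom tail, the classic "one rotatable bond" motif
bonds = [(i, (i + 1) % 6) for i in range(6)] + [(0, 6), (6, 7)]
mol = build_molecule(["C"] * 8, bonds, name="ring-with-tail")

ic = enumerate_internal_coords(mol)
print(f"{mol.name}: {mol.n_atoms} atoms, {len(ic.bonds)} bonds, "
      f"{len(ic.angles)} angles, {len(ic.dihedrals)} dihedrals")

cvs = select_torsion_cvs(mol)
print(f"rotatable bonds (torsion CVs): {cvs}")
# ring bonds are excluded (scanning them would tear the ring); only the
# exocyclic 0-6 bond qualifies

ring = 1.4 * np.array(
    [[np.cos(np.radians(60 * k)), np.sin(np.radians(60 * k)), 0] for k in range(6)]
)
coords = np.vstack([ring, [[2.9, 0.0, 0.35], [3.9, 0.9, 0.7]]])
conf = Conformation(mol, coords)
phi = measure(conf, cvs[0])
print(f"starting dihedral about the rotatable bond: {phi:.1f} degrees")
# this is the angle a torsion scan would use as its grid origin
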