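"""Build a grid free-energy map, write/read it as OpenDX, and score a pose.

A FragMap stores, per voxel, the binding free energy of a chemical probe
type (apolar carbon, H-bond donor, ...). A ligand pose is scored by summing,
over its classified heavy atoms, the GFE of the voxel each atom occupies.
"""

import tempfile
from pathlib import Path

import numpy as np

from fragdock import (
    Conformer,
    boltzmann_transform,
    lgfe,
    read_gfe_map,
    write_gfe_map,
)
from fragdock.synthetic import build_chain_ligand, single_well_map

# Boltzmann transform: probability 2x bulk → favorable GFE; empty voxel → cap
probs = np.array([2.0, 1.0, 0.5, 0.0])
print("probabilities:", probs)
print("GFE (kcal/mol):", np.round(boltzmann_transform(probs, temperature=300.0), 4))
# -0.4132 means a probe is twice as likely there as in bulk; 3.0 is the
# penalty cap for never-visited voxels.

# A synthetic apolar map: one Gaussian well of depth -6 kcal/mol at the origin
maps = single_well_map(map_type="GENN", depth=-6.0, width=2.5)
with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "demo.GENN.dx"
    write_gfe_map(maps["GENN"], path)
    grid = read_gfe_map(path)
print("\nround-tripped grid:", grid.map_type, grid.dims, "min =", round(grid.values.min(), 3))

# Score a 3-carbon chain sitting across the well center
lig, assignment = build_chain_ligand("propane-like", ["GENN", "GENN", "GENN"])
conf = Conformer(lig, lig.coords - lig.coords.mean(axis=0))  # center on the well
score = lgfe(conf, assignment, maps)
print("LGFE of centered chain: %.3f kcal/mol" % score)
# More negative = better predicted binding; each atom contributes the GFE of
# the voxel it occupies.
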