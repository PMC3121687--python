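"""Membrane-mediated dimerization of two peripheral membrane proteins.

Places two long-anchor proteins (anchor longer than the leaflet is thick)
in the same leaflet of a small bilayer patch, just outside contact, and
tracks their minimum bead-bead distance through a production run. The
contact occupancy is compared with the areal-fraction null expectation
for non-interacting disks: a large excess is the signature of the
membrane-mediated attraction (no direct protein-protein attraction exists
in the force field). Takes several minutes.
"""

import numpy as np

from memdpd import (DPDSimulation, MembraneSpec, ProteinSpec,
                    assemble_bilayer, detect_clusters, insert_protein)
from memdpd.pmf import _min_interprotein_distance
from memdpd.run import equilibrate

state, topo, ff = assemble_bilayer(MembraneSpec(nx=12, ny=12,
                                                box_height=10.0), seed=1)
pspec = ProteinSpec(side_beads=3, n_hydrophobic_layers=5, leaflet="upper")
cx, cy = state.box[0] / 2, state.box[1] / 2
state, topo, mol_a = insert_protein(state, topo, pspec, (cx - 1.5, cy),
                                    seed=101)
state, topo, mol_b = insert_protein(state, topo, pspec, (cx + 1.5, cy),
                                    seed=202)
beads = {0: state.molecule_indices(mol_a), 1: state.molecule_indices(mol_b)}

sim = DPDSimulation(state, ff, topo, seed=1)
equilibrate(sim, 6000)

frames, dists = [], []
for k in range(400):
    sim.step(25)
    dists.append(_min_interprotein_distance(sim.state, beads[0], beads[1]))
    if k % 10 == 0:
        frames.append(sim.state.copy())

dists = np.array(dists[40:])                  # discard burn-in
occupancy = (dists < 1.0).mean()
r_contact = 2 * 0.9 + 1.0
null = np.pi * r_contact ** 2 / (sim.state.box[0] * sim.state.box[1])
print(f"contact occupancy: {occupancy:.2f}   non-interacting null: {null:.2f}")

ts = detect_clusters(frames, beads, cutoff=1.0)
dimer = ts.lifetimes.get(frozenset({0, 1}), 0)
print(f"longest dimer interval: {dimer} of {len(frames)} sampled frames")
print("Occupancy far above the null means the bilayer itself glues the")
print("proteins together: relieving the local membrane perturbation pays")
print("for the lost translational entropy.")
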