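"""Membrane perturbation profile around an embedded peripheral protein.

Inserts a hexagonal-cylinder protein (19 beads per layer, 3-layer
hydrophobic anchor) into the upper leaflet of a bilayer patch, runs a
short production, and prints the radial profile of bilayer thickness and
order parameter around the protein axis, plus the protein's tilt. The
far-field bins recover the unperturbed values; bins near the protein show
the local deformation that drives membrane-mediated attraction.
Takes a few minutes.
"""

import numpy as np

from memdpd import (DPDSimulation, MembraneSpec, ProteinSpec,
                    assemble_bilayer, bilayer_profiles, insert_protein,
                    protein_tilt)
from memdpd.run import equilibrate, produce

state, topo, ff = assemble_bilayer(MembraneSpec(nx=12, ny=12,
                                                box_height=10.0), seed=3)
pspec = ProteinSpec(side_beads=3, n_hydrophobic_layers=3, leaflet="upper")
state, topo, mol = insert_protein(state, topo, pspec,
                                  (state.box[0] / 2, state.box[1] / 2),
                                  seed=4)
sim = DPDSimulation(state, ff, topo, seed=5)
equilibrate(sim, 12000)
frames = produce(sim, 6000, output_interval=100)

prof = bilayer_profiles(frames, protein_molecule=mol, bin_width=0.75)
print(" r      d     h_up   h_lo   coup   S_up   S_lo   n")
for k in range(len(prof.bin_centers)):
    if prof.counts[k] > 50:
        print(f"{prof.bin_centers[k]:4.2f}  {prof.d[k]:5.2f}  "
              f"{prof.h_upper[k]:5.2f}  {prof.h_lower[k]:5.2f}  "
              f"{prof.coupling[k]:5.2f}  {prof.S_upper[k]:5.2f}  "
              f"{prof.S_lower[k]:5.2f}  {int(prof.counts[k]):5d}")

tilt = protein_tilt(frames, mol)
print(f"\nprotein tilt: {tilt.mean_deg:.1f} +- {tilt.std_deg:.1f} deg")
print("Thickness and order deviate near the protein (small r) and relax")
print("to the unperturbed far-field values at large r.")
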