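"""Assemble a lipid bilayer patch and relax it to zero lateral tension.

A 10x10-lipid-per-leaflet patch of H(head)+3T(tail) lipids is built on a
grid, equilibrated with the area barostat, and its structural observables
are printed: the head-to-head bilayer thickness d, the leaflet thickness h
(head center to terminal tail center), the inter-leaflet distance, and the
lipid orientational order parameter S. Takes a couple of minutes.
"""

from memdpd import DPDSimulation, MembraneSpec, assemble_bilayer, bilayer_profiles
from memdpd.run import equilibrate

spec = MembraneSpec(nx=10, ny=10, box_height=10.0)
state, topo, ff = assemble_bilayer(spec, seed=7)
print(f"assembled {state.n_beads} beads in a "
      f"{state.box[0]:.1f} x {state.box[1]:.1f} x {state.box[2]:.1f} box")

sim = DPDSimulation(state, ff, topo, seed=7)
eq = equilibrate(sim, 25000)
print(f"tension after equilibration: {eq.final_tension:+.3f} k_BT/r_c^2")
print(f"area per lipid: {sim.state.box[0] * sim.state.box[1] / 100:.3f} r_c^2")

prof = bilayer_profiles([sim.state], bin_width=50.0)  # one global bin
print(f"bilayer thickness d        = {prof.d[0]:.2f} r_c")
print(f"leaflet thickness h        = {0.5 * (prof.h_upper[0] + prof.h_lower[0]):.2f} r_c")
print(f"inter-leaflet distance     = {prof.coupling[0]:.2f} r_c")
print(f"order parameter S          = {0.5 * (prof.S_upper[0] + prof.S_lower[0]):.2f}")
print("S well above 0 but below 1 indicates an ordered yet fluid bilayer;")
print("d = h_upper + h_lower + coupling holds exactly by construction.")
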