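# Methods

## Model

The system is a standard DPD fluid of soft beads at global density
ρ = 3 r_c⁻³, with three chemistry classes: water (W), hydrophilic (lipid
heads H/H2, protein caps PH) and hydrophobic (lipid tails T/T2, protein
anchors PT). Beads closer than the cutoff r_c interact through three
pairwise forces:

* conservative soft repulsion `F_C = a_ij (1 − r/r_c) r̂`, with a_ij = 25
  between beads of the same hydrophobicity class and 100 across classes —
  the standard parameterization at ρ = 3, where a = 25 reproduces water
  compressibility. The hydrophobic/hydrophilic contrast (100) is what
  drives bilayer self-organization and protein anchoring.
* dissipative force `−γ w(r)² (r̂·v_ij) r̂` with γ = 4.5 and
  w(r) = 1 − r/r_c;
* random force `σ w(r) ζ r̂ / √dt` with σ = √(2 γ k_BT) = 3 fixed by
  fluctuation–dissipation; ζ is a zero-mean unit-variance draw shared by
  the pair.

These defaults are the widely used DPD literature convention; every value
is configurable and recorded in the run manifest. In two-lipid-species
membranes all repulsions between beads of the two lipid species are
amplified by 1.2 to induce demixing; lipid–water and lipid–protein
amplitudes are untouched.

Lipids are linear H–Tₙ chains (standard n = 3, long species n = 5, chosen
two beads longer so the long species forms a visibly thicker domain)
bonded by `½ k_bond (r − l₀)²` with k_bond = 100 k_BT/r_c², l₀ = 0.45 r_c,
and straightened by the three-point potential `½ k_bend (θ − π)²` with
k_bend = 20 k_BT. The ½-prefactor convention is used for both harmonic
terms throughout.

Proteins are hexagonal cylinders: one hydrophilic cap layer plus L
hydrophobic layers, each layer a triangular-lattice hexagon with
`3s² − 3s + 1` beads for s beads per side, lattice spacing l₀. Every
intra-protein pair closer than 1.5 l₀ is connected by a spring at its
built distance. The 1.5 l₀ cutoff deliberately includes the inter-layer
diagonals: with in-layer and vertical springs only, the layer stack would
be shear-floppy, while the diagonal springs make the body rigid (radius of
gyration varies by ~3% in production runs) without needing angle terms —
consistent with treating the protein as a compact folded object.

## Integration and thermostat quality

Equations of motion use the modified velocity-Verlet scheme
(position update with current forces, single force re-evaluation at the
predicted velocity v + λ dt f with λ = 0.5, half-step velocity
correction), dt = 0.02 reduced time. The random-force 1/√dt scaling is
applied inside the force so the integrator treats all forces uniformly.
At these settings a 3000-bead homogeneous fluid holds ⟨T_kin⟩ within ~1%
of the k_BT = 1 target and total momentum is conserved to ~10⁻¹³ per
10³ steps.

Random numbers are counter-based: the noise for pair (i, j) at step t is a
splitmix64 hash of (seed, t, min(i,j), max(i,j)), mapped to a uniform
variate scaled to zero mean and unit variance (only the first two moments
matter for the thermostat). Trajectories are therefore bit-reproducible
for a given seed and independent of the order in which the cell walk
enumerates pairs. The neighbor search counting-sorts beads into cells of
edge ≥ r_c and walks a 13-offset half shell with precomputed periodic
shifts; boxes too small for three cells per dimension fall back to an
all-pairs loop. Both paths are tested against a brute-force reference.

## Tension and the tensionless state

The lateral tension is measured by the virial route,
γ_s = L_z (P_zz − (P_xx + P_yy)/2), with the full pairwise + bonded virial
accumulated in the force pass (the dissipative/random contributions enter
too; their time average is indistinguishable from the conservative-only
estimate in practice). During equilibration a Berendsen-style area
feedback runs every 50 steps on the block-averaged tension: the lateral
area is rescaled by 1 − g(γ_s − γ_target) with gain g = 2·10⁻³, z rescaled
to conserve volume, linear scale clamped to [0.99, 1.01] per call. Under
active feedback the long-window mean tension settles to 0 within ±0.02
k_BT/r_c² (seed-to-seed spread), comfortably inside the ±0.1 band used by
the tests.

With these parameters the tensionless state of the H+3T membrane sits at a
projected area per lipid of ≈ 0.68 r_c² (bilayer thickness d ≈ 3.4 r_c,
leaflet thickness ≈ 1.5 r_c, order parameter S ≈ 0.65–0.7 — ordered yet
fluid). Assembly starts from 1.25 r_c² per site and the barostat walks the
patch down; the membrane is transiently porous above ~1.1 r_c² on the way,
which is harmless during equilibration. The L = 3 anchor
(3·0.45 ≈ 1.35 r_c) approximately matches the leaflet thickness; L = 5
(2.25 r_c) penetrates the opposing leaflet — the regime with the strongest
membrane-mediated attraction.

## Analysis definitions

* Frames are recentered in z using the circular mean of terminal tail
  beads, so a drifting bilayer never straddles the periodic boundary. The
  midplane is global per frame (adequate for small tensionless patches,
  not for strongly undulating ones).
* Leaflet assignment: sign of (head z − midplane).
* Radial profiles assign a lipid to a bin by its head bead's lateral
  minimum-image distance to the protein axis (bin width 0.5 r_c default).
  Per bin, d = mean head z (upper) − mean head z (lower); h = head −
  terminal-tail within the leaflet; coupling = terminal-tail across
  leaflets. The identity d = h_up + h_lo + coupling holds exactly because
  all three are differences of the same per-bin means. Empty bins carry
  count 0 and NaN.
* Order parameter: P2 form S = (3⟨cos²θ⟩ − 1)/2 of the head→terminal-tail
  director against the z axis — 1 when parallel, 0 for random
  orientations, matching the stated extremes; ⟨|cos θ|⟩ is reported
  alongside in case a different functional convention is wanted.
* Protein tilt: angle between z and the vector from the cap-layer centroid
  to the centroid of all anchor beads. Both centroids lie on the symmetry
  axis in any rigid-body orientation, so the definition is exact under
  rotation and immune to the degenerate inertia tensor of wide flat
  proteins. Angles are folded into [0°, 90°].
* Tracks: per-frame lateral COM, unwrapped by minimum-image increments;
  a per-frame displacement above half the box is a sampling-rate error.
* MSD: time-averaged over all start points (FFT evaluation); D from a
  through-origin fit of MSD = 4Dt over lags in 10–25% of the maximum lag,
  with max lag defaulting to n/100 samples. Keeping the fitted lags short
  relative to the track bounds the single-trajectory statistical error of
  the time-averaged MSD (which grows like √(lag/n)) to the few-percent
  level; fitting at lags of 10–25% of the full track length would carry
  ~50% statistical error and is deliberately not done.
* Saffman–Delbrück fits use μ_w and μ_m·h as the two free parameters with
  initial guesses from the exact log-linear structure (slope of D vs ln R
  fixes μ_m·h). Diffusion coefficients may be absolute or normalized by
  the lipid D; the normalization is absorbed by the parameters.

## Free-energy pipeline

Umbrella windows restrain the in-plane COM distance with
`½ k_u (r − r_i)²` (defaults k_u = 50 k_BT/r_c², spacing 0.25 r_c),
distributing the generalized force uniformly over each protein's beads,
equal and opposite so no net momentum enters. WHAM iterates the standard
self-consistency equations to 10⁻¹⁰ on the window free energies; adjacent
windows must have overlapping sample support (a gap is an error naming the
interval). Because r is a 2-D radial coordinate, the default output applies
the Jacobian correction W = −k_BT ln P + k_BT ln r + C; whether the
original analysis used it is not determinable, so both variants are
always emitted and a flag disables the correction (the known-generator
oracle samples a 1-D density and is checked with the correction off). The
zero level is the mean over the outer 20% of the sampled range; the
binding energy is −min W, the well width the contiguous extent below
−1 k_BT (threshold configurable). Block bootstrap over window time series
(200 resamples, 50-sample blocks) supplies ΔE uncertainties.

Escape times integrate the overdamped double integral on the tabulated
PMF by composite trapezoid on a 4000-point refined grid, from the well
minimum a to the first zero-level crossing b, with a reflecting boundary
at the inner edge of the sampled range (hard-core contact). The D entering
τ defaults to the single-protein diffusion coefficient (the relative
coefficient D₁+D₂ can be passed instead; the choice is left to the caller
since either convention appears in the literature). The quadrature is
validated three ways: the flat-potential closed form L²/2D (exact), an
independent Euler–Maruyama first-passage simulation (10⁴ walkers, within
10%), and the Kramers scaling laws — quadratic in well width (exact under
dilation) and exponential in depth, with the asymptotic Arrhenius slope
d ln τ/dE → 1/k_BT checked at depths 6–12 k_BT where the ~1/√E prefactor
correction is small (at 3–6 k_BT the measured slope is ~0.8, which is the
expected finite-depth correction, not an error).

Clusters: proteins are graph vertices, connected when the minimum
bead–bead distance (full 3-D minimum image, so stacked cross-leaflet pairs
qualify) is below 1.0 r_c; clusters are connected components and a
composition's lifetime is its longest contiguous run of frames.

## Synthetic-data generators and what they do (not) show

The fixture module produces bilayer frames with prescribed head/tail
planes and imposed radial deflections, Brownian tracks with known D,
Metropolis samples of known biased densities, and rigid bodies at known
orientations. They validate the *estimators* — binning, unwrapping, MSD,
WHAM, quadrature — against closed-form truth, independent of the DPD
engine. They do not emulate correlated lipid motion, undulations, or
finite sampling of a real trajectory, so passing the oracle tests shows
estimator correctness, not simulation realism; the end-to-end tests
(thermostat, tensionless equilibration, protein dimerization) cover the
latter qualitatively at deliberately modest problem sizes: 10×10 to 14×14
lipids per leaflet, 20–50k equilibration steps, 5–20k production steps —
sizes chosen so the whole validation chain runs on a single CPU while
still exhibiting every qualitative regime of interest.

## Numerical choices and degenerate inputs

* Angle forces regularize 1/sin θ at θ → π; the bending force stays finite
  and smooth there because (θ − θ₀) vanishes simultaneously.
* A zero-length pair displacement is a degenerate-geometry error in the
  API-level force functions and is skipped (no force) inside the kernels,
  where the soft core makes exact coincidence a measure-zero transient.
* The umbrella bias at r = 0 with r_i > 0 picks a random in-plane
  direction (logged).
* WHAM bins with zero samples propagate as NaN and are excluded from the
  zero level, the well search and RMS comparisons.
* The barostat clamps the per-call linear scale to [0.99, 1.01] and logs
  clamping; a negative proposed area is replaced by the clamp floor.
* Protein insertion evicts lipids whose head falls in the extended
  hexagonal footprint of the host leaflet *and* any lipid with a bead
  within 0.5 r_c of a protein bead (long anchors reach into the opposing
  leaflet, which the footprint rule alone would miss), plus waters within
  0.8 r_c.

## Known limitations

* No electrostatics, no explicit water structure, no curvature/undulation
  spectra: geometric and hydrodynamic effects only.
* The global-midplane assumption breaks for strongly undulating or curved
  membranes.
* Periodic-image hydrodynamic corrections to D are not applied; absolute
  diffusion coefficients in small boxes are suppressed relative to the
  infinite-system value (relative comparisons across radii remain
  meaningful).
* The tensionless area per lipid (~0.68 r_c²) is a property of the chosen
  literature-standard parameter set; a different a_ij/bond parameterization
  shifts all structural numbers.
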