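"""Construct lipids, hexagonal-cylinder proteins and bilayer patches.

Lipids are linear H-T_n polymers (single hydrophilic head, n hydrophobic
tail beads; the standard lipid has three, the "long" second species five).
Peripheral membrane proteins are hexagonal cylinders: one hydrophilic cap
layer plus L hydrophobic anchor layers, each layer a triangular-lattice
hexagon with ``3 s^2 - 3 s + 1`` beads for ``s`` beads per side. All
intra-protein bead pairs closer than 1.5 bond lengths are connected by
harmonic springs (in-layer neighbors, vertical inter-layer neighbors and
the inter-layer diagonals), which makes the body rigid without angle terms.

Bilayers are pre-assembled: two opposed leaflets on a jittered lateral
grid, tails toward the midplane, water filling the rest of the box to the
global bead density. A protein is inserted with its cap at the head-group
plane of the chosen leaflet, anchor pointing at the midplane, evicting
overlapping lipids and waters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forcefield import SPECIES_INDEX, ForceFieldParams, default_interaction_matrix
from .state import MOL_LIPID, MOL_LIPID_LONG, MOL_PROTEIN, MOL_WATER, SimulationState
from .topology import (DEFAULT_K_BEND, DEFAULT_K_BOND, DEFAULT_L0,
                       DEFAULT_THETA0, Topology)

__all__ = [
    "LipidSpec", "ProteinSpec", "MembraneSpec", "MoleculeBuild",
    "hexagon_layer", "hexagon_bead_count", "build_lipid", "build_protein",
    "assemble_bilayer", "insert_protein",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LipidSpec:
    n_tail: int = 3
    species_tag: str = "standard"   # "standard" or "long"

    def __post_init__(self):
        if self.n_tail < 1:
            raise ValueError("lipids need at least one tail bead")
        if self.species_tag not in ("standard", "long"):
            raise ValueError("species_tag must be 'standard' or 'long'")


@dataclass(frozen=True)
class ProteinSpec:
    side_beads: int = 2           # beads per hexagon side; sets the radius
    n_hydrophobic_layers: int = 3  # anchor length L
    leaflet: str = "upper"

    def __post_init__(self):
        if self.side_beads < 1:
            raise ValueError("side_beads must be >= 1")
        if self.n_hydrophobic_layers < 1:
            raise ValueError("need at least one hydrophobic layer")
        if self.leaflet not in ("upper", "lower"):
            raise ValueError("leaflet must be 'upper' or 'lower'")

    @property
    def beads_per_layer(self) -> int:
        return hexagon_bead_count(self.side_beads)


@dataclass(frozen=True)
class MembraneSpec:
    nx: int = 12
    ny: int = 12
    fraction_long: float = 0.0      # fraction of long lipids in the upper leaflet
    asymmetric: bool = True
    cross_species_factor: float = 1.2
    n_tail: int = 3
    n_tail_long: int = 5
    area_per_lipid: float = 1.25    # initial; barostat relaxes it
    box_height: float = 10.0

    def __post_init__(self):
        if not (0.0 <= self.fraction_long <= 1.0):
            raise ValueError("fraction_long must be in [0, 1]")
        if self.n_tail_long <= self.n_tail:
            raise ValueError("long lipid must have strictly more tail beads")


@dataclass
class MoleculeBuild:
    """A molecule template: positions relative to its own origin."""
    positions: np.ndarray
    species: np.ndarray
    topology: Topology


def hexagon_bead_count(side: int) -> int:
    return 3 * side * side - 3 * side + 1


def hexagon_layer(side: int, spacing: float) -> np.ndarray:
    """Triangular-lattice hexagon (axial coordinates), centered at 0."""
    s = side - 1
    pts = []
    for q in range(-s, s + 1):
        for r in range(-s, s + 1):
            if abs(q + r) <= s:
                pts.append((spacing * (q + 0.5 * r),
                            spacing * (np.sqrt(3.0) / 2.0) * r))
    return np.array(pts, dtype=np.float64).reshape(-1, 2)


def build_lipid(
    spec: LipidSpec,
    l0: float = DEFAULT_L0,
    k_bond: float = DEFAULT_K_BOND,
    k_bend: float = DEFAULT_K_BEND,
    theta0: float = DEFAULT_THETA0,
) -> MoleculeBuild:
    """Straight H-T_n chain along -z, head at the origin."""
    n = spec.n_tail
    pos = np.zeros((n + 1, 3))
    pos[:, 2] = -l0 * np.arange(n + 1)
    if spec.species_tag == "standard":
        sp = [SPECIES_INDEX["H"]] + [SPECIES_INDEX["T"]] * n
    else:
        sp = [SPECIES_INDEX["H2"]] + [SPECIES_INDEX["T2"]] * n
    bonds = np.column_stack([np.arange(n), np.arange(1, n + 1)])
    bond_params = np.tile([k_bond, l0], (n, 1))
    if n >= 2:
        angles = np.column_stack([np.arange(n - 1), np.arange(1, n),
                                  np.arange(2, n + 1)])
        angle_params = np.tile([k_bend, theta0], (n - 1, 1))
    else:
        angles = np.empty((0, 3), dtype=np.int64)
        angle_params = np.empty((0, 2))
    return MoleculeBuild(
        positions=pos,
        species=np.array(sp, dtype=np.int64),
        topology=Topology(bonds=bonds, bond_params=bond_params,
                          angles=angles, angle_params=angle_params),
    )


def build_protein(
    spec: ProteinSpec,
    l0: float = DEFAULT_L0,
    k_bond: float = DEFAULT_K_BOND,
) -> MoleculeBuild:
    """Hexagonal cylinder: cap layer at z = 0, anchor layers below.

    Every intra-protein pair closer than ``1.5 * l0`` is bonded with the
    standard spring constant at its built distance, yielding a rigid
    compact body (radius of gyration stays within a few percent during a
    run).
    """
    layer = hexagon_layer(spec.side_beads, l0)
    nl = layer.shape[0]
    n_layers = spec.n_hydrophobic_layers + 1
    pos = np.zeros((n_layers * nl, 3))
    sp = np.empty(n_layers * nl, dtype=np.int64)
    for k in range(n_layers):
        sl = slice(k * nl, (k + 1) * nl)
        pos[sl, :2] = layer
        pos[sl, 2] = -l0 * k
        sp[sl] = SPECIES_INDEX["PH"] if k == 0 else SPECIES_INDEX["PT"]
    d = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    ii, jj = np.nonzero((r > 1e-9) & (r < 1.5 * l0))
    keep = ii < jj
    bonds = np.column_stack([ii[keep], jj[keep]])
    bond_params = np.column_stack([np.full(bonds.shape[0], k_bond),
                                   r[ii[keep], jj[keep]]])
    return MoleculeBuild(
        positions=pos, species=sp,
        topology=Topology(bonds=bonds, bond_params=bond_params),
    )


def assemble_bilayer(
    spec: MembraneSpec,
    ff: ForceFieldParams | None = None,
    rho: float = 3.0,
    seed: int = 1,
    l0: float = DEFAULT_L0,
    jitter: float = 0.1,
) -> tuple[SimulationState, Topology, ForceFieldParams]:
    """Pre-assembled two-leaflet bilayer patch plus filling water.

    Returns ``(state, topology, forcefield)``; the returned force field has
    the cross-lipid-species repulsions amplified by
    ``spec.cross_species_factor`` when long lipids are present.
    """
    rng = np.random.default_rng(seed)
    dx = np.sqrt(spec.area_per_lipid)
    lx, ly, lz = spec.nx * dx, spec.ny * dx, spec.box_height
    box = np.array([lx, ly, lz])
    zmid = lz / 2.0
    n_sites = spec.nx * spec.ny
    n_long = int(round(spec.fraction_long * n_sites))
    long_sites = set(rng.choice(n_sites, size=n_long, replace=False).tolist()) \
        if n_long else set()

    std = build_lipid(LipidSpec(spec.n_tail, "standard"), l0=l0)
    lng = build_lipid(LipidSpec(spec.n_tail_long, "long"), l0=l0)

    positions, species, mol_id, mol_kind = [], [], [], []
    topo = Topology()
    mol = 0
    offset = 0
    for leaflet in ("upper", "lower"):
        for site in range(n_sites):
            ix, iy = divmod(site, spec.ny)
            use_long = (leaflet == "upper" and site in long_sites)
            tmpl = lng if use_long else std
            nb = tmpl.positions.shape[0]
            x = (ix + 0.5) * dx + rng.uniform(-jitter, jitter)
            y = (iy + 0.5) * dx + rng.uniform(-jitter, jitter)
            # chain runs head -> terminal tail toward the midplane
            n_tail = nb - 1
            if leaflet == "upper":
                z_head = zmid + 0.15 + n_tail * l0
                z = z_head + tmpl.positions[:, 2]          # template is -z
            else:
                z_head = zmid - 0.15 - n_tail * l0
                z = z_head - tmpl.positions[:, 2]
            p = np.column_stack([np.full(nb, x), np.full(nb, y), z])
            positions.append(p)
            species.append(tmpl.species)
            mol_id.append(np.full(nb, mol))
            mol_kind.append(np.full(nb, MOL_LIPID_LONG if use_long else MOL_LIPID))
            topo = topo.merged(tmpl.topology.shifted(offset))
            offset += nb
            mol += 1

    n_lipid_beads = offset
    n_total = int(round(rho * lx * ly * lz))
    n_water = n_total - n_lipid_beads
    if n_water <= 0:
        raise ValueError(
            f"bead density {rho} infeasible: {n_lipid_beads} lipid beads "
            f"exceed total budget {n_total} for this box")
    # waters go into the two slabs outside the bilayer core
    half_core = spec.n_tail * l0 + 0.4
    wz_top = lz - (zmid + half_core)
    wz_bot = zmid - half_core
    if wz_top <= 0 or wz_bot <= 0:
        raise ValueError("box_height too small for the bilayer core")
    zw = rng.uniform(0.0, wz_top + wz_bot, size=n_water)
    zw = np.where(zw < wz_bot, zw, zw - wz_bot + zmid + half_core)
    pw = np.column_stack([
        rng.uniform(0, lx, size=n_water),
        rng.uniform(0, ly, size=n_water),
        zw,
    ])
    positions.append(pw)
    species.append(np.full(n_water, SPECIES_INDEX["W"], dtype=np.int64))
    mol_id.append(mol + np.arange(n_water))
    mol_kind.append(np.full(n_water, MOL_WATER))

    pos = np.vstack(positions)
    n = pos.shape[0]
    vel = rng.normal(scale=1.0, size=(n, 3))  # k_BT = m = 1
    vel -= vel.mean(axis=0)
    state = SimulationState(
        positions=pos, velocities=vel,
        species=np.concatenate(species),
        molecule_id=np.concatenate(mol_id),
        box=box, mol_kind=np.concatenate(mol_kind),
    )
    if ff is None:
        factor = spec.cross_species_factor if n_long else 1.0
        ff = ForceFieldParams(a=default_interaction_matrix(
            cross_species_factor=factor))
    return state, topo, ff


def insert_protein(
    state: SimulationState,
    topo: Topology,
    spec: ProteinSpec,
    xy: tuple[float, float],
    l0: float = DEFAULT_L0,
    seed: int = 1,
) -> tuple[SimulationState, Topology, int]:
    """Insert a protein at lateral position ``xy`` into the chosen leaflet.

    The hydrophilic cap is placed at the leaflet's mean head-group plane
    with the anchor pointing toward the midplane. Lipids whose head falls
    inside the hexagonal footprint (circumradius + 0.5 r_c) of the host
    leaflet, lipids with any bead within 0.5 r_c of a protein bead, and
    waters within 0.8 r_c of a protein bead are removed. Returns the new
    state, topology and the molecule id of the protein.
    """
    x0, y0 = xy
    if not (0 <= x0 < state.box[0] and 0 <= y0 < state.box[1]):
        raise ValueError("xy must lie inside the box")
    rng = np.random.default_rng(seed)
    head_codes = (SPECIES_INDEX["H"], SPECIES_INDEX["H2"])
    lipid_mask = np.isin(state.mol_kind, (MOL_LIPID, MOL_LIPID_LONG))
    head_mask = lipid_mask & np.isin(state.species, head_codes)
    tail_term = _terminal_tail_mask(state)
    zmid = float(state.positions[tail_term, 2].mean())
    head_z = state.positions[head_mask, 2]
    if spec.leaflet == "upper":
        plane = float(head_z[head_z > zmid].mean())
        zsign = -1.0
    else:
        plane = float(head_z[head_z < zmid].mean())
        zsign = +1.0

    prot = build_protein(spec, l0=l0)
    ppos = prot.positions.copy()
    ppos[:, 2] *= -zsign            # template cap at 0, anchor at -z
    ppos[:, 0] += x0
    ppos[:, 1] += y0
    ppos[:, 2] += plane
    np_beads = ppos.shape[0]

    # eviction masks
    foot_r = l0 * (spec.side_beads - 1) + 0.5
    dxy = state.positions[:, :2] - np.array([x0, y0])
    dxy -= state.box[:2] * np.round(dxy / state.box[:2])
    in_foot = (np.einsum("ij,ij->i", dxy, dxy) < foot_r ** 2)
    host = (state.positions[:, 2] > zmid) if spec.leaflet == "upper" \
        else (state.positions[:, 2] < zmid)
    doomed_mol = set(state.molecule_id[head_mask & in_foot & host].tolist())

    d = state.positions[:, None, :] - ppos[None, :, :]
    d -= state.box * np.round(d / state.box)
    min_d2 = np.einsum("ijk,ijk->ij", d, d).min(axis=1)
    close_lipid = lipid_mask & (min_d2 < 0.5 ** 2)
    doomed_mol |= set(state.molecule_id[close_lipid].tolist())
    doomed = np.isin(state.molecule_id, sorted(doomed_mol))
    doomed |= (state.mol_kind == MOL_WATER) & (min_d2 < 0.8 ** 2)

    keep = ~doomed
    if not np.any(head_mask & host & keep):
        raise ValueError("protein footprint would evict an entire leaflet")

    new_topo = topo.remapped(keep).merged(
        prot.topology.shifted(int(keep.sum())))
    pvel = rng.normal(scale=1.0, size=(np_beads, 3))
    pvel -= pvel.mean(axis=0)
    new_mol = int(state.molecule_id.max()) + 1
    new_state = SimulationState(
        positions=np.vstack([state.positions[keep], ppos]),
        velocities=np.vstack([state.velocities[keep], pvel]),
        species=np.concatenate([state.species[keep], prot.species]),
        molecule_id=np.concatenate([state.molecule_id[keep],
                                    np.full(np_beads, new_mol)]),
        box=state.box.copy(),
        time=state.time,
        mol_kind=np.concatenate([state.mol_kind[keep],
                                 np.full(np_beads, MOL_PROTEIN)]),
        images=np.vstack([state.images[keep],
                          np.zeros((np_beads, 3), dtype=np.int64)]),
    )
    log.info("inserted protein (side=%d, L=%d, %s leaflet): removed %d beads",
             spec.side_beads, spec.n_hydrophobic_layers, spec.leaflet,
             int(doomed.sum()))
    return new_state, new_topo, new_mol


def _terminal_tail_mask(state: SimulationState) -> np.ndarray:
    """Mask of the last (terminal) tail bead of every lipid molecule.

    Relies on lipid beads being contiguous and head-first within a
    molecule, which all builders guarantee.
    """
    lipid = np.isin(state.mol_kind, (MOL_LIPID, MOL_LIPID_LONG))
    idx = np.flatnonzero(lipid)
    if idx.size == 0:
        return np.zeros(state.n_beads, dtype=bool)
    mid = state.molecule_id[idx]
    last = np.ones(idx.size, dtype=bool)
    last[:-1] = mid[1:] != mid[:-1]
    mask = np.zeros(state.n_beads, dtype=bool)
    mask[idx[last]] = True
    return mask
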