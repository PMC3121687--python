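"""Membrane perturbation observables as radial profiles around a protein.

A peripheral membrane protein deforms the host bilayer locally; the
deformation is characterized by four per-bin quantities measured as a
function of lateral distance from the protein axis:

* ``d`` -- bilayer thickness: mean head-center z of the upper leaflet minus
  that of the lower leaflet;
* ``h_upper`` / ``h_lower`` -- leaflet thickness: head center to terminal
  tail-bead center within the leaflet;
* ``coupling`` -- inter-leaflet distance: terminal tail centers across
  leaflets.

By construction ``d = h_upper + h_lower + coupling`` holds exactly per bin.
The lipid orientational order parameter is the P2-style
``S = (3 <cos^2 theta> - 1) / 2`` of the head-to-terminal-tail director
against the bilayer normal (1 for perfect alignment, 0 for random
orientation); the plain ``<|cos theta|>`` is reported alongside for
robustness against the functional-form choice.

Frames are recentered in z by the circular mean of the terminal tail beads
so the midplane never straddles the periodic boundary; the midplane is a
single global plane per frame (adequate for small tensionless patches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builders import _terminal_tail_mask
from .forcefield import SPECIES_INDEX
from .state import MOL_LIPID, MOL_LIPID_LONG, SimulationState

__all__ = [
    "MembraneProfile", "TiltResult",
    "assign_leaflets", "bilayer_profiles", "order_parameter", "protein_tilt",
    "recenter_z", "lipid_head_tail_indices",
]

_HEAD_CODES = None


def _head_codes():
    global _HEAD_CODES
    if _HEAD_CODES is None:
        _HEAD_CODES = (SPECIES_INDEX["H"], SPECIES_INDEX["H2"])
    return _HEAD_CODES


@dataclass
class MembraneProfile:
    bin_centers: np.ndarray
    d: np.ndarray
    h_upper: np.ndarray
    h_lower: np.ndarray
    coupling: np.ndarray
    S_upper: np.ndarray
    S_lower: np.ndarray
    abs_cos_upper: np.ndarray
    abs_cos_lower: np.ndarray
    counts: np.ndarray


@dataclass
class TiltResult:
    angles_deg: np.ndarray   # per frame, folded into [0, 90]
    mean_deg: float
    std_deg: float


def recenter_z(state: SimulationState) -> np.ndarray:
    """Positions with the bilayer midplane shifted to box-center z.

    The midplane is the circular mean of terminal tail-bead z, so a
    bilayer drifting across the periodic z boundary is handled correctly.
    Returns a copy; x/y are untouched.
    """
    pos = state.positions.copy()
    lz = state.box[2]
    term = _terminal_tail_mask(state)
    if not term.any():
        return pos
    ang = pos[term, 2] / lz * 2.0 * np.pi
    zmid = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi) * lz
    pos[:, 2] = (pos[:, 2] - zmid + lz / 2.0) % lz
    return pos


def lipid_head_tail_indices(state: SimulationState) -> tuple[np.ndarray, np.ndarray]:
    """(head bead index, terminal tail bead index) per lipid molecule."""
    heads = np.flatnonzero(
        np.isin(state.mol_kind, (MOL_LIPID, MOL_LIPID_LONG))
        & np.isin(state.species, _head_codes()))
    tails = np.flatnonzero(_terminal_tail_mask(state))
    return heads, tails


def assign_leaflets(state: SimulationState) -> np.ndarray:
    """Per-lipid leaflet label (+1 upper, -1 lower).

    A lipid belongs to the upper leaflet when its head bead lies above the
    midplane (mean z of all terminal tail beads). Invariant under global
    translation because the frame is recentered first.
    """
    pos = recenter_z(state)
    heads, _ = lipid_head_tail_indices(state)
    zmid = state.box[2] / 2.0
    return np.where(pos[heads, 2] > zmid, 1, -1)


def _protein_axis_xy(state: SimulationState, pos: np.ndarray,
                     molecule: int | None) -> np.ndarray:
    if molecule is None:
        return state.box[:2] / 2.0
    idx = state.molecule_indices(molecule)
    p = pos[idx, :2]
    ref = p[0]
    d = p - ref
    d -= state.box[:2] * np.round(d / state.box[:2])
    return (ref + d.mean(axis=0)) % state.box[:2]


def bilayer_profiles(
    frames,
    protein_molecule: int | None = None,
    bin_width: float = 0.5,
    r_max: float | None = None,
) -> MembraneProfile:
    """Time-averaged radial membrane profile around the protein axis.

    ``protein_molecule = None`` uses the box center as the axis (the
    protein-free reference). Lipids are assigned to radial bins by the
    lateral minimum-image distance of their head bead to the axis; empty
    bins carry count 0 and NaN values. Far-field bins give the unperturbed
    reference.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    if r_max is None:
        r_max = float(min(frames[0].box[0], frames[0].box[1])) / 2.0
    nbins = max(1, int(np.ceil(r_max / bin_width)))
    sums = {k: np.zeros(nbins) for k in
            ("zh_up", "zt_up", "zh_lo", "zt_lo", "c2_up", "c2_lo",
             "ac_up", "ac_lo")}
    n_up = np.zeros(nbins)
    n_lo = np.zeros(nbins)

    for state in frames:
        pos = recenter_z(state)
        heads, tails = lipid_head_tail_indices(state)
        zmid = state.box[2] / 2.0
        upper = pos[heads, 2] > zmid
        axis = _protein_axis_xy(state, pos, protein_molecule)
        dxy = pos[heads, :2] - axis
        dxy -= state.box[:2] * np.round(dxy / state.box[:2])
        r = np.sqrt(np.einsum("ij,ij->i", dxy, dxy))
        b = np.minimum((r / bin_width).astype(int), nbins - 1)
        ok = r < r_max
        # director: head - terminal tail (minimum image)
        dvec = pos[heads] - pos[tails]
        dvec -= state.box * np.round(dvec / state.box)
        norm = np.linalg.norm(dvec, axis=1)
        cz = np.abs(dvec[:, 2]) / np.where(norm > 0, norm, 1.0)
        for leaf, nacc, tag in ((upper, n_up, "up"), (~upper, n_lo, "lo")):
            sel = ok & leaf
            bb = b[sel]
            np.add.at(nacc, bb, 1.0)
            np.add.at(sums[f"zh_{tag}"], bb, pos[heads[sel], 2])
            np.add.at(sums[f"zt_{tag}"], bb, pos[tails[sel], 2])
            np.add.at(sums[f"c2_{tag}"], bb, cz[sel] ** 2)
            np.add.at(sums[f"ac_{tag}"], bb, cz[sel])

    with np.errstate(invalid="ignore", divide="ignore"):
        zh_up = sums["zh_up"] / n_up
        zt_up = sums["zt_up"] / n_up
        zh_lo = sums["zh_lo"] / n_lo
        zt_lo = sums["zt_lo"] / n_lo
        s_up = 0.5 * (3.0 * sums["c2_up"] / n_up - 1.0)
        s_lo = 0.5 * (3.0 * sums["c2_lo"] / n_lo - 1.0)
        ac_up = sums["ac_up"] / n_up
        ac_lo = sums["ac_lo"] / n_lo
    centers = (np.arange(nbins) + 0.5) * bin_width
    return MembraneProfile(
        bin_centers=centers,
        d=zh_up - zh_lo,
        h_upper=zh_up - zt_up,
        h_lower=zt_lo - zh_lo,
        coupling=zt_up - zt_lo,
        S_upper=s_up, S_lower=s_lo,
        abs_cos_upper=ac_up, abs_cos_lower=ac_lo,
        counts=n_up + n_lo,
    )


def order_parameter(directors: np.ndarray, normal=(0.0, 0.0, 1.0)) -> float:
    """P2 order parameter of a set of director vectors against ``normal``.

    ``S = (3 <cos^2 theta> - 1) / 2``: 1 when all directors are parallel
    to the normal, 0 for directions uniform on the (hemi)sphere.
    """
    d = np.asarray(directors, dtype=np.float64)
    n = np.asarray(normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    c = d @ n / np.linalg.norm(d, axis=1)
    return float(0.5 * (3.0 * np.mean(c * c) - 1.0))


def protein_tilt(frames, molecule: int) -> TiltResult:
    """Tilt of the protein axis against the bilayer normal, per frame.

    The axis of the hexagonal cylinder is the vector from the centroid of
    the hydrophilic cap layer to the centroid of the whole hydrophobic
    anchor -- both centroids lie on the symmetry axis for any rigid-body
    orientation, so the definition is exact under rotation and needs no
    inertia tensor (which is degenerate for wide, flat proteins). The
    angle to the bilayer normal is folded into [0, 90] degrees.
    """
    angles = []
    for state in frames:
        idx = state.molecule_indices(molecule)
        if idx.size == 0:
            raise ValueError(f"molecule {molecule} absent from frame")
        sp = state.species[idx]
        cap_mask = sp == SPECIES_INDEX["PH"]
        body_mask = sp == SPECIES_INDEX["PT"]
        if not cap_mask.any() or not body_mask.any():
            raise ValueError("molecule is not a cap + anchor protein")
        pos = state.positions
        rel = pos[idx] - pos[idx[0]]
        rel -= state.box * np.round(rel / state.box)
        ax = rel[body_mask].mean(axis=0) - rel[cap_mask].mean(axis=0)
        c = abs(ax[2]) / np.linalg.norm(ax)
        angles.append(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    angles = np.asarray(angles)
    return TiltResult(angles_deg=angles, mean_deg=float(angles.mean()),
                      std_deg=float(angles.std()))
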