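"""Synthetic inputs with known ground truth for every analysis stage.

These generators emulate the *outputs* of a DPD run -- bilayer frames with
prescribed geometry, Brownian tracks with a known diffusion coefficient,
biased samples from a known free-energy profile, rigid bodies at a known
orientation -- so each analysis operation can be validated against an
independent, closed-form truth without running any dynamics. Everything is
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit

from .builders import ProteinSpec, build_protein
from .forcefield import SPECIES_INDEX
from .pmf import UmbrellaWindow
from .state import MOL_LIPID, MOL_PROTEIN, SimulationState
from .transport import Track

__all__ = [
    "FixtureFrame", "flat_bilayer_frame", "perturbed_bilayer_frame",
    "brownian_track", "biased_samples_from_known_pmf", "double_well",
    "rotated_rigid_body", "langevin_escape_times", "rotation_matrix",
]


@dataclass
class FixtureFrame:
    """A synthetic frame (or set of frames) plus its ground truth."""
    state: SimulationState
    truth: dict


def _lipid_frame(
    head_z: float,
    tail_z: float,
    n_per_leaflet: int,
    box: np.ndarray,
    seed: int,
    upper_offset: Callable[[np.ndarray], np.ndarray] | None = None,
    tilt_deg: float = 0.0,
) -> FixtureFrame:
    """Two leaflets of 4-bead lipids with prescribed head/tail planes.

    Heads sit at ``zmid +- head_z`` and terminal tails at ``zmid +-
    tail_z`` (intermediate beads interpolated), optionally deflecting the
    whole upper leaflet by ``upper_offset(r)`` of the lateral distance
    from the box center, and optionally tilting every director by
    ``tilt_deg`` about a random azimuth.
    """
    rng = np.random.default_rng(seed)
    n_tail = 3
    zmid = box[2] / 2.0
    xy = np.column_stack([rng.uniform(0, box[0], 2 * n_per_leaflet),
                          rng.uniform(0, box[1], 2 * n_per_leaflet)])
    positions, species, mol_id, kind = [], [], [], []
    length = head_z - tail_z
    theta = np.radians(tilt_deg)
    for m in range(2 * n_per_leaflet):
        upper = m < n_per_leaflet
        s = 1.0 if upper else -1.0
        x, y = xy[m]
        hz, tz = s * head_z, s * tail_z
        if upper and upper_offset is not None:
            r = np.hypot(x - box[0] / 2, y - box[1] / 2)
            off = float(upper_offset(np.array([r]))[0])
            hz += off
            tz += off
        phi = rng.uniform(0, 2 * np.pi)
        # director tilted by theta from the normal, length preserved
        dz = length * np.cos(theta)
        dxy = length * np.sin(theta)
        frac = np.linspace(0.0, 1.0, n_tail + 1)   # head -> terminal tail
        zs = zmid + hz - frac * dz * s
        xs = x + frac * dxy * np.cos(phi)
        ys = y + frac * dxy * np.sin(phi)
        if tilt_deg == 0.0:
            zs = zmid + hz + frac * (tz - hz)
        positions.append(np.column_stack([xs, ys, zs]))
        species.append([SPECIES_INDEX["H"]] + [SPECIES_INDEX["T"]] * n_tail)
        mol_id.append(np.full(n_tail + 1, m))
        kind.append(np.full(n_tail + 1, MOL_LIPID))
    state = SimulationState(
        positions=np.vstack(positions),
        velocities=np.zeros((4 * 2 * n_per_leaflet, 3)),
        species=np.concatenate(species),
        molecule_id=np.concatenate(mol_id),
        box=box.astype(float),
        mol_kind=np.concatenate(kind),
    )
    truth = {
        "d": 2.0 * head_z,
        "h_leaflet": head_z - tail_z,
        "coupling": 2.0 * tail_z,
        "tilt_deg": tilt_deg,
        "S": 0.5 * (3.0 * np.cos(theta) ** 2 - 1.0),
    }
    return FixtureFrame(state=state, truth=truth)


def flat_bilayer_frame(
    head_z: float = 2.0,
    tail_z: float = 0.5,
    n_per_leaflet: int = 200,
    box=(12.0, 12.0, 10.0),
    seed: int = 0,
    tilt_deg: float = 0.0,
) -> FixtureFrame:
    """Flat bilayer with exact head/tail planes (d = 2*head_z, etc.)."""
    return _lipid_frame(head_z, tail_z, n_per_leaflet, np.asarray(box),
                        seed, tilt_deg=tilt_deg)


def perturbed_bilayer_frame(
    deflection: Callable[[np.ndarray], np.ndarray],
    head_z: float = 2.0,
    tail_z: float = 0.5,
    n_per_leaflet: int = 2000,
    box=(20.0, 20.0, 12.0),
    seed: int = 0,
) -> FixtureFrame:
    """Bilayer whose upper leaflet is deflected by ``deflection(r)``.

    The imposed function is attached as ground truth; the recovered
    profile should match it within bin-discretization error.
    """
    fx = _lipid_frame(head_z, tail_z, n_per_leaflet, np.asarray(box), seed,
                      upper_offset=deflection)
    fx.truth["deflection"] = deflection
    return fx


def brownian_track(
    D: float = 0.05,
    n: int = 100000,
    dt: float = 1.0,
    seed: int = 0,
) -> tuple[Track, float]:
    """2-D Brownian track with known diffusion coefficient."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(scale=np.sqrt(2.0 * D * dt), size=(n, 2))
    steps[0] = 0.0
    xy = np.cumsum(steps, axis=0)
    return Track(times=np.arange(n) * dt, xy=xy), D


def double_well(
    r: np.ndarray,
    depth_main: float = 4.0,
    r_main: float = 1.2,
    width_main: float = 0.35,
    depth_side: float = 1.5,
    r_side: float = 2.4,
    width_side: float = 0.3,
) -> np.ndarray:
    """Smooth double-well free-energy profile, zero at large r (k_BT)."""
    r = np.asarray(r, dtype=np.float64)
    return (-depth_main * np.exp(-0.5 * ((r - r_main) / width_main) ** 2)
            - depth_side * np.exp(-0.5 * ((r - r_side) / width_side) ** 2))


def biased_samples_from_known_pmf(
    W: Callable[[np.ndarray], np.ndarray],
    centers: np.ndarray,
    k_u: float = 50.0,
    n_samples: int = 5000,
    seed: int = 0,
    k_BT: float = 1.0,
    r_bounds: tuple[float, float] = (0.05, 8.0),
    n_chains: int = 64,
    burn_in: int = 800,
    thin: int = 10,
    proposal: float = 0.12,
) -> list[UmbrellaWindow]:
    """Metropolis samples from exp(-(W(r) + bias)/k_BT) per window.

    A direct Markov-chain sampler of the 1-D biased densities -- no
    dynamics involved -- used as the known-generator oracle for WHAM.
    ``n_chains`` independent walkers run in lockstep (vectorized); after
    burn-in every ``thin``-th sweep is recorded until ``n_samples`` values
    per window are collected.
    """
    rng = np.random.default_rng(seed)
    windows = []
    for c in np.asarray(centers, dtype=np.float64):
        def logp(r):
            out = np.full_like(r, -np.inf)
            ok = (r > r_bounds[0]) & (r < r_bounds[1])
            out[ok] = -(W(r[ok]) + 0.5 * k_u * (r[ok] - c) ** 2) / k_BT
            return out
        x = np.full(n_chains, c) + rng.normal(scale=0.05, size=n_chains)
        lp = logp(x)
        collected = []
        sweeps = burn_in + thin * int(np.ceil(n_samples / n_chains))
        for s in range(sweeps):
            prop = x + rng.normal(scale=proposal, size=n_chains)
            lp_new = logp(prop)
            accept = np.log(rng.uniform(size=n_chains)) < lp_new - lp
            x = np.where(accept, prop, x)
            lp = np.where(accept, lp_new, lp)
            if s >= burn_in and (s - burn_in) % thin == 0:
                collected.append(x.copy())
        samples = np.concatenate(collected)[:n_samples]
        windows.append(UmbrellaWindow(center=float(c), k_u=k_u,
                                      samples=samples))
    return windows


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle`` (radians)."""
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def rotated_rigid_body(
    spec: ProteinSpec | None = None,
    axis=(1.0, 0.3, 0.2),
    angle: float = 0.4,
    box=(20.0, 20.0, 20.0),
    seed: int = 0,
) -> FixtureFrame:
    """A protein rotated by a known matrix, with the exact tilt attached.

    The cylinder axis starts along -z (cap up); the ground-truth tilt is
    the angle between the rotated axis and z, folded into [0, 90] deg.
    """
    if spec is None:
        spec = ProteinSpec(side_beads=3, n_hydrophobic_layers=3)
    build = build_protein(spec)
    R = rotation_matrix(np.asarray(axis), angle)
    pos = build.positions @ R.T
    center = np.asarray(box) / 2.0
    pos = pos + center
    n = pos.shape[0]
    state = SimulationState(
        positions=pos, velocities=np.zeros((n, 3)),
        species=build.species,
        molecule_id=np.zeros(n, dtype=np.int64),
        box=np.asarray(box, dtype=float),
        mol_kind=np.full(n, MOL_PROTEIN),
    )
    ax = R @ np.array([0.0, 0.0, -1.0])
    tilt = np.degrees(np.arccos(abs(ax[2])))
    return FixtureFrame(state=state, truth={"tilt_deg": float(tilt),
                                            "rotation": R})


@njit(cache=True)
def _escape_loop(g, force, D, a, b, r_reflect, n_walkers, dt, seed, k_BT,
                 max_steps):
    np.random.seed(seed)
    times = np.empty(n_walkers)
    amp = np.sqrt(2.0 * D * dt)
    drift = D * dt / k_BT
    g0 = g[0]
    inv_dg = (g.size - 1) / (g[-1] - g0)
    for wlk in range(n_walkers):
        x = a
        for step in range(1, max_steps + 1):
            # linear interpolation of the tabulated force
            u = (x - g0) * inv_dg
            k = int(u)
            if k < 0:
                k = 0
            elif k >= g.size - 1:
                k = g.size - 2
            frac = u - k
            f = force[k] * (1.0 - frac) + force[k + 1] * frac
            x = x + drift * f + amp * np.random.standard_normal()
            if x < r_reflect:
                x = 2.0 * r_reflect - x
            if x >= b:
                times[wlk] = step * dt
                break
        else:
            times[wlk] = np.nan
    return times


def langevin_escape_times(
    r: np.ndarray,
    W: np.ndarray,
    D: float,
    a: float,
    b: float,
    r_reflect: float,
    n_walkers: int = 10000,
    dt: float = 1e-3,
    seed: int = 0,
    k_BT: float = 1.0,
    max_steps: int = 50_000_000,
) -> np.ndarray:
    """Brute-force overdamped first-passage oracle on a tabulated potential.

    Euler-Maruyama integration of ``dr = -D W'(r)/k_BT dt + sqrt(2 D dt)
    xi`` from ``a``, reflecting at ``r_reflect``, absorbing at ``b``.
    Returns the individual escape times; independent of the quadrature
    route it cross-checks. ``dt`` must stay well below the relaxation time
    ``k_BT / (D max|W''|)`` for the Euler discretization bias to be
    negligible.
    """
    g = np.linspace(r[0], max(b, r[-1]), 4000)
    wg = np.interp(g, r, W)
    force = -np.gradient(wg, g)          # -dW/dr
    times = _escape_loop(g, force, float(D), float(a), float(b),
                         float(r_reflect), int(n_walkers), float(dt),
                         int(seed) & 0x7FFFFFFF, float(k_BT), int(max_steps))
    if np.any(np.isnan(times)):
        raise RuntimeError("escape simulation exceeded max_steps")
    return times
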