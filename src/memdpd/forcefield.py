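"""DPD force field: species table and pairwise force laws.

All quantities are in reduced units: the interaction cutoff ``r_c``, the bead
mass ``m`` and the thermostat temperature ``k_BT`` set the length, mass and
energy scales. Beads interact through three pairwise forces inside the
cutoff -- a soft linear conservative repulsion whose amplitude ``a_ij``
encodes the hydrophobicity contrast of the two species, and a
dissipative/random pair that together act as a momentum-conserving
(Galilean-invariant) thermostat. The random amplitude is tied to the friction
by the fluctuation-dissipation relation ``sigma^2 = 2 * gamma * k_BT``, which
is enforced at construction and cannot be overridden independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPECIES",
    "SPECIES_INDEX",
    "HYDROPHOBIC",
    "ForceFieldParams",
    "default_interaction_matrix",
    "conservative_pair_force",
    "dissipative_random_pair_forces",
]

#: Bead species: water, lipid head/tail (standard and long species),
#: protein hydrophilic cap and hydrophobic anchor.
SPECIES = ("W", "H", "T", "H2", "T2", "PH", "PT")
SPECIES_INDEX = {s: i for i, s in enumerate(SPECIES)}
HYDROPHOBIC = frozenset({"T", "T2", "PT"})

#: Beads belonging to the two lipid species (used for the cross-species
#: repulsion amplification that drives domain formation).
LIPID_A = frozenset({"H", "T"})
LIPID_B = frozenset({"H2", "T2"})


def default_interaction_matrix(
    a_like: float = 25.0,
    a_cross: float = 100.0,
    cross_species_factor: float = 1.0,
) -> np.ndarray:
    """Conservative repulsion matrix for the standard seven species.

    ``a_like`` applies between beads of the same hydrophobicity class
    (both hydrophilic/water or both hydrophobic), ``a_cross`` between a
    hydrophobic and a hydrophilic/water bead.  ``cross_species_factor``
    amplifies every repulsion between beads of the two *lipid* species
    (H,T vs H2,T2) to induce demixing of a two-component membrane;
    lipid-water and lipid-protein amplitudes are left unchanged.
    """
    n = len(SPECIES)
    a = np.empty((n, n), dtype=np.float64)
    for i, si in enumerate(SPECIES):
        for j, sj in enumerate(SPECIES):
            like = (si in HYDROPHOBIC) == (sj in HYDROPHOBIC)
            a[i, j] = a_like if like else a_cross
            if (si in LIPID_A and sj in LIPID_B) or (si in LIPID_B and sj in LIPID_A):
                a[i, j] *= cross_species_factor
    return a


@dataclass(frozen=True)
class ForceFieldParams:
    """DPD interaction parameters.

    Parameters
    ----------
    a
        Symmetric ``(n_species, n_species)`` matrix of conservative repulsion
        amplitudes, in k_BT / r_c, indexed by :data:`SPECIES` order.
    gamma
        Dissipative friction coefficient, in sqrt(m * k_BT) / r_c.
    r_c
        Interaction cutoff (the length unit).
    k_BT
        Thermostat temperature (the energy unit).

    The random-force amplitude ``sigma`` is derived, never stored:
    ``sigma = sqrt(2 * gamma * k_BT)``.
    """

    a: np.ndarray
    gamma: float = 4.5
    r_c: float = 1.0
    k_BT: float = 1.0
    species: tuple = SPECIES

    def __post_init__(self):
        a = np.asarray(self.a, dtype=np.float64)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("interaction matrix must be square")
        if not np.allclose(a, a.T):
            raise ValueError("interaction matrix must be symmetric")
        if np.any(a < 0):
            raise ValueError("repulsion amplitudes must be non-negative")
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.k_BT <= 0:
            raise ValueError("k_BT must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        object.__setattr__(self, "a", a)

    @property
    def sigma(self) -> float:
        """Random-force amplitude from fluctuation-dissipation."""
        return float(np.sqrt(2.0 * self.gamma * self.k_BT))

    @classmethod
    def default(
        cls,
        a_like: float = 25.0,
        a_cross: float = 100.0,
        cross_species_factor: float = 1.0,
        gamma: float = 4.5,
        r_c: float = 1.0,
        k_BT: float = 1.0,
    ) -> "ForceFieldParams":
        return cls(
            a=default_interaction_matrix(a_like, a_cross, cross_species_factor),
            gamma=gamma,
            r_c=r_c,
            k_BT=k_BT,
        )

    def species_id(self, name: str) -> int:
        return SPECIES_INDEX[name]


def _unit_vector(r_vec: np.ndarray) -> tuple[float, np.ndarray]:
    r_vec = np.asarray(r_vec, dtype=np.float64)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise ValueError("zero-length displacement: pair geometry is degenerate")
    return r, r_vec / r


def conservative_pair_force(
    r_vec: np.ndarray, species_i: str, species_j: str, ff: ForceFieldParams
) -> np.ndarray:
    """Soft linear repulsion ``a_ij * (1 - r/r_c) * r_hat`` on bead i.

    ``r_vec`` is the minimum-image displacement ``r_i - r_j``; the force on j
    is the exact negation.  Zero beyond the cutoff; finite (``a_ij``) at
    contact -- the soft core that lets DPD take large time steps.
    """
    r, e = _unit_vector(r_vec)
    if r >= ff.r_c:
        return np.zeros(3)
    aij = ff.a[SPECIES_INDEX[species_i], SPECIES_INDEX[species_j]]
    return aij * (1.0 - r / ff.r_c) * e


def dissipative_random_pair_forces(
    r_vec: np.ndarray,
    v_rel: np.ndarray,
    ff: ForceFieldParams,
    dt: float,
    noise: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Thermostat pair: dissipative and random forces on bead i.

    Dissipative part ``-gamma * w_D(r) * (r_hat . v_rel) * r_hat`` with
    ``w_D = (1 - r/r_c)^2``; random part ``sigma * w_R(r) * zeta * r_hat /
    sqrt(dt)`` with ``w_R = 1 - r/r_c`` and ``zeta`` a zero-mean,
    unit-variance draw shared by the pair (forces on j are the negations,
    so momentum is conserved draw by draw). The ``1/sqrt(dt)`` factor makes
    the integrator treat the random force like any other force.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    r, e = _unit_vector(r_vec)
    if r >= ff.r_c:
        z = np.zeros(3)
        return z, z.copy()
    w_r = 1.0 - r / ff.r_c
    v_rel = np.asarray(v_rel, dtype=np.float64)
    f_diss = -ff.gamma * w_r * w_r * float(np.dot(e, v_rel)) * e
    f_rand = ff.sigma * w_r * noise / np.sqrt(dt) * e
    return f_diss, f_rand
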