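"""Bonded topology: harmonic bonds and three-point angles.

Potentials use the half-prefactor convention
``U_bond = 1/2 k_bond (r - l0)^2`` and ``U_angle = 1/2 k_bend (theta -
theta0)^2`` (theta at the central bead of an (i, j, k) triple). Forces are
the exact negative gradients; see :func:`memdpd.engine.bonded_forces`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Topology", "DEFAULT_K_BOND", "DEFAULT_L0", "DEFAULT_K_BEND", "DEFAULT_THETA0"]

DEFAULT_K_BOND = 100.0   # k_BT / r_c^2
DEFAULT_L0 = 0.45        # r_c
DEFAULT_K_BEND = 20.0    # k_BT / rad^2
DEFAULT_THETA0 = np.pi


def _empty_int(cols: int) -> np.ndarray:
    return np.empty((0, cols), dtype=np.int64)


def _empty_float(cols: int) -> np.ndarray:
    return np.empty((0, cols), dtype=np.float64)


@dataclass
class Topology:
    """Bond and angle records with per-record constants.

    ``bonds``: (nb, 2) bead indices; ``bond_params``: (nb, 2) = (k_bond, l0).
    ``angles``: (na, 3) bead indices, central bead second;
    ``angle_params``: (na, 2) = (k_bend, theta0).
    """

    bonds: np.ndarray = field(default_factory=lambda: _empty_int(2))
    bond_params: np.ndarray = field(default_factory=lambda: _empty_float(2))
    angles: np.ndarray = field(default_factory=lambda: _empty_int(3))
    angle_params: np.ndarray = field(default_factory=lambda: _empty_float(2))

    def __post_init__(self):
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_params = np.ascontiguousarray(self.bond_params, dtype=np.float64).reshape(-1, 2)
        self.angles = np.ascontiguousarray(self.angles, dtype=np.int64).reshape(-1, 3)
        self.angle_params = np.ascontiguousarray(self.angle_params, dtype=np.float64).reshape(-1, 2)
        if self.bonds.shape[0] != self.bond_params.shape[0]:
            raise ValueError("bond_params must match bonds")
        if self.angles.shape[0] != self.angle_params.shape[0]:
            raise ValueError("angle_params must match angles")
        for rec in self.bonds:
            if rec[0] == rec[1]:
                raise ValueError("bond indices must be distinct")
        for rec in self.angles:
            if len({int(rec[0]), int(rec[1]), int(rec[2])}) != 3:
                raise ValueError("angle indices must be distinct")

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]

    @property
    def n_angles(self) -> int:
        return self.angles.shape[0]

    def validate(self, n_beads: int) -> None:
        for arr in (self.bonds, self.angles):
            if arr.size and (arr.min() < 0 or arr.max() >= n_beads):
                raise IndexError("topology refers to beads outside the state")

    def shifted(self, offset: int) -> "Topology":
        """Topology with all bead indices shifted by ``offset``."""
        return Topology(
            bonds=self.bonds + offset,
            bond_params=self.bond_params.copy(),
            angles=self.angles + offset,
            angle_params=self.angle_params.copy(),
        )

    def merged(self, other: "Topology") -> "Topology":
        return Topology(
            bonds=np.vstack([self.bonds, other.bonds]),
            bond_params=np.vstack([self.bond_params, other.bond_params]),
            angles=np.vstack([self.angles, other.angles]),
            angle_params=np.vstack([self.angle_params, other.angle_params]),
        )

    def remapped(self, keep_mask: np.ndarray) -> "Topology":
        """Drop records touching removed beads and renumber the rest.

        ``keep_mask`` is a boolean array over the old bead indices; new
        indices are the positions within the kept subset.
        """
        keep_mask = np.asarray(keep_mask, dtype=bool)
        new_index = np.cumsum(keep_mask) - 1
        def _filter(rec, par):
            if rec.size == 0:
                return rec, par
            ok = keep_mask[rec].all(axis=1)
            return new_index[rec[ok]], par[ok]
        b, bp = _filter(self.bonds, self.bond_params)
        an, ap = _filter(self.angles, self.angle_params)
        return Topology(bonds=b, bond_params=bp, angles=an, angle_params=ap)
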