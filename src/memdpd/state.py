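"""Simulation state container.

Positions are always stored wrapped into the periodic box; an integer image
count per bead keeps the unwrapped displacement history needed for mean
square displacements. Species are small integer codes into
:data:`memdpd.forcefield.SPECIES`; ``molecule_id`` groups beads into
molecules (each water bead is its own molecule) and ``mol_kind`` is a coarse
per-bead tag (water / standard lipid / long lipid / protein) used by the
analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimulationState", "MOL_WATER", "MOL_LIPID", "MOL_LIPID_LONG", "MOL_PROTEIN"]

MOL_WATER = 0
MOL_LIPID = 1
MOL_LIPID_LONG = 2
MOL_PROTEIN = 3


@dataclass
class SimulationState:
    positions: np.ndarray        # (N, 3), wrapped into [0, box_i)
    velocities: np.ndarray       # (N, 3)
    species: np.ndarray          # (N,) int codes into SPECIES
    molecule_id: np.ndarray      # (N,) int
    box: np.ndarray              # (3,) periodic edge lengths
    time: float = 0.0
    mol_kind: np.ndarray = None  # (N,) int, MOL_* codes
    images: np.ndarray = None    # (N, 3) int, periodic image counts

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        self.molecule_id = np.ascontiguousarray(self.molecule_id, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        for name in ("velocities",):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} must match positions shape")
        for name in ("species", "molecule_id"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length N")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if self.mol_kind is None:
            self.mol_kind = np.zeros(n, dtype=np.int64)
        else:
            self.mol_kind = np.ascontiguousarray(self.mol_kind, dtype=np.int64)
        if self.images is None:
            self.images = np.zeros((n, 3), dtype=np.int64)
        else:
            self.images = np.ascontiguousarray(self.images, dtype=np.int64)
        self.wrap()

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def wrap(self) -> None:
        """Wrap positions into [0, box) updating image counts."""
        shift = np.floor(self.positions / self.box)
        if np.any(shift != 0):
            self.images += shift.astype(np.int64)
            self.positions -= shift * self.box

    @property
    def unwrapped_positions(self) -> np.ndarray:
        return self.positions + self.images * self.box

    def copy(self) -> "SimulationState":
        return SimulationState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            box=self.box.copy(),
            time=self.time,
            mol_kind=self.mol_kind.copy(),
            images=self.images.copy(),
        )

    def molecule_indices(self, mol_id: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_id == mol_id)
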