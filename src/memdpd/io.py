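"""Trajectory serialization: extended XYZ (text) and HDF5 (binary).

The XYZ flavor is one ``species x y z`` line per bead with the box and
time on the comment line; good for eyeballing and interchange, lossy only
to the printed precision. The HDF5 container stores positions, velocities,
species codes, molecule ids, box and time per frame, bit-exactly.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np

from .forcefield import SPECIES, SPECIES_INDEX
from .state import SimulationState

__all__ = ["write_xyz", "read_xyz", "write_h5", "read_h5", "file_sha256",
           "write_manifest"]


def write_xyz(path, frames, precision: int = 5) -> None:
    """Append-free write of frames as extended XYZ."""
    fmt = f"{{}} {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with open(path, "w") as fh:
        for state in frames:
            fh.write(f"{state.n_beads}\n")
            bx = " ".join(f"{b:.8f}" for b in state.box)
            fh.write(f'box="{bx}" time={state.time:.8f}\n')
            for sp, p in zip(state.species, state.positions):
                fh.write(fmt.format(SPECIES[sp], p[0], p[1], p[2]))


def read_xyz(path) -> list[SimulationState]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise ValueError(f"{path}: line {i + 1}: expected bead count") from err
        comment = lines[i + 1]
        try:
            box_str = comment.split('box="')[1].split('"')[0]
            box = np.array([float(x) for x in box_str.split()])
            time = float(comment.split("time=")[1].split()[0])
        except (IndexError, ValueError) as err:
            raise ValueError(f"{path}: line {i + 2}: malformed comment") from err
        pos = np.empty((n, 3))
        sp = np.empty(n, dtype=np.int64)
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) != 4:
                raise ValueError(f"{path}: line {i + 3 + k}: expected 4 fields")
            sp[k] = SPECIES_INDEX[parts[0]]
            pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(SimulationState(
            positions=pos, velocities=np.zeros((n, 3)), species=sp,
            molecule_id=np.zeros(n, dtype=np.int64), box=box, time=time))
        i += 2 + n
    return frames


def write_h5(path, frames, extra: dict | None = None) -> None:
    import h5py
    frames = list(frames)
    n = frames[0].n_beads
    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions",
                          data=np.stack([f.positions for f in frames]))
        h5.create_dataset("velocities",
                          data=np.stack([f.velocities for f in frames]))
        h5.create_dataset("images",
                          data=np.stack([f.images for f in frames]))
        h5.create_dataset("box", data=np.stack([f.box for f in frames]))
        h5.create_dataset("time", data=np.array([f.time for f in frames]))
        h5.create_dataset("species", data=frames[0].species)
        h5.create_dataset("molecule_id", data=frames[0].molecule_id)
        h5.create_dataset("mol_kind", data=frames[0].mol_kind)
        for key, val in (extra or {}).items():
            h5.attrs[key] = val


def read_h5(path) -> list[SimulationState]:
    import h5py
    frames = []
    with h5py.File(path, "r") as h5:
        pos = h5["positions"][:]
        vel = h5["velocities"][:]
        img = h5["images"][:]
        box = h5["box"][:]
        time = h5["time"][:]
        species = h5["species"][:]
        mol_id = h5["molecule_id"][:]
        kind = h5["mol_kind"][:]
    for k in range(pos.shape[0]):
        frames.append(SimulationState(
            positions=pos[k], velocities=vel[k], species=species,
            molecule_id=mol_id, box=box[k], time=float(time[k]),
            mol_kind=kind, images=img[k]))
    return frames


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, files: list, config: dict) -> Path:
    """Machine-readable run manifest: checksums + resolved configuration."""
    outdir = Path(outdir)
    manifest = {
        "files": {str(Path(f).name): file_sha256(f) for f in files},
        "config": config,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
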