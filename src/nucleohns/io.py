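"""Trajectory and configuration text formats.

Two dialects are supported:

* extended XYZ — carries species name, position, molecule id and periodic
  image counters per particle, plus box and time in the comment line;
* a LAMMPS-dump text dialect (``ITEM: TIMESTEP / NUMBER OF ATOMS /
  BOX BOUNDS pp pp pp / ATOMS id type x y z``) with 1-based ids and
  numeric types 1..4.

The dump dialect does not carry topology; on read it is reconstructed from
the builder's particle-ordering convention (ring monomers first, then one
(core, patch, patch) triple per H-NS, then crowders), which
:func:`topology_from_species` implements.
"""

from __future__ import annotations


from pathlib import Path

import numpy as np

from .builder import (
    CORE,
    CROWDER,
    MONOMER,
    PATCH,
    ParticleConfiguration,
)
from .dynamics import Frame, Trajectory
from .interactions import BondedParams

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_lammps_dump",
    "read_lammps_dump",
    "read_trajectory",
    "write_trajectory",
    "topology_from_species",
    "TrajectoryParseError",
]

SPECIES_TO_NAME = {MONOMER: "monomer", PATCH: "patch", CORE: "core", CROWDER: "crowder"}
NAME_TO_SPECIES = {v: k for k, v in SPECIES_TO_NAME.items()}

POS_FMT = "%.6f"  # 1e-6 sigma: lossless for every analysis tolerance


class TrajectoryParseError(ValueError):
    pass


def topology_from_species(
    species: np.ndarray, box: float, bp: BondedParams = BondedParams()
) -> ParticleConfiguration:
    """Rebuild ring/triplex topology from the builder's particle ordering.

    Monomers must come first (closed FENE ring in index order), each H-NS
    as a contiguous (core, patch, patch) triple, crowders last.
    """
    species = np.asarray(species)
    n = len(species)
    mono = np.flatnonzero(species == MONOMER)
    n_mono = len(mono)
    if n_mono and not np.array_equal(mono, np.arange(n_mono)):
        raise TrajectoryParseError("ring monomers are not a contiguous leading block")
    i = n_mono
    harm_bonds, angles, mol = [], [], [0] * n_mono
    mol_id = 1
    while i < n and species[i] != CROWDER:
        if i + 2 >= n or species[i] != CORE or species[i + 1] != PATCH or species[i + 2] != PATCH:
            raise TrajectoryParseError(
                f"unrecognized H-NS triple at particle {i} "
                f"(expected core, patch, patch)"
            )
        harm_bonds += [[i, i + 1], [i, i + 2]]
        angles.append([i + 1, i, i + 2])
        mol += [mol_id] * 3
        mol_id += 1
        i += 3
    n_crowd = n - i
    if np.any(species[i:] != CROWDER):
        raise TrajectoryParseError("crowders must form the trailing block")
    mol += list(range(mol_id, mol_id + n_crowd))
    n_hns = len(angles)
    fene = (
        np.stack([np.arange(n_mono), (np.arange(n_mono) + 1) % n_mono], axis=1)
        if n_mono
        else np.zeros((0, 2), dtype=np.int64)
    )
    return ParticleConfiguration(
        positions=np.zeros((n, 3)),
        species=species.astype(np.int64),
        molecule_id=np.array(mol, dtype=np.int64),
        box=float(box),
        fene_bonds=fene.astype(np.int64),
        harm_bonds=np.array(harm_bonds, dtype=np.int64).reshape(-1, 2),
        harm_k=np.full(2 * n_hns, bp.hns_K),
        harm_r0=np.full(2 * n_hns, bp.hns_r0),
        harm_kind=np.zeros(2 * n_hns, dtype=np.int64),
        angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
    )


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path) -> None:
    box = traj.box
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{len(fr.positions)}\n")
            fh.write(
                f'Lattice="{box} 0 0 0 {box} 0 0 0 {box}" '
                "Properties=species:S:1:pos:R:3:molecule:I:1:image:I:3 "
                f"Time={fr.time}\n"
            )
            for p, s, m, im in zip(
                fr.positions, traj.topology.species, traj.topology.molecule_id, fr.images
            ):
                fh.write(
                    f"{SPECIES_TO_NAME[int(s)]} {POS_FMT % p[0]} {POS_FMT % p[1]} "
                    f"{POS_FMT % p[2]} {m} {im[0]} {im[1]} {im[2]}\n"
                )


def read_xyz(path) -> Trajectory:
    frames, species, mol, box = [], None, None, None
    lines = Path(path).read_text().splitlines()
    i = 0
    last_complete = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as e:
            raise TrajectoryParseError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from e
        if i + 1 + nat >= len(lines) + 1 and i + 1 + nat > len(lines):
            raise TrajectoryParseError(
                f"truncated file after {last_complete} complete frame(s) "
                f"(frame starting at line {i + 1})"
            )
        header = lines[i + 1]
        try:
            lat = header.split('Lattice="')[1].split('"')[0].split()
            box = float(lat[0])
            time = float(header.split("Time=")[1].split()[0])
        except (IndexError, ValueError) as e:
            raise TrajectoryParseError(f"line {i + 2}: malformed frame header") from e
        sp, ml, pos, img = [], [], [], []
        for k in range(nat):
            ln = i + 2 + k
            if ln >= len(lines):
                raise TrajectoryParseError(
                    f"truncated file after {last_complete} complete frame(s)"
                )
            tok = lines[ln].split()
            if len(tok) != 8:
                raise TrajectoryParseError(f"line {ln + 1}: expected 8 columns")
            if tok[0] not in NAME_TO_SPECIES:
                raise TrajectoryParseError(f"line {ln + 1}: unknown species {tok[0]!r}")
            sp.append(NAME_TO_SPECIES[tok[0]])
            pos.append([float(t) for t in tok[1:4]])
            ml.append(int(tok[4]))
            img.append([int(t) for t in tok[5:8]])
        if species is None:
            species, mol = np.array(sp), np.array(ml)
        frames.append(
            Frame(time=time, positions=np.array(pos), images=np.array(img, dtype=np.int64))
        )
        last_complete += 1
        i += 2 + nat
    if not frames:
        raise TrajectoryParseError("no frames found")
    topo = topology_from_species(species, box)
    topo.molecule_id = mol.astype(np.int64)
    topo.positions = frames[0].positions.copy()
    return Trajectory(topology=topo, frames=frames)


# ---------------------------------------------------------------------------
# LAMMPS dump dialect
# ---------------------------------------------------------------------------

def write_lammps_dump(traj: Trajectory, path, dt: float = 0.005) -> None:
    """Text dump with 1-based ids and numeric species types 1..4.

    Frame times are encoded as integer timesteps time/dt."""
    box = traj.box
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write("ITEM: TIMESTEP\n%d\n" % round(fr.time / dt))
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % len(fr.positions))
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write("0.0 %s\n" % (POS_FMT % box))
            fh.write("ITEM: ATOMS id type x y z\n")
            for idx, (p, s) in enumerate(zip(fr.positions, traj.topology.species)):
                fh.write(
                    f"{idx + 1} {int(s)} {POS_FMT % p[0]} {POS_FMT % p[1]} "
                    f"{POS_FMT % p[2]}\n"
                )


def read_lammps_dump(path, dt: float = 0.005) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames, species, box = [], None, None
    i = 0
    last_complete = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise TrajectoryParseError(f"line {i + 1}: expected ITEM: TIMESTEP")
        try:
            step = int(lines[i + 1])
            if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
                raise ValueError
            nat = int(lines[i + 3])
            if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
                raise ValueError
            lo, hi = (float(t) for t in lines[i + 5].split())
            box = hi - lo
            if not lines[i + 8].startswith("ITEM: ATOMS"):
                raise ValueError
        except (ValueError, IndexError) as e:
            raise TrajectoryParseError(
                f"malformed frame header at line {i + 1} "
                f"(after {last_complete} complete frame(s))"
            ) from e
        if i + 9 + nat > len(lines):
            raise TrajectoryParseError(
                f"truncated file after {last_complete} complete frame(s)"
            )
        sp = np.empty(nat, dtype=np.int64)
        pos = np.empty((nat, 3))
        for k in range(nat):
            tok = lines[i + 9 + k].split()
            if len(tok) != 5:
                raise TrajectoryParseError(f"line {i + 10 + k}: expected 5 columns")
            idx = int(tok[0]) - 1
            s = int(tok[1])
            if s not in SPECIES_TO_NAME:
                raise TrajectoryParseError(f"line {i + 10 + k}: unknown type {s}")
            sp[idx] = s
            pos[idx] = [float(t) for t in tok[2:5]]
        if species is None:
            species = sp
        frames.append(
            Frame(
                time=step * dt,
                positions=pos,
                images=np.zeros((nat, 3), dtype=np.int64),
            )
        )
        last_complete += 1
        i += 9 + nat
    if not frames:
        raise TrajectoryParseError("no frames found")
    topo = topology_from_species(species, box)
    topo.positions = frames[0].positions.copy()
    return Trajectory(topology=topo, frames=frames)


def write_trajectory(traj: Trajectory, path, dialect: str = "xyz", **kw) -> None:
    if dialect == "xyz":
        write_xyz(traj, path)
    elif dialect == "lammpsdump":
        write_lammps_dump(traj, path, **kw)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_trajectory(path, dialect: str = "xyz", **kw) -> Trajectory:
    if dialect == "xyz":
        return read_xyz(path)
    if dialect == "lammpsdump":
        return read_lammps_dump(path, **kw)
    raise ValueError(f"unknown dialect {dialect!r}")
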