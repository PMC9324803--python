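"""Reading and writing structures, trajectories, parameters and reports.

Structures come in as PDB files (via Biopython); trajectories as multi-model
PDB (MODEL/ENDMDL) or a plain text coordinate table (one ``FRAME k [time]``
line followed by one ``x y z`` row per atom, per frame).  Reports go out as
CSV or JSON through pandas.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from . import chemdata
from .core import Atom, Residue, RoleAnnotations, Topology, Trajectory

__all__ = [
    "read_topology",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_report",
    "ParseError",
]


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


_POLYMER = chemdata.AMINO_ACIDS | chemdata.RIBONUCLEOTIDES


def _derive_roles(atoms: list[Atom], residues: list[Residue],
                  bonds: list[tuple[int, int]]) -> RoleAnnotations:
    adj: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    roles = RoleAnnotations()
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el == "H":
            for j in adj[i]:
                if atoms[j].element.upper() in ("N", "O"):
                    roles.hbond_donor_H[i] = j
                    break
        elif el == "O":
            roles.hbond_acceptor.add(i)
        elif el == "N":
            has_h = any(atoms[j].element.upper() == "H" for j in adj[i])
            heavy = sum(1 for j in adj[i] if atoms[j].element.upper() != "H")
            if not has_h and heavy <= 2:
                roles.hbond_acceptor.add(i)
    for res in residues:
        name_to_idx = {atoms[i].name: i for i in res.atom_indices}
        rname = res.name.upper()
        for an in chemdata.CATION_GROUPS.get(rname, ()):  # cationic N
            if an in name_to_idx:
                roles.cation_group.add(name_to_idx[an])
        for an in chemdata.ANION_GROUPS.get(rname, ()):  # anionic O
            if an in name_to_idx:
                roles.anion_group.add(name_to_idx[an])
        for ring in chemdata.AROMATIC_RINGS.get(rname, ()):
            if all(an in name_to_idx for an in ring):
                roles.aromatic_rings.append(tuple(name_to_idx[an] for an in ring))
        if rname in chemdata.APOLAR_RESIDUES:
            for an, i in name_to_idx.items():
                if an not in chemdata.BACKBONE_ATOMS and atoms[i].element.upper() == "C":
                    roles.apolar_carbon.add(i)
    return roles


def _build_bonds(atoms: list[Atom], residues: list[Residue],
                 link_polymer: bool = True) -> list[tuple[int, int]]:
    bonds: list[tuple[int, int]] = []
    for ri, res in enumerate(residues):
        name_to_idx = {atoms[i].name: i for i in res.atom_indices}
        template = chemdata.HEAVY_BONDS.get(res.name.upper(), [])
        for a, b in template:
            if a in name_to_idx and b in name_to_idx:
                bonds.append((name_to_idx[a], name_to_idx[b]))
        heavy_names = [atoms[i].name for i in res.atom_indices
                       if atoms[i].element.upper() != "H"]
        for i in res.atom_indices:
            if atoms[i].element.upper() == "H":
                heavy = chemdata.attach_hydrogen(atoms[i].name, heavy_names)
                if heavy is not None:
                    bonds.append((i, name_to_idx[heavy]))
        # peptide / phosphodiester link to the next residue in the same chain
        if link_polymer and ri + 1 < len(residues):
            nxt = residues[ri + 1]
            if nxt.chain_id == res.chain_id and res.name.upper() in _POLYMER \
                    and nxt.name.upper() in _POLYMER:
                nxt_names = {atoms[i].name: i for i in nxt.atom_indices}
                if res.name.upper() in chemdata.AMINO_ACIDS:
                    if "C" in name_to_idx and "N" in nxt_names:
                        bonds.append((name_to_idx["C"], nxt_names["N"]))
                elif "O3'" in name_to_idx and "P" in nxt_names:
                    bonds.append((name_to_idx["O3'"], nxt_names["P"]))
    return bonds


def topology_from_records(
    records: Sequence[tuple[int, str, str, str, int, str]],
    parameter_table: dict | None = None,
    solvent_resnames: set[str] | None = None,
    link_polymer: bool = True,
) -> Topology:
    """Assemble a Topology from flat atom records.

    Each record is (serial, atom_name, element, resname, author_number,
    chain_id), in file order.  Parameters default to the bundled table.
    ``link_polymer=False`` suppresses inter-residue backbone bonds (used by
    toy systems whose residues are independent molecules).
    """
    if parameter_table is None:
        parameter_table = chemdata.load_parameter_table()
    solvent = chemdata.SOLVENT_RESNAMES if solvent_resnames is None else solvent_resnames

    atoms: list[Atom] = []
    residues: list[Residue] = []
    unknown: set[str] = set()
    serials_seen: set[int] = set()
    current_key: tuple[str, int, str] | None = None
    for serial, name, element, resname, number, chain in records:
        if serial in serials_seen:
            raise ParseError(f"duplicate atom serial {serial}")
        serials_seen.add(serial)
        key = (resname, number, chain)
        if key != current_key:
            if residues:
                residues[-1].atom_stop = len(atoms)
            residues.append(Residue(resname, number, chain, len(atoms), len(atoms)))
            current_key = key
        params = parameter_table.get((resname.upper(), name))
        if params is None:
            if resname.upper() not in chemdata.AMINO_ACIDS | chemdata.RIBONUCLEOTIDES \
                    | chemdata.SOLVENT_RESNAMES:
                unknown.add(resname)
            q = 0.0
            s, e = chemdata.ELEMENT_LJ.get(element.upper(), (3.4, 0.05))
        else:
            q, s, e = params
        atoms.append(
            Atom(serial, name, element, q, s, e, len(residues) - 1, chain,
                 resname.upper() in solvent)
        )
    if residues:
        residues[-1].atom_stop = len(atoms)
    if unknown:
        warnings.warn(
            f"unknown residues assigned zero charge: {sorted(unknown)}"
        )
    bonds = _build_bonds(atoms, residues, link_polymer)
    roles = _derive_roles(atoms, residues, bonds)
    return Topology(atoms, residues, bonds, roles)


def _parse_pdb(path: str | Path):
    parser = PDBParser(QUIET=True)
    try:
        return parser.get_structure("s", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc


def _model_records(model):
    records = []
    coords = []
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            number = residue.get_id()[1]
            for atom in residue:
                element = atom.element.strip() or chemdata.element_from_name(
                    atom.get_name(), resname
                )
                records.append(
                    (atom.get_serial_number(), atom.get_name(), element,
                     resname, number, chain.get_id())
                )
                coords.append(atom.get_coord())
    return records, np.asarray(coords, dtype=float)


def read_topology(
    path: str | Path,
    parameter_table: str | Path | dict | None = None,
    solvent_resnames: set[str] | None = None,
) -> Topology:
    """Read a PDB file into a Topology with parameters and role annotations.

    ``parameter_table`` may be a path to a TSV (residue, atom, charge, sigma,
    epsilon) or an already-loaded mapping; it defaults to the bundled set.
    Atoms of residues absent from both the table and the built-in templates
    get zero charge (with a warning) and element-based LJ parameters.
    """
    if parameter_table is not None and not isinstance(parameter_table, dict):
        parameter_table = chemdata.load_parameter_table(parameter_table)
    structure = _parse_pdb(path)
    model = next(iter(structure))
    records, _ = _model_records(model)
    if not records:
        raise ParseError(f"{path}: no atoms found")
    return topology_from_records(records, parameter_table, solvent_resnames)


def read_trajectory(topology: Topology, path: str | Path) -> Trajectory:
    """Read a multi-model PDB or plain coordinate table as a Trajectory.

    Frames appear in file order; every frame must contain exactly
    ``topology.n_atoms`` coordinate rows.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(4096)
    if "FRAME" in head.split("\n")[0].upper():
        frames, times = _read_coordinate_table(path)
    else:
        structure = _parse_pdb(path)
        frames = []
        times = None
        for model in structure:
            _, coords = _model_records(model)
            frames.append(coords)
    for k, f in enumerate(frames):
        if f.shape[0] != topology.n_atoms:
            raise ParseError(
                f"{path}: frame {k} has {f.shape[0]} atoms, "
                f"topology has {topology.n_atoms}"
            )
    return Trajectory(topology, frames, times)


def _read_coordinate_table(path: Path):
    frames: list[np.ndarray] = []
    times: list[float] = []
    current: list[list[float]] = []
    have_times = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper().startswith("FRAME"):
                if current:
                    frames.append(np.asarray(current))
                    current = []
                parts = line.split()
                if len(parts) >= 3:
                    times.append(float(parts[2]))
                else:
                    have_times = False
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(f"{path}:{lineno}: expected 'x y z', got {line!r}")
                current.append([float(x) for x in parts])
    if current:
        frames.append(np.asarray(current))
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames, (times if have_times and len(times) == len(frames) else None)


# -- writing ---------------------------------------------------------------

def _pdb_atom_line(serial: int, atom: Atom, resname: str, resnum: int,
                   chain: str, xyz: np.ndarray) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    record = "HETATM" if atom.is_solvent else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4s} {resname:<3s} {chain:1s}"
        f"{resnum:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"  1.00  0.00          {atom.element.upper():>2s}"
    )


def write_structure(topology: Topology, coords: np.ndarray, path: str | Path) -> None:
    """Write one frame as a PDB file (author numbering preserved)."""
    write_trajectory(Trajectory(topology, [np.asarray(coords)]), path)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL records)."""
    top = traj.topology
    lines: list[str] = []
    for k, frame in enumerate(traj.frames):
        lines.append(f"MODEL     {k + 1:>4d}")
        serial = 1
        prev_chain = None
        for res in top.residues:
            if prev_chain is not None and res.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = res.chain_id
            for i in res.atom_indices:
                lines.append(
                    _pdb_atom_line(serial, top.atoms[i], res.name,
                                   res.author_number, res.chain_id, frame[i])
                )
                serial += 1
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(records, path: str | Path, format: str = "csv") -> None:
    """Write analysis rows (list of dicts or DataFrame) as CSV or JSON.

    Round-tripping the file returns identical values at printed precision.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if df.empty:
        raise ValueError("write_report: empty record table")
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=float)
    else:
        raise ValueError(f"unknown report format {format!r}")
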