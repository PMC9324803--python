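"""Build receptor::RNA models by superposition transplant plus refinement.

Given a target receptor, a reference receptor co-crystallized with a ligand,
and an explicit Calpha residue correspondence, the reference receptor is
Kabsch-fitted onto the target and the same rigid transform carries the
ligand into the target frame; the merged model is reported with a steric
clash list (receptor-ligand pairs closer than 2.0 A).  Refinement relaxes
every residue with an atom within 6 A of the ligand (plus the ligand
itself) using the local conjugate-gradient minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Topology
from .io_structures import topology_from_records
from .mutagenesis import MinimizationResult, local_minimize
from .structure_metrics import Superposition, superpose

__all__ = ["TransplantResult", "transplant_ligand", "refine_interface", "clash_pairs"]

CLASH_DISTANCE = 2.0


@dataclass
class TransplantResult:
    topology: Topology
    coords: np.ndarray
    transform: Superposition
    ligand_chain: str
    clashes: list[tuple[int, int, float]] = field(default_factory=list)


def _ca_index(topology: Topology, chain: str, number: int) -> int:
    for res in topology.residues:
        if res.chain_id == chain and res.author_number == number:
            for i in res.atom_indices:
                if topology.atoms[i].name == "CA":
                    return i
            raise ValueError(f"residue {chain}{number} has no CA atom")
    raise ValueError(f"residue {chain}{number} not found")


def clash_pairs(coords: np.ndarray, idx_a, idx_b,
                distance: float = CLASH_DISTANCE) -> list[tuple[int, int, float]]:
    """(i, j, distance) for cross-group pairs closer than ``distance``."""
    out = []
    for i in idx_a:
        d = np.linalg.norm(coords[idx_b] - coords[i], axis=1)
        for pos in np.nonzero(d < distance)[0]:
            out.append((int(i), int(idx_b[pos]), float(d[pos])))
    return out


def transplant_ligand(
    target_topology: Topology,
    target_coords: np.ndarray,
    reference_topology: Topology,
    reference_coords: np.ndarray,
    ligand_chain: str,
    mapping: list[tuple[tuple[str, int], tuple[str, int]]],
    parameter_table: dict | None = None,
) -> TransplantResult:
    """Place the reference ligand onto the target receptor by superposition.

    ``mapping`` pairs (target chain, resnum) with (reference chain, resnum);
    the Kabsch fit runs on these Calpha atoms (>= 3 pairs required).  The
    receptor keeps its coordinates; the ligand's internal geometry is
    preserved exactly by the rigid transform.
    """
    target_coords = np.asarray(target_coords, dtype=float)
    reference_coords = np.asarray(reference_coords, dtype=float)
    if len(mapping) < 3:
        raise ValueError("mapping needs at least 3 residue pairs")
    tgt_idx = [_ca_index(target_topology, c, n) for (c, n), _ in mapping]
    ref_idx = [_ca_index(reference_topology, c, n) for _, (c, n) in mapping]
    sup = superpose(target_coords[tgt_idx], reference_coords[ref_idx])

    lig_atoms = [i for i in range(reference_topology.n_atoms)
                 if reference_topology.atoms[i].chain_id == ligand_chain]
    if not lig_atoms:
        raise ValueError(f"ligand chain {ligand_chain!r} not found in reference")
    lig_coords = sup.apply(reference_coords[lig_atoms])

    # merged model: target atoms followed by the transplanted ligand
    records = []
    coords_out = []
    serial = 1
    used_chains = set(target_topology.chains)
    out_chain = ligand_chain
    while out_chain in used_chains:
        out_chain = chr(ord(out_chain) + 1) if out_chain != "Z" else "0"
    for res in target_topology.residues:
        for i in res.atom_indices:
            a = target_topology.atoms[i]
            records.append((serial, a.name, a.element, res.name,
                            res.author_number, res.chain_id))
            coords_out.append(target_coords[i])
            serial += 1
    lig_pos = {i: k for k, i in enumerate(lig_atoms)}
    for res in reference_topology.residues:
        if res.chain_id != ligand_chain:
            continue
        for i in res.atom_indices:
            a = reference_topology.atoms[i]
            records.append((serial, a.name, a.element, res.name,
                            res.author_number, out_chain))
            coords_out.append(lig_coords[lig_pos[i]])
            serial += 1
    topology = topology_from_records(records, parameter_table)
    coords_out = np.asarray(coords_out)
    rec_idx = np.arange(target_topology.n_atoms)
    new_lig_idx = np.arange(target_topology.n_atoms, topology.n_atoms)
    clashes = clash_pairs(coords_out, rec_idx, new_lig_idx)
    return TransplantResult(topology, coords_out, sup, out_chain, clashes)


def refine_interface(
    topology: Topology,
    coords: np.ndarray,
    ligand_chain: str,
    radius: float = 6.0,
    include_bonded: bool = True,
    **minimize_kwargs,
) -> tuple[np.ndarray, MinimizationResult]:
    """Relax residues within ``radius`` of the ligand, ligand included.

    Returns (refined coordinates, minimization result).  When no receptor
    residue lies within the radius the model is returned unchanged.
    """
    coords = np.asarray(coords, dtype=float)
    lig = np.asarray([i for i in range(topology.n_atoms)
                      if topology.atoms[i].chain_id == ligand_chain], dtype=int)
    if lig.size == 0:
        raise ValueError(f"ligand chain {ligand_chain!r} not flagged in topology")
    diff = coords[:, None, :] - coords[lig][None, :, :]
    close = (np.linalg.norm(diff, axis=2) <= radius).any(axis=1)
    close[lig] = False
    receptor_res = {topology.atoms[i].residue_index
                    for i in np.nonzero(close)[0]}
    if not receptor_res:
        return coords, MinimizationResult(coords, True, 0, 0.0, 0.0)
    region = sorted(
        set(lig.tolist())
        | {i for ri in receptor_res for i in topology.residues[ri].atom_indices}
    )
    result = local_minimize(coords, topology, np.asarray(region, dtype=int),
                            include_bonded=include_bonded, **minimize_kwargs)
    return result.coords, result
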