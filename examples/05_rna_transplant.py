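"""Ligand transplant by Calpha superposition, with interface refinement.

A reference complex (receptor + 4-atom nucleotide fragment) is fitted onto
a rotated copy of the receptor; the same rigid transform carries the
ligand, preserving its internal geometry exactly, and the merged model is
then locally relaxed around the ligand.
"""
import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

import protomerkit as pk
from protomerkit.complex_building import refine_interface, transplant_ligand
from protomerkit.io_structures import topology_from_records

receptor_top, receptor_xyz, _ = pk.make_toy_dimer(4, 3, ["salt_bridge"])
records, serial = [], 1
for res in receptor_top.residues:
    for i in res.atom_indices:
        a = receptor_top.atoms[i]
        records.append((serial, a.name, a.element, res.name,
                        res.author_number, res.chain_id))
        serial += 1
for name, el in (("C1'", "C"), ("N9", "N"), ("C8", "C"), ("N7", "N")):
    records.append((serial, name, el, "G", 1, "R"))
    serial += 1
ligand_xyz = np.array([[0.0, 3, 5], [1.5, 3, 5], [3.0, 3, 5], [3.0, 4.5, 5]])
reference_top = topology_from_records(records, link_polymer=False)
reference_xyz = np.vstack([receptor_xyz, ligand_xyz])

rot = Rotation.from_euler("xyz", [25, -30, 60], degrees=True).as_matrix()
target_xyz = receptor_xyz @ rot.T + np.array([4.0, -1.0, 2.0])

mapping = ([(("A", i), ("A", i)) for i in range(1, 5)]
           + [(("B", i), ("B", i)) for i in range(1, 4)])
result = transplant_ligand(receptor_top, target_xyz, reference_top,
                           reference_xyz, "R", mapping)

placed = result.coords[receptor_top.n_atoms:]
print(f"fit RMSD over mapping: {result.transform.rmsd:.2e} A")
print(f"rotation recovery error: "
      f"{np.abs(result.transform.rotation - rot).max():.2e}")
print(f"ligand internal-distance distortion: "
      f"{np.abs(pdist(placed) - pdist(ligand_xyz)).max():.2e} A")
print(f"clash pairs (< 2.0 A): {len(result.clashes)}")
refined, info = refine_interface(result.topology, result.coords,
                                 result.ligand_chain)
print(f"refinement moved atoms by up to "
      f"{np.abs(refined - result.coords).max():.2f} A "
      f"(converged: {info.converged})")
# The rigid transplant is exact to machine precision; refinement then
# relaxes the 6 A shell around the ligand with the package potential.
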