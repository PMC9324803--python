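"""Nonbonded energy model and the dimer-formation energy balance.

The kernel is a transparent fixed-charge model: Coulomb ``k q_i q_j / r``
with ``k = 332.0636 kcal A / (mol e^2)`` plus Lennard-Jones 12-6 with
Lorentz-Berthelot combining, hard-truncated at a cutoff (12 A default, no
shifting or long-range correction).  Pairs that are bonded or 1-3 connected
are excluded; intramolecular 1-4 pairs are scaled by 0.5.  Internal energies
add harmonic bond ``k_b (r - r0)^2`` and angle ``k_t (theta - theta0)^2``
terms with a small generic parameter set.  Absolute values are not
comparable to any specific MD engine; the bookkeeping of the formation
energy balance

    dE = E_self(AB) + E_solv(AB) + E_inter(AB)
         - [E_self(A) + E_solv(A) + E_self(B) + E_solv(B)]

is what the module guarantees: dimer-system terms minus separated-monomer
terms, each averaged over an analysis window (second trajectory half by
default), with the uncertainty combined in quadrature across terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import Topology, Trajectory

__all__ = [
    "COULOMB_K",
    "DEFAULT_CUTOFF",
    "EnergyComponents",
    "DimerFormationEnergy",
    "ResidueEnergyDecomposition",
    "BondedParams",
    "PotentialModel",
    "pair_energy",
    "chain_internal_energy",
    "protein_solvent_energy",
    "dimer_formation_energy",
    "decompose_interface_energy",
    "implicit_binding_energy",
]

COULOMB_K = 332.0636  # kcal*A/(mol*e^2)
DEFAULT_CUTOFF = 12.0  # A
WATER_DIELECTRIC = 78.5

#: harmonic bond reference lengths (A) by sorted element pair
BOND_R0: dict[tuple[str, str], float] = {
    ("C", "C"): 1.53, ("C", "N"): 1.41, ("C", "O"): 1.36, ("C", "H"): 1.09,
    ("H", "N"): 1.01, ("H", "O"): 0.96, ("C", "S"): 1.81, ("H", "S"): 1.34,
    ("O", "P"): 1.59, ("N", "N"): 1.35,
}
DEFAULT_R0 = 1.50


@dataclass
class BondedParams:
    """Generic harmonic bonded terms (E = k (x - x0)^2, no 1/2 factor)."""

    bond_k: float = 300.0  # kcal/mol/A^2
    angle_k: float = 50.0  # kcal/mol/rad^2
    theta0_sp3: float = 109.47  # deg
    theta0_sp2: float = 120.0  # deg, centers with >= 3 heavy neighbors

    def r0(self, el_a: str, el_b: str) -> float:
        key = tuple(sorted((el_a.upper(), el_b.upper())))
        return BOND_R0.get(key, DEFAULT_R0)


def _check_parameters(topology: Topology, indices: np.ndarray) -> None:
    bad = [topology.atoms[i].serial for i in indices
           if topology.atoms[i].element in ("X", "")]
    if bad:
        raise ValueError(f"atoms without usable parameters (serials): {bad}")


def _screen(r: np.ndarray, qq: np.ndarray, model: str) -> np.ndarray:
    """Electrostatic energy per pair under the chosen solvent surrogate."""
    if model == "vacuum":
        return COULOMB_K * qq / r
    if model == "distance_dielectric":
        return COULOMB_K * qq / (4.0 * r * r)  # eps(r) = 4r
    if model == "born_surrogate":
        a = 2.0  # fixed effective Born radius, A
        f_gb = np.sqrt(r * r + a * a * np.exp(-(r * r) / (4 * a * a)))
        return COULOMB_K * qq / r - (1.0 - 1.0 / WATER_DIELECTRIC) * COULOMB_K * qq / f_gb
    raise ValueError(f"unknown solvent model {model!r}")


def _pair_arrays(topology: Topology, idx_a, idx_b):
    atoms = topology.atoms
    q_a = np.array([atoms[i].charge for i in idx_a])
    q_b = np.array([atoms[i].charge for i in idx_b])
    s_a = np.array([atoms[i].lj_sigma for i in idx_a])
    s_b = np.array([atoms[i].lj_sigma for i in idx_b])
    e_a = np.array([atoms[i].lj_epsilon for i in idx_a])
    e_b = np.array([atoms[i].lj_epsilon for i in idx_b])
    return q_a, q_b, s_a, s_b, e_a, e_b


def pair_energy(
    frame: np.ndarray,
    topology: Topology,
    set_a: Sequence[int],
    set_b: Sequence[int],
    cutoff: float = DEFAULT_CUTOFF,
    solvent_model: str = "vacuum",
) -> tuple[float, float]:
    """(electrostatic, van der Waals) energy between two disjoint atom sets.

    Bonded and 1-3 connected pairs are excluded; the cutoff is a hard
    inclusive truncation on the interatomic distance.
    """
    idx_a = np.asarray(sorted(set(int(i) for i in set_a)), dtype=int)
    idx_b = np.asarray(sorted(set(int(i) for i in set_b)), dtype=int)
    if set(idx_a.tolist()) & set(idx_b.tolist()):
        raise ValueError("atom sets must be disjoint")
    if idx_a.size == 0 or idx_b.size == 0:
        return 0.0, 0.0
    _check_parameters(topology, idx_a)
    _check_parameters(topology, idx_b)
    frame = np.asarray(frame, dtype=float)
    excluded, _ = topology.exclusions()
    tree = cKDTree(frame[idx_b])
    neighbors = tree.query_ball_point(frame[idx_a], cutoff)
    pairs = [(ia, ib) for ia, nb in enumerate(neighbors) for ib in nb
             if (min(idx_a[ia], idx_b[ib]), max(idx_a[ia], idx_b[ib])) not in excluded]
    if not pairs:
        return 0.0, 0.0
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    q_a, q_b, s_a, s_b, e_a, e_b = _pair_arrays(topology, idx_a, idx_b)
    r = np.linalg.norm(frame[idx_a[ia]] - frame[idx_b[ib]], axis=1)
    elec = float(np.sum(_screen(r, q_a[ia] * q_b[ib], solvent_model)))
    sigma = 0.5 * (s_a[ia] + s_b[ib])
    eps = np.sqrt(e_a[ia] * e_b[ib])
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(sigma > 0, (sigma / r) ** 6, 0.0)
    vdw = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
    return elec, vdw


def _angles_from_bonds(topology: Topology, atom_subset: set[int] | None = None):
    adj = topology.adjacency()
    angles = []
    for j in range(topology.n_atoms):
        if atom_subset is not None and j not in atom_subset:
            continue
        nbrs = sorted(adj[j])
        if atom_subset is not None:
            nbrs = [x for x in nbrs if x in atom_subset]
        for ii in range(len(nbrs)):
            for kk in range(ii + 1, len(nbrs)):
                angles.append((nbrs[ii], j, nbrs[kk]))
    return angles


def _theta0(topology: Topology, center: int, bonded: BondedParams) -> float:
    heavy = sum(1 for x in topology.bonded_neighbors(center)
                if topology.atoms[x].element.upper() != "H")
    return bonded.theta0_sp2 if heavy >= 3 else bonded.theta0_sp3


def chain_internal_energy(
    frame: np.ndarray,
    topology: Topology,
    chain: str,
    cutoff: float = DEFAULT_CUTOFF,
    bonded: BondedParams | None = None,
    include_bonded: bool = True,
) -> float:
    """Intra-chain energy: nonbonded (1-2/1-3 excluded, 1-4 scaled by 0.5)
    plus harmonic bond and angle terms, in kcal/mol."""
    idx = topology.chain_atoms(chain, include_solvent=False)
    if idx.size == 0:
        raise ValueError(f"chain {chain!r} not found or empty")
    model = PotentialModel(topology, atom_subset=idx, cutoff=cutoff,
                           bonded=bonded if bonded is not None else BondedParams(),
                           include_bonded=include_bonded)
    return model.energy(np.asarray(frame, dtype=float))


def protein_solvent_energy(
    frame: np.ndarray,
    topology: Topology,
    chain: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Interaction energy of one protein chain with all solvent (water and
    ions), electrostatic and van der Waals components summed."""
    solvent = topology.solvent_atoms()
    if solvent.size == 0:
        warnings.warn("no solvent atoms flagged; protein-solvent energy is 0")
        return 0.0
    chain_idx = topology.chain_atoms(chain, include_solvent=False)
    elec, vdw = pair_energy(frame, topology, chain_idx, solvent, cutoff)
    return elec + vdw


# -- formation energy ------------------------------------------------------

@dataclass
class EnergyComponents:
    """Mean Eq-style energy terms of one system over a window (kcal/mol)."""

    E_self: dict[str, float]
    E_solv: dict[str, float]
    E_inter: float = 0.0


@dataclass
class DimerFormationEnergy:
    delta_E: float
    uncertainty: float
    term_means: dict[str, float]
    term_sds: dict[str, float]
    series: dict[str, np.ndarray] = field(default_factory=dict)
    window: dict[str, list[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "delta_E": self.delta_E,
            "uncertainty": self.uncertainty,
            "terms": {k: {"mean": self.term_means[k], "sd": self.term_sds[k]}
                      for k in self.term_means},
        }


def _protein_chains(topology: Topology) -> list[str]:
    chains = []
    for res in topology.residues:
        a0 = topology.atoms[res.atom_start]
        if not a0.is_solvent and res.chain_id not in chains:
            chains.append(res.chain_id)
    return chains


def _chain_signature(topology: Topology, chain: str) -> list[str]:
    return [r.name for r in topology.residues
            if r.chain_id == chain
            and not topology.atoms[r.atom_start].is_solvent]


def second_half(n_frames: int) -> list[int]:
    """Default analysis window: the equilibrated second half of a run."""
    return list(range(n_frames // 2, n_frames))


def dimer_formation_energy(
    dimer_traj: Trajectory,
    monomer_traj_a: Trajectory,
    monomer_traj_b: Trajectory,
    window: dict[str, Sequence[int]] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    include_bonded: bool = True,
) -> DimerFormationEnergy:
    """Energy balance of forming the dimer from its separated monomers.

    Per-frame internal (E_self), protein-solvent (E_solv) and inter-chain
    (E_inter) terms are averaged over each system's window (second half by
    default); the balance subtracts monomer means from dimer-system means,
    term-wise, and the quoted uncertainty is the quadrature combination of
    the per-term standard deviations.
    """
    chains = _protein_chains(dimer_traj.topology)
    if len(chains) != 2:
        raise ValueError(f"dimer system must have 2 protein chains, found {chains}")
    ca, cb = chains
    mono_a_chain = _protein_chains(monomer_traj_a.topology)
    mono_b_chain = _protein_chains(monomer_traj_b.topology)
    if len(mono_a_chain) != 1 or len(mono_b_chain) != 1:
        raise ValueError("monomer systems must each have exactly 1 protein chain")
    if _chain_signature(dimer_traj.topology, ca) != _chain_signature(
            monomer_traj_a.topology, mono_a_chain[0]):
        raise ValueError("chain composition mismatch: dimer chain A vs monomer A")
    if _chain_signature(dimer_traj.topology, cb) != _chain_signature(
            monomer_traj_b.topology, mono_b_chain[0]):
        raise ValueError("chain composition mismatch: dimer chain B vs monomer B")

    if window is None:
        window = {}
    win_d = list(window.get("dimer", second_half(dimer_traj.n_frames)))
    win_a = list(window.get("monomer_a", second_half(monomer_traj_a.n_frames)))
    win_b = list(window.get("monomer_b", second_half(monomer_traj_b.n_frames)))
    for name, w in (("dimer", win_d), ("monomer_a", win_a), ("monomer_b", win_b)):
        if not w:
            raise ValueError(f"empty analysis window for {name}")

    series: dict[str, np.ndarray] = {}

    def _system_series(traj, chain_ids, with_inter):
        top = traj.topology
        frames = win_d if with_inter else (win_a if traj is monomer_traj_a else win_b)
        self_terms = {c: [] for c in chain_ids}
        solv_terms = {c: [] for c in chain_ids}
        inter = []
        has_solvent = top.solvent_atoms().size > 0
        for fi in frames:
            f = traj.frames[fi]
            for c in chain_ids:
                self_terms[c].append(
                    chain_internal_energy(f, top, c, cutoff, include_bonded=include_bonded))
                if has_solvent:
                    solv_terms[c].append(protein_solvent_energy(f, top, c, cutoff))
                else:
                    solv_terms[c].append(0.0)
            if with_inter:
                e, v = pair_energy(f, top, top.chain_atoms(chain_ids[0], False),
                                   top.chain_atoms(chain_ids[1], False), cutoff)
                inter.append(e + v)
        return self_terms, solv_terms, inter

    d_self, d_solv, d_inter = _system_series(dimer_traj, [ca, cb], True)
    a_self, a_solv, _ = _system_series(monomer_traj_a, mono_a_chain, False)
    b_self, b_solv, _ = _system_series(monomer_traj_b, mono_b_chain, False)

    series["E_self_AB"] = np.array(d_self[ca]) + np.array(d_self[cb])
    series["E_solv_AB"] = np.array(d_solv[ca]) + np.array(d_solv[cb])
    series["E_inter_AB"] = np.array(d_inter)
    series["E_self_A"] = np.array(a_self[mono_a_chain[0]])
    series["E_solv_A"] = np.array(a_solv[mono_a_chain[0]])
    series["E_self_B"] = np.array(b_self[mono_b_chain[0]])
    series["E_solv_B"] = np.array(b_solv[mono_b_chain[0]])

    means = {k: float(np.mean(v)) for k, v in series.items()}
    sds = {k: float(np.std(v)) for k, v in series.items()}
    delta = (means["E_self_AB"] + means["E_solv_AB"] + means["E_inter_AB"]
             - means["E_self_A"] - means["E_solv_A"]
             - means["E_self_B"] - means["E_solv_B"])
    uncertainty = float(np.sqrt(sum(s ** 2 for s in sds.values())))
    return DimerFormationEnergy(
        delta_E=float(delta), uncertainty=uncertainty, term_means=means,
        term_sds=sds, series=series,
        window={"dimer": win_d, "monomer_a": win_a, "monomer_b": win_b},
    )


# -- decomposition ---------------------------------------------------------

@dataclass
class ResidueEnergyDecomposition:
    """Per-residue share of the inter-chain energy (kcal/mol).

    Keys are (chain, author residue number); values are (electrostatic,
    van der Waals).  Each chain's contributions sum to the total E_inter.
    """

    contributions: dict[tuple[str, int], tuple[float, float]]
    total_electrostatic: float
    total_vdw: float

    @property
    def total(self) -> float:
        return self.total_electrostatic + self.total_vdw

    def to_records(self) -> list[dict]:
        return [
            {"chain": c, "residue": r, "electrostatic": e, "vdw": v,
             "total": e + v}
            for (c, r), (e, v) in sorted(self.contributions.items())
        ]


def decompose_interface_energy(
    frame: np.ndarray,
    topology: Topology,
    chain_a: str,
    chain_b: str,
    cutoff: float = DEFAULT_CUTOFF,
    solvent_model: str = "vacuum",
) -> ResidueEnergyDecomposition:
    """Residue-level split of the chain A / chain B interaction energy."""
    idx_b = topology.chain_atoms(chain_b, include_solvent=False)
    idx_a = topology.chain_atoms(chain_a, include_solvent=False)
    total_e, total_v = pair_energy(frame, topology, idx_a, idx_b, cutoff,
                                   solvent_model)
    contributions: dict[tuple[str, int], tuple[float, float]] = {}
    for res in topology.residues:
        if res.chain_id not in (chain_a, chain_b):
            continue
        if topology.atoms[res.atom_start].is_solvent:
            continue
        partner = idx_b if res.chain_id == chain_a else idx_a
        own = [i for i in res.atom_indices]
        e, v = pair_energy(frame, topology, own, partner, cutoff, solvent_model)
        contributions[(res.chain_id, res.author_number)] = (e, v)
    return ResidueEnergyDecomposition(contributions, total_e, total_v)


def implicit_binding_energy(
    frame: np.ndarray,
    topology: Topology,
    receptor: Sequence[int],
    ligand: Sequence[int],
    solvent_model: str = "distance_dielectric",
    cutoff: float = DEFAULT_CUTOFF,
):
    """MM/GBSA-like surrogate binding energy of a rigid complex frame.

    dG_bind = E(complex) - E(receptor) - E(ligand) under an implicit-solvent
    surrogate; for a rigid frame the intramolecular terms cancel, leaving
    the screened receptor-ligand cross energy.  Returns (dG, per-residue
    contributions keyed by the ligand-facing residue).  All outputs should
    be labelled "MM/GBSA-like surrogate" in reports.
    """
    if solvent_model not in ("vacuum", "distance_dielectric", "born_surrogate"):
        raise ValueError(f"unknown solvent model {solvent_model!r}")
    receptor = np.asarray(sorted(set(int(i) for i in receptor)), dtype=int)
    ligand = np.asarray(sorted(set(int(i) for i in ligand)), dtype=int)
    elec, vdw = pair_energy(frame, topology, receptor, ligand, cutoff, solvent_model)
    per_residue: dict[tuple[str, int], float] = {}
    lig_set = set(ligand.tolist())
    for res in topology.residues:
        own = [i for i in res.atom_indices if i in set(receptor.tolist())]
        if not own:
            continue
        e, v = pair_energy(frame, topology, own, ligand, cutoff, solvent_model)
        per_residue[(res.chain_id, res.author_number)] = e + v
    return float(elec + vdw), per_residue


# -- differentiable potential for minimization -----------------------------

class PotentialModel:
    """Energy + analytic gradient of a (sub)system under the package kernel.

    Precomputes the nonbonded pair list (all pairs within the atom subset
    minus 1-2/1-3 exclusions, 1-4 scaled by ``scale_14``), harmonic bonds
    and angles.  The cutoff is applied at evaluation time as a hard
    truncation.
    """

    def __init__(
        self,
        topology: Topology,
        atom_subset: Sequence[int] | None = None,
        cutoff: float = DEFAULT_CUTOFF,
        scale_14: float = 0.5,
        bonded: BondedParams | None = None,
        include_bonded: bool = True,
        solvent_model: str = "vacuum",
    ) -> None:
        self.topology = topology
        self.cutoff = cutoff
        self.solvent_model = solvent_model
        self.bonded = bonded if bonded is not None else BondedParams()
        self.include_bonded = include_bonded
        subset = (np.arange(topology.n_atoms) if atom_subset is None
                  else np.asarray(sorted(set(int(i) for i in atom_subset))))
        self.subset = subset
        sub_set = set(subset.tolist())
        excluded, one_four = topology.exclusions(scale_14=True)
        pairs_i, pairs_j, scales = [], [], []
        subset_list = subset.tolist()
        for a_pos in range(len(subset_list)):
            i = subset_list[a_pos]
            for b_pos in range(a_pos + 1, len(subset_list)):
                j = subset_list[b_pos]
                key = (i, j)
                if key in excluded:
                    continue
                pairs_i.append(i)
                pairs_j.append(j)
                scales.append(scale_14 if key in one_four else 1.0)
        atoms = topology.atoms
        self.pi = np.asarray(pairs_i, dtype=int)
        self.pj = np.asarray(pairs_j, dtype=int)
        self.scale = np.asarray(scales)
        self.qq = np.array([atoms[i].charge * atoms[j].charge
                            for i, j in zip(pairs_i, pairs_j)])
        self.sigma = np.array([0.5 * (atoms[i].lj_sigma + atoms[j].lj_sigma)
                               for i, j in zip(pairs_i, pairs_j)])
        self.eps = np.array([np.sqrt(atoms[i].lj_epsilon * atoms[j].lj_epsilon)
                             for i, j in zip(pairs_i, pairs_j)])
        self.bonds = [(i, j) for i, j in topology.bonds
                      if i in sub_set and j in sub_set]
        self.bond_r0 = np.array([
            self.bonded.r0(atoms[i].element, atoms[j].element)
            for i, j in self.bonds])
        self.angles = _angles_from_bonds(topology, sub_set)
        self.angle_t0 = np.array([
            np.radians(_theta0(topology, j, self.bonded))
            for (_, j, _) in self.angles])

    # energy ---------------------------------------------------------------

    def _nonbonded(self, coords, with_gradient):
        if self.pi.size == 0:
            return 0.0, (np.zeros_like(coords) if with_gradient else None)
        d = coords[self.pi] - coords[self.pj]
        r = np.linalg.norm(d, axis=1)
        mask = r <= self.cutoff
        r = np.where(mask, r, 1.0)
        elec_pair = self.scale * _screen(r, self.qq, self.solvent_model)
        with np.errstate(divide="ignore", invalid="ignore"):
            sr6 = np.where(self.sigma > 0, (self.sigma / r) ** 6, 0.0)
        vdw_pair = self.scale * 4.0 * self.eps * (sr6 * sr6 - sr6)
        energy = float(np.sum(np.where(mask, elec_pair + vdw_pair, 0.0)))
        if not with_gradient:
            return energy, None
        if self.solvent_model == "vacuum":
            de_dr = -self.scale * COULOMB_K * self.qq / r ** 2
        elif self.solvent_model == "distance_dielectric":
            de_dr = -2.0 * self.scale * COULOMB_K * self.qq / (4.0 * r ** 3)
        else:  # numeric derivative of the born surrogate screening
            h = 1e-6
            de_dr = self.scale * (
                _screen(r + h, self.qq, self.solvent_model)
                - _screen(r - h, self.qq, self.solvent_model)) / (2 * h)
        de_dr = de_dr + self.scale * 4.0 * self.eps * (-12 * sr6 * sr6 + 6 * sr6) / r
        de_dr = np.where(mask, de_dr, 0.0)
        grad = np.zeros_like(coords)
        contrib = (de_dr / r)[:, None] * d
        np.add.at(grad, self.pi, contrib)
        np.add.at(grad, self.pj, -contrib)
        return energy, grad

    def _bond_terms(self, coords, with_gradient):
        if not self.bonds:
            return 0.0, (np.zeros_like(coords) if with_gradient else None)
        bi = np.array([b[0] for b in self.bonds])
        bj = np.array([b[1] for b in self.bonds])
        d = coords[bi] - coords[bj]
        r = np.linalg.norm(d, axis=1)
        dr = r - self.bond_r0
        energy = float(np.sum(self.bonded.bond_k * dr ** 2))
        if not with_gradient:
            return energy, None
        de_dr = 2.0 * self.bonded.bond_k * dr
        grad = np.zeros_like(coords)
        contrib = (de_dr / r)[:, None] * d
        np.add.at(grad, bi, contrib)
        np.add.at(grad, bj, -contrib)
        return energy, grad

    def _angle_terms(self, coords, with_gradient):
        if not self.angles:
            return 0.0, (np.zeros_like(coords) if with_gradient else None)
        energy = 0.0
        grad = np.zeros_like(coords) if with_gradient else None
        k = self.bonded.angle_k
        for (i, j, l), t0 in zip(self.angles, self.angle_t0):
            u = coords[i] - coords[j]
            v = coords[l] - coords[j]
            nu = np.linalg.norm(u)
            nv = np.linalg.norm(v)
            cos_t = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(cos_t)
            dt = theta - t0
            energy += k * dt ** 2
            if with_gradient:
                sin_t = np.sqrt(max(1.0 - cos_t ** 2, 1e-12))
                uh = u / nu
                vh = v / nv
                dth_di = (cos_t * uh - vh) / (nu * sin_t)
                dth_dl = (cos_t * vh - uh) / (nv * sin_t)
                dth_dj = -(dth_di + dth_dl)
                de = 2.0 * k * dt
                grad[i] += de * dth_di
                grad[j] += de * dth_dj
                grad[l] += de * dth_dl
        return float(energy), grad

    def energy(self, coords: np.ndarray) -> float:
        coords = np.asarray(coords, dtype=float)
        e, _ = self._nonbonded(coords, False)
        if self.include_bonded:
            eb, _ = self._bond_terms(coords, False)
            ea, _ = self._angle_terms(coords, False)
            e += eb + ea
        return e

    def energy_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = np.asarray(coords, dtype=float)
        e, g = self._nonbonded(coords, True)
        if self.include_bonded:
            eb, gb = self._bond_terms(coords, True)
            ea, ga = self._angle_terms(coords, True)
            e += eb + ea
            g = g + gb + ga
        return e, g
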