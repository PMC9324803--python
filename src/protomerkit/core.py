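"""Core in-memory containers: atoms, topologies, trajectories, selections.

Coordinates are Cartesian and in Angstrom throughout the package.  Atom and
residue indices are 0-based internally; every user-facing report uses the
author residue numbering and chain id carried by the topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Trajectory",
    "select",
]


@dataclass
class Atom:
    """One atom with its nonbonded parameters and bookkeeping flags.

    charge is in elementary charges, lj_sigma in Angstrom and lj_epsilon in
    kcal/mol (Lennard-Jones 12-6 with Lorentz-Berthelot combining rules).
    """

    serial: int
    name: str
    element: str
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    residue_index: int = 0
    chain_id: str = "A"
    is_solvent: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): empty element")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError(
                f"atom {self.serial} ({self.name}): negative LJ parameter"
            )


@dataclass
class Residue:
    """Residue record: template name, author numbering, atom index range."""

    name: str
    author_number: int
    chain_id: str
    atom_start: int  # inclusive
    atom_stop: int  # exclusive

    @property
    def atom_indices(self) -> range:
        return range(self.atom_start, self.atom_stop)


@dataclass
class RoleAnnotations:
    """Per-atom chemical role flags used by the interaction detectors.

    hbond_donor_H maps a polar hydrogen index to its donor heavy atom.
    aromatic_rings is a list of atom-index tuples, one per ring (>= 5 atoms).
    """

    hbond_donor_H: dict[int, int] = field(default_factory=dict)
    hbond_acceptor: set[int] = field(default_factory=set)
    cation_group: set[int] = field(default_factory=set)
    anion_group: set[int] = field(default_factory=set)
    aromatic_rings: list[tuple[int, ...]] = field(default_factory=list)
    apolar_carbon: set[int] = field(default_factory=set)


class Topology:
    """Atoms, residues, chains, bonds and role annotations of one system."""

    def __init__(
        self,
        atoms: Sequence[Atom],
        residues: Sequence[Residue],
        bonds: Iterable[tuple[int, int]] = (),
        roles: RoleAnnotations | None = None,
    ) -> None:
        self.atoms = list(atoms)
        self.residues = list(residues)
        self.bonds = [(min(i, j), max(i, j)) for i, j in bonds]
        self.roles = roles if roles is not None else RoleAnnotations()
        self._validate()
        self._adjacency: dict[int, set[int]] | None = None
        self._exclusion_cache: dict[bool, tuple[set, set]] = {}

    def _validate(self) -> None:
        n = len(self.atoms)
        covered = []
        for res in self.residues:
            if not (0 <= res.atom_start <= res.atom_stop <= n):
                raise ValueError(f"residue {res.name}{res.author_number}: bad atom range")
            covered.extend(res.atom_indices)
        if sorted(covered) != list(range(n)):
            raise ValueError("residue atom ranges do not partition the atom list")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references invalid atom")
        for ring in self.roles.aromatic_rings:
            if len(ring) < 5:
                raise ValueError("aromatic ring with fewer than 5 member atoms")

    # -- derived views ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for res in self.residues:
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def chain_atoms(self, chain_id: str, include_solvent: bool = True) -> np.ndarray:
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and (include_solvent or not a.is_solvent)
        ]
        return np.asarray(idx, dtype=int)

    def solvent_atoms(self) -> np.ndarray:
        return np.asarray(
            [i for i, a in enumerate(self.atoms) if a.is_solvent], dtype=int
        )

    def residue_of(self, atom_index: int) -> Residue:
        return self.residues[self.atoms[atom_index].residue_index]

    def adjacency(self) -> dict[int, set[int]]:
        if self._adjacency is None:
            adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
            for i, j in self.bonds:
                adj[i].add(j)
                adj[j].add(i)
            self._adjacency = adj
        return self._adjacency

    def bonded_neighbors(self, i: int) -> set[int]:
        return self.adjacency()[i]

    def exclusions(self, scale_14: bool = False) -> tuple[set, set]:
        """(excluded 1-2/1-3 pairs, 1-4 pairs) as sets of sorted tuples."""
        if scale_14 in self._exclusion_cache:
            return self._exclusion_cache[scale_14]
        adj = self.adjacency()
        excluded: set[tuple[int, int]] = set()
        one_four: set[tuple[int, int]] = set()
        for i in range(self.n_atoms):
            for j in adj[i]:
                if i < j:
                    excluded.add((i, j))
                for k in adj[j]:
                    if k != i:
                        excluded.add((min(i, k), max(i, k)))
                        if scale_14:
                            for l in adj[k]:
                                if l not in (i, j):
                                    pair = (min(i, l), max(i, l))
                                    one_four.add(pair)
        one_four -= excluded
        one_four = {p for p in one_four if p[0] != p[1]}
        self._exclusion_cache[scale_14] = (excluded, one_four)
        return excluded, one_four

    def subset(self, atom_indices: Sequence[int]) -> "Topology":
        """New topology restricted to the given atoms (order preserved)."""
        atom_indices = list(atom_indices)
        old2new = {old: new for new, old in enumerate(atom_indices)}
        atoms = []
        res_map: dict[int, list[int]] = {}
        for new, old in enumerate(atom_indices):
            a = self.atoms[old]
            res_map.setdefault(a.residue_index, []).append(new)
            atoms.append(
                Atom(a.serial, a.name, a.element, a.charge, a.lj_sigma,
                     a.lj_epsilon, 0, a.chain_id, a.is_solvent)
            )
        residues = []
        for old_ri in sorted(res_map):
            news = res_map[old_ri]
            if news != list(range(news[0], news[-1] + 1)):
                raise ValueError("subset atoms must be contiguous within residues")
            old_res = self.residues[old_ri]
            ri = len(residues)
            for n_ in news:
                atoms[n_].residue_index = ri
            residues.append(
                Residue(old_res.name, old_res.author_number, old_res.chain_id,
                        news[0], news[-1] + 1)
            )
        bonds = [
            (old2new[i], old2new[j])
            for i, j in self.bonds
            if i in old2new and j in old2new
        ]
        roles = RoleAnnotations(
            hbond_donor_H={
                old2new[h]: old2new[d]
                for h, d in self.roles.hbond_donor_H.items()
                if h in old2new and d in old2new
            },
            hbond_acceptor={old2new[i] for i in self.roles.hbond_acceptor if i in old2new},
            cation_group={old2new[i] for i in self.roles.cation_group if i in old2new},
            anion_group={old2new[i] for i in self.roles.anion_group if i in old2new},
            aromatic_rings=[
                tuple(old2new[i] for i in ring)
                for ring in self.roles.aromatic_rings
                if all(i in old2new for i in ring)
            ],
            apolar_carbon={old2new[i] for i in self.roles.apolar_carbon if i in old2new},
        )
        return Topology(atoms, residues, bonds, roles)


class Trajectory:
    """Ordered coordinate frames (Angstrom) bound to one topology."""

    def __init__(
        self,
        topology: Topology,
        frames: Sequence[np.ndarray],
        frame_times: Sequence[float] | None = None,
    ) -> None:
        if len(frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        self.topology = topology
        self.frames = [np.asarray(f, dtype=float) for f in frames]
        for k, f in enumerate(self.frames):
            if f.shape != (topology.n_atoms, 3):
                raise ValueError(
                    f"frame {k}: expected {topology.n_atoms} atoms, got {f.shape[0]}"
                )
        self.frame_times = None if frame_times is None else list(frame_times)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return self.n_frames

    def coordinates(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked array."""
        return np.stack(self.frames)

    def sliced(self, frame_indices: Sequence[int]) -> "Trajectory":
        times = (
            None
            if self.frame_times is None
            else [self.frame_times[i] for i in frame_indices]
        )
        return Trajectory(self.topology, [self.frames[i] for i in frame_indices], times)


# -- selection mini-grammar ------------------------------------------------

def _match_resid(token: str, res: Residue) -> bool:
    if "-" in token[1:]:  # allow leading minus sign
        lo, hi = token.rsplit("-", 1) if not token.startswith("-") else (token, token)
        try:
            return int(lo) <= res.author_number <= int(hi)
        except ValueError:
            pass
    return res.author_number == int(token)


def select(topology: Topology, expression: str) -> np.ndarray:
    """Resolve a selection expression to sorted atom indices.

    Grammar: terms joined by ``and``; each term is one of
    ``all``, ``protein`` (non-solvent), ``solvent``, ``chain <id>[,<id>...]``,
    ``name <n>[,<n>...]``, ``resname <n>[,...]``, ``resid <a>[-<b>][,...]``,
    ``element <sym>[,...]``.  Example: ``chain A and name CA``.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    tokens = expression.split()
    i = 0
    while i < len(tokens):
        word = tokens[i].lower()
        if word == "and":
            i += 1
            continue
        if word == "all":
            i += 1
            continue
        if word == "protein":
            mask &= np.array([not a.is_solvent for a in topology.atoms])
            i += 1
            continue
        if word == "solvent":
            mask &= np.array([a.is_solvent for a in topology.atoms])
            i += 1
            continue
        if i + 1 >= len(tokens):
            raise ValueError(f"selection term '{tokens[i]}' lacks an argument")
        args = tokens[i + 1].split(",")
        if word == "chain":
            mask &= np.array([a.chain_id in args for a in topology.atoms])
        elif word == "name":
            mask &= np.array([a.name in args for a in topology.atoms])
        elif word == "element":
            up = {x.upper() for x in args}
            mask &= np.array([a.element.upper() in up for a in topology.atoms])
        elif word == "resname":
            mask &= np.array(
                [topology.residue_of(k).name in args for k in range(topology.n_atoms)]
            )
        elif word == "resid":
            mask &= np.array(
                [
                    any(_match_resid(tok, topology.residue_of(k)) for tok in args)
                    for k in range(topology.n_atoms)
                ]
            )
        else:
            raise ValueError(f"unknown selection term '{tokens[i]}'")
        i += 2
    return np.nonzero(mask)[0]
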