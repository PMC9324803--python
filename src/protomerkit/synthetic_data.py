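"""Self-contained toy systems and trajectories with planted ground truth.

The generators emulate the statistical structure the trajectory analyses
assume — interface contacts with known frame-wise occupancy, Gaussian
positional wobble, discrete conformational basins — without any physical
dynamics.  Two mini protein chains face each other across a ~10 A gap:
chain A residues sit near z = 0 with side chains pointing up, chain B
residues hang above with side chains pointing down, and each requested
contact type is planted on its own residue pair with at least 10% geometric
margin relative to the detector cutoffs.  Residues are independent
molecules (no inter-residue bonds), which keeps the toy potential free of
artificial backbone strain.

Every generator draws from one seeded NumPy Generator per call and is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Topology, Trajectory
from .energetics import COULOMB_K
from .interactions import InteractionCriteria, detect_interactions
from .io_structures import topology_from_records

__all__ = [
    "PlantedContact",
    "PlantedBasin",
    "PlantedSpec",
    "GroundTruth",
    "make_toy_dimer",
    "make_trajectory",
    "make_energy_fixture",
]

CONTACT_TYPES = ("hbond", "salt_bridge", "pi_pi", "pi_cation", "apolar")

_BACKBONE = [
    ("N", (-1.20, 0.77, 0.0)),
    ("H", (-1.58, 1.70, 0.0)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (1.25, 0.88, 0.0)),
    ("O", (1.85, 1.95, 0.0)),
]


def _ring(centroid, radius=1.39, phase=0.0, z_sign=1.0):
    """Hexagon atom offsets in the plane z = centroid_z (normal along z)."""
    out = []
    for k in range(6):
        ang = np.radians(phase + 60.0 * k)
        out.append((centroid[0] + radius * np.sin(ang),
                    centroid[1] - radius * np.cos(ang) * z_sign,
                    centroid[2]))
    return out


def _sidechain(restype: str):
    """Side-chain atom templates relative to CA, pointing toward +z."""
    if restype == "LYS":
        atoms = [("CB", (0, 0.6, 1.3)), ("CG", (0, -0.3, 2.5)),
                 ("CD", (0, 0.6, 3.7)), ("CE", (0, -0.3, 4.9)),
                 ("NZ", (0, 0.3, 6.1))]
        nz = np.array([0, 0.3, 6.1])
        for k, d in enumerate([(0.93, 0, -0.41), (-0.93, 0, -0.41),
                               (0, 0.93, -0.41)], 1):
            atoms.append((f"HZ{k}", tuple(nz + np.array(d))))
        return atoms
    if restype == "ASP":
        return [("CB", (0, 0.6, 1.3)), ("CG", (0, -0.2, 2.6)),
                ("OD1", (0, 0.2, 3.8)), ("OD2", (0, -1.4, 2.9))]
    if restype == "SER":
        return [("CB", (0, 0.6, 1.3)), ("OG", (0, 0.0, 2.6)),
                ("HG", (0, 0.0, 3.56))]
    if restype == "ASN":
        return [("CB", (0, 0.6, 1.3)), ("CG", (0, 0.0, 2.6)),
                ("OD1", (0, 0.0, 3.83)), ("ND2", (0, 1.2, 2.2)),
                ("HD21", (0.8, 1.7, 1.75)), ("HD22", (-0.8, 1.7, 1.75))]
    if restype == "PHE":
        atoms = [("CB", (0, 0.7, 1.2)), ("CG", (0, 0.5, 2.7))]
        names = ["CD1", "CE1", "CZ", "CE2", "CD2"]
        centroid = (0.0, 1.89, 2.7)
        ring = _ring(centroid)  # position 0 coincides with CG
        for name, xyz in zip(names, ring[1:]):
            atoms.append((name, xyz))
        return atoms
    if restype == "LEU":
        return [("CB", (0, 0.3, 1.3)), ("CG", (0, 0.0, 2.6)),
                ("CD1", (0, 0.5, 3.9)), ("CD2", (0, -1.2, 3.5))]
    if restype == "GLY":
        return []
    if restype == "ALA":
        return [("CB", (0, 0.6, 1.3))]
    raise ValueError(f"no toy template for residue {restype}")


#: per contact type: (A residue, B residue, B-side CA height above z=0,
#: optional extra lateral CA offset for chain B)
_CONTACT_LAYOUT = {
    "salt_bridge": ("LYS", "ASP", 12.9, (0.0, 0.1)),
    "hbond": ("SER", "ASN", 9.29, (0.0, 0.0)),
    "pi_pi": ("PHE", "PHE", 8.9, (0.0, 0.0)),
    "pi_cation": ("PHE", "LYS", 13.3, (0.0, 1.59)),
    "apolar": ("LEU", "LEU", 11.4, (0.0, 0.0)),
}

SPACING = 8.0  # A between consecutive residue slots along x
DEFAULT_B_HEIGHT = 10.0


@dataclass
class PlantedContact:
    """Ground truth for one planted interface contact."""

    type: str
    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    occupancy: float = 1.0
    schedule: np.ndarray | None = None  # filled by make_trajectory


@dataclass
class PlantedBasin:
    """A rigid displacement applied to chain B on a subset of frames."""

    translation: tuple[float, float, float]
    fraction: float


@dataclass
class PlantedSpec:
    """Planted trajectory structure: contacts, wobble, basins, seed."""

    contacts: list[PlantedContact] = field(default_factory=list)
    wobble_sigma: float = 0.05
    basins: list[PlantedBasin] = field(default_factory=list)
    seed: int = 0
    verify: bool = True


@dataclass
class GroundTruth:
    """Planted per-frame truth recorded by make_trajectory."""

    contact_schedules: dict[tuple, np.ndarray]
    basin_labels: np.ndarray


def make_toy_dimer(
    n_res_a: int,
    n_res_b: int,
    interface_contacts: Sequence[str] = (),
    filler: str = "GLY",
) -> tuple[Topology, np.ndarray, list[PlantedContact]]:
    """Two facing mini-chains with the requested contacts planted.

    Contact k occupies residue k of each chain (author numbers start at 1);
    remaining residues are ``filler`` (glycine by default; use e.g. "SER"
    or "LEU" to make non-interface positions alanine-scannable).  Chains
    need at least as many residues as contacts.
    """
    if n_res_a < 1 or n_res_b < 1:
        raise ValueError("each chain needs at least one residue")
    contacts = list(interface_contacts)
    for t in contacts:
        if t not in _CONTACT_LAYOUT:
            raise ValueError(f"unknown contact type {t!r}")
    if len(contacts) > min(n_res_a, n_res_b):
        raise ValueError("more contacts requested than residues available")

    records = []
    coords = []
    serial = 1

    def add_residue(restype, chain, number, ca, z_sign):
        nonlocal serial
        ca = np.asarray(ca, dtype=float)
        flip = np.array([1.0, 1.0, z_sign])
        for name, off in _BACKBONE + _sidechain(restype):
            xyz = ca + np.asarray(off) * flip
            records.append((serial, name, name[0], restype, number, chain))
            coords.append(xyz)
            serial += 1

    planted: list[PlantedContact] = []
    b_rows: list[tuple[str, int, np.ndarray]] = []
    for i in range(n_res_a):
        x = i * SPACING
        if i < len(contacts):
            res_a, res_b, zb, (dxb, dyb) = _CONTACT_LAYOUT[contacts[i]]
            add_residue(res_a, "A", i + 1, (x, 0.0, 0.0), +1.0)
            b_rows.append((res_b, i + 1, np.array([x + dxb, dyb, zb])))
            planted.append(PlantedContact(contacts[i], ("A", i + 1), ("B", i + 1)))
        else:
            add_residue(filler, "A", i + 1, (x, 0.0, 0.0), +1.0)
    for j in range(len(contacts), n_res_b):
        x = j * SPACING
        b_rows.append((filler, j + 1, np.array([x, 0.0, DEFAULT_B_HEIGHT])))
    b_rows.sort(key=lambda r: r[1])
    for res_b, number, ca in b_rows:
        add_residue(res_b, "B", number, ca, -1.0)

    topology = topology_from_records(records, link_polymer=False)
    coords = np.asarray(coords)

    # generator contract: every planted contact must actually be detected
    crit = InteractionCriteria()
    group_a = topology.chain_atoms("A")
    group_b = topology.chain_atoms("B")
    for pc in planted:
        events = detect_interactions(coords, topology, group_a, group_b,
                                     crit, (pc.type,))
        pairs = {(e.residue_1, e.residue_2) for e in events}
        if (pc.residue_a, pc.residue_b) not in pairs:
            raise AssertionError(
                f"toy geometry failed to plant {pc.type} at {pc.residue_a}")
    return topology, coords, planted


def _sidechain_atoms(topology: Topology, residue: tuple[str, int]) -> np.ndarray:
    for res in topology.residues:
        if (res.chain_id, res.author_number) == residue:
            return np.asarray(
                [i for i in res.atom_indices
                 if topology.atoms[i].name not in ("N", "CA", "C", "O", "H")],
                dtype=int)
    raise ValueError(f"residue {residue} not found")


def make_trajectory(
    topology: Topology,
    ideal_coords: np.ndarray,
    spec: PlantedSpec,
    n_frames: int,
) -> tuple[Trajectory, GroundTruth]:
    """Noisy frames around the ideal geometry with planted schedules.

    For each contact, round(occupancy * n_frames) frames are 'on'; on the
    remaining frames the B-side side chain of that contact is displaced 8 A
    upward, which breaks every detector criterion.  Basin displacements
    apply rigid chain-B translations to disjoint frame subsets.  With
    ``spec.verify`` the planted schedule is re-checked with the detectors
    and a violation (e.g. wobble too large) raises at generation time.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    ideal = np.asarray(ideal_coords, dtype=float)
    schedules: dict[tuple, np.ndarray] = {}
    off_shift = np.array([0.0, 0.0, 8.0])

    contact_atoms = {}
    for pc in spec.contacts:
        n_on = int(round(pc.occupancy * n_frames))
        order = rng.permutation(n_frames)
        on = np.zeros(n_frames, dtype=bool)
        on[order[:n_on]] = True
        pc.schedule = on
        schedules[(pc.residue_a, pc.residue_b, pc.type)] = on
        contact_atoms[(pc.residue_a, pc.residue_b, pc.type)] = _sidechain_atoms(
            topology, pc.residue_b)

    basin_labels = np.zeros(n_frames, dtype=int)
    if spec.basins:
        counts = [int(round(b.fraction * n_frames)) for b in spec.basins]
        if sum(counts) > n_frames:
            raise ValueError("basin fractions exceed the trajectory length")
        order = rng.permutation(n_frames)
        pos = 0
        for bi, c in enumerate(counts, start=1):
            basin_labels[order[pos:pos + c]] = bi
            pos += c
    chain_b = topology.chain_atoms("B")

    frames = []
    for k in range(n_frames):
        f = ideal.copy()
        for key, on in schedules.items():
            if not on[k]:
                f[contact_atoms[key]] += off_shift
        if basin_labels[k] > 0:
            basin = spec.basins[basin_labels[k] - 1]
            f[chain_b] += np.asarray(basin.translation)
        if spec.wobble_sigma > 0:
            f += rng.normal(0.0, spec.wobble_sigma, size=f.shape)
        frames.append(f)
    traj = Trajectory(topology, frames)

    if spec.verify and spec.contacts:
        group_a = topology.chain_atoms("A")
        group_b = topology.chain_atoms("B")
        types = tuple({pc.type for pc in spec.contacts})
        for k in range(n_frames):
            events = detect_interactions(traj.frames[k], topology, group_a,
                                         group_b, None, types, k)
            present = {(e.residue_1, e.residue_2, e.type) for e in events}
            for key, on in schedules.items():
                if on[k] and key not in present:
                    raise ValueError(
                        f"wobble sigma {spec.wobble_sigma} broke planted "
                        f"contact {key} in frame {k}")
                if not on[k] and key in present:
                    raise ValueError(
                        f"off-frame {k} still shows planted contact {key}")
    return traj, GroundTruth(schedules, basin_labels)


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom D given three predecessors and internal coordinates."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        -bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_dihedral_backbone(
    phi_psi: Sequence[tuple[float, float]],
    chain: str = "A",
    resname: str = "GLY",
) -> tuple[Topology, np.ndarray]:
    """Poly-residue N/CA/C backbone built from (phi, psi) in degrees.

    Standard bond geometry (N-CA 1.458, CA-C 1.525, C-N 1.329 A; trans
    peptide, omega = 180).  phi of the first residue and psi of the last
    are undefined and ignored.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    coords = []
    # first residue in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    ang = np.radians(111.2)
    c0 = ca0 + 1.525 * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.extend([n0, ca0, c0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[-3], coords[-2], coords[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = _nerf(n_prev, ca_prev, c_prev, 1.329, 116.2, psi_prev)
        ca_i = _nerf(ca_prev, c_prev, n_i, 1.458, 121.7, 180.0)
        c_i = _nerf(c_prev, n_i, ca_i, 1.525, 111.2, phi_psi[i][0])
        coords.extend([n_i, ca_i, c_i])
    records = []
    serial = 1
    for ri in range(n_res):
        for name in ("N", "CA", "C"):
            records.append((serial, name, name[0], resname, ri + 1, chain))
            serial += 1
    topology = topology_from_records(records)
    return topology, np.asarray(coords)


# -- energy fixtures -------------------------------------------------------

def _point_topology(specs, solvent_flags=None):
    """Chains of single-residue point particles with explicit parameters.

    specs: list of (chain, resname, atom name, element, charge, sigma,
    epsilon, xyz).
    """
    from .core import Atom, Residue

    atoms, residues, coords = [], [], []
    for k, (chain, resname, name, element, q, s, e, xyz) in enumerate(specs):
        solvent = solvent_flags[k] if solvent_flags else False
        atoms.append(Atom(k + 1, name, element, q, s, e, len(residues), chain,
                          solvent))
        residues.append(Residue(resname, len(residues) + 1, chain, k, k + 1))
        coords.append(xyz)
    return Topology(atoms, residues), np.asarray(coords, dtype=float)


def make_energy_fixture(kind: str, seed: int = 0) -> dict:
    """Toy systems with closed-form expectations for every energy term.

    Kinds: ``charge_pair`` (+1/-1 e at 3.320636 A -> E_inter exactly -100
    kcal/mol), ``lj_pair`` (LJ minimum -> -epsilon), ``separated_dimer``
    (chains beyond twice the cutoff -> dE = 0) and ``solvated_monomers``
    (one charge + one 3-site water per monomer; E_solv hand-summed here by
    direct per-site Coulomb terms).  Returns systems, trajectories and an
    ``expected`` dict.
    """
    r100 = 3.320636
    if kind == "charge_pair":
        dimer_top, dimer_xyz = _point_topology([
            ("A", "QPT", "Q1", "NA", +1.0, 0.0, 0.0, (0.0, 0.0, 0.0)),
            ("B", "QPT", "Q2", "CL", -1.0, 0.0, 0.0, (r100, 0.0, 0.0)),
        ])
        mono_a_top, mono_a_xyz = _point_topology(
            [("A", "QPT", "Q1", "NA", +1.0, 0.0, 0.0, (0.0, 0.0, 0.0))])
        mono_b_top, mono_b_xyz = _point_topology(
            [("B", "QPT", "Q2", "CL", -1.0, 0.0, 0.0, (0.0, 0.0, 0.0))])
        return {
            "dimer": Trajectory(dimer_top, [dimer_xyz]),
            "monomer_a": Trajectory(mono_a_top, [mono_a_xyz]),
            "monomer_b": Trajectory(mono_b_top, [mono_b_xyz]),
            "expected": {"E_inter": -COULOMB_K / r100, "delta_E": -100.0},
        }
    if kind == "lj_pair":
        sigma, eps = 3.0, 0.5
        r_min = 2.0 ** (1.0 / 6.0) * sigma
        top, xyz = _point_topology([
            ("A", "LJP", "C1", "C", 0.0, sigma, eps, (0.0, 0.0, 0.0)),
            ("B", "LJP", "C2", "C", 0.0, sigma, eps, (r_min, 0.0, 0.0)),
        ])
        return {"system": Trajectory(top, [xyz]), "r_min": r_min,
                "sigma": sigma, "epsilon": eps,
                "expected": {"E_vdw": -eps}}
    if kind == "separated_dimer":
        rng = np.random.default_rng(seed)
        base = rng.uniform(-1.5, 1.5, size=(3, 3))
        charges = [0.4, -0.7, 0.3]
        far = 30.0  # > 2 x default cutoff
        specs = []
        for k in range(3):
            specs.append(("A", "TRI", f"C{k+1}", "C", charges[k], 3.0, 0.1,
                          tuple(base[k])))
        for k in range(3):
            specs.append(("B", "TRI", f"C{k+1}", "C", charges[k], 3.0, 0.1,
                          tuple(base[k] + np.array([far, 0.0, 0.0]))))
        dimer_top, dimer_xyz = _point_topology(specs)
        mono_top, mono_xyz = _point_topology(specs[:3])
        mono_b_top, mono_b_xyz = _point_topology(
            [("B",) + s[1:] for s in specs[:3]])
        return {
            "dimer": Trajectory(dimer_top, [dimer_xyz]),
            "monomer_a": Trajectory(mono_top, [mono_xyz]),
            "monomer_b": Trajectory(mono_b_top, [mono_b_xyz]),
            "expected": {"delta_E": 0.0},
        }
    if kind == "solvated_monomers":
        # one +0.5 e point charge per monomer plus one SPC-like water;
        # the dimer carries the two charges far apart and no solvent
        q = 0.5
        qo, qh = -0.82, 0.41
        water = [("W", "HOH", "OW", "O", qo, 3.166, 0.1553, (3.0, 0.0, 0.0)),
                 ("W", "HOH", "HW1", "H", qh, 0.0, 0.0, (3.6, 0.8, 0.0)),
                 ("W", "HOH", "HW2", "H", qh, 0.0, 0.0, (3.6, -0.8, 0.0))]
        probe_a = ("A", "QPT", "Q1", "NA", q, 0.0, 0.0, (0.0, 0.0, 0.0))
        probe_b = ("B", "QPT", "Q1", "NA", q, 0.0, 0.0, (0.0, 0.0, 0.0))
        mono_a_top, mono_a_xyz = _point_topology(
            [probe_a] + water, solvent_flags=[False, True, True, True])
        mono_b_top, mono_b_xyz = _point_topology(
            [probe_b] + water, solvent_flags=[False, True, True, True])
        far = 40.0
        dimer_top, dimer_xyz = _point_topology([
            probe_a,
            ("B", "QPT", "Q1", "NA", q, 0.0, 0.0, (far, 0.0, 0.0)),
        ])
        # hand-summed per-site Coulomb (LJ vanishes: probe sigma = 0)
        e_solv = 0.0
        probe_xyz = np.array(probe_a[7])
        for (_, _, _, _, qs, _, _, xyz) in water:
            e_solv += COULOMB_K * q * qs / np.linalg.norm(np.array(xyz) - probe_xyz)
        expected_delta = 0.0 - 2.0 * e_solv  # dimer has no solvent terms
        return {
            "dimer": Trajectory(dimer_top, [dimer_xyz]),
            "monomer_a": Trajectory(mono_a_top, [mono_a_xyz]),
            "monomer_b": Trajectory(mono_b_top, [mono_b_xyz]),
            "expected": {"E_solv_monomer": e_solv, "delta_E": expected_delta},
        }
    raise ValueError(f"unknown fixture kind {kind!r}")
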