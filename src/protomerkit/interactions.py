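"""Geometric detection of non-covalent contacts and their time persistence.

Detected classes and default criteria (all cutoffs inclusive, config-exposed;
they mirror widely used interaction-fingerprint definitions):

* hbond        H...acceptor <= 2.8 A, donor-H...acceptor angle >= 120 deg,
               H...acceptor-antecedent angle >= 90 deg for every heavy
               neighbor of the acceptor (vacuous when it has none)
* salt_bridge  cationic-group N to anionic-group O <= 4.0 A
* pi_pi        ring-centroid distance <= 4.4 A with inter-plane angle
               <= 30 deg (face-to-face), or <= 5.5 A with 60-90 deg
               (edge-to-face; plane angles are folded into [0, 90])
* pi_cation    cation atom to ring centroid <= 6.6 A, cation within 30 deg
               of the ring normal
* apolar       carbon-carbon <= 4.5 A between apolar side-chain carbons
               (an in-package surrogate for external hydrophobic-contact
               servers; flagged as such in reports)

Candidate pairs come from a cKDTree fixed-radius search, which returns
exactly the pairs an all-against-all scan would (same metric, inclusive
radius), so detector output is identical to a brute-force recheck.

Persistence of a contact is the exact fraction of frames in which at least
one event of its type links the residue pair; the conventional report filter
keeps pairs present for more than 30% of the simulated time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import Topology, Trajectory

__all__ = [
    "InteractionCriteria",
    "InteractionEvent",
    "PersistenceProfile",
    "detect_interactions",
    "interaction_count_series",
    "persistence_profile",
    "ALL_TYPES",
]

ALL_TYPES = ("hbond", "salt_bridge", "pi_pi", "pi_cation", "apolar")

PERSISTENCE_THRESHOLD = 0.30


@dataclass
class InteractionCriteria:
    """Geometric cutoffs for every contact class (Angstrom / degrees)."""

    hbond_distance: float = 2.8
    hbond_donor_angle: float = 120.0
    hbond_acceptor_angle: float = 90.0
    hbond_heavy_fallback_distance: float = 3.5
    salt_bridge_distance: float = 4.0
    pi_pi_face_distance: float = 4.4
    pi_pi_face_angle: float = 30.0
    pi_pi_edge_distance: float = 5.5
    pi_pi_edge_angle: float = 60.0
    pi_cation_distance: float = 6.6
    pi_cation_angle: float = 30.0
    apolar_distance: float = 4.5

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class InteractionEvent:
    """One detected contact in one frame.

    ``residue_1`` always belongs to the first query group; atom indices are
    0-based topology indices (for ring contacts, the full ring tuple).
    ``geometry`` records the distances (A) and angles (deg) actually
    measured.
    """

    frame: int
    type: str
    atoms: tuple
    residue_1: tuple[str, int]
    residue_2: tuple[str, int]
    geometry: dict[str, float] = field(default_factory=dict)

    @property
    def residue_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.residue_1, self.residue_2)


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u = a - vertex
    v = b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, vt[2]


def _pairs_within(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float):
    """Index pairs (i into a, j into b) with distance <= cutoff."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return []
    tree = cKDTree(coords_b)
    out = []
    for i, neighbors in enumerate(tree.query_ball_point(coords_a, cutoff)):
        for j in neighbors:
            out.append((i, j))
    return out


def _res_key(topology: Topology, atom_index: int) -> tuple[str, int]:
    res = topology.residue_of(atom_index)
    return (res.chain_id, res.author_number)


def detect_interactions(
    frame: np.ndarray,
    topology: Topology,
    group_a: Sequence[int],
    group_b: Sequence[int],
    criteria: InteractionCriteria | None = None,
    types: Iterable[str] = ALL_TYPES,
    frame_index: int = 0,
) -> list[InteractionEvent]:
    """All contacts between two disjoint atom groups in one frame.

    Detection is symmetric in the two groups up to partner ordering:
    ``residue_1`` is reported from ``group_a``.
    """
    frame = np.asarray(frame, dtype=float)
    crit = criteria if criteria is not None else InteractionCriteria()
    set_a = set(int(i) for i in group_a)
    set_b = set(int(i) for i in group_b)
    if set_a & set_b:
        raise ValueError("query groups must be disjoint")
    events: list[InteractionEvent] = []
    for t in types:
        if t == "hbond":
            events.extend(_detect_hbonds(frame, topology, set_a, set_b, crit, frame_index))
        elif t == "salt_bridge":
            events.extend(_detect_salt_bridges(frame, topology, set_a, set_b, crit, frame_index))
        elif t == "pi_pi":
            events.extend(_detect_pi_pi(frame, topology, set_a, set_b, crit, frame_index))
        elif t == "pi_cation":
            events.extend(_detect_pi_cation(frame, topology, set_a, set_b, crit, frame_index))
        elif t == "apolar":
            events.extend(_detect_apolar(frame, topology, set_a, set_b, crit, frame_index))
        else:
            raise ValueError(f"unknown interaction type {t!r}")
    return events


def _directed_pairs(set_a, set_b):
    yield set_a, set_b, False
    yield set_b, set_a, True


def _mk_event(topology, frame_index, type_, atoms, idx_in_a, idx_in_b, geometry):
    return InteractionEvent(
        frame=frame_index, type=type_, atoms=tuple(atoms),
        residue_1=_res_key(topology, idx_in_a),
        residue_2=_res_key(topology, idx_in_b),
        geometry=geometry,
    )


def _detect_hbonds(frame, topology, set_a, set_b, crit, frame_index):
    roles = topology.roles
    events = []
    if not roles.hbond_donor_H:
        # no hydrogens anywhere: documented heavy-atom fallback
        return _detect_hbonds_heavy(frame, topology, set_a, set_b, crit, frame_index)
    for donors_from, acceptors_from, swapped in _directed_pairs(set_a, set_b):
        dh = [(h, d) for h, d in roles.hbond_donor_H.items() if h in donors_from]
        acc = [a for a in roles.hbond_acceptor if a in acceptors_from]
        if not dh or not acc:
            continue
        h_coords = frame[[h for h, _ in dh]]
        a_coords = frame[acc]
        for hi, ai in _pairs_within(h_coords, a_coords, crit.hbond_distance):
            h, d = dh[hi]
            a = acc[ai]
            dist = float(np.linalg.norm(frame[h] - frame[a]))
            donor_angle = _angle(frame[d], frame[h], frame[a])
            if donor_angle < crit.hbond_donor_angle:
                continue
            antecedents = [j for j in topology.bonded_neighbors(a)
                           if topology.atoms[j].element.upper() != "H"]
            acc_angles = [_angle(frame[h], frame[a], frame[j]) for j in antecedents]
            if acc_angles and min(acc_angles) < crit.hbond_acceptor_angle:
                continue
            geometry = {"distance": dist, "donor_angle": donor_angle}
            if acc_angles:
                geometry["acceptor_angle"] = min(acc_angles)
            a_side, b_side = ((a, h) if swapped else (h, a))
            events.append(_mk_event(topology, frame_index, "hbond", (d, h, a),
                                    a_side, b_side, geometry))
    return events


def _detect_hbonds_heavy(frame, topology, set_a, set_b, crit, frame_index):
    """Distance-only donor/acceptor criterion for hydrogen-free topologies."""
    polar_a = [i for i in set_a if topology.atoms[i].element.upper() in ("N", "O")]
    polar_b = [i for i in set_b if topology.atoms[i].element.upper() in ("N", "O")]
    events = []
    for ia, ib in _pairs_within(frame[polar_a] if polar_a else np.empty((0, 3)),
                                frame[polar_b] if polar_b else np.empty((0, 3)),
                                crit.hbond_heavy_fallback_distance):
        i, j = polar_a[ia], polar_b[ib]
        dist = float(np.linalg.norm(frame[i] - frame[j]))
        events.append(_mk_event(topology, frame_index, "hbond", (i, j), i, j,
                                {"distance": dist, "heavy_fallback": 1.0}))
    return events


def _detect_salt_bridges(frame, topology, set_a, set_b, crit, frame_index):
    roles = topology.roles
    events = []
    for pos_from, neg_from, swapped in _directed_pairs(set_a, set_b):
        cations = sorted(roles.cation_group & pos_from)
        anions = sorted(roles.anion_group & neg_from)
        if not cations or not anions:
            continue
        for ci, ai in _pairs_within(frame[cations], frame[anions],
                                    crit.salt_bridge_distance):
            c, a = cations[ci], anions[ai]
            dist = float(np.linalg.norm(frame[c] - frame[a]))
            a_side, b_side = ((a, c) if swapped else (c, a))
            events.append(_mk_event(topology, frame_index, "salt_bridge",
                                    (c, a), a_side, b_side, {"distance": dist}))
    return events


def _group_rings(topology, atom_set):
    return [ring for ring in topology.roles.aromatic_rings
            if all(i in atom_set for i in ring)]


def _detect_pi_pi(frame, topology, set_a, set_b, crit, frame_index):
    rings_a = _group_rings(topology, set_a)
    rings_b = _group_rings(topology, set_b)
    events = []
    for ra in rings_a:
        ca, na = _ring_plane(frame[list(ra)])
        for rb in rings_b:
            cb, nb = _ring_plane(frame[list(rb)])
            dist = float(np.linalg.norm(ca - cb))
            if dist > max(crit.pi_pi_face_distance, crit.pi_pi_edge_distance):
                continue
            cosang = abs(float(np.dot(na, nb)))
            plane_angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            face = (dist <= crit.pi_pi_face_distance
                    and plane_angle <= crit.pi_pi_face_angle)
            edge = (dist <= crit.pi_pi_edge_distance
                    and plane_angle >= crit.pi_pi_edge_angle)
            if face or edge:
                events.append(_mk_event(
                    topology, frame_index, "pi_pi", (ra, rb), ra[0], rb[0],
                    {"distance": dist, "plane_angle": plane_angle,
                     "face_to_face": 1.0 if face else 0.0}))
    return events


def _detect_pi_cation(frame, topology, set_a, set_b, crit, frame_index):
    roles = topology.roles
    events = []
    for cat_from, ring_from, swapped in _directed_pairs(set_a, set_b):
        cations = sorted(roles.cation_group & cat_from)
        rings = _group_rings(topology, ring_from)
        for ring in rings:
            centroid, normal = _ring_plane(frame[list(ring)])
            for c in cations:
                vec = frame[c] - centroid
                dist = float(np.linalg.norm(vec))
                if dist > crit.pi_cation_distance or dist == 0.0:
                    continue
                cosang = abs(float(np.dot(vec / dist, normal)))
                off_axis = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
                if off_axis <= crit.pi_cation_angle:
                    a_side, b_side = ((ring[0], c) if swapped else (c, ring[0]))
                    events.append(_mk_event(
                        topology, frame_index, "pi_cation", (c, ring),
                        a_side, b_side,
                        {"distance": dist, "off_axis_angle": off_axis}))
    return events


def _detect_apolar(frame, topology, set_a, set_b, crit, frame_index):
    carbons_a = sorted(topology.roles.apolar_carbon & set_a)
    carbons_b = sorted(topology.roles.apolar_carbon & set_b)
    events = []
    if not carbons_a or not carbons_b:
        return events
    for ia, ib in _pairs_within(frame[carbons_a], frame[carbons_b],
                                crit.apolar_distance):
        i, j = carbons_a[ia], carbons_b[ib]
        dist = float(np.linalg.norm(frame[i] - frame[j]))
        events.append(_mk_event(topology, frame_index, "apolar", (i, j), i, j,
                                {"distance": dist}))
    return events


# -- time statistics -------------------------------------------------------

def _resolve_range(traj: Trajectory, frame_range) -> list[int]:
    if frame_range is None:
        return list(range(traj.n_frames))
    frames = list(frame_range)
    if not frames:
        raise ValueError("empty frame range")
    return frames


def interaction_count_series(
    traj: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    type: str,
    criteria: InteractionCriteria | None = None,
    frame_range: Iterable[int] | None = None,
):
    """Per-frame distinct-contact counts with mean and population SD.

    A contact is counted once per residue pair per frame even when several
    atom pairs qualify, matching residue-level reporting.
    """
    frames = _resolve_range(traj, frame_range)
    counts = np.empty(len(frames), dtype=int)
    for k, fi in enumerate(frames):
        events = detect_interactions(traj.frames[fi], traj.topology, group_a,
                                     group_b, criteria, (type,), fi)
        counts[k] = len({e.residue_pair for e in events})
    return counts, float(np.mean(counts)), float(np.std(counts))


@dataclass
class PersistenceProfile:
    """Occupancy fraction per (residue pair, type) over an analysis window."""

    entries: dict[tuple[tuple[str, int], tuple[str, int], str], float]
    counts: dict[tuple[tuple[str, int], tuple[str, int], str], int]
    n_frames: int

    def filtered(self, threshold: float = PERSISTENCE_THRESHOLD) -> dict:
        """Pairs persisting for more than ``threshold`` of the window."""
        return {k: v for k, v in self.entries.items() if v > threshold}

    def to_records(self) -> list[dict]:
        rows = []
        for (r1, r2, t), frac in sorted(self.entries.items()):
            rows.append({
                "chain_1": r1[0], "residue_1": r1[1],
                "chain_2": r2[0], "residue_2": r2[1],
                "type": t, "fraction": frac,
                "n_frames": self.n_frames,
            })
        return rows


def persistence_profile(
    traj: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    types: Iterable[str] = ALL_TYPES,
    criteria: InteractionCriteria | None = None,
    frame_range: Iterable[int] | None = None,
) -> PersistenceProfile:
    """Fraction of frames each residue pair shows each contact type.

    Fractions are exact ratios of integer counts over the window length.
    """
    frames = _resolve_range(traj, frame_range)
    counts: dict[tuple, int] = {}
    for fi in frames:
        events = detect_interactions(traj.frames[fi], traj.topology, group_a,
                                     group_b, criteria, types, fi)
        seen = {(e.residue_1, e.residue_2, e.type) for e in events}
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    n = len(frames)
    entries = {k: c / n for k, c in counts.items()}
    return PersistenceProfile(entries, counts, n)
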