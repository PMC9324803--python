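"""Independent brute-force re-implementations used as test oracles.

Everything here is written as plain double/triple loops straight from the
geometric and algorithmic definitions, deliberately sharing no code with
the package implementations beyond the ring-plane convention (best-fit SVD
plane, which is the definition of the ring plane, not an implementation
detail).
"""

import numpy as np

COULOMB_K = 332.0636


def angle_deg(a, vertex, b):
    u = np.asarray(a) - np.asarray(vertex)
    v = np.asarray(b) - np.asarray(vertex)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


def ring_plane(coords):
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid, full_matrices=False)
    return centroid, vt[2]


def brute_force_events(frame, topology, group_a, group_b, criteria):
    """All-pairs recheck of every interaction criterion.

    Returns a set of hashable event keys:
    (type, atoms-or-rings tuple, residue_1, residue_2).
    """
    set_a, set_b = set(map(int, group_a)), set(map(int, group_b))
    roles = topology.roles
    c = criteria
    events = set()

    def reskey(i):
        r = topology.residue_of(i)
        return (r.chain_id, r.author_number)

    # hydrogen bonds (directed: donors of one side to acceptors of the other)
    for donors, acceptors, swapped in ((set_a, set_b, False), (set_b, set_a, True)):
        for h, d in roles.hbond_donor_H.items():
            if h not in donors:
                continue
            for a in roles.hbond_acceptor:
                if a not in acceptors:
                    continue
                if np.linalg.norm(frame[h] - frame[a]) > c.hbond_distance:
                    continue
                if angle_deg(frame[d], frame[h], frame[a]) < c.hbond_donor_angle:
                    continue
                ants = [j for j in topology.bonded_neighbors(a)
                        if topology.atoms[j].element.upper() != "H"]
                if ants and min(angle_deg(frame[h], frame[a], frame[j])
                                for j in ants) < c.hbond_acceptor_angle:
                    continue
                r1, r2 = (reskey(a), reskey(h)) if swapped else (reskey(h), reskey(a))
                events.add(("hbond", (d, h, a), r1, r2))

    for cations, anions, swapped in ((set_a, set_b, False), (set_b, set_a, True)):
        for i in roles.cation_group:
            if i not in cations:
                continue
            for j in roles.anion_group:
                if j not in anions:
                    continue
                if np.linalg.norm(frame[i] - frame[j]) <= c.salt_bridge_distance:
                    r1, r2 = (reskey(j), reskey(i)) if swapped else (reskey(i), reskey(j))
                    events.add(("salt_bridge", (i, j), r1, r2))

    rings_a = [r for r in roles.aromatic_rings if all(i in set_a for i in r)]
    rings_b = [r for r in roles.aromatic_rings if all(i in set_b for i in r)]
    for ra in rings_a:
        ca_, na_ = ring_plane(frame[list(ra)])
        for rb in rings_b:
            cb_, nb_ = ring_plane(frame[list(rb)])
            dist = np.linalg.norm(ca_ - cb_)
            ang = np.degrees(np.arccos(np.clip(abs(np.dot(na_, nb_)), 0, 1)))
            face = dist <= c.pi_pi_face_distance and ang <= c.pi_pi_face_angle
            edge = dist <= c.pi_pi_edge_distance and ang >= c.pi_pi_edge_angle
            if face or edge:
                events.add(("pi_pi", (ra, rb), reskey(ra[0]), reskey(rb[0])))

    for cations, ringside, swapped in ((set_a, set_b, False), (set_b, set_a, True)):
        rings = [r for r in roles.aromatic_rings if all(i in ringside for i in r)]
        for ring in rings:
            centroid, normal = ring_plane(frame[list(ring)])
            for i in roles.cation_group:
                if i not in cations:
                    continue
                vec = frame[i] - centroid
                dist = np.linalg.norm(vec)
                if dist == 0 or dist > c.pi_cation_distance:
                    continue
                off = np.degrees(np.arccos(np.clip(abs(np.dot(vec / dist, normal)), 0, 1)))
                if off <= c.pi_cation_angle:
                    r1, r2 = ((reskey(ring[0]), reskey(i)) if swapped
                              else (reskey(i), reskey(ring[0])))
                    events.add(("pi_cation", (i, ring), r1, r2))

    for i in roles.apolar_carbon & set_a:
        for j in roles.apolar_carbon & set_b:
            if np.linalg.norm(frame[i] - frame[j]) <= c.apolar_distance:
                events.add(("apolar", (i, j), reskey(i), reskey(j)))
    return events


def event_keys(events):
    """Package events converted to the oracle's key form."""
    return {(e.type, e.atoms, e.residue_1, e.residue_2) for e in events}


def naive_pair_energy(frame, topology, set_a, set_b, cutoff=12.0):
    """Direct double-loop Coulomb + LJ with the same exclusion rule."""
    excluded, _ = topology.exclusions()
    elec = vdw = 0.0
    for i in set_a:
        for j in set_b:
            if (min(i, j), max(i, j)) in excluded:
                continue
            r = np.linalg.norm(frame[i] - frame[j])
            if r > cutoff:
                continue
            ai, aj = topology.atoms[i], topology.atoms[j]
            elec += COULOMB_K * ai.charge * aj.charge / r
            sigma = 0.5 * (ai.lj_sigma + aj.lj_sigma)
            eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            if sigma > 0:
                sr6 = (sigma / r) ** 6
                vdw += 4 * eps * (sr6 ** 2 - sr6)
    return elec, vdw


def gromos_peeling(matrix, cutoff):
    """Step-by-step literal transcription of the neighbor-peeling rule."""
    n = matrix.shape[0]
    unassigned = set(range(n))
    labels = [-1] * n
    sizes, centers = [], []
    cid = 0
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned
                        if j != i and matrix[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = {best} | {j for j in unassigned
                            if j != best and matrix[best, j] <= cutoff}
        for m in members:
            labels[m] = cid
        unassigned -= members
        sizes.append(len(members))
        centers.append(best)
        cid += 1
    return labels, sizes, centers
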