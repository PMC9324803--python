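"""Interaction detectors against a brute-force oracle; persistence stats."""

import numpy as np
import pytest

import protomerkit as pk
from protomerkit.interactions import InteractionCriteria, detect_interactions

from oracles import brute_force_events, event_keys


def _groups(top):
    return top.chain_atoms("A"), top.chain_atoms("B")


class TestDetectors:
    def test_planted_contacts_found(self, toy_dimer_all_contacts):
        top, xyz, planted = toy_dimer_all_contacts
        ga, gb = _groups(top)
        for pc in planted:
            events = detect_interactions(xyz, top, ga, gb, types=(pc.type,))
            pairs = {(e.residue_1, e.residue_2) for e in events}
            assert (pc.residue_a, pc.residue_b) in pairs

    def test_ideal_hbond_geometry(self):
        """N-H...O at 1.9 A and 180 deg is one hydrogen bond; 4 A is none."""
        top, xyz, planted = pk.make_toy_dimer(2, 2, ["hbond"])
        ga, gb = _groups(top)
        events = detect_interactions(xyz, top, ga, gb, types=("hbond",))
        assert len({(e.residue_1, e.residue_2) for e in events}) == 1
        (ev,) = [e for e in events]
        assert ev.geometry["distance"] == pytest.approx(1.9, abs=0.05)
        far = xyz.copy()
        accept = [i for i in range(top.n_atoms) if top.atoms[i].name == "OD1"]
        far[accept] += np.array([0.0, 0.0, 2.1])  # H...O beyond 2.8 A
        assert detect_interactions(far, top, ga, gb, types=("hbond",)) == []

    def test_groups_must_be_disjoint(self, toy_dimer_all_contacts):
        top, xyz, _ = toy_dimer_all_contacts
        ga, _ = _groups(top)
        with pytest.raises(ValueError, match="disjoint"):
            detect_interactions(xyz, top, ga, ga)

    def test_symmetry_under_group_swap(self, toy_dimer_all_contacts):
        top, xyz, _ = toy_dimer_all_contacts
        ga, gb = _groups(top)
        fwd = detect_interactions(xyz, top, ga, gb)
        rev = detect_interactions(xyz, top, gb, ga)
        fwd_pairs = {(e.type, e.residue_1, e.residue_2) for e in fwd}
        rev_pairs = {(e.type, e.residue_2, e.residue_1) for e in rev}
        assert fwd_pairs == rev_pairs

    @pytest.mark.parametrize("seed", range(10))
    def test_random_frames_equal_brute_force(self, toy_dimer_all_contacts, seed):
        """Scrambled geometry: detector output = all-pairs recheck, exactly."""
        top, xyz, _ = toy_dimer_all_contacts
        rng = np.random.default_rng(seed)
        frame = xyz + rng.normal(scale=2.5, size=xyz.shape)
        ga, gb = _groups(top)
        crit = InteractionCriteria()
        got = event_keys(detect_interactions(frame, top, ga, gb, crit))
        assert got == brute_force_events(frame, top, ga, gb, crit)

    def test_tightening_cutoffs_monotone(self, toy_dimer_all_contacts):
        """Shrinking any distance cutoff never adds events."""
        top, xyz, _ = toy_dimer_all_contacts
        rng = np.random.default_rng(3)
        frame = xyz + rng.normal(scale=1.0, size=xyz.shape)
        ga, gb = _groups(top)
        for attr in ("hbond_distance", "salt_bridge_distance",
                     "apolar_distance", "pi_cation_distance"):
            previous = None
            for scale in (1.0, 0.8, 0.6, 0.4):
                crit = InteractionCriteria()
                setattr(crit, attr, getattr(crit, attr) * scale)
                n = len(detect_interactions(frame, top, ga, gb, crit))
                if previous is not None:
                    assert n <= previous
                previous = n

    def test_cutoffs_are_inclusive_at_the_boundary(self):
        """A pair at exactly the cutoff distance counts; just beyond does
        not."""
        from protomerkit.core import Atom, Residue, RoleAnnotations, Topology
        atoms = [Atom(1, "NZ", "N", 1.0, 3.25, 0.17, 0, "A"),
                 Atom(2, "OD1", "O", -1.0, 2.96, 0.21, 1, "B")]
        residues = [Residue("LYS", 1, "A", 0, 1), Residue("ASP", 1, "B", 1, 2)]
        roles = RoleAnnotations(cation_group={0}, anion_group={1})
        top = Topology(atoms, residues, roles=roles)
        crit = InteractionCriteria()
        at_cutoff = np.array([[0.0, 0, 0], [crit.salt_bridge_distance, 0, 0]])
        events = detect_interactions(at_cutoff, top, [0], [1],
                                     types=("salt_bridge",))
        assert len(events) == 1
        beyond = np.array([[0.0, 0, 0],
                           [crit.salt_bridge_distance + 1e-9, 0, 0]])
        assert detect_interactions(beyond, top, [0], [1],
                                   types=("salt_bridge",)) == []

    def test_heavy_atom_fallback_without_hydrogens(self):
        """Hydrogen-free topology falls back to a flagged N/O distance rule."""
        top, xyz, _ = pk.make_toy_dimer(2, 2, ["hbond"])
        keep = [i for i in range(top.n_atoms)
                if top.atoms[i].element.upper() != "H"]
        sub = top.subset(keep)
        assert not sub.roles.hbond_donor_H
        events = detect_interactions(xyz[keep], sub, sub.chain_atoms("A"),
                                     sub.chain_atoms("B"), types=("hbond",))
        assert events, "fallback should recover the planted polar contact"
        assert all(e.geometry.get("heavy_fallback") for e in events)


class TestCountSeries:
    def test_planted_constant_counts(self):
        top, xyz, planted = pk.make_toy_dimer(3, 3, ["hbond", "salt_bridge"])
        spec = pk.PlantedSpec(contacts=planted, wobble_sigma=0.03, seed=11)
        traj, _ = pk.make_trajectory(top, xyz, spec, 20)
        ga, gb = _groups(top)
        counts, mean, sd = pk.interaction_count_series(traj, ga, gb, "hbond")
        assert (counts == 1).all()
        assert mean == 1.0 and sd == 0.0

    def test_alternating_schedule_mean_and_sd(self):
        """2 and 4 contacts alternating -> mean 3.0, population SD 1.0."""
        top, xyz, planted = pk.make_toy_dimer(
            4, 4, ["hbond", "salt_bridge", "pi_cation", "apolar"])
        # frames alternate: all four contacts on / only two on
        frames = []
        from protomerkit.synthetic_data import _sidechain_atoms
        off = [
            _sidechain_atoms(top, pc.residue_b)
            for pc in planted[2:]
        ]
        for k in range(10):
            f = xyz.copy()
            if k % 2 == 1:
                for idx in off:
                    f[idx] += np.array([0.0, 0.0, 8.0])
            frames.append(f)
        traj = pk.Trajectory(top, frames)
        ga, gb = _groups(top)
        total = np.zeros(10, dtype=int)
        for t in ("hbond", "salt_bridge", "pi_cation", "apolar"):
            counts, _, _ = pk.interaction_count_series(traj, ga, gb, t)
            total += counts
        assert total.tolist() == [4, 2] * 5
        assert total.mean() == 3.0
        assert np.std(total) == 1.0

    def test_no_contacts_all_zero(self):
        top, xyz, _ = pk.make_toy_dimer(3, 3, [])
        traj = pk.Trajectory(top, [xyz, xyz])
        ga, gb = _groups(top)
        counts, mean, sd = pk.interaction_count_series(traj, ga, gb,
                                                       "salt_bridge")
        assert counts.tolist() == [0, 0] and mean == 0.0

    def test_empty_frame_range_rejected(self, toy_dimer_all_contacts):
        top, xyz, _ = toy_dimer_all_contacts
        traj = pk.Trajectory(top, [xyz])
        ga, gb = _groups(top)
        with pytest.raises(ValueError, match="empty frame range"):
            pk.interaction_count_series(traj, ga, gb, "hbond", frame_range=[])


class TestPersistence:
    def test_planted_occupancy_exact(self):
        """600 on-frames out of 1000 recover fraction 0.600 exactly."""
        top, xyz, planted = pk.make_toy_dimer(2, 2, ["salt_bridge"])
        planted[0].occupancy = 0.6
        spec = pk.PlantedSpec(contacts=planted, wobble_sigma=0.0, seed=4)
        traj, truth = pk.make_trajectory(top, xyz, spec, 1000)
        ga, gb = _groups(top)
        profile = pk.persistence_profile(traj, ga, gb, ("salt_bridge",))
        key = (planted[0].residue_a, planted[0].residue_b, "salt_bridge")
        assert profile.entries[key] == 600 / 1000
        assert profile.counts[key] == 600

    def test_always_on_contact_is_one(self):
        top, xyz, planted = pk.make_toy_dimer(2, 2, ["hbond"])
        spec = pk.PlantedSpec(contacts=planted, wobble_sigma=0.02, seed=8)
        traj, _ = pk.make_trajectory(top, xyz, spec, 50)
        ga, gb = _groups(top)
        profile = pk.persistence_profile(traj, ga, gb, ("hbond",))
        assert set(profile.entries.values()) == {1.0}

    def test_threshold_filter_is_strict(self):
        """Fractions 0.29 / 0.31 at the 30% filter: only 0.31 survives."""
        prof = pk.PersistenceProfile(
            entries={(("A", 1), ("B", 1), "hbond"): 0.29,
                     (("A", 2), ("B", 2), "hbond"): 0.31},
            counts={(("A", 1), ("B", 1), "hbond"): 29,
                    (("A", 2), ("B", 2), "hbond"): 31},
            n_frames=100)
        kept = prof.filtered(0.30)
        assert list(kept) == [(("A", 2), ("B", 2), "hbond")]

    def test_fractions_are_exact_ratios(self):
        top, xyz, planted = pk.make_toy_dimer(2, 2, ["hbond"])
        planted[0].occupancy = 1 / 3
        spec = pk.PlantedSpec(contacts=planted, wobble_sigma=0.0, seed=2)
        traj, _ = pk.make_trajectory(top, xyz, spec, 9)
        ga, gb = _groups(top)
        profile = pk.persistence_profile(traj, ga, gb, ("hbond",))
        (frac,) = profile.entries.values()
        assert frac == 3 / 9
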