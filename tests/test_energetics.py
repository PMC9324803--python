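"""Nonbonded kernel closed forms, the formation-energy balance, and
per-residue decomposition conservation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import protomerkit as pk
from protomerkit.core import Atom, Residue, Topology
from protomerkit.energetics import (
    COULOMB_K,
    PotentialModel,
    chain_internal_energy,
    decompose_interface_energy,
    dimer_formation_energy,
    implicit_binding_energy,
    pair_energy,
    protein_solvent_energy,
)

from oracles import naive_pair_energy


def _point_system(entries):
    """entries: (chain, name, element, q, sigma, eps, xyz)."""
    atoms, residues, coords = [], [], []
    for k, (chain, name, element, q, s, e, xyz) in enumerate(entries):
        atoms.append(Atom(k + 1, name, element, q, s, e, k, chain))
        residues.append(Residue("UNK", k + 1, chain, k, k + 1))
        coords.append(xyz)
    return Topology(atoms, residues), np.asarray(coords, float)


class TestPairEnergy:
    def test_coulomb_closed_form(self):
        """Two +1 e charges at k/100 A give +100 kcal/mol exactly."""
        top, xyz = _point_system([
            ("A", "Q1", "NA", 1.0, 0.0, 0.0, (0, 0, 0)),
            ("B", "Q2", "NA", 1.0, 0.0, 0.0, (3.320636, 0, 0))])
        elec, vdw = pair_energy(xyz, top, [0], [1])
        assert elec == pytest.approx(100.0, abs=1e-9)
        assert vdw == 0.0

    def test_lj_minimum(self):
        sigma, eps = 3.0, 0.5
        top, xyz = _point_system([
            ("A", "C1", "C", 0.0, sigma, eps, (0, 0, 0)),
            ("B", "C2", "C", 0.0, sigma, eps, (2 ** (1 / 6) * sigma, 0, 0))])
        elec, vdw = pair_energy(xyz, top, [0], [1])
        assert vdw == pytest.approx(-eps, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_system_matches_direct_summation(self, seed):
        """50-atom random system equals the naive double loop to 1e-8."""
        rng = np.random.default_rng(seed)
        points = []
        while len(points) < 50:  # rejection-sample a loose packing
            p = rng.uniform(0, 16, 3)
            if all(np.linalg.norm(p - q) > 2.4 for q in points):
                points.append(p)
        entries = []
        for k in range(50):
            chain = "A" if k < 25 else "B"
            entries.append((chain, f"C{k}", "C", float(rng.uniform(-0.8, 0.8)),
                            float(rng.uniform(2.5, 3.8)),
                            float(rng.uniform(0.05, 0.3)),
                            tuple(points[k])))
        top, xyz = _point_system(entries)
        set_a, set_b = list(range(25)), list(range(25, 50))
        got = pair_energy(xyz, top, set_a, set_b)
        want = naive_pair_energy(xyz, top, set_a, set_b)
        assert got[0] == pytest.approx(want[0], abs=1e-8)
        assert got[1] == pytest.approx(want[1], abs=1e-8)

    def test_bonded_and_13_pairs_excluded(self):
        atoms = [Atom(1, "C1", "C", 1.0, 0, 0, 0, "A"),
                 Atom(2, "C2", "C", 1.0, 0, 0, 1, "A"),
                 Atom(3, "C3", "C", 1.0, 0, 0, 2, "A")]
        residues = [Residue("UNK", i + 1, "A", i, i + 1) for i in range(3)]
        top = Topology(atoms, residues, bonds=[(0, 1), (1, 2)])
        xyz = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]], float)
        elec, _ = pair_energy(xyz, top, [0], [1])  # 1-2 pair
        assert elec == 0.0
        elec, _ = pair_energy(xyz, top, [0], [2])  # 1-3 pair
        assert elec == 0.0

    def test_beyond_cutoff_zero(self):
        top, xyz = _point_system([
            ("A", "Q1", "NA", 1.0, 0, 0, (0, 0, 0)),
            ("B", "Q2", "NA", -1.0, 0, 0, (25.0, 0, 0))])
        assert pair_energy(xyz, top, [0], [1]) == (0.0, 0.0)


class TestInternalAndSolvent:
    def test_three_charge_chain_hand_sum(self):
        """Unbonded 3-charge chain matches the explicit three-term sum."""
        q = [0.5, -0.3, 0.2]
        pos = [(0, 0, 0), (2.0, 0, 0), (2.0, 3.0, 0)]
        top, xyz = _point_system(
            [("A", f"Q{k}", "NA", q[k], 0.0, 0.0, pos[k]) for k in range(3)])
        expected = sum(
            COULOMB_K * q[i] * q[j] / np.linalg.norm(np.subtract(pos[i], pos[j]))
            for i in range(3) for j in range(i + 1, 3))
        got = chain_internal_energy(xyz, top, "A")
        assert got == pytest.approx(expected, abs=1e-9)

    def test_bonded_pair_at_equilibrium_zero_bond_term(self):
        atoms = [Atom(1, "C1", "C", 0.0, 0, 0, 0, "A"),
                 Atom(2, "C2", "C", 0.0, 0, 0, 1, "A")]
        residues = [Residue("UNK", i + 1, "A", i, i + 1) for i in range(2)]
        top = Topology(atoms, residues, bonds=[(0, 1)])
        xyz = np.array([[0, 0, 0], [1.53, 0, 0]], float)  # C-C r0
        assert chain_internal_energy(xyz, top, "A") == pytest.approx(0.0, abs=1e-12)

    def test_water_probe_analytic_three_site_sum(self):
        """One charge next to one SPC-like water: per-site Coulomb sum."""
        fx = pk.make_energy_fixture("solvated_monomers")
        traj = fx["monomer_a"]
        got = protein_solvent_energy(traj.frames[0], traj.topology, "A")
        assert got == pytest.approx(fx["expected"]["E_solv_monomer"], abs=1e-9)

    def test_no_solvent_warns_and_returns_zero(self):
        top, xyz = _point_system([("A", "Q1", "NA", 1.0, 0, 0, (0, 0, 0))])
        with pytest.warns(UserWarning, match="no solvent"):
            assert protein_solvent_energy(xyz, top, "A") == 0.0


class TestFormationEnergy:
    def test_charge_pair_closed_form(self):
        fx = pk.make_energy_fixture("charge_pair")
        dfe = dimer_formation_energy(fx["dimer"], fx["monomer_a"],
                                     fx["monomer_b"])
        assert dfe.delta_E == pytest.approx(-100.0, abs=1e-9)
        assert dfe.term_means["E_inter_AB"] == pytest.approx(-100.0, abs=1e-9)

    def test_separated_dimer_zero(self):
        fx = pk.make_energy_fixture("separated_dimer")
        dfe = dimer_formation_energy(fx["dimer"], fx["monomer_a"],
                                     fx["monomer_b"])
        assert abs(dfe.delta_E) < 1e-3  # truncation tolerance

    def test_solvent_reorganization_bookkeeping(self):
        """Water only in the monomer systems: dE = -2 E_solv by Eq. terms."""
        fx = pk.make_energy_fixture("solvated_monomers")
        dfe = dimer_formation_energy(fx["dimer"], fx["monomer_a"],
                                     fx["monomer_b"])
        assert dfe.delta_E == pytest.approx(fx["expected"]["delta_E"], abs=1e-9)

    def test_termwise_identity_on_reported_means(self):
        """delta_E always equals the term-wise balance of the means."""
        fx = pk.make_energy_fixture("solvated_monomers")
        dfe = dimer_formation_energy(fx["dimer"], fx["monomer_a"],
                                     fx["monomer_b"])
        m = dfe.term_means
        recomputed = (m["E_self_AB"] + m["E_solv_AB"] + m["E_inter_AB"]
                      - m["E_self_A"] - m["E_solv_A"]
                      - m["E_self_B"] - m["E_solv_B"])
        assert dfe.delta_E == pytest.approx(recomputed, abs=1e-12)
        # means recomputed from the stored per-frame series
        for key, series in dfe.series.items():
            assert m[key] == pytest.approx(float(np.mean(series)), abs=1e-12)

    def test_rigid_transform_invariance(self, rng):
        fx = pk.make_energy_fixture("charge_pair")
        rot = Rotation.from_euler("xyz", rng.uniform(0, 90, 3),
                                  degrees=True).as_matrix()
        dimer = fx["dimer"]
        moved = pk.Trajectory(dimer.topology,
                              [dimer.frames[0] @ rot.T + np.array([3, 4, 5.0])])
        dfe = dimer_formation_energy(moved, fx["monomer_a"], fx["monomer_b"])
        assert dfe.delta_E == pytest.approx(-100.0, abs=1e-9)

    def test_chain_swap_invariance(self):
        fx = pk.make_energy_fixture("solvated_monomers")
        fwd = dimer_formation_energy(fx["dimer"], fx["monomer_a"],
                                     fx["monomer_b"]).delta_E
        # swapping which monomer run is called A/B leaves the balance alone
        rev = dimer_formation_energy(fx["dimer"], fx["monomer_b"],
                                     fx["monomer_a"]).delta_E
        assert fwd == pytest.approx(rev, abs=1e-9)

    def test_composition_mismatch_rejected(self):
        fx = pk.make_energy_fixture("charge_pair")
        other = pk.make_energy_fixture("separated_dimer")
        with pytest.raises(ValueError, match="mismatch"):
            dimer_formation_energy(fx["dimer"], other["monomer_a"],
                                   fx["monomer_b"])

    def test_default_window_is_second_half(self):
        fx = pk.make_energy_fixture("charge_pair")
        dimer = fx["dimer"]
        frames = [dimer.frames[0]] * 4
        dfe = dimer_formation_energy(pk.Trajectory(dimer.topology, frames),
                                     fx["monomer_a"], fx["monomer_b"])
        assert dfe.window["dimer"] == [2, 3]

    def test_cutoff_doubling_negligible_for_contained_system(self):
        """All interactions well inside half the cutoff: < 1% change."""
        fx = pk.make_energy_fixture("charge_pair")
        d1 = dimer_formation_energy(fx["dimer"], fx["monomer_a"],
                                    fx["monomer_b"], cutoff=12.0).delta_E
        d2 = dimer_formation_energy(fx["dimer"], fx["monomer_a"],
                                    fx["monomer_b"], cutoff=24.0).delta_E
        assert abs(d2 - d1) < 0.01 * abs(d1)


class TestDecomposition:
    @pytest.mark.parametrize("seed", range(3))
    def test_residue_sums_conserve_total(self, seed, toy_dimer_all_contacts):
        top, xyz, _ = toy_dimer_all_contacts
        rng = np.random.default_rng(seed)
        frame = xyz + rng.normal(scale=0.5, size=xyz.shape)
        dec = decompose_interface_energy(frame, top, "A", "B")
        for chain in ("A", "B"):
            e_sum = sum(e for (c, _), (e, v) in dec.contributions.items()
                        if c == chain)
            v_sum = sum(v for (c, _), (e, v) in dec.contributions.items()
                        if c == chain)
            assert e_sum == pytest.approx(dec.total_electrostatic, abs=1e-6)
            assert v_sum == pytest.approx(dec.total_vdw, abs=1e-6)

    def test_single_interacting_pair_gets_everything(self):
        top, xyz, planted = pk.make_toy_dimer(3, 3, ["salt_bridge"])
        dec = decompose_interface_energy(xyz, top, "A", "B")
        total = dec.total
        (ra, rb) = planted[0].residue_a, planted[0].residue_b
        # planted pair dominates: everything else is neutral glycine backbone
        assert dec.contributions[ra][0] + dec.contributions[ra][1] == \
            pytest.approx(total, rel=0.3)

    def test_per_residue_matches_masked_brute_force(self, rng,
                                                    toy_dimer_all_contacts):
        top, xyz, _ = toy_dimer_all_contacts
        frame = xyz + rng.normal(scale=0.3, size=xyz.shape)
        dec = decompose_interface_energy(frame, top, "A", "B")
        idx_b = top.chain_atoms("B")
        for res in top.residues:
            if res.chain_id != "A":
                continue
            want = naive_pair_energy(frame, top, list(res.atom_indices),
                                     idx_b.tolist())
            got = dec.contributions[(res.chain_id, res.author_number)]
            assert got[0] == pytest.approx(want[0], abs=1e-8)
            assert got[1] == pytest.approx(want[1], abs=1e-8)


class TestImplicitBinding:
    def test_vacuum_reduces_to_pair_energy(self):
        top, xyz, _ = pk.make_toy_dimer(3, 3, ["salt_bridge"])
        rec, lig = top.chain_atoms("A"), top.chain_atoms("B")
        dg, per_res = implicit_binding_energy(xyz, top, rec, lig, "vacuum")
        assert dg == pytest.approx(sum(pair_energy(xyz, top, rec, lig)),
                                   abs=1e-9)
        assert sum(per_res.values()) == pytest.approx(dg, abs=1e-6)

    def test_distance_dielectric_scaled_coulomb(self):
        """eps(r) = 4r screens a charge pair to k q1 q2 / (4 r^2)."""
        r = 5.0
        top, xyz = _point_system([
            ("A", "Q1", "NA", 1.0, 0.0, 0.0, (0, 0, 0)),
            ("B", "Q2", "NA", -1.0, 0.0, 0.0, (r, 0, 0))])
        dg, _ = implicit_binding_energy(xyz, top, [0], [1],
                                        "distance_dielectric")
        assert dg == pytest.approx(-COULOMB_K / (4 * r * r), abs=1e-9)

    def test_ligand_beyond_cutoff_is_zero(self):
        top, xyz = _point_system([
            ("A", "Q1", "NA", 1.0, 0.0, 0.0, (0, 0, 0)),
            ("B", "Q2", "NA", -1.0, 0.0, 0.0, (30.0, 0, 0))])
        dg, _ = implicit_binding_energy(xyz, top, [0], [1], "born_surrogate")
        assert abs(dg) < 1e-9

    def test_unknown_model_rejected(self):
        top, xyz = _point_system([("A", "Q1", "NA", 1.0, 0, 0, (0, 0, 0)),
                                  ("B", "Q2", "NA", 1.0, 0, 0, (3, 0, 0))])
        with pytest.raises(ValueError, match="unknown solvent model"):
            implicit_binding_energy(xyz, top, [0], [1], "pbsa")


class TestPotentialModelGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        top, xyz, _ = pk.make_toy_dimer(2, 2, ["salt_bridge"])
        model = PotentialModel(top)
        _, g = model.energy_gradient(xyz)
        h = 1e-6
        rng = np.random.default_rng(0)
        for _ in range(12):
            i = int(rng.integers(top.n_atoms))
            k = int(rng.integers(3))
            xp, xm = xyz.copy(), xyz.copy()
            xp[i, k] += h
            xm[i, k] -= h
            num = (model.energy(xp) - model.energy(xm)) / (2 * h)
            assert g[i, k] == pytest.approx(num, abs=5e-5)
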