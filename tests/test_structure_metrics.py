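"""Kabsch superposition, RMSD/RMSF series, secondary-structure windows."""

import numpy as np
import pytest
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation

import protomerkit as pk
from protomerkit.structure_metrics import assign_sse, backbone_dihedrals
from protomerkit.synthetic_data import make_dihedral_backbone


def _random_cloud(rng, n=20):
    return rng.normal(size=(n, 3)) * 3.0


def _rigid(coords, rng):
    rot = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 31)))).as_matrix()
    t = rng.normal(size=3) * 5
    return coords @ rot.T + t


class TestSuperpose:
    def test_identity(self, rng):
        ref = _random_cloud(rng)
        sup = pk.superpose(ref, ref)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self, rng):
        ref = _random_cloud(rng)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot.T + np.array([5.0, 0.0, 0.0])
        sup = pk.superpose(ref, mobile)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.apply(mobile), ref, atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_numerical_minimization(self, rng):
        """Kabsch equals direct minimization of the quadratic objective."""
        ref = _random_cloud(rng, 12)
        mobile = ref + rng.normal(scale=0.3, size=ref.shape)
        sup = pk.superpose(ref, mobile)

        def objective(p):
            rot = Rotation.from_rotvec(p[:3]).as_matrix()
            moved = mobile @ rot.T + p[3:]
            return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

        best = min(
            scipy_minimize(objective, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 20000}).fun
            for x0 in (np.zeros(6), np.array([0.1, -0.1, 0.05, 1, -1, 0.5]))
        )
        assert sup.rmsd == pytest.approx(best, abs=1e-4)

    def test_rmsd_invariant_under_common_rigid_transform(self, rng):
        ref = _random_cloud(rng)
        mobile = ref + rng.normal(scale=0.5, size=ref.shape)
        base = pk.superpose(ref, mobile).rmsd
        for _ in range(5):
            moved = pk.superpose(_rigid(ref, rng), _rigid(mobile, rng)).rmsd
            assert moved == pytest.approx(base, abs=1e-6)

    def test_collinear_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            pk.superpose(line, line + 1.0)

    def test_too_few_atoms_rejected(self, rng):
        ref = _random_cloud(rng)
        with pytest.raises(ValueError, match=">= 3"):
            pk.superpose(ref, ref, selection=[0, 1])


class TestRmsdSeries:
    def test_reference_frame_zero(self, toy_dimer_all_contacts):
        top, xyz, _ = toy_dimer_all_contacts
        traj, _ = pk.make_trajectory(top, xyz, pk.PlantedSpec(wobble_sigma=0.1, seed=1), 5)
        ca = pk.select(top, "name CA")
        series = pk.rmsd_series(traj, 0, ca)
        assert series[0] == pytest.approx(0.0, abs=1e-12)
        assert (series >= 0).all()

    def test_rigid_copies_give_zero(self, rng, toy_dimer_all_contacts):
        top, xyz, _ = toy_dimer_all_contacts
        frames = [xyz] + [_rigid(xyz, rng) for _ in range(4)]
        traj = pk.Trajectory(top, frames)
        ca = pk.select(top, "name CA")
        series = pk.rmsd_series(traj, 0, ca, ca)
        assert np.abs(series).max() < 1e-9

    def test_two_basin_bimodal(self, toy_dimer_all_contacts):
        """Basin frames show the planted displacement, others stay near 0."""
        top, xyz, _ = toy_dimer_all_contacts
        spec = pk.PlantedSpec(basins=[pk.PlantedBasin((0, 0, 5), 0.5)],
                              wobble_sigma=0.02, seed=9)
        traj, truth = pk.make_trajectory(top, xyz, spec, 30)
        ca = pk.select(top, "name CA")
        ref = int(np.nonzero(truth.basin_labels == 0)[0][0])
        series = pk.rmsd_series(traj, ref, ca)
        same = series[truth.basin_labels == truth.basin_labels[ref]]
        other = series[truth.basin_labels != truth.basin_labels[ref]]
        assert same.max() < 1.0
        assert other.min() > 2.0

    def test_separate_fit_and_measure_selections(self, toy_dimer_all_contacts):
        """Fit on chain A only; measure chain B displacement without refit."""
        top, xyz, _ = toy_dimer_all_contacts
        moved = xyz.copy()
        b_atoms = top.chain_atoms("B")
        moved[b_atoms] += np.array([0.0, 0.0, 3.0])
        traj = pk.Trajectory(top, [xyz, moved])
        fit = pk.select(top, "chain A")  # toy chain-A CAs are collinear
        measure = pk.select(top, "chain B and name CA")
        series = pk.rmsd_series(traj, 0, fit, measure)
        assert series[1] == pytest.approx(3.0, abs=1e-9)


class TestRmsf:
    def test_static_trajectory_zero(self, toy_dimer_all_contacts):
        top, xyz, _ = toy_dimer_all_contacts
        traj = pk.Trajectory(top, [xyz, xyz, xyz])
        vals = pk.rmsf(traj)
        assert max(vals.values()) == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_wobble_closed_form(self):
        """RMSF of iid sigma=0.5 A noise approaches sigma*sqrt(3)=0.866 A."""
        top, xyz, _ = pk.make_toy_dimer(6, 6, [])
        spec = pk.PlantedSpec(wobble_sigma=0.5, seed=77)
        traj, _ = pk.make_trajectory(top, xyz, spec, 2000)
        vals = np.array(list(pk.rmsf(traj).values()))
        expected = 0.5 * np.sqrt(3.0)
        assert vals.mean() == pytest.approx(expected, rel=0.05)

    def test_one_mobile_residue(self, rng):
        top, xyz, _ = pk.make_toy_dimer(4, 4, [])
        mobile = [i for i in range(top.n_atoms)
                  if (top.residue_of(i).chain_id,
                      top.residue_of(i).author_number) == ("A", 2)]
        frames = []
        for _ in range(50):
            f = xyz.copy()
            f[mobile] += rng.normal(scale=0.8, size=(len(mobile), 3))
            frames.append(f)
        vals = pk.rmsf(pk.Trajectory(top, frames))
        assert vals[("A", 2)] > 0.5
        quiet = [v for k, v in vals.items() if k != ("A", 2)]
        assert max(quiet) < 0.25  # fit residual only

    def test_single_frame_rejected(self, toy_dimer_all_contacts):
        top, xyz, _ = toy_dimer_all_contacts
        with pytest.raises(ValueError, match="2 frames"):
            pk.rmsf(pk.Trajectory(top, [xyz]))

    def test_two_frame_half_displacement(self):
        """2-frame RMSF is half the fitted inter-frame displacement."""
        top, xyz, _ = pk.make_toy_dimer(4, 4, [])
        other = xyz.copy()
        other[0] += np.array([0.8, 0.0, 0.0])
        traj = pk.Trajectory(top, [xyz, other])
        per_atom = pk.rmsf(traj, by_residue=False)
        # the moved atom fluctuates by ~half its displacement about the mean
        assert per_atom[0] == pytest.approx(0.4, abs=0.05)


class TestSecondaryStructure:
    def test_ideal_helix_interior(self):
        top, xyz = make_dihedral_backbone([(-57.0, -47.0)] * 10)
        labels = assign_sse(xyz, top)
        assert "".join(labels[1:-1]) == "H" * 8
        assert labels[0] == labels[-1] == "C"  # undefined phi/psi at termini

    def test_ideal_strand_interior(self):
        top, xyz = make_dihedral_backbone([(-139.0, 135.0)] * 8)
        labels = assign_sse(xyz, top)
        assert "".join(labels[1:-1]) == "E" * 6

    def test_coil_outside_windows(self, rng):
        """Dihedrals outside both windows label C; verified by recomputing
        the torsions independently from the coordinates."""
        pairs = [(60.0 + rng.uniform(-20, 20), 60.0 + rng.uniform(-20, 20))
                 for _ in range(8)]
        top, xyz = make_dihedral_backbone(pairs)
        phi, psi, _ = backbone_dihedrals(xyz, top)
        for i in range(1, 7):
            assert phi[i] == pytest.approx(pairs[i][0], abs=1.0)
        assert "".join(assign_sse(xyz, top)) == "C" * 8

    def test_short_helical_run_stays_coil(self):
        """Fewer than 4 consecutive helical residues never label H."""
        pairs = [(60, 60), (-57, -47), (-57, -47), (-57, -47), (60, 60),
                 (60, 60)]
        top, xyz = make_dihedral_backbone(pairs)
        assert "H" not in assign_sse(xyz, top)

    def test_fraction_tallies_match_labels(self):
        top, xyz = make_dihedral_backbone([(-57.0, -47.0)] * 12)
        traj = pk.Trajectory(top, [xyz, xyz])
        series = pk.sse_series(traj)
        n_res = len(top.residues)
        for k in range(2):
            h = (series.labels[k] == "H").sum() / n_res * 100
            e = (series.labels[k] == "E").sum() / n_res * 100
            assert series.helix_fraction[k] == h
            assert series.strand_fraction[k] == e
            assert series.helix_fraction[k] + series.strand_fraction[k] <= 100
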