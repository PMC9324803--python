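# protomerkit

Post-simulation analysis of protein dimer trajectories: how stable is a
homo- or heterodimer, which residues hold its interface together, and how
does it recognize an RNA ligand?

The package grew out of the analysis workflow used to compare dimers of the
DBHS-family RNA-binding proteins (NONO, SFPQ), whose RRM2/NOPS/coiled-coil
interfaces drive dimerization while RRM1 domains recognize G-rich RNA.  It
is, however, a general toolkit for any dimer + matched monomer simulations:

- **Stability metrics** — Kabsch superposition, RMSD time series with
  independent fit/measure selections, per-residue RMSF about the mean
  structure, and a dihedral-window secondary-structure monitor
  (% helix / % strand per frame).
- **Interaction fingerprints** — geometric detection of hydrogen bonds,
  salt bridges, π–π and π–cation contacts (plus an apolar-contact
  surrogate), per-frame counts with mean ± SD, and per-residue-pair
  **time persistence**: the exact fraction of frames a contact exists,
  conventionally filtered at > 30% of the simulated time.
- **GROMOS conformational clustering** — pairwise Cα-RMSD matrix, iterative
  neighbor-peeling, and medoid extraction; all single-point analyses
  consume the medoid of the largest cluster.
- **Dimer formation energy** — the balance

  ```
  ΔE = E_self(A:B) + E_solv(A:B) + E_inter(A:B)
       − [E_self(A) + E_solv(A) + E_self(B) + E_solv(B)]
  ```

  over the equilibrated second half of a dimer run and two separated
  monomer runs, with per-term SDs combined in quadrature.  Negative ΔE
  means dimer formation is favorable.
- **Per-residue decomposition** of the inter-chain energy (electrostatic +
  van der Waals), conserving the total exactly.
- **In silico alanine scanning** — side-chain truncation at Cβ, 6 Å local
  relaxation by Polak-Ribière conjugate gradients (gradient threshold
  0.05 kJ mol⁻¹ Å⁻¹), and ΔAffinity = E_inter(mutant) − E_inter(wild type).
- **Ligand transplant** — place an RNA (or any ligand) from a reference
  complex onto a target receptor by Cα superposition over an explicit
  residue mapping, with clash reporting and local refinement.
- **Synthetic data with planted ground truth** — toy dimers whose interface
  contacts, occupancy schedules, noise level and conformational basins are
  known exactly, so every stage of the pipeline is testable end to end
  without any external data.

Energies use a transparent fixed-charge kernel (Coulomb with
k = 332.0636 kcal·Å/(mol·e²), Lennard-Jones 12-6 with Lorentz–Berthelot
combining, bundled parameter table, hard 12 Å cutoff).  Absolute kcal/mol
values are not comparable to any specific MD engine's force field; the
bookkeeping of every balance and decomposition is exact and tested.

## Worked example

```python
import protomerkit as pk

top, xyz, planted = pk.make_toy_dimer(4, 4, ["salt_bridge", "hbond"])
planted[0].occupancy = 0.6
spec = pk.PlantedSpec(contacts=planted, wobble_sigma=0.05, seed=42)
traj, truth = pk.make_trajectory(top, xyz, spec, 500)

profile = pk.persistence_profile(traj, top.chain_atoms("A"),
                                 top.chain_atoms("B"),
                                 ("salt_bridge", "hbond"))
for (r1, r2, ctype), frac in sorted(profile.entries.items()):
    print(f"{r1[0]}{r1[1]} :: {r2[0]}{r2[1]}  {ctype:<12s} {frac:.3f}")
```

prints

```
A1 :: B1  salt_bridge  0.600
A2 :: B2  hbond        1.000
```

— the planted occupancies recovered exactly: the Lys1–Asp1 salt bridge was
switched on in 300 of 500 frames and the Ser2–Asn2 hydrogen bond in all of
them.  The `examples/` directory holds one short script per capability
(persistence, clustering, formation energy, alanine scan, transplant,
stability metrics), each printing the numbers it computes and what they
mean.  A command-line layer mirrors the library
(`protomerkit simulate|interactions|cluster|formation-energy|ala-scan|
transplant|run ...`), and `protomerkit run --config run.yaml` executes the
whole pipeline with full provenance.

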