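# Methods

This note records the models, defaults and numerical choices behind each
analysis, what the synthetic generator does and does not emulate, and the
known limitations.

## Scope and data model

The package analyzes *existing* trajectories; it does not run dynamics.
Systems are held as a `Topology` (atoms with partial charges and
Lennard-Jones parameters, residues with author numbering, chains, bonds,
and chemical role flags) plus a `Trajectory` of Cartesian frames in
Ångström.  Internal indices are 0-based; all reports use the author
residue numbering and chain id from the input, because that is how
structural biologists name residues.

Structures come in as PDB or multi-model PDB (read via Biopython), or a
documented plain text table (`FRAME k [time]` header lines followed by one
`x y z` row per atom).  Waters and ions are identified by a residue-name
whitelist (HOH/WAT/SPC/NA/CL, overridable).

## Parameters and roles

A bundled TSV maps (residue, atom) to charge/σ/ε for the 20 standard amino
acids, the four ribonucleotides, SPC-like water and Na⁺/Cl⁻.  It is a
deliberately simple fixed-charge set: polar groups carry literature-typical
partial charges, apolar atoms are neutral, and each residue nets its formal
charge exactly.  Users can substitute any table with the same layout.
Atoms of unknown residues get zero charge (with a warning) and
element-based LJ parameters.

Detector roles are derived, not tabulated: donor hydrogens are H bonded to
N/O; acceptors are all O plus any N with no bonded hydrogen and at most two
heavy neighbors (captures His ND1/NE2 and purine N7/N1/N3, excludes amide
and proline nitrogens); cation/anion groups, aromatic rings and apolar
side-chain carbons come from per-residue name sets.  Hydrogens attach to
heavy atoms by the PDBv3 remote-position naming convention.  Topologies
without hydrogens fall back to a flagged heavy-atom N/O–N/O distance rule
(≤ 3.5 Å) for hydrogen bonds.

## Interaction criteria

Defaults (all inclusive, all config-exposed, all recorded in run
provenance): H···acceptor ≤ 2.8 Å with donor angle ≥ 120° and acceptor
antecedent angle ≥ 90°; cation-N to anion-O ≤ 4.0 Å; ring centroids
≤ 4.4 Å at plane angle ≤ 30° (face-to-face) or ≤ 5.5 Å at 60–90°
(edge-to-face, plane angles folded into [0°, 90°]); cation within 6.6 Å of
a ring centroid and within 30° of its normal; apolar side-chain carbons
≤ 4.5 Å.  These mirror widely used interaction-fingerprint definitions;
they are explicit stand-ins for vendor defaults that are not published.
The apolar class is an in-package surrogate for external
hydrophobic-contact servers and is labelled as such in reports.

An interaction is counted once per residue pair per type per frame, because
persistence and count reports are residue-level.  Persistence is the exact
integer ratio (frames with ≥ 1 event) / (frames in window); the
conventional report filter keeps pairs present *more than* 30% of the
window.  Candidate pairs come from a cKDTree fixed-radius query, which
returns exactly what an all-pairs scan would; equality with a brute-force
recheck is asserted in the test suite.

## Geometry

Superposition is the least-squares rigid fit (scipy's quaternion
`align_vectors`, equivalent to the Kabsch optimum; proper rotation
guaranteed).  Collinear or <3-point selections are rejected.  RMSD series
fit each frame on one selection and measure on another without refitting,
which supports e.g. a protein-Cα fit with an RNA-atom measurement.

RMSF fits all frames to the frame-average with one fixed-point iteration
(fit → new mean → fit), then reports per-atom root-mean-square deviation
from the mean position; the per-residue value is the Cα's RMSF (mean over
selected atoms when no Cα is selected).  For isotropic iid noise of
per-coordinate σ the expected RMSF is σ√3, minus a small absorption by the
6 rigid-body degrees of freedom removed by fitting (≈ 2–4% for the toy
sizes used in tests, which is why the closed-form check carries a 5%
tolerance).

Secondary structure uses a dihedral-window assignment rather than
hydrogen-bond topology: helix if (φ, ψ) is within ±30° of (−57°, −47°) in
a run of ≥ 4 consecutive residues, strand within ±40° of (−139°, 135°) in
a run of ≥ 2, else coil; termini with undefined φ or ψ are coil.  This is
self-contained and deterministic, and adequate for monitoring % content
over time; it is not a DSSP replacement.

## Clustering

The distance matrix holds the superposed Cα RMSD for every frame pair
(dense; stride trajectories to a few thousand frames first).  GROMOS
clustering repeatedly takes the unassigned frame with the most unassigned
neighbors within the cutoff (ties to the lowest frame index) and removes
it with its neighbors as one cluster.  The peeling *center* maximizes the
neighbor count; the reported *medoid* minimizes the summed intra-cluster
distance and is recomputed within each final cluster — downstream
single-point analyses always consume the medoid.  The default cutoff is
2.0 Å; it is a required, logged choice rather than a universal constant.

## Energetics

The kernel is Coulomb `k qᵢqⱼ/r` (k = 332.0636 kcal·Å·mol⁻¹·e⁻²) plus
Lennard-Jones 12-6 with Lorentz–Berthelot combining, hard-truncated at
12 Å with no shifting or long-range correction.  Bonded and 1-3 pairs are
excluded; intramolecular 1-4 pairs are scaled by 0.5.  Internal energies
add harmonic bonds `k_b (r − r₀)²` (k_b = 300 kcal·mol⁻¹·Å⁻², r₀ from a
small element-pair table) and angles `k_θ (θ − θ₀)²` (k_θ = 50
kcal·mol⁻¹·rad⁻², θ₀ = 109.47° or 120° for centers with ≥ 3 heavy
neighbors).  No ½ factors; the convention is stated because tests pin the
closed forms.

The formation-energy balance subtracts separated-monomer terms from
dimer-system terms, term-wise on window means; the default window is the
second (equilibrated) half of each trajectory.  Protein–solvent terms sum
the electrostatic and van der Waals components (reported separately in
the series).  The quoted uncertainty combines per-term SDs in quadrature,
which assumes term independence — a stated simplification.  Truncation
bias largely cancels between the like terms of the balance; the contract
is exactness of the bookkeeping, not parity with any MD engine, and the
absolute scale of a real system's ΔE under this kernel will differ from
values computed with an engine force field.

Per-residue decomposition assigns each residue the sum of its atoms' pair
energies with the entire partner chain; chain-wise sums equal the total
inter-chain energy to ≤ 10⁻⁶ kcal/mol by construction (asserted).

The implicit-solvent rescoring is an **MM/GBSA-like surrogate** (so
labelled in every output): ΔG_bind = E(complex) − E(receptor) − E(ligand)
under vacuum, a distance-dependent dielectric ε(r) = 4r (default), or a
one-parameter generalized-Born-style screening with a fixed 2 Å effective
radius.  It ranks toy interfaces; it is not a calibrated solvation model.

## Minimization

Local relaxation uses Polak-Ribière conjugate gradients (scipy `CG`) with
analytic gradients, terminating at a gradient RMS of 0.05 kJ·mol⁻¹·Å⁻¹
(0.011950 kcal·mol⁻¹·Å⁻¹) over the free coordinates.  Only the region
atoms move; the model covers the region plus every frozen atom within the
nonbonded cutoff of it, and evaluates that local subsystem *untruncated*
so line searches never cross the energy discontinuity of a hard cutoff.
CG line searches can stall on the stiff mixed bonded/nonbonded scales;
stalls restart CG and finish with an L-BFGS-B polish to the same
threshold, with the convergence flag reporting the achieved gradient RMS.
The iteration cap defaults to 4000.

## Alanine scan

For each scannable residue (not Gly/Ala/Pro, which are reported as skipped
entries): truncate the side chain at Cβ, rebuild three β-hydrogens with
ideal tetrahedral geometry, remap charges to the alanine template, relax
every residue having ≥ 1 atom within 6 Å of the mutated residue (the
mutant included), and recompute the inter-chain interaction energy.  The
wild-type complex is re-minimized with the identical protocol around the
same site before differencing, so minimizer bias cancels.
ΔAffinity = E_inter(mutant) − E_inter(wild type); positive values mean the
mutation destabilizes the interface (the convention is printed in report
headers).  Every mutation starts from the same input structure, making
results independent of visit order.  The rebuilt side chain uses ideal
internal coordinates with no rotamer search.

## Ligand transplant

The reference receptor is Kabsch-fitted onto the target over an explicit,
user-supplied Cα residue mapping (≥ 3 pairs, non-collinear); the same
rigid transform places the ligand, preserving its internal distance matrix
exactly, and receptor–ligand pairs closer than 2.0 Å are reported as
clashes.  An explicit mapping was chosen over automated alignment to keep
the operation deterministic and auditable.  Refinement relaxes residues
within 6 Å of the ligand plus the ligand itself; it is a single
minimization pass — the mobile shell is recomputed from the input
coordinates, so a strongly settling ligand may take a few passes to reach
a fixed point (the test suite checks the no-op property at that fixed
point).  De novo nucleotide building is out of scope; the ligand must be
supplied as coordinates.

## Synthetic data

The generator emulates the *statistical* structure the analyses assume,
not physics.  Two mini-chains face each other across a ~10 Å gap; each
requested contact type occupies its own residue pair, built from
hand-placed side-chain templates so the detector criteria are met with
≥ 10% geometric margin (boundary behavior is tested separately with
explicit at-cutoff fixtures; cutoffs are inclusive).  Toy residues are
independent molecules (no backbone polymer bonds) so the toy potential is
free of artificial inter-residue strain.  Frames add iid Gaussian wobble;
"off" frames displace the contact's B-side side chain 8 Å out of the
interface, which breaks every criterion of every type; occupancy schedules
are exact on-fraction permutations.  Conformational basins are rigid
chain-B translations on disjoint frame subsets — displacements along the
inter-chain axis are used in tests because purely lateral shifts are
largely absorbed by superposition.  Generation is bit-reproducible from a
single seeded generator per call, and a post-hoc verification re-runs the
detectors on every frame, raising if the wobble broke a planted contact.

Consequently, passing tests demonstrate correct *bookkeeping and
algorithmics* — exact occupancy recovery, cluster recovery, closed-form
energies, scan signs — on systems whose truth is known.  They do not
demonstrate force-field accuracy, sampling adequacy, or detector
criterion choices matching any particular vendor's, which real-data use
must judge separately.

Energy fixtures carry closed-form expectations: a ±1 e pair at
r = 3.320636 Å (ΔE exactly −100 kcal/mol from k/r), an LJ pair at
r = 2^{1/6}σ (−ε), a separated dimer (ΔE = 0 under truncation), and
solvated monomers whose protein–solvent term is a hand-summed three-site
Coulomb sum recorded in the fixture itself.

## Problem sizes

Defaults were chosen so the full synthetic pipeline and the acceptance
script each complete in well under a minute of CPU: toy chains of 2–8
residues (~40–120 atoms), 20–1000 frames for persistence statistics, 2000
frames for the RMSF closed form, 40–60 frames for clustering, and
alanine scans over a handful of selected sites.  All are arguments, not
constants.

## Known limitations

- The energy kernel is not an engine force field; absolute energies of
  real proteins are qualitative.
- No PME/Ewald, no polarization, no entropy terms, no water-mediated
  bridges, no halogen bonds, no contact lifetime kinetics.
- Secondary structure is a dihedral-window monitor, not DSSP.
- Distance matrices are dense; very long trajectories must be strided.
- The minimizer freezes everything outside the mobile shell; backbone
  relaxation beyond that shell is deliberately out of scope.
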