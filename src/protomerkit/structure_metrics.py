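"""Superposition, RMSD/RMSF time series and secondary-structure monitoring.

The Kabsch fit is delegated to scipy's quaternion-based
``Rotation.align_vectors`` (equivalent optimum).  Secondary structure uses a
dihedral-window assignment: a residue is helical (H) when its (phi, psi) lies
within +/-30 deg of (-57, -47) as part of a run of >= 4 consecutive such
residues, strand (E) within +/-40 deg of (-139, 135) in a run of >= 2, else
coil (C).  Chain termini with undefined phi or psi are coil.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import chemdata
from .core import Topology, Trajectory

__all__ = [
    "Superposition",
    "SSELabelSeries",
    "superpose",
    "rmsd_series",
    "rmsf",
    "assign_sse",
    "sse_series",
]

HELIX_CENTER = (-57.0, -47.0)
HELIX_WINDOW = 30.0
HELIX_MIN_RUN = 4
STRAND_CENTER = (-139.0, 135.0)
STRAND_WINDOW = 40.0
STRAND_MIN_RUN = 2


@dataclass
class Superposition:
    """Optimal rigid fit: x_fit = rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class SSELabelSeries:
    """Per-frame, per-residue secondary-structure labels with % content."""

    labels: np.ndarray  # (n_frames, n_residues) of 'H'/'E'/'C'
    helix_fraction: np.ndarray  # per-frame %, 0..100
    strand_fraction: np.ndarray


def _check_selection(sel, n: int, minimum: int = 1) -> np.ndarray:
    sel = np.asarray(sel, dtype=int)
    if sel.size < minimum:
        raise ValueError(f"selection needs >= {minimum} atoms, got {sel.size}")
    if sel.size and (sel.min() < 0 or sel.max() >= n):
        raise ValueError("selection index out of range")
    return sel


def superpose(reference: np.ndarray, mobile: np.ndarray,
              selection: Sequence[int] | None = None) -> Superposition:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    The fit and the reported RMSD both use ``selection`` (all atoms when
    None).  Requires >= 3 non-collinear selected atoms.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if selection is None:
        selection = np.arange(reference.shape[0])
    sel = _check_selection(selection, min(reference.shape[0], mobile.shape[0]), 3)
    ref = reference[sel]
    mob = mobile[sel]
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    a = ref - ref_c
    b = mob - mob_c
    # collinearity check: rank of the centered reference cloud
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("selection is collinear; superposition is ill-defined")
    rot, rssd = Rotation.align_vectors(a, b)
    rmsd = float(rssd) / np.sqrt(sel.size)
    matrix = rot.as_matrix()
    translation = ref_c - matrix @ mob_c
    return Superposition(matrix, translation, rmsd)


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    fit_selection: Sequence[int] | None = None,
    measure_selection: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) versus a reference frame.

    Each frame is first fitted to the reference on ``fit_selection``; the
    RMSD is then measured over ``measure_selection`` without refitting,
    which supports e.g. a protein-Calpha fit with an RNA-atom measurement.
    """
    n = traj.topology.n_atoms
    fit = (np.arange(n) if fit_selection is None
           else _check_selection(fit_selection, n, 3))
    measure = (fit if measure_selection is None
               else _check_selection(measure_selection, n, 1))
    ref = traj.frames[reference_frame]
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        sup = superpose(ref, frame, fit)
        moved = sup.apply(frame[measure])
        out[k] = np.sqrt(np.mean(np.sum((moved - ref[measure]) ** 2, axis=1)))
    return out


def rmsf(traj: Trajectory, selection: Sequence[int] | None = None,
         by_residue: bool = True):
    """Root-mean-square fluctuation about the mean structure.

    Frames are fitted to the frame-average with one fixed-point iteration
    (fit to the raw mean, recompute the mean, fit again).  With
    ``by_residue`` the value reported per residue is its Calpha RMSF, or the
    mean over its selected atoms when no Calpha is selected; otherwise the
    per-atom array is returned.
    """
    if traj.n_frames < 2:
        raise ValueError("rmsf needs at least 2 frames")
    n = traj.topology.n_atoms
    sel = (np.arange(n) if selection is None else _check_selection(selection, n, 3))
    coords = traj.coordinates()
    fitted = coords.copy()
    for _ in range(2):  # fit -> new mean -> fit
        mean = fitted.mean(axis=0)
        for k in range(coords.shape[0]):
            sup = superpose(mean, coords[k], sel)
            fitted[k] = sup.apply(coords[k])
    mean = fitted.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    if not by_residue:
        return per_atom
    sel_set = set(sel.tolist())
    top = traj.topology
    values = {}
    for ri, res in enumerate(top.residues):
        in_sel = [i for i in res.atom_indices if i in sel_set]
        if not in_sel:
            continue
        ca = [i for i in in_sel if top.atoms[i].name == "CA"]
        pick = ca if ca else in_sel
        values[(res.chain_id, res.author_number)] = float(np.mean(per_atom[pick]))
    return values


# -- secondary structure ---------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points (IUPAC sign convention)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(coords: np.ndarray, topology: Topology):
    """(phi, psi) per residue in degrees; NaN where undefined."""
    n_res = len(topology.residues)
    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    bb: list[dict[str, int] | None] = []
    for res in topology.residues:
        d = {topology.atoms[i].name: i for i in res.atom_indices
             if topology.atoms[i].name in ("N", "CA", "C")}
        bb.append(d if len(d) == 3 else None)
    for ri in range(n_res):
        if bb[ri] is None:
            continue
        res = topology.residues[ri]
        prev_ok = (ri > 0 and bb[ri - 1] is not None
                   and topology.residues[ri - 1].chain_id == res.chain_id)
        next_ok = (ri + 1 < n_res and bb[ri + 1] is not None
                   and topology.residues[ri + 1].chain_id == res.chain_id)
        if prev_ok:
            phi[ri] = dihedral(coords[bb[ri - 1]["C"]], coords[bb[ri]["N"]],
                               coords[bb[ri]["CA"]], coords[bb[ri]["C"]])
        if next_ok:
            psi[ri] = dihedral(coords[bb[ri]["N"]], coords[bb[ri]["CA"]],
                               coords[bb[ri]["C"]], coords[bb[ri + 1]["N"]])
    return phi, psi, bb


def _in_window(phi, psi, center, half_width) -> bool:
    if np.isnan(phi) or np.isnan(psi):
        return False
    dphi = (phi - center[0] + 180.0) % 360.0 - 180.0
    dpsi = (psi - center[1] + 180.0) % 360.0 - 180.0
    return abs(dphi) <= half_width and abs(dpsi) <= half_width


def assign_sse(coords: np.ndarray, topology: Topology) -> np.ndarray:
    """Per-residue secondary-structure labels 'H'/'E'/'C' for one frame."""
    phi, psi, bb = backbone_dihedrals(np.asarray(coords, dtype=float), topology)
    n_res = len(topology.residues)
    missing = [ri for ri in range(n_res) if bb[ri] is None
               and topology.residues[ri].name.upper() in chemdata.AMINO_ACIDS]
    if missing:
        warnings.warn(f"residues missing backbone atoms labelled C: {missing}")
    labels = np.array(["C"] * n_res)
    helix_ok = [_in_window(phi[i], psi[i], HELIX_CENTER, HELIX_WINDOW)
                for i in range(n_res)]
    strand_ok = [_in_window(phi[i], psi[i], STRAND_CENTER, STRAND_WINDOW)
                 for i in range(n_res)]
    for ok, min_run, symbol in ((helix_ok, HELIX_MIN_RUN, "H"),
                                (strand_ok, STRAND_MIN_RUN, "E")):
        run_start = None
        for i in range(n_res + 1):
            good = i < n_res and ok[i] and labels[i] == "C"
            if good and run_start is None:
                run_start = i
            elif not good and run_start is not None:
                if i - run_start >= min_run:
                    labels[run_start:i] = symbol
                run_start = None
    return labels


def sse_series(traj: Trajectory) -> SSELabelSeries:
    """Secondary-structure labels for every frame plus % helix / % strand."""
    all_labels = np.stack([assign_sse(f, traj.topology) for f in traj.frames])
    n_res = all_labels.shape[1]
    helix = (all_labels == "H").sum(axis=1) / n_res * 100.0
    strand = (all_labels == "E").sum(axis=1) / n_res * 100.0
    return SSELabelSeries(all_labels, helix, strand)
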