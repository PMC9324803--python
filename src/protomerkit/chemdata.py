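"""Residue chemistry templates: bonds, roles, and nonbonded parameter tables.

The package ships a transparent fixed-charge parameter set
(``data/params.tsv``) covering the 20 standard amino acids, the four
ribonucleotides, a 3-site water and Na+/Cl- ions.  It is deliberately simple:
polar groups carry literature-typical partial charges, apolar atoms are
neutral, and each residue's net charge equals its formal charge exactly.
Users may substitute their own table (same TSV layout) for any run.

Roles for the interaction detectors are derived, not tabulated:

* donor hydrogens: any H bonded to N or O;
* acceptors: any O, plus any N with no bonded hydrogen and at most two
  heavy-atom neighbors (captures His ND1/NE2, purine N7/N1/N3, excludes
  amide and proline nitrogens);
* cation / anion groups, aromatic rings and apolar side-chain carbons come
  from per-residue name sets below.
"""

from __future__ import annotations

import csv
import warnings
from importlib import resources
from pathlib import Path

__all__ = [
    "BACKBONE_ATOMS",
    "SOLVENT_RESNAMES",
    "load_parameter_table",
    "default_parameter_path",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "HA2", "HA3", "H1", "H2", "H3"}

#: residue names treated as solvent (water or monatomic ions); overridable.
SOLVENT_RESNAMES = {"HOH", "WAT", "SPC", "TIP3", "NA", "CL", "SOD", "CLA"}

ION_RESNAMES = {"NA", "CL", "SOD", "CLA"}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

RIBONUCLEOTIDES = {"A", "U", "G", "C", "RA", "RU", "RG", "RC"}

#: heavy-atom bond templates (side chain + backbone) per residue name.
_BB = [("N", "CA"), ("CA", "C"), ("C", "O")]
HEAVY_BONDS: dict[str, list[tuple[str, str]]] = {
    "GLY": _BB,
    "ALA": _BB + [("CA", "CB")],
    "SER": _BB + [("CA", "CB"), ("CB", "OG")],
    "CYS": _BB + [("CA", "CB"), ("CB", "SG")],
    "THR": _BB + [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "VAL": _BB + [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "LEU": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ILE": _BB + [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "MET": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PRO": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "PHE": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
                  ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "TYR": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
                  ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
                  ("CZ", "OH")],
    "TRP": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
                  ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
                  ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "ASP": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "GLU": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
                  ("CD", "OE2")],
    "ASN": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "GLN": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
                  ("CD", "NE2")],
    "LYS": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
                  ("CE", "NZ")],
    "ARG": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
                  ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "HIS": _BB + [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
                  ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "HOH": [("OW", "HW1"), ("OW", "HW2"), ("O", "H1"), ("O", "H2")],
}

_SUGAR = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"),
    ("C4'", "O4'"), ("C4'", "C3'"), ("C3'", "O3'"), ("C3'", "C2'"),
    ("C2'", "O2'"), ("C2'", "C1'"), ("O4'", "C1'"),
]
_PURINE = [
    ("C1'", "N9"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C4"),
    ("N9", "C4"), ("C4", "N3"), ("N3", "C2"), ("C2", "N1"), ("N1", "C6"),
    ("C6", "C5"),
]
_PYRIMIDINE = [
    ("C1'", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
    ("C5", "C6"), ("C6", "N1"), ("C2", "O2"),
]
HEAVY_BONDS["G"] = _SUGAR + _PURINE + [("C6", "O6"), ("C2", "N2")]
HEAVY_BONDS["A"] = _SUGAR + _PURINE + [("C6", "N6")]
HEAVY_BONDS["U"] = _PYRIMIDINE + _SUGAR + [("C4", "O4")]
HEAVY_BONDS["C"] = _PYRIMIDINE + _SUGAR + [("C4", "N4")]
for _alias, _src in (("RG", "G"), ("RA", "A"), ("RU", "U"), ("RC", "C")):
    HEAVY_BONDS[_alias] = HEAVY_BONDS[_src]

#: cationic nitrogen groups (salt-bridge donors of positive charge)
CATION_GROUPS: dict[str, set[str]] = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "NA": {"NA"},
    "SOD": {"NA", "SOD"},
}

#: anionic oxygen groups
ANION_GROUPS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "CL": {"CL"},
    "CLA": {"CL", "CLA"},
}
_PHOSPHATE_ANION = {"OP1", "OP2"}
for _r in RIBONUCLEOTIDES:
    ANION_GROUPS[_r] = set(_PHOSPHATE_ANION)

#: aromatic ring member atom names, one tuple per ring
AROMATIC_RINGS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
}
for _r, _base in (("G", "pur"), ("A", "pur"), ("RG", "pur"), ("RA", "pur"),
                  ("U", "pyr"), ("C", "pyr"), ("RU", "pyr"), ("RC", "pyr")):
    if _base == "pur":
        AROMATIC_RINGS[_r] = [("N9", "C8", "N7", "C5", "C4"),
                              ("C4", "C5", "C6", "N1", "C2", "N3")]
    else:
        AROMATIC_RINGS[_r] = [("N1", "C2", "N3", "C4", "C5", "C6")]

#: residues whose side-chain carbons count as apolar contact partners
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}

#: element-based Lennard-Jones fallbacks (sigma Angstrom, epsilon kcal/mol)
ELEMENT_LJ: dict[str, tuple[float, float]] = {
    "H": (2.50, 0.030),
    "C": (3.50, 0.066),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.60, 0.355),
    "P": (3.74, 0.200),
    "NA": (3.33, 0.0028),
    "CL": (4.40, 0.100),
}


def default_parameter_path() -> Path:
    """Path of the bundled nonbonded parameter table."""
    return Path(resources.files("protomerkit") / "data" / "params.tsv")


def load_parameter_table(path: str | Path | None = None) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Load a (residue, atom) -> (charge, sigma, epsilon) table from TSV.

    The TSV has a header line ``residue atom charge sigma epsilon`` and one
    row per atom; residue/atom names are matched case-sensitively against
    PDB names.
    """
    path = default_parameter_path() if path is None else Path(path)
    table: dict[tuple[str, str], tuple[float, float, float]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"residue", "atom", "charge", "sigma", "epsilon"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"parameter table {path}: expected columns {sorted(required)}")
        for row in reader:
            key = (row["residue"], row["atom"])
            if key in table:
                warnings.warn(f"duplicate parameter row for {key}; keeping last")
            table[key] = (
                float(row["charge"]),
                float(row["sigma"]),
                float(row["epsilon"]),
            )
    return table


def element_from_name(name: str, resname: str) -> str:
    """Best-effort element inference from a PDB atom name."""
    if resname.upper() in ION_RESNAMES:
        return "NA" if resname.upper() in {"NA", "SOD"} else "CL"
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in {"CL", "NA", "MG", "ZN", "FE", "BR"} and len(name) <= 2:
        return stripped[:2].upper()
    return stripped[0].upper()


def attach_hydrogen(h_name: str, heavy_names: list[str]) -> str | None:
    """Resolve which heavy atom a hydrogen named ``h_name`` is bonded to.

    Uses the PDBv3 naming convention: the remote-position code of the H name
    (e.g. ``HB2`` -> ``B``, ``HG11`` -> ``G1``) matches the heavy atom whose
    name minus its element letter equals that code.  Returns None when no
    unambiguous match exists.
    """
    if h_name in ("H", "H1", "H2", "H3", "HN"):
        for cand in ("N", "OW", "O"):  # backbone amide or water
            if cand in heavy_names:
                return cand
        return None
    if h_name.startswith("HW") and "OW" in heavy_names:
        return "OW"
    if h_name.startswith("HO"):  # HO2', HO5' sugar hydroxyls
        target = "O" + h_name[2:]
        return target if target in heavy_names else None
    rest = h_name[1:]
    candidates = [hv for hv in heavy_names if hv[1:] == rest]
    if not candidates and rest and rest[-1].isdigit():
        candidates = [hv for hv in heavy_names if hv[1:] == rest[:-1]]
    if len(candidates) == 1:
        return candidates[0]
    # prefer carbon when ambiguous (e.g. HD1 in residues with both CD1/ND1)
    carbons = [c for c in candidates if c.startswith("C")]
    if len(carbons) == 1:
        return carbons[0]
    return None
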