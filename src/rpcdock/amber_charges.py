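"""Embedded AMBER-style partial charges for heavy atoms.

Hydrogen-free PDB structures are the norm in docking, so each hydrogen's
charge is folded into its bonded heavy atom (united-atom style), and the
resulting per-residue totals are renormalised at load so every complete
residue carries exactly its formal charge: 0 for neutral amino acids,
+1 for LYS/ARG, -1 for ASP/GLU, and -1 per ribonucleotide (one
phosphate). The renormalisation spreads the small residual uniformly
over the residue's atoms, so chemistry (sign pattern, polar vs apolar
magnitudes) is preserved while totals are exact.
"""

from __future__ import annotations

from .structure_io import normalize_nt

__all__ = ["ChargeTable", "default_charge_table", "FORMAL_CHARGES"]

_BB = {"N": -0.15, "CA": 0.10, "C": 0.60, "O": -0.55}

_AA_SIDE = {
    "ALA": {"CB": 0.00},
    "ARG": {"CB": 0.00, "CG": 0.00, "CD": 0.12, "NE": -0.20, "CZ": 0.64,
            "NH1": 0.22, "NH2": 0.22},
    "ASN": {"CB": 0.00, "CG": 0.58, "OD1": -0.57, "ND2": -0.01},
    "ASP": {"CB": -0.10, "CG": 0.62, "OD1": -0.76, "OD2": -0.76},
    "CYS": {"CB": 0.05, "SG": -0.05},
    "GLN": {"CB": 0.00, "CG": 0.00, "CD": 0.58, "OE1": -0.57, "NE2": -0.01},
    "GLU": {"CB": 0.00, "CG": -0.10, "CD": 0.62, "OE1": -0.76, "OE2": -0.76},
    "GLY": {},
    "HIS": {"CB": 0.00, "CG": 0.10, "ND1": -0.25, "CD2": 0.12, "CE1": 0.28,
            "NE2": -0.25},
    "ILE": {"CB": 0.00, "CG1": 0.00, "CG2": 0.00, "CD1": 0.00},
    "LEU": {"CB": 0.00, "CG": 0.00, "CD1": 0.00, "CD2": 0.00},
    "LYS": {"CB": 0.00, "CG": 0.00, "CD": 0.00, "CE": 0.25, "NZ": 0.75},
    "MET": {"CB": 0.00, "CG": 0.05, "SD": -0.10, "CE": 0.05},
    "PHE": {"CB": 0.00, "CG": 0.00, "CD1": 0.00, "CD2": 0.00, "CE1": 0.00,
            "CE2": 0.00, "CZ": 0.00},
    "PRO": {"CB": 0.00, "CG": 0.00, "CD": 0.10},
    "SER": {"CB": 0.12, "OG": -0.12},
    "THR": {"CB": 0.15, "OG1": -0.15, "CG2": 0.00},
    "TRP": {"CB": 0.00, "CG": -0.05, "CD1": 0.10, "CD2": 0.00, "NE1": -0.20,
            "CE2": 0.15, "CE3": 0.00, "CZ2": 0.00, "CZ3": 0.00, "CH2": 0.00},
    "TYR": {"CB": 0.00, "CG": 0.00, "CD1": 0.00, "CD2": 0.00, "CE1": 0.00,
            "CE2": 0.00, "CZ": 0.15, "OH": -0.15},
    "VAL": {"CB": 0.00, "CG1": 0.00, "CG2": 0.00},
}

# Proline has no backbone NH; its N keeps a less negative folded charge.
_AA_BB_OVERRIDES = {"PRO": {"N": -0.05}}

_SUGAR_PHOSPHATE = {
    "P": 1.17, "OP1": -0.78, "OP2": -0.78, "O5'": -0.50, "C5'": 0.06,
    "C4'": 0.11, "O4'": -0.35, "C3'": 0.20, "O3'": -0.52, "C2'": 0.07,
    "O2'": -0.21, "C1'": 0.03,
}

_BASES = {
    "A": {"N9": -0.03, "C8": 0.25, "N7": -0.58, "C5": 0.05, "C6": 0.70,
          "N6": -0.46, "N1": -0.76, "C2": 0.40, "N3": -0.70},
    "G": {"N9": 0.05, "C8": 0.22, "N7": -0.57, "C5": 0.20, "C6": 0.48,
          "O6": -0.56, "N1": -0.25, "C2": 0.74, "N2": -0.51, "N3": -0.66},
    "C": {"N1": -0.05, "C2": 0.75, "O2": -0.63, "N3": -0.76, "C4": 0.82,
          "N4": -0.52, "C5": -0.30, "C6": 0.20},
    "U": {"N1": 0.04, "C2": 0.47, "O2": -0.55, "N3": -0.12, "C4": 0.59,
          "O4": -0.58, "C5": -0.25, "C6": 0.10},
}

FORMAL_CHARGES = {
    "ARG": 1.0, "LYS": 1.0, "ASP": -1.0, "GLU": -1.0,
    "A": -1.0, "U": -1.0, "G": -1.0, "C": -1.0,
}

_ATOM_ALIASES = {"O1P": "OP1", "O2P": "OP2", "OXT": None}


class ChargeTable:
    """Mapping (res_name, atom_name) -> partial charge, with PDB-name
    aliasing (RA/ADE -> A, O1P -> OP1, * -> ')."""

    def __init__(self, table: dict[str, dict[str, float]]):
        self._table = table

    def lookup(self, res_name: str, atom_name: str) -> float | None:
        res = res_name.strip().upper()
        nt = normalize_nt(res)
        if nt is not None:
            res = nt
        entry = self._table.get(res)
        if entry is None:
            return None
        name = atom_name.strip().upper().replace("*", "'")
        name = _ATOM_ALIASES.get(name, name)
        if name is None:
            return None
        return entry.get(name)

    def residue_total(self, res_name: str) -> float:
        res = res_name.strip().upper()
        nt = normalize_nt(res)
        if nt is not None:
            res = nt
        return sum(self._table[res].values())

    def residues(self):
        return list(self._table)


def _normalised(raw: dict[str, float], formal: float) -> dict[str, float]:
    residual = formal - sum(raw.values())
    shift = residual / len(raw)
    return {k: v + shift for k, v in raw.items()}


def default_charge_table() -> ChargeTable:
    table: dict[str, dict[str, float]] = {}
    for res, side in _AA_SIDE.items():
        raw = dict(_BB)
        raw.update(_AA_BB_OVERRIDES.get(res, {}))
        raw.update(side)
        table[res] = _normalised(raw, FORMAL_CHARGES.get(res, 0.0))
    for nt, base in _BASES.items():
        raw = dict(_SUGAR_PHOSPHATE)
        raw.update(base)
        table[nt] = _normalised(raw, FORMAL_CHARGES.get(nt, 0.0))
    return ChargeTable(table)
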