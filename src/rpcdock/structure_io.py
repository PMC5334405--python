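"""PDB coordinate I/O and basic structure manipulation.

Fixed-column PDB parsing/writing (ATOM/HETATM/TER/MODEL/ENDMDL), chain
selection by concatenated single-character IDs, molecule-type
classification, and partial-charge assignment from an embedded
AMBER-style table.

Only the first MODEL of multi-model files is read; alternate locations
are resolved to the highest-occupancy conformer (ties prefer blank or
'A'); HETATM waters and common monatomic ions are dropped.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "read_pdb",
    "write_pdb",
    "select_chains",
    "classify_molecule",
    "assign_charges",
    "STANDARD_AMINO_ACIDS",
    "STANDARD_NUCLEOTIDES",
]

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# RNA residue names as they appear in current and legacy PDB files.
_NT_ALIASES = {
    "A": "A", "U": "U", "G": "G", "C": "C",
    "RA": "A", "RU": "U", "RG": "G", "RC": "C",
    "ADE": "A", "URA": "U", "URI": "U", "GUA": "G", "CYT": "C",
}
STANDARD_NUCLEOTIDES = set(_NT_ALIASES)

PURINES = {"A", "G"}
PYRIMIDINES = {"U", "C"}

_WATER_AND_IONS = {
    "HOH", "WAT", "DOD", "NA", "CL", "K", "MG", "ZN", "MN", "FE", "CU",
    "CA2", "BR", "IOD", "CS", "LI", "NI", "CD", "SR", "BA",
}


def normalize_nt(res_name: str) -> str | None:
    """Canonical 1-letter ribonucleotide code, or None if not RNA."""
    return _NT_ALIASES.get(res_name.strip().upper())


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    charge: float = 0.0
    serial: int = 0
    occupancy: float = 1.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    res_name: str
    res_seq: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def res_id(self) -> str:
        return f"{self.res_seq}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    @property
    def is_amino_acid(self) -> bool:
        return self.res_name in STANDARD_AMINO_ACIDS

    @property
    def is_nucleotide(self) -> bool:
        return normalize_nt(self.res_name) is not None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def moltype(self) -> str:
        """protein | rna | other by the 90% majority rule."""
        if not self.residues:
            return "other"
        n = len(self.residues)
        n_aa = sum(r.is_amino_acid for r in self.residues)
        n_nt = sum(r.is_nucleotide for r in self.residues)
        if n_aa >= 0.9 * n:
            return "protein"
        if n_nt >= 0.9 * n:
            return "rna"
        return "other"

    def atoms(self):
        for r in self.residues:
            yield from r.atoms


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in {self.source!r}: {ids}")

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def atoms(self):
        for c in self.chains:
            yield from c.atoms()

    def coords(self) -> np.ndarray:
        pts = [a.coord for a in self.atoms()]
        if not pts:
            return np.zeros((0, 3))
        return np.array(pts)

    def set_coords(self, xyz: np.ndarray) -> None:
        for a, row in zip(self.atoms(), np.asarray(xyz, dtype=float), strict=True):
            a.coord = row.copy()

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


class PDBFormatError(ValueError):
    pass


def _guess_element(name: str, res_name: str) -> str:
    n = name.strip()
    if len(n) >= 2 and n[:2] in ("CL", "BR", "FE", "MG", "ZN", "MN", "NA") \
            and res_name.strip() in _WATER_AND_IONS:
        return n[:2].capitalize()
    for ch in n:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_pdb(path: str) -> Structure:
    """Parse a PDB file into a Structure (first model, best altlocs).

    Raises OSError on unreadable files and PDBFormatError when no ATOM
    record is present.
    """
    with open(path) as fh:
        lines = fh.readlines()

    # (chain, resseq, icode, atomname) -> list of (altloc, occupancy, record)
    records: list[dict] = []
    seen_first_model = False
    in_first_model = True
    for line in lines:
        rec = line[0:6]
        if rec == "MODEL ":
            if seen_first_model:
                in_first_model = False
            seen_first_model = True
            continue
        if rec == "ENDMDL":
            in_first_model = False
            continue
        if not in_first_model:
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        res_name = line[17:20].strip()
        if rec == "HETATM" and res_name in _WATER_AND_IONS:
            continue
        name = line[12:16].strip()
        if not name:
            continue
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(line[12:16], line[17:20])
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            serial = int(line[6:11]) if line[6:11].strip() else 0
            res_seq = int(line[22:26])
        except ValueError as exc:
            raise PDBFormatError(f"{path}: malformed coordinate record: {line.rstrip()!r}") from exc
        occ_field = line[54:60].strip() if len(line) >= 60 else ""
        occupancy = float(occ_field) if occ_field else 1.0
        records.append({
            "chain": line[21],
            "res_name": res_name,
            "res_seq": res_seq,
            "icode": line[26].strip(),
            "name": name,
            "altloc": line[16].strip(),
            "element": element.capitalize(),
            "coord": (x, y, z),
            "occupancy": occupancy,
            "serial": serial,
            "hydrogen": element.upper() in ("H", "D"),
        })

    if not records:
        raise PDBFormatError(f"{path}: no ATOM records found")

    # Resolve altlocs: highest occupancy wins; ties prefer blank then 'A'.
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for r in records:
        key = (r["chain"], r["res_seq"], r["icode"], r["name"])
        if key not in best:
            best[key] = r
            order.append(key)
        else:
            b = best[key]
            if (r["occupancy"], -_altloc_rank(r["altloc"])) > (b["occupancy"], -_altloc_rank(b["altloc"])):
                best[key] = r

    structure = Structure(source=path)
    chain_map: dict[str, Chain] = {}
    res_map: dict[tuple, Residue] = {}
    for key in order:
        r = best[key]
        cid = r["chain"] if r["chain"].strip() else " "
        if cid not in chain_map:
            chain_map[cid] = Chain(chain_id=cid)
            structure.chains.append(chain_map[cid])
        rkey = (cid, r["res_seq"], r["icode"], r["res_name"])
        if rkey not in res_map:
            res_map[rkey] = Residue(res_name=r["res_name"], res_seq=r["res_seq"], icode=r["icode"])
            chain_map[cid].residues.append(res_map[rkey])
        res_map[rkey].atoms.append(Atom(
            name=r["name"], element=r["element"], coord=np.array(r["coord"]),
            serial=r["serial"], occupancy=r["occupancy"],
        ))
    return structure


def _altloc_rank(altloc: str) -> int:
    if altloc in ("", " "):
        return 0
    return ord(altloc) - ord("A") + 1


def _format_atom_name(name: str, element: str) -> str:
    # 4-char names fill cols 13-16; shorter names of 1-char elements start at 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(s: Structure, path: str) -> None:
    """Write standard 80-column ATOM records, chain by chain with TER lines."""
    serial = 0
    out = []
    for chain in s.chains:
        for res in chain.residues:
            for a in res.atoms:
                serial += 1
                x, y, z = a.coord
                out.append(
                    "ATOM  {serial:>5d} {name:<4s}{alt}{res:<3s} {ch}{seq:>4d}{ic}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                        serial=serial % 100000,
                        name=_format_atom_name(a.name, a.element),
                        alt=" ",
                        res=res.res_name,
                        ch=chain.chain_id,
                        seq=res.res_seq,
                        ic=res.icode if res.icode else " ",
                        x=x, y=y, z=z,
                        occ=a.occupancy, b=0.0,
                        el=a.element[:2].upper(),
                    )
                )
        serial += 1
        out.append(f"TER   {serial % 100000:>5d}")
    out.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def select_chains(s: Structure, chain_ids: str) -> Structure:
    """Return a new Structure holding exactly the chains named in
    `chain_ids` (concatenated single characters, e.g. "CB"), in request
    order. Case-sensitive; raises KeyError naming any absent chain."""
    picked = []
    for cid in chain_ids:
        c = s.chain(cid)
        if c is None:
            raise KeyError(f"chain {cid} not found in {s.source or 'structure'}")
        picked.append(copy.deepcopy(c))
    return Structure(chains=picked, source=s.source)


def classify_molecule(s: Structure) -> str:
    """protein | rna | mixed by the 90% majority rule over all residues."""
    residues = [r for c in s.chains for r in c.residues]
    if not residues:
        raise ValueError("cannot classify an empty structure")
    n = len(residues)
    n_aa = sum(r.is_amino_acid for r in residues)
    n_nt = sum(r.is_nucleotide for r in residues)
    if n_aa >= 0.9 * n:
        return "protein"
    if n_nt >= 0.9 * n:
        return "rna"
    return "mixed"


def assign_charges(s: Structure, table=None) -> tuple[Structure, int]:
    """Set per-atom partial charges from a (res_name, atom_name) table.

    Returns (new structure, miss count). Atoms without a table entry get
    charge 0 and count as misses. Coordinates are untouched.
    """
    if table is None:
        from .amber_charges import default_charge_table
        table = default_charge_table()
    out = s.copy()
    misses = 0
    for chain in out.chains:
        for res in chain.residues:
            for a in res.atoms:
                q = table.lookup(res.res_name, a.name)
                if q is None:
                    a.charge = 0.0
                    misses += 1
                else:
                    a.charge = q
    return out, misses
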